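# Synthetic 10-gene, 21-edge benchmark network (skeleton; weights are
# placeholders — benchmark runs draw fresh weights per dataset).
# Constructed so that N6 is a root with seven descendants (admissible order
# positions 1-3) and N3 is a sink with all nine other genes as ancestors
# (admissible position 10 only); see docs/methods.md.
source	target	weight
N6	N4	1.0
N6	N9	1.0
N6	N5	1.0
N6	N2	1.0
N1	N2	1.0
N1	N5	1.0
N1	N8	1.0
N7	N10	1.0
N7	N8	1.0
N7	N4	1.0
N4	N2	1.0
N4	N10	1.0
N4	N3	1.0
N9	N8	1.0
N9	N10	1.0
N9	N3	1.0
N5	N2	1.0
N5	N3	1.0
N2	N3	1.0
N8	N3	1.0
N10	N3	1.0
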