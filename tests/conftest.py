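import numpy as np
import pytest

import ordercause as oc


@pytest.fixture(scope="session")
def bench_skeleton():
    return oc.benchmark_dag_skeleton()


@pytest.fixture()
def chain3():
    """3-gene chain 0 -> 1 -> 2 with a shortcut 0 -> 2."""
    W = np.zeros((3, 3))
    W[0, 1], W[1, 2], W[0, 2] = 0.8, -0.6, 0.3
    return oc.WeightedDag(labels=["g1", "g2", "g3"], W=W)


@pytest.fixture()
def chain3_params(chain3):
    return oc.GbnParams(dag=chain3, m=np.array([0.5, 0.5, 0.5]), sigma=np.array([0.1, 0.2, 0.15]))


def random_dag(p, rng, density=0.4):
    """Random acyclic weighted graph in a random node order."""
    perm = rng.permutation(p)
    W = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < density:
                W[perm[a], perm[b]] = rng.uniform(0.25, 1.0) * rng.choice([-1, 1])
    return oc.WeightedDag(labels=[f"v{i}" for i in range(p)], W=W)
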