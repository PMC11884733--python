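import numpy as np
import pytest

from tcrnp import Clone, GroupSpec, Repertoire


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_spec():
    """Two groups of 3 columns each."""
    return GroupSpec(names=["a", "b"], sizes=[3, 3])


@pytest.fixture
def schema_spec():
    """The 11-group / 70-column network property layout."""
    return GroupSpec(
        names=[f"g{i}" for i in range(11)],
        sizes=[6, 6, 6, 6, 7, 7, 6, 6, 7, 6, 7],
    )


def make_logistic_instance(rng, n=60, sizes=(3, 3), signal=(0.8, 0.0)):
    """Standardized X and a Bernoulli y with per-group effect sizes."""
    spec = GroupSpec(names=[f"g{i}" for i in range(len(sizes))], sizes=list(sizes))
    X = rng.standard_normal((n, spec.P))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.concatenate(
        [np.full(v, s) for v, s in zip(sizes, signal)]
    )
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(float)
    if y.min() == y.max():  # force both classes
        y[0], y[1] = 0.0, 1.0
    return X, y, spec


@pytest.fixture
def logistic_instance(rng):
    return make_logistic_instance(rng)


@pytest.fixture
def path_repertoire():
    """A-B-C path plus an isolated sequence: clusters {path}, singleton."""
    return Repertoire(
        patient_id="p1",
        clones=[
            Clone("CASSA", 5, 1),
            Clone("CASSB", 3, 2),   # dist 1 from CASSA and CASSC? no: CASSB~CASSC dist 1
            Clone("CBSSB", 2, 4),   # dist 1 from CASSB only
            Clone("WWWWWWWW", 7, 0),
        ],
    )
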