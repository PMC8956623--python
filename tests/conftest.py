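import numpy as np
import pytest

from connstats.io import CohortDataset, Subject, WeightedNetwork


def make_net(weights, labels=None):
    w = np.asarray(weights, dtype=float)
    if labels is None:
        labels = tuple(f"node_{i:03d}" for i in range(w.shape[0]))
    return WeightedNetwork(tuple(labels), w)


def random_net(rng, n, density=0.5, lo=0.2, hi=0.7):
    """Random symmetric non-negative weighted network for oracle tests."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.uniform(lo, hi, size=len(iu[0])) * present
    w[iu] = vals
    w += w.T
    return make_net(w)


def make_cohort(weight_list, groups, ages=None, sexes=None, clinical=None,
                control="HC"):
    """Cohort from raw weight matrices and per-subject attributes."""
    n_subj = len(weight_list)
    ages = ages if ages is not None else [30.0 + i for i in range(n_subj)]
    sexes = sexes if sexes is not None else [i % 2 for i in range(n_subj)]
    subjects = []
    for i, (w, g) in enumerate(zip(weight_list, groups)):
        clin = clinical[i] if clinical is not None else {}
        subjects.append(Subject(f"s{i:03d}", g, float(ages[i]),
                                int(sexes[i]), clin, make_net(w)))
    return CohortDataset(tuple(subjects), control_group=control)


@pytest.fixture
def path3():
    """Path 1-2-3 with both edge weights 0.5."""
    return make_net([[0, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0]])


@pytest.fixture
def triangle():
    """Complete 3-node network, all weights 0.5."""
    w = np.full((3, 3), 0.5)
    np.fill_diagonal(w, 0)
    return make_net(w)


@pytest.fixture
def k4_unit():
    """Complete 4-node network, all weights 1."""
    w = np.ones((4, 4))
    np.fill_diagonal(w, 0)
    return make_net(w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
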