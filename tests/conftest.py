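import numpy as np
import pytest

from stableconn import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_cohort():
    """Default clean synthetic cohort (300 subjects, 1770 edges, 20 planted)."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def contaminated_cohort():
    """Default cohort with outlier subjects and heteroscedastic trait noise."""
    return generate(SyntheticSpec(seed=1).contaminated())


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort (120 subjects, 435 edges) for CV-level tests."""
    spec = SyntheticSpec(n_subjects=120, n_nodes=30, n_signal_edges=10, seed=5)
    return generate(spec)


def brute_midranks(v):
    """Independent oracle: midranks by explicit sorting and tie grouping."""
    v = list(v)
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return np.array(ranks)


def brute_pearson(a, b):
    """Independent oracle: Pearson correlation by its definitional sums."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    sa, sb = sum(a), sum(b)
    saa = sum(x * x for x in a)
    sbb = sum(x * x for x in b)
    sab = sum(x * y for x, y in zip(a, b))
    num = n * sab - sa * sb
    den = ((n * saa - sa * sa) * (n * sbb - sb * sb)) ** 0.5
    return num / den if den else 0.0
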