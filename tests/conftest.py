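import numpy as np
import pytest

from ltcox import Dataset, SubjectRecord, calibrated_design, simulate_dataset

INF = float("inf")


@pytest.fixture(scope="session")
def table1_design():
    """Partly interval-censored design, uniform entry times."""
    return calibrated_design("partly_interval", "uniform")


@pytest.fixture(scope="session")
def small_pic_dataset(table1_design):
    """One simulated partly interval-censored dataset, n=50."""
    return simulate_dataset(table1_design, 50, seed=424242)


@pytest.fixture()
def two_point_dataset():
    """Minimal two-subject dataset from the grid-construction contract."""
    return Dataset([
        SubjectRecord("a", 0.2, 1, (0.0,), T=0.5),
        SubjectRecord("b", 0.1, 0, (0.0,), L=0.3, R=INF),
    ])


def make_right_censored(n, seed, p=1):
    """Right-censored-only sample with entry times, for EM unit tests."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        z = tuple(rng.binomial(1, 0.5, size=p).astype(float))
        g = np.exp(0.7 * sum(z))
        t = np.sqrt(rng.exponential() / g)
        a = rng.uniform(0, 0.8)
        if t < a:
            t = a + rng.uniform(0, 0.5)  # keep it simple: shift instead of reject
        if rng.uniform() < 0.3:
            c = a + rng.uniform(0, 1.0)
            if t > c:
                recs.append(SubjectRecord(i, a, 0, z, L=c, R=INF))
                continue
        recs.append(SubjectRecord(i, a, 1, z, T=t))
    return Dataset(recs)
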