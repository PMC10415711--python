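import numpy as np
import pandas as pd
import pytest

from granulediv import CommunityTable, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_table():
    """3 ASVs x 2 samples with column sums [10, 10]."""
    return CommunityTable(["A", "B", "C"], ["s1", "s2"],
                          np.array([[5, 0], [5, 5], [0, 5]]))


def make_random_table(seed, n_asvs=30, n_samples=8, depth=1500, sigma=1.5):
    """Lognormal-profile multinomial count table (all columns equal depth)."""
    r = np.random.default_rng(seed)
    base = r.lognormal(0.0, sigma, n_asvs)
    base /= base.sum()
    cols = []
    for _ in range(n_samples):
        p = base * np.exp(r.normal(0.0, 0.5, n_asvs))
        p /= p.sum()
        cols.append(r.multinomial(depth, p))
    return CommunityTable([f"ASV_{i + 1}" for i in range(n_asvs)],
                          [f"S{k + 1}" for k in range(n_samples)],
                          np.column_stack(cols))


@pytest.fixture
def random_table():
    return make_random_table(7)


@pytest.fixture
def small_tree():
    import granulediv
    return granulediv.read_newick("((A:1,B:1):1,C:2);")


def make_metadata(n_per_reactor=5, reactors=("R2", "R3"), step=7,
                  inoculum=True):
    rows = []
    if inoculum:
        rows.append({"sample_id": "inoc", "reactor": "R1", "day": 0,
                     "role": "inoculum"})
    for r in reactors:
        for k in range(n_per_reactor):
            rows.append({"sample_id": f"{r}_t{k}", "reactor": r,
                         "day": k * step, "role": "timepoint"})
    return pd.DataFrame(rows)


@pytest.fixture
def metadata():
    return make_metadata()


@pytest.fixture
def yule_tree():
    return simulate_tree(12, seed=5)
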