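import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import granulediv as gd
from granulediv.hill_diversity import dissimilarity_square


def random_composition(rng, n, sparse=False):
    p = rng.dirichlet(np.ones(n))
    if sparse:
        p[rng.random(n) < 0.3] = 0.0
        if p.sum() == 0:
            p[0] = 1.0
        p /= p.sum()
    return p


# ---------------------------------------------------------------------------
# Naive oracles, written directly from the closed-form definitions
# ---------------------------------------------------------------------------

def mid_entropy(p):
    p = p[p > 0]
    return -np.sum(p * np.log(p))


def naive_hill(p, q):
    p = [x for x in p if x > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x ** q for x in p) ** (1 / (1 - q))


def naive_qpd(p, d, q):
    """Total effective phylogenetic distance via explicit double sums."""
    n = len(p)
    rao = sum(d[i][j] * p[i] * p[j] for i in range(n) for j in range(n))
    if rao == 0:
        return 0.0
    if q == 1:
        expo = -0.5 * sum((d[i][j] / rao) * p[i] * p[j]
                          * math.log(p[i] * p[j])
                          for i in range(n) for j in range(n)
                          if p[i] > 0 and p[j] > 0)
        dq = math.exp(expo)
    else:
        s = sum((d[i][j] / rao) * (p[i] * p[j]) ** q
                for i in range(n) for j in range(n)
                if p[i] > 0 and p[j] > 0)
        dq = s ** (1 / (2 * (1 - q)))
    return dq * dq * rao


class TestTaxonomicAlpha:
    def test_richness_inverse_simpson_and_shannon(self):
        assert gd.taxonomic_alpha([0.25] * 4, 0) == pytest.approx(4)
        assert gd.taxonomic_alpha([0.5, 0.5], 2) == pytest.approx(2)
        expect = math.exp(-(0.8 * math.log(0.8) + 0.2 * math.log(0.2)))
        assert gd.taxonomic_alpha([0.8, 0.2], 1) == pytest.approx(expect,
                                                                  abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_composition(rng, 10, sparse=True)
        for q in (0, 0.5, 1, 2, 3):
            assert gd.taxonomic_alpha(p, q) == pytest.approx(
                naive_hill(p, q), rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_nonincreasing_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = random_composition(rng, 12)
        values = [gd.taxonomic_alpha(p, q) for q in (0, 0.5, 1, 1.5, 2, 3)]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_continuity_at_one(self, rng):
        """The analytic q=1 limit is bracketed by the q->1 formula values,
        with a relative gap below 1e-3 (the absolute gap scales with
        D * Var(ln p), so only a relative bound holds for arbitrary
        compositions)."""
        for _ in range(50):
            p = random_composition(rng, 15)
            lo = gd.taxonomic_alpha(p, 1.001)
            mid = gd.taxonomic_alpha(p, 1.0)
            hi = gd.taxonomic_alpha(p, 0.999)
            assert lo - 1e-12 <= mid <= hi + 1e-12
            # Taylor: |D(1+e) - D(1-e)| ~ e * D * Var_p(ln p)
            var_logp = np.average((np.log(p) + mid_entropy(p)) ** 2,
                                  weights=p)
            assert (hi - lo) <= 0.002 * mid * var_logp + 1e-6

    def test_replication_principle(self, rng):
        """Pooling two equal-weight copies on disjoint supports doubles qTD."""
        p = random_composition(rng, 6)
        pooled = np.concatenate([p / 2, p / 2])
        for q in (0, 1, 2):
            assert gd.taxonomic_alpha(pooled, q) == pytest.approx(
                2 * gd.taxonomic_alpha(p, q), rel=1e-10)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            gd.taxonomic_alpha([0.0, 0.0], 1)
        with pytest.raises(ValueError):
            gd.taxonomic_alpha([0.5, 0.2], 1)


class TestPhyloAlpha:
    def test_closed_forms(self):
        d2 = np.array([[0.0, 1.0], [1.0, 0.0]])
        for q in (0, 1, 2):
            assert gd.phylo_alpha([0.5, 0.5], d2, q) == pytest.approx(2.0)
        d4 = np.full((4, 4), 0.3)
        np.fill_diagonal(d4, 0.0)
        for q in (0, 1, 2):
            assert gd.phylo_alpha([0.25] * 4, d4, q) == pytest.approx(
                0.3 * 4 * 3, abs=1e-6)

    def test_single_asv_is_zero(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert gd.phylo_alpha([1.0, 0.0], d, 2) == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        p = random_composition(rng, n, sparse=True)
        d = rng.uniform(0.1, 2.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        for q in (0, 0.5, 1, 2):
            assert gd.phylo_alpha(p, d, q) == pytest.approx(
                naive_qpd(p, d.tolist(), q), abs=1e-9)


class TestTaxonomicDissimilarity:
    @pytest.mark.parametrize("q", [0, 1, 2])
    def test_identical_zero_disjoint_one(self, rng, q):
        p = random_composition(rng, 8)
        assert gd.taxonomic_dissimilarity(p, p, q) == pytest.approx(0, abs=1e-12)
        a = np.concatenate([p, np.zeros(8)])
        b = np.concatenate([np.zeros(8), p])
        assert gd.taxonomic_dissimilarity(a, b, q) == pytest.approx(1, abs=1e-12)

    def test_half_overlap_even_pair_q0(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.0, 0.5, 0.5])
        assert gd.taxonomic_dissimilarity(a, b, 0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_q0_local_is_sorensen(self, seed):
        """Presence/absence q=0 local overlap equals Sorensen dissimilarity."""
        rng = np.random.default_rng(seed)
        pres_a = rng.random(10) < 0.6
        pres_b = rng.random(10) < 0.6
        pres_a[0] = pres_b[1] = True
        a = pres_a / pres_a.sum()
        b = pres_b / pres_b.sum()
        shared = int((pres_a & pres_b).sum())
        sorensen = 1 - 2 * shared / (pres_a.sum() + pres_b.sum())
        assert gd.taxonomic_dissimilarity(a, b, 0) == pytest.approx(sorensen,
                                                                    abs=1e-12)

    def test_q0_regional_is_jaccard(self):
        a = np.array([0.5, 0.5, 0.0])
        b = np.array([0.0, 0.5, 0.5])
        jaccard = 1 - 1 / 3
        assert gd.taxonomic_dissimilarity(a, b, 0, variant="regional") == \
            pytest.approx(jaccard, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_composition(rng, 10, sparse=True)
        b = random_composition(rng, 10, sparse=True)
        for q in (0, 1, 2):
            d_ab = gd.taxonomic_dissimilarity(a, b, q)
            d_ba = gd.taxonomic_dissimilarity(b, a, q)
            assert 0.0 <= d_ab <= 1.0
            assert d_ab == pytest.approx(d_ba, abs=1e-12)


class TestPhyloDissimilarity:
    def test_identical_zero(self, rng):
        p = random_composition(rng, 6)
        d = rng.uniform(0.1, 1, (6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        for q in (0, 1, 2):
            assert gd.phylo_dissimilarity(p, p, d, q) == pytest.approx(0,
                                                                       abs=1e-12)

    def test_disjoint_singletons_one(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        for q in (0, 1, 2):
            assert gd.phylo_dissimilarity([1, 0], [0, 1], d, q) == \
                pytest.approx(1.0, abs=1e-12)

    def test_identical_singletons_q_zero_rao(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert gd.phylo_dissimilarity([1, 0], [1, 0], d, 2) == 0.0

    def test_disjoint_pairs_one_any_distances(self, rng):
        a = np.array([0.4, 0.6, 0.0, 0.0])
        b = np.array([0.0, 0.0, 0.3, 0.7])
        d = rng.uniform(0.2, 1.5, (4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        for q in (0, 1, 2):
            assert gd.phylo_dissimilarity(a, b, d, q) == pytest.approx(1.0,
                                                                       abs=1e-9)

    def test_equidistant_matches_taxonomic_at_q1_large_s(self, rng):
        """With equal off-diagonal distances the functional q=1 dissimilarity
        converges to the taxonomic one as richness grows (the two differ only
        through the excluded diagonal)."""
        n = 400
        a = rng.dirichlet(np.ones(n) * 5)
        b = rng.dirichlet(np.ones(n) * 5)
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0)
        t = gd.taxonomic_dissimilarity(a, b, 1)
        p = gd.phylo_dissimilarity(a, b, d, 1)
        assert abs(t - p) < 1e-3


class TestDissimilarityMatrix:
    def test_pair_count_and_consistency(self, random_table):
        sub = random_table.select_samples(random_table.sample_ids[:5])
        records = gd.dissimilarity_matrix(sub, orders=[0, 1, 2])
        assert len(records) == 10 * 3
        rel = sub.relative_abundances()
        idx = {s: i for i, s in enumerate(sub.sample_ids)}
        for rec in records.sample(10, random_state=0).itertuples():
            expect = gd.taxonomic_dissimilarity(rel[:, idx[rec.sample_a]],
                                                rel[:, idx[rec.sample_b]],
                                                rec.q)
            assert rec.value == pytest.approx(expect, abs=1e-12)

    def test_sample_order_invariance(self, random_table):
        fwd = gd.dissimilarity_matrix(random_table, orders=[1])
        rev = gd.dissimilarity_matrix(
            random_table.select_samples(random_table.sample_ids[::-1]),
            orders=[1])
        key = lambda df: {frozenset((a, b)): v for a, b, v in
                          zip(df.sample_a, df.sample_b, df.value)}
        f, r = key(fwd), key(rev)
        assert f.keys() == r.keys()
        assert all(f[k] == pytest.approx(r[k], abs=1e-12) for k in f)

    def test_requires_distances_for_phylo(self, random_table):
        with pytest.raises(ValueError):
            gd.dissimilarity_matrix(random_table, kind="phylogenetic")

    def test_square_view_roundtrip(self, random_table):
        records = gd.dissimilarity_matrix(random_table, orders=[1])
        square = dissimilarity_square(records, random_table.sample_ids, 1,
                                      "taxonomic")
        assert square.shape == (8, 8)
        assert np.allclose(square, square.T)
        assert np.all(np.diag(square) == 0)
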