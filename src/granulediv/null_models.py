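"""Null models for community assembly: Hill-based Raup-Crick and betaNTI.

Both statistics are standardized effect sizes (SES): the observed pairwise
turnover is compared with the mean and standard deviation of a null
distribution built by randomizing community structure while holding
sample-level properties fixed,

    SES = (observed - mean(null)) / sd(null)

|SES| < 2 is read as turnover indistinguishable from the null expectation
(stochastic assembly); SES < -2 means the two samples are more similar
(share more taxa / are phylogenetically closer) than expected by chance,
SES > 2 more different.

qRC (taxonomic): null community pairs are assembled from the regional
species pool preserving each observed sample's richness and read total;
the observed and null statistics are Hill-based dissimilarities of order q.

betaNTI (phylogenetic): the observed statistic is the abundance-weighted
beta mean nearest-taxon distance (betaMNTD); nulls shuffle ASV labels
across the tips of the regional-pool phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_io import CommunityTable, DistanceMatrix
from .hill_diversity import phylo_dissimilarity, taxonomic_dissimilarity
from .seeding import child_rng

__all__ = [
    "NullConfig",
    "SESResult",
    "assemble_null_sample",
    "assemble_null_pair",
    "raup_crick",
    "raup_crick_multi",
    "beta_mntd",
    "beta_nti",
    "ses_series",
]

WEIGHTINGS = ("frequency", "abundance", "frequency_x_abundance")
POOL_SCOPES = ("all_samples", "per_reactor")


@dataclass
class NullConfig:
    """Parameters shared by all SES null models."""

    n_randomizations: int = 999
    threshold: float = 2.0
    pool_scope: str = "all_samples"
    weighting: str = "frequency_x_abundance"
    seed: int = 0

    def __post_init__(self):
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.pool_scope not in POOL_SCOPES:
            raise ValueError(f"unknown pool_scope {self.pool_scope!r}")


@dataclass
class SESResult:
    """Observed statistic, null moments and standardized effect size."""

    sample_a: str
    sample_b: str
    statistic: str          # "qRC" or "betaNTI"
    q: float | None
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_randomizations: int
    threshold: float
    degenerate: bool = False
    significant: bool = field(init=False)
    direction: str = field(init=False)

    def __post_init__(self):
        if self.degenerate or not np.isfinite(self.ses):
            self.ses = float("nan")
            self.degenerate = True
            self.significant = False
            self.direction = "null"
            return
        self.significant = abs(self.ses) > self.threshold
        if self.ses < -self.threshold:
            self.direction = "less_than_chance"
        elif self.ses > self.threshold:
            self.direction = "greater_than_chance"
        else:
            self.direction = "null"


def _make_ses(sample_a, sample_b, statistic, q, observed, nulls,
              config: NullConfig) -> SESResult:
    nulls = np.asarray(nulls, dtype=float)
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if nulls.size > 1 else 0.0
    # a null distribution collapsed to numerical noise carries no signal
    degenerate = sd <= 1e-12 * max(1.0, abs(mean))
    ses = float("nan") if degenerate else (observed - mean) / sd
    return SESResult(str(sample_a), str(sample_b), statistic, q,
                     float(observed), mean, sd, ses,
                     int(nulls.size), config.threshold, degenerate)


# ---------------------------------------------------------------------------
# Raup-Crick (taxonomic turnover)
# ---------------------------------------------------------------------------

def _pool_weights(pool_counts: np.ndarray, weighting: str):
    """Occurrence frequencies and relative abundances of the regional pool."""
    freq = (pool_counts > 0).mean(axis=1)
    abund = pool_counts.sum(axis=1).astype(float)
    abund /= abund.sum()
    if weighting == "frequency":
        select = freq.copy()
    elif weighting == "abundance":
        select = abund.copy()
    else:
        select = freq * abund
    return select, abund


def assemble_null_sample(richness: int, total: int, select_w: np.ndarray,
                         abund_w: np.ndarray, rng: np.random.Generator
                         ) -> np.ndarray:
    """One null community: fixed richness and read total, pool-weighted.

    ASV identities are drawn without replacement with probability
    proportional to ``select_w``; reads are then allocated among the chosen
    ASVs (one guaranteed read each, the rest multinomially proportional to
    the pool relative abundances ``abund_w``).
    """
    candidates = np.flatnonzero(select_w > 0)
    if richness > candidates.size:
        raise ValueError(
            f"sample richness {richness} exceeds regional pool richness "
            f"{candidates.size}"
        )
    p = select_w[candidates] / select_w[candidates].sum()
    chosen = rng.choice(candidates, size=richness, replace=False, p=p)
    null = np.zeros(select_w.size, dtype=np.int64)
    null[chosen] = 1
    remaining = int(total) - int(richness)
    if remaining > 0:
        alloc_p = abund_w[chosen]
        alloc_p = alloc_p / alloc_p.sum()
        null[chosen] += rng.multinomial(remaining, alloc_p)
    return null


def assemble_null_pair(table: CommunityTable, pair, weighting: str,
                       rng: np.random.Generator, pool=None):
    """Null abundance pair preserving each sample's richness and total."""
    pool_tab = table if pool is None else table.select_samples(pool)
    select_w, abund_w = _pool_weights(pool_tab.counts, weighting)
    out = []
    for sid in pair:
        counts = table.sample_counts(sid)
        out.append(assemble_null_sample(int((counts > 0).sum()),
                                        int(counts.sum()),
                                        select_w, abund_w, rng))
    return tuple(out)


def _batch_taxonomic_dissimilarity(a: np.ndarray, b: np.ndarray, q: float,
                                   variant: str = "local") -> np.ndarray:
    """Row-wise Hill dissimilarity of proportion-matrix pairs (n x S each).

    Vectorized equivalent of hill_diversity.taxonomic_dissimilarity; used
    to score many null pairs at once.
    """
    from scipy.special import xlogy
    za, zb = a / 2.0, b / 2.0
    pooled = za + zb
    if q == 1.0:
        gamma = np.exp(-xlogy(pooled, pooled).sum(axis=1))
        alpha = 0.5 * np.exp(-(xlogy(za, za) + xlogy(zb, zb)).sum(axis=1))
        beta = np.clip(gamma / alpha, 1.0, 2.0)
        return np.log(beta) / np.log(2.0)
    gamma = np.where(pooled > 0, pooled, 1.0) ** q
    gamma = np.where(pooled > 0, gamma, 0.0).sum(axis=1) ** (1.0 / (1.0 - q))
    za_q = np.where(za > 0, np.where(za > 0, za, 1.0) ** q, 0.0)
    zb_q = np.where(zb > 0, np.where(zb > 0, zb, 1.0) ** q, 0.0)
    alpha = 0.5 * (za_q + zb_q).sum(axis=1) ** (1.0 / (1.0 - q))
    beta = np.clip(gamma / alpha, 1.0, 2.0)
    e = (1.0 - q) if variant == "local" else (q - 1.0)
    return np.clip((1.0 - beta ** e) / (1.0 - 2.0 ** e), 0.0, 1.0)


def raup_crick_multi(table: CommunityTable, pair, orders,
                     config: NullConfig, pool=None,
                     variant: str = "local") -> list[SESResult]:
    """qRC for several diversity orders, sharing one set of null pairs.

    The null-pair assembly does not depend on q, so all orders are scored
    against the same ``n_randomizations`` assembled pairs.
    """
    sample_a, sample_b = pair
    pool_tab = table if pool is None else table.select_samples(pool)
    select_w, abund_w = _pool_weights(pool_tab.counts, config.weighting)
    ca = table.sample_counts(sample_a)
    cb = table.sample_counts(sample_b)
    pa, pb = ca / ca.sum(), cb / cb.sum()
    orders = [float(q) for q in orders]
    observed = {q: taxonomic_dissimilarity(pa, pb, q, variant) for q in orders}
    rng = child_rng(config.seed, "raup_crick", sample_a, sample_b)
    n_it = config.n_randomizations
    na = np.empty((n_it, table.n_asvs))
    nb = np.empty((n_it, table.n_asvs))
    for it in range(n_it):
        na[it] = assemble_null_sample(int((ca > 0).sum()), int(ca.sum()),
                                      select_w, abund_w, rng)
        nb[it] = assemble_null_sample(int((cb > 0).sum()), int(cb.sum()),
                                      select_w, abund_w, rng)
    na /= na.sum(axis=1, keepdims=True)
    nb /= nb.sum(axis=1, keepdims=True)
    nulls = {q: _batch_taxonomic_dissimilarity(na, nb, q, variant)
             for q in orders}
    return [_make_ses(sample_a, sample_b, "qRC", q, observed[q], nulls[q],
                      config) for q in orders]


def raup_crick(table: CommunityTable, pair, q: float, config: NullConfig,
               pool=None, variant: str = "local") -> SESResult:
    """Hill-based Raup-Crick SES for one sample pair at one order q."""
    return raup_crick_multi(table, pair, [q], config, pool, variant)[0]


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI (phylogenetic turnover)
# ---------------------------------------------------------------------------

def beta_mntd(abund_a, abund_b, distances, weighted: bool = True) -> float:
    """Abundance-weighted beta mean nearest-taxon distance.

    betaMNTD = 1/2 [ sum_i p_i^A min_{j in B} d(i,j)
                   + sum_j p_j^B min_{i in A} d(j,i) ]

    ASVs present in both samples contribute nearest-taxon distance 0
    (self-match allowed).  ``weighted=False`` replaces abundances with
    equal weights over each sample's present ASVs.
    """
    pa = np.asarray(abund_a, dtype=float)
    pb = np.asarray(abund_b, dtype=float)
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(
        distances, dtype=float)
    ia, ib = np.flatnonzero(pa > 0), np.flatnonzero(pb > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("empty community in betaMNTD")
    sub = d[np.ix_(ia, ib)]
    min_a = sub.min(axis=1)          # nearest taxon in B for each ASV of A
    min_b = sub.min(axis=0)          # nearest taxon in A for each ASV of B
    if weighted:
        wa = pa[ia] / pa[ia].sum()
        wb = pb[ib] / pb[ib].sum()
    else:
        wa = np.full(ia.size, 1.0 / ia.size)
        wb = np.full(ib.size, 1.0 / ib.size)
    return float(0.5 * (wa @ min_a + wb @ min_b))


def beta_nti(table: CommunityTable, distances: DistanceMatrix, pair,
             config: NullConfig, pool=None, weighted: bool = True
             ) -> SESResult:
    """betaNTI: SES of betaMNTD under tip-label shuffling.

    Each of the ``n_randomizations`` iterations draws one permutation of
    ASV labels across the tips of the regional-pool phylogeny (only tips
    occurring in the pool are shuffled) and applies it to both samples.
    """
    sample_a, sample_b = pair
    pool_tab = table if pool is None else table.select_samples(pool)
    pool_asvs = [a for a, present in
                 zip(table.asv_ids, pool_tab.counts.sum(axis=1) > 0) if present]
    d = distances.array_for(pool_asvs)
    index = {a: i for i, a in enumerate(table.asv_ids)}
    pool_idx = np.array([index[a] for a in pool_asvs])
    pa_full = table.sample_counts(sample_a).astype(float)
    pb_full = table.sample_counts(sample_b).astype(float)
    outside = np.setdiff1d(np.flatnonzero((pa_full > 0) | (pb_full > 0)),
                           pool_idx)
    if outside.size:
        bad = [table.asv_ids[i] for i in outside]
        raise ValueError(f"pair ASVs outside the regional pool: {bad}")
    pa = pa_full[pool_idx] / pa_full.sum()
    pb = pb_full[pool_idx] / pb_full.sum()
    observed = beta_mntd(pa, pb, d, weighted)
    rng = child_rng(config.seed, "beta_nti", sample_a, sample_b)
    nulls = np.empty(config.n_randomizations)
    n_pool = len(pool_asvs)
    for it in range(config.n_randomizations):
        perm = rng.permutation(n_pool)
        nulls[it] = beta_mntd(pa[perm], pb[perm], d, weighted)
    return _make_ses(sample_a, sample_b, "betaNTI", None, observed, nulls,
                     config)


# ---------------------------------------------------------------------------
# Series driver
# ---------------------------------------------------------------------------

def ses_series(table: CommunityTable, series: pd.DataFrame, statistic: str,
               config: NullConfig, orders=None,
               distances: DistanceMatrix | None = None, pool=None,
               variant: str = "local") -> pd.DataFrame:
    """One SESResult per pair of a comparison series, as a long DataFrame.

    ``series`` is a frame with sample_a / sample_b columns (see
    succession.build_series); extra columns (kind, delta_days, reactor)
    are carried through to the output.
    """
    if statistic not in ("qRC", "betaNTI"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "qRC" and not orders:
        raise ValueError("qRC requires diversity orders")
    if statistic == "betaNTI" and distances is None:
        raise ValueError("betaNTI requires a distance matrix")
    rows = []
    carried = [c for c in series.columns if c not in ("sample_a", "sample_b")]
    for rec in series.itertuples(index=False):
        pair = (rec.sample_a, rec.sample_b)
        if statistic == "qRC":
            results = raup_crick_multi(table, pair, orders, config, pool,
                                       variant)
        else:
            results = [beta_nti(table, distances, pair, config, pool)]
        for res in results:
            row = {c: getattr(rec, c) for c in carried}
            row.update({
                "sample_a": res.sample_a, "sample_b": res.sample_b,
                "statistic": res.statistic,
                "q": float("nan") if res.q is None else res.q,
                "observed": res.observed, "null_mean": res.null_mean,
                "null_sd": res.null_sd, "ses": res.ses,
                "significant": res.significant, "direction": res.direction,
                "degenerate": res.degenerate,
                "n_randomizations": res.n_randomizations,
            })
            rows.append(row)
    return pd.DataFrame(rows)
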