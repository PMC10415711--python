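"""Successional comparison series, time-decay rates and PERMANOVA.

The reactor experiment is a time series: two replicate reactors sampled
repeatedly after a shared inoculum.  This module builds the three pair
series the analysis uses (successive time points within a reactor,
matched days between reactors, every time point versus the inoculum),
fits time-decay rates (slope of log community similarity against the
time separating a sample pair), and tests group differences with a
permutational multivariate ANOVA (PERMANOVA) on a dissimilarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .seeding import child_rng

__all__ = [
    "build_series",
    "TimeDecayFit",
    "time_decay_rate",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
]

SERIES_KINDS = ("successive", "between_reactor", "vs_inoculum")


def _timepoints(metadata: pd.DataFrame) -> pd.DataFrame:
    tp = metadata[metadata["role"] != "inoculum"] if "role" in metadata else metadata
    return tp.sort_values(["reactor", "day", "sample_id"]).reset_index(drop=True)


def build_series(metadata: pd.DataFrame, kind: str,
                 reactor: str | None = None) -> pd.DataFrame:
    """Deterministic comparison series from the sample metadata.

    Returns a frame with columns kind, reactor, sample_a, sample_b,
    delta_days.  ``successive`` pairs adjacent time points within each
    reactor (or only ``reactor`` if given); ``between_reactor`` pairs
    equal days across each reactor pair; ``vs_inoculum`` pairs every time
    point with the unique inoculum sample.
    """
    if kind not in SERIES_KINDS:
        raise ValueError(f"unknown series kind {kind!r}")
    tp = _timepoints(metadata)
    if reactor is not None:
        tp = tp[tp["reactor"] == reactor]
    rows = []
    if kind == "successive":
        for r, grp in tp.groupby("reactor", sort=True):
            grp = grp.sort_values(["day", "sample_id"])
            if len(grp) < 2:
                raise ValueError(
                    f"reactor {r}: need >= 2 time points for a successive series"
                )
            ids, days = grp["sample_id"].tolist(), grp["day"].tolist()
            for a, b, da, db in zip(ids, ids[1:], days, days[1:]):
                rows.append({"kind": kind, "reactor": r, "sample_a": a,
                             "sample_b": b, "delta_days": db - da})
    elif kind == "between_reactor":
        reactors = sorted(tp["reactor"].unique())
        for ra, rb in combinations(reactors, 2):
            a_by_day = tp[tp["reactor"] == ra].groupby("day")["sample_id"].first()
            b_by_day = tp[tp["reactor"] == rb].groupby("day")["sample_id"].first()
            for day in sorted(set(a_by_day.index) & set(b_by_day.index)):
                rows.append({"kind": kind, "reactor": f"{ra}|{rb}",
                             "sample_a": a_by_day[day], "sample_b": b_by_day[day],
                             "delta_days": 0, "day": day})
    else:  # vs_inoculum
        if "role" not in metadata.columns:
            raise ValueError("vs_inoculum series requires a role column")
        inoc = metadata[metadata["role"] == "inoculum"]
        if len(inoc) != 1:
            raise ValueError(
                f"vs_inoculum series requires exactly one inoculum sample, "
                f"found {len(inoc)}"
            )
        inoc_id = inoc["sample_id"].iloc[0]
        for rec in tp.itertuples(index=False):
            rows.append({"kind": kind, "reactor": rec.reactor,
                         "sample_a": inoc_id, "sample_b": rec.sample_id,
                         "delta_days": int(rec.day)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time decay
# ---------------------------------------------------------------------------

@dataclass
class TimeDecayFit:
    """OLS fit of ln(similarity) on the day separation of sample pairs."""

    reactor: str
    q: float
    kind: str
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_pairs: int
    n_dropped: int


def time_decay_rate(dissimilarities: pd.DataFrame, metadata: pd.DataFrame,
                    reactor: str, q: float, kind: str = "taxonomic",
                    day_range: tuple[int, int] | None = None) -> TimeDecayFit:
    """Time-decay rate of community similarity within one reactor.

    Every within-reactor pair of time points (optionally restricted to
    ``day_range``, inclusive) contributes a point (delta_days,
    ln(1 - dissimilarity)); the decay rate is the OLS slope (natural log,
    per day).  Pairs with similarity <= 0 are dropped and counted.
    """
    tp = _timepoints(metadata)
    tp = tp[tp["reactor"] == reactor]
    if day_range is not None:
        lo, hi = day_range
        tp = tp[(tp["day"] >= lo) & (tp["day"] <= hi)]
    day_of = dict(zip(tp["sample_id"], tp["day"]))
    sub = dissimilarities[
        (dissimilarities["q"] == float(q))
        & (dissimilarities["kind"] == kind)
        & dissimilarities["sample_a"].isin(day_of)
        & dissimilarities["sample_b"].isin(day_of)
    ]
    dt = np.array([abs(day_of[a] - day_of[b])
                   for a, b in zip(sub["sample_a"], sub["sample_b"])])
    sim = 1.0 - sub["value"].to_numpy(dtype=float)
    keep = dt > 0
    dt, sim = dt[keep], sim[keep]
    positive = sim > 0
    n_dropped = int((~positive).sum())
    dt, sim = dt[positive], sim[positive]
    if dt.size < 2:
        raise ValueError(
            f"reactor {reactor}, q={q}: fewer than 2 usable pairs for the "
            f"time-decay fit"
        )
    if np.ptp(dt) == 0:
        raise ValueError("all pairs share the same day separation")
    log_sim = np.log(sim)
    if np.ptp(log_sim) == 0.0:
        # constant similarity: zero slope, no evidence against it
        return TimeDecayFit(reactor=str(reactor), q=float(q), kind=kind,
                            slope=0.0, intercept=float(log_sim[0]),
                            p_value=1.0, r_squared=0.0,
                            n_pairs=int(dt.size), n_dropped=n_dropped)
    fit = stats.linregress(dt, log_sim)
    return TimeDecayFit(reactor=str(reactor), q=float(q), kind=kind,
                        slope=float(fit.slope), intercept=float(fit.intercept),
                        p_value=float(fit.pvalue),
                        r_squared=float(fit.rvalue ** 2),
                        n_pairs=int(dt.size), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Pseudo-F and permutation p-value for a grouping of samples."""

    grouping: str
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _group_indices(labels: np.ndarray):
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _pseudo_f(sq: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from squared dissimilarities (Gower-centred partition)."""
    n = sq.shape[0]
    groups = _group_indices(labels)
    a = len(groups)
    ss_total = sq.sum() / (2.0 * n)
    ss_within = sum(sq[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
                    for idx in groups)
    ss_among = ss_total - ss_within
    if ss_within == 0.0:
        return np.inf
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dissimilarity: np.ndarray, groups, n_permutations: int = 999,
              seed: int = 0, label: str | None = None) -> PermanovaResult:
    """One-way PERMANOVA on a square symmetric dissimilarity matrix.

    p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1) under random
    relabeling of the samples.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("dissimilarity must be a square symmetric matrix")
    labels = np.asarray([str(g) for g in groups])
    if labels.size != n:
        raise ValueError("one group label per sample required")
    sizes = [idx.size for idx in _group_indices(labels)]
    if len(sizes) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if min(sizes) < 2:
        raise ValueError("every group needs >= 2 members")
    sq = d ** 2
    f_obs = _pseudo_f(sq, labels)
    rng = child_rng(seed, "permanova", label or "|".join(np.unique(labels)))
    hits = 0
    for _ in range(n_permutations):
        if _pseudo_f(sq, labels[rng.permutation(n)]) >= f_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(grouping=label or "|".join(np.unique(labels)),
                           pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=int(n_permutations),
                           n_samples=int(n), n_groups=len(sizes))


def pairwise_permanova(dissimilarity: np.ndarray, groups,
                       n_permutations: int = 999, seed: int = 0,
                       adjust: str | None = None) -> pd.DataFrame:
    """PERMANOVA for every pair of groups (raw p-values by default).

    ``adjust="bh"`` appends Benjamini-Hochberg adjusted p-values.
    """
    labels = np.asarray([str(g) for g in groups])
    d = np.asarray(dissimilarity, dtype=float)
    rows = []
    for ga, gb in combinations(sorted(np.unique(labels)), 2):
        idx = np.flatnonzero((labels == ga) | (labels == gb))
        res = permanova(d[np.ix_(idx, idx)], labels[idx],
                        n_permutations=n_permutations, seed=seed,
                        label=f"{ga}|{gb}")
        rows.append({"group_a": ga, "group_b": gb, "pseudo_F": res.pseudo_f,
                     "p_value": res.p_value,
                     "n_permutations": res.n_permutations})
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        out["p_adjusted"] = stats.false_discovery_control(
            out["p_value"].to_numpy(), method="bh")
    elif adjust not in (None, "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out
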