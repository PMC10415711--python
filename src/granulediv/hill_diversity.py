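"""Hill-number taxonomic and phylogenetic diversity, alpha and beta.

Taxonomic alpha-diversity of order q is the Hill number

    qTD = (sum_i p_i^q)^(1/(1-q)),   q != 1
    1TD = exp(-sum_i p_i ln p_i)     (the q -> 1 limit)

an "effective number of ASVs": q = 0 counts every ASV equally (richness),
q = 1 weights by abundance (exp Shannon, the "common" ASVs), q = 2
emphasises dominants (inverse Simpson, the "abundant" ASVs).

Phylogenetic alpha-diversity uses the distance-based (functional) Hill
framework: with pairwise tip distances d_ij and Rao quadratic entropy
Q = sum_ij d_ij p_i p_j, the functional Hill number of order q is

    qD(Q) = (sum_ij (d_ij / Q) (p_i p_j)^q)^(1/(2(1-q)))

and the total effective phylogenetic distance reported here is

    qPD = qD(Q)^2 * Q

i.e. the summed distance of an idealised community of qD(Q) equally
abundant, mutually equidistant elements.

Beta-diversity of a sample pair is gamma/alpha of the evenly pooled pair
(beta in [1, 2]); it is mapped to a dissimilarity in [0, 1] with the
two-sample overlap transform (local C_qN variant by default, regional
U_qN optional; the functional versions use the doubled exponent 2(1-q)).
0 means identical samples, 1 means no shared ASVs (taxonomic) or no
shared effective distance (phylogenetic).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .community_io import CommunityTable, DistanceMatrix

__all__ = [
    "taxonomic_alpha",
    "phylo_alpha",
    "taxonomic_dissimilarity",
    "phylo_dissimilarity",
    "alpha_table",
    "dissimilarity_matrix",
    "dissimilarity_square",
    "DEFAULT_ORDERS",
]

#: Diversity orders computed by default throughout the pipeline.
DEFAULT_ORDERS = (0.0, 1.0, 2.0)

_VARIANTS = ("local", "regional")


def _clean_proportions(p, name="abundances") -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be finite and nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError(f"{name} sum to zero")
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total})")
    return p


def taxonomic_alpha(abundances, q: float) -> float:
    """Hill number qTD of a single proportion vector."""
    p = _clean_proportions(abundances)
    p = p[p > 0]
    q = float(q)
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def _distance_array(distances, n: int) -> np.ndarray:
    d = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(
        distances, dtype=float)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
    return d


def _functional_hill(a: np.ndarray, pp: np.ndarray, q: float) -> float:
    """qD(Q) given a = d_ij/Q and the joint weights pp_ij (sum a*pp = 1)."""
    mask = pp > 0
    if q == 1.0:
        return float(np.exp(-0.5 * np.sum(a[mask] * pp[mask] * np.log(pp[mask]))))
    return float(np.sum(a[mask] * pp[mask] ** q) ** (1.0 / (2.0 * (1.0 - q))))


def phylo_alpha(abundances, distances, q: float) -> float:
    """Total effective phylogenetic distance qPD of one sample.

    A community of S equally abundant, mutually equidistant (distance d)
    ASVs has qPD = d * S * (S - 1) for every q.  A single-ASV community
    has Q = 0 and qPD is defined as 0.
    """
    p = _clean_proportions(abundances)
    d = _distance_array(distances, p.size)
    q = float(q)
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    keep = p > 0
    p, d = p[keep], d[np.ix_(keep, keep)]
    rao = float(p @ d @ p)
    if rao <= 0.0:
        return 0.0
    dq = _functional_hill(d / rao, np.outer(p, p), q)
    return dq * dq * rao


def _overlap_dissimilarity(beta: float, q: float, variant: str,
                           exponent_scale: float) -> float:
    """Map beta in [1, N] (N = 2 samples) to a [0, 1] dissimilarity.

    local (C_qN-type):    (1 - beta^(m(1-q))) / (1 - N^(m(1-q)))
    regional (U_qN-type): (1 - beta^(m(q-1))) / (1 - N^(m(q-1)))

    with m = 1 for taxonomic and m = 2 for functional beta; both variants
    share the q = 1 limit ln(beta)/ln(N).
    """
    n = 2.0
    beta = min(max(beta, 1.0), n)
    if q == 1.0:
        val = np.log(beta) / np.log(n)
    else:
        e = exponent_scale * (1.0 - q) if variant == "local" else \
            exponent_scale * (q - 1.0)
        val = (1.0 - beta ** e) / (1.0 - n ** e)
    return float(min(max(val, 0.0), 1.0))


def _check_pair(abund_a, abund_b, variant):
    if variant not in _VARIANTS:
        raise ValueError(f"unknown overlap variant {variant!r}")
    pa = _clean_proportions(abund_a, "abund_a")
    pb = _clean_proportions(abund_b, "abund_b")
    if pa.size != pb.size:
        raise ValueError("abundance vectors use different ASV universes")
    keep = (pa > 0) | (pb > 0)
    return pa, pb, keep


def taxonomic_dissimilarity(abund_a, abund_b, q: float,
                            variant: str = "local") -> float:
    """Hill-based taxonomic dissimilarity of a sample pair, in [0, 1].

    gamma is the Hill diversity of the evenly pooled pair, alpha the
    Chiu-Chao mean within-sample diversity; beta = gamma/alpha in [1, 2]
    is normalised with the two-sample overlap transform.
    """
    pa, pb, keep = _check_pair(abund_a, abund_b, variant)
    pa, pb = pa[keep], pb[keep]
    q = float(q)
    za, zb = pa / 2.0, pb / 2.0
    pooled = za + zb
    gamma = taxonomic_alpha(pooled, q)
    z = np.concatenate([za[za > 0], zb[zb > 0]])
    if q == 1.0:
        alpha = 0.5 * np.exp(-np.sum(z * np.log(z)))
    else:
        alpha = 0.5 * np.sum(z ** q) ** (1.0 / (1.0 - q))
    return _overlap_dissimilarity(gamma / alpha, q, variant, exponent_scale=1.0)


def _pow0(v: np.ndarray, q: float) -> np.ndarray:
    """v**q with the 0^q := 0 convention (also at q = 0)."""
    out = np.zeros_like(v)
    pos = v > 0
    out[pos] = v[pos] ** q
    return out


def phylo_dissimilarity(abund_a, abund_b, distances, q: float,
                        variant: str = "local") -> float:
    """Distance-based (functional) dissimilarity of a sample pair, in [0, 1].

    Functional beta of the evenly pooled pair, normalised with the
    two-sample overlap transform at the doubled exponent 2(1-q).  A pooled
    pair with Rao Q = 0 (e.g. two identical single-ASV samples) is defined
    to have dissimilarity 0.
    """
    pa, pb, keep = _check_pair(abund_a, abund_b, variant)
    d = _distance_array(distances, pa.size)[np.ix_(keep, keep)]
    pa, pb = pa[keep], pb[keep]
    q = float(q)
    pooled = (pa + pb) / 2.0
    rao = float(pooled @ d @ pooled)
    if rao <= 0.0:
        return 0.0
    a = d / rao
    gamma = _functional_hill(a, np.outer(pooled, pooled), q)
    za, zb = pa / 2.0, pb / 2.0
    if q == 1.0:
        ell = np.zeros_like(za)
        for z in (za, zb):
            pos = z > 0
            ell[pos] += z[pos] * np.log(z[pos])
        alpha = 0.5 * np.exp(-(ell @ a @ pooled))
    else:
        w = _pow0(za, q) + _pow0(zb, q)
        alpha = 0.5 * float(w @ a @ w) ** (1.0 / (2.0 * (1.0 - q)))
    return _overlap_dissimilarity(gamma / alpha, q, variant, exponent_scale=2.0)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

def alpha_table(table: CommunityTable, orders=DEFAULT_ORDERS,
                distances: DistanceMatrix | None = None) -> pd.DataFrame:
    """Per-sample alpha diversities: columns sample_id, q, qTD[, qPD]."""
    rel = table.relative_abundances()
    d = distances.array_for(table.asv_ids) if distances is not None else None
    rows = []
    for j, sid in enumerate(table.sample_ids):
        p = rel[:, j]
        for q in orders:
            row = {"sample_id": sid, "q": float(q),
                   "qTD": taxonomic_alpha(p, q)}
            if d is not None:
                row["qPD"] = phylo_alpha(p, d, q)
            rows.append(row)
    return pd.DataFrame(rows)


def dissimilarity_matrix(table: CommunityTable, orders=DEFAULT_ORDERS,
                         kind: str = "taxonomic",
                         distances: DistanceMatrix | None = None,
                         variant: str = "local") -> pd.DataFrame:
    """All unordered sample-pair dissimilarities, long format.

    Columns: sample_a, sample_b, q, kind, value.
    """
    if kind not in ("taxonomic", "phylogenetic"):
        raise ValueError(f"unknown dissimilarity kind {kind!r}")
    if kind == "phylogenetic" and distances is None:
        raise ValueError("phylogenetic dissimilarity requires a distance matrix")
    rel = table.relative_abundances()
    d = distances.array_for(table.asv_ids) if kind == "phylogenetic" else None
    rows = []
    for i, j in combinations(range(table.n_samples), 2):
        pa, pb = rel[:, i], rel[:, j]
        for q in orders:
            if kind == "taxonomic":
                value = taxonomic_dissimilarity(pa, pb, q, variant)
            else:
                value = phylo_dissimilarity(pa, pb, d, q, variant)
            rows.append({"sample_a": table.sample_ids[i],
                         "sample_b": table.sample_ids[j],
                         "q": float(q), "kind": kind, "value": value})
    return pd.DataFrame(rows)


def dissimilarity_square(records: pd.DataFrame, sample_ids, q: float,
                         kind: str) -> np.ndarray:
    """Square symmetric matrix view of long-format dissimilarity records."""
    sample_ids = [str(s) for s in sample_ids]
    index = {s: i for i, s in enumerate(sample_ids)}
    sub = records[(records["q"] == float(q)) & (records["kind"] == kind)]
    n = len(sample_ids)
    mat = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    for a, b, v in zip(sub["sample_a"], sub["sample_b"], sub["value"]):
        if a in index and b in index:
            i, j = index[a], index[b]
            mat[i, j] = mat[j, i] = v
            seen[i, j] = seen[j, i] = True
    np.fill_diagonal(seen, True)
    if not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise KeyError(
            f"missing dissimilarity for pair ({sample_ids[i]}, {sample_ids[j]})"
        )
    return mat
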