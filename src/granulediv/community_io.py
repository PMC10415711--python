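"""Count tables, sample metadata and phylogenies: the data model of the pipeline.

An amplicon study's downstream product is an ASV-by-sample table of read
counts, a metadata table placing each sample on a reactor/day grid, and a
rooted phylogeny covering the ASVs.  This module reads and validates those
three inputs, provides rarefaction (without-replacement subsampling to a
common depth) and relative-abundance views, and computes patristic
(branch-length path sum) distance matrices from the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .seeding import child_rng

logger = logging.getLogger("granulediv")

__all__ = [
    "CommunityTable",
    "DistanceMatrix",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_newick",
    "patristic_distances",
    "rarefy",
    "relative_abundances",
    "DEFAULT_RAREFACTION_DEPTH",
]

#: Default subsampling depth (reads per sample) applied before any
#: diversity computation.
DEFAULT_RAREFACTION_DEPTH = 70492

METADATA_COLUMNS = ("sample_id", "reactor", "day")
ROLE_VALUES = ("inoculum", "timepoint")


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CommunityTable:
    """ASV x sample matrix of nonnegative integer read counts.

    Rows are ASVs, columns are samples.  Every statistic in the package is
    computed on (a rarefied view of) one of these.
    """

    asv_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.asv_ids = [str(a) for a in self.asv_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise TableFormatError("duplicate ASV ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableFormatError("duplicate sample ids")
        if counts.size == 0:
            raise TableFormatError("empty count table")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))
                i, j = (bad[0] if len(bad) else (0, 0))
                raise TableFormatError(
                    f"non-integer count at ASV {self.asv_ids[int(i)]!r}, "
                    f"sample {self.sample_ids[int(j)]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise TableFormatError(
                f"negative count at ASV {self.asv_ids[int(i)]!r}, "
                f"sample {self.sample_ids[int(j)]!r}"
            )
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise TableFormatError(f"samples with no reads: {empty}")
        self.counts = counts.astype(np.int64)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(str(sample_id))
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def relative_abundances(self) -> np.ndarray:
        """Proportion matrix; every column sums to 1 (within 1e-12)."""
        return relative_abundances(self)

    def sample_relative(self, sample_id: str) -> np.ndarray:
        c = self.sample_counts(sample_id)
        return c / c.sum()

    def select_samples(self, sample_ids) -> "CommunityTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CommunityTable(list(self.asv_ids), [self.sample_ids[i] for i in idx],
                              self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.asv_ids, name="asv_id"),
                            columns=self.sample_ids)


@dataclass
class DistanceMatrix:
    """Square symmetric nonnegative distance matrix with a zero diagonal."""

    ids: list
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite distances")
        if np.any(v < 0):
            raise ValueError("negative distances")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric within 1e-9")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        self._index = {a: i for i, a in enumerate(self.ids)}

    def submatrix(self, ids) -> "DistanceMatrix":
        try:
            idx = [self._index[str(i)] for i in ids]
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in distance matrix") from None
        return DistanceMatrix([str(i) for i in ids], self.values[np.ix_(idx, idx)])

    def array_for(self, ids) -> np.ndarray:
        """Distance submatrix as a plain array ordered like ``ids``."""
        return self.submatrix(ids).values


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

def read_counts(path, metadata: pd.DataFrame | None = None,
                orientation: str = "auto") -> CommunityTable:
    """Read a TSV count table (first column = ASV id, header = sample ids).

    ``orientation`` may be ``"asv_rows"``, ``"sample_rows"`` or ``"auto"``;
    auto-detection transposes the table when the header matches the
    metadata's sample ids on the rows instead of the columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise TableFormatError(f"{path}: empty count table")
    if df.index.name is None:
        df.index.name = "asv_id"
    try:
        body = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric cell ({exc})") from None
    if orientation not in ("auto", "asv_rows", "sample_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    transpose = orientation == "sample_rows"
    if orientation == "auto" and metadata is not None:
        meta_ids = set(metadata["sample_id"].astype(str))
        cols_hit = len(meta_ids & set(map(str, body.columns)))
        rows_hit = len(meta_ids & set(map(str, body.index)))
        transpose = rows_hit > cols_hit
    if transpose:
        body = body.T
        body.index.name = "asv_id"
    frac = body.to_numpy(dtype=float)
    if np.any(frac != np.floor(frac)):
        i, j = np.argwhere(frac != np.floor(frac))[0]
        raise TableFormatError(
            f"{path}: non-integer count at row {body.index[i]!r}, "
            f"column {body.columns[j]!r}"
        )
    return CommunityTable(list(body.index), list(body.columns),
                          frac.astype(np.int64))


def write_counts(table: CommunityTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path, max_inocula: int = 1) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, reactor, day[, role])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "reactor": str})
    if df.empty:
        raise TableFormatError(f"{path}: empty metadata table")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {missing}")
    if "role" not in df.columns:
        df["role"] = "timepoint"
    df["role"] = df["role"].fillna("timepoint")
    bad_roles = set(df["role"]) - set(ROLE_VALUES)
    if bad_roles:
        raise TableFormatError(f"{path}: unknown roles {sorted(bad_roles)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableFormatError(f"{path}: duplicated sample ids {dup}")
    df["day"] = pd.to_numeric(df["day"]).astype(int)
    if (df["day"] < 0).any():
        raise TableFormatError(f"{path}: negative day values")
    n_inoc = int((df["role"] == "inoculum").sum())
    if n_inoc > max_inocula:
        raise TableFormatError(
            f"{path}: {n_inoc} inoculum samples, at most {max_inocula} allowed"
        )
    return df.reset_index(drop=True)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def validate_metadata(table: CommunityTable, metadata: pd.DataFrame) -> None:
    """Every sample in the count table must appear in the metadata."""
    known = set(metadata["sample_id"].astype(str))
    missing = [s for s in table.sample_ids if s not in known]
    if missing:
        raise TableFormatError(
            f"samples in count table missing from metadata: {missing}"
        )


# ---------------------------------------------------------------------------
# Trees and patristic distances
# ---------------------------------------------------------------------------

def read_newick(source, required_tips=None) -> dendropy.Tree:
    """Parse a Newick tree (path or string) with branch lengths.

    Negative branch lengths (an occasional artifact of ML tree inference)
    are clamped to zero with a warning.  ``required_tips``, if given, must
    all be present as tip labels.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        src = {"path": str(source)}
    else:
        src = {"data": str(source)}
    try:
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **src)
    except Exception as exc:
        raise ValueError(f"unparseable Newick input: {exc}") from None
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.warning("clamped %d negative branch lengths to zero", n_clamped)
    if required_tips is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = sorted(set(map(str, required_tips)) - tips)
        if missing:
            raise ValueError(f"tree is missing required tips: {missing}")
    return tree


def tree_tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distances(tree: dendropy.Tree, ids=None) -> DistanceMatrix:
    """Pairwise branch-length path sums between the given tips.

    ``ids`` defaults to all tip labels (in tree order).
    """
    if ids is None:
        ids = tree_tip_labels(tree)
    ids = [str(i) for i in ids]
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = sorted(set(ids) - set(taxa))
    if missing:
        raise KeyError(f"ids not in tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True,
                       suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Rarefaction and relative abundances
# ---------------------------------------------------------------------------

def rarefy(table: CommunityTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample (equivalent to
    shuffling the sample's reads and keeping the first ``depth``).  Samples
    with fewer than ``depth`` total reads are dropped with a warning, so
    the equal-depth contract holds exactly for every retained column.
    Reproducible: each sample's draw is seeded from (seed, "rarefy",
    sample_id), independent of column order.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    keep_ids, columns = [], []
    for sid in table.sample_ids:
        counts = table.sample_counts(sid)
        total = int(counts.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < rarefaction depth %d",
                sid, total, depth,
            )
            continue
        if total == depth:
            drawn = counts.copy()
        else:
            rng = child_rng(seed, "rarefy", sid)
            drawn = rng.multivariate_hypergeometric(counts, depth)
        keep_ids.append(sid)
        columns.append(drawn)
    if not keep_ids:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return CommunityTable(list(table.asv_ids), keep_ids,
                          np.column_stack(columns).astype(np.int64))


def relative_abundances(table: CommunityTable) -> np.ndarray:
    """Column-normalised proportion matrix (columns sum to 1)."""
    totals = table.sample_totals.astype(float)
    return table.counts / totals[np.newaxis, :]
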