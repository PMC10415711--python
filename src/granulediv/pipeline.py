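"""End-to-end analysis pipeline: rarefy -> alpha -> beta -> null models ->
time decay -> PERMANOVA.

A run is described by a YAML config naming either the three input files
(counts TSV, metadata TSV, Newick tree) or a ``simulate`` block for the
synthetic generator.  Outputs are five TSV tables plus a JSON manifest
that records every parameter, the master seed and input checksums, so a
run is reproducible byte for byte.

Two named parameter profiles exist: ``paper`` (rarefaction depth 70492,
999 randomizations — the study-faithful defaults) and ``reduced`` (depth
5000, 99 randomizations) for quick runs and tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community_io import (
    CommunityTable, patristic_distances, rarefy, read_counts, read_metadata,
    read_newick, validate_metadata, write_counts, write_metadata, write_newick,
)
from .hill_diversity import alpha_table, dissimilarity_matrix, dissimilarity_square
from .null_models import NullConfig, ses_series
from .succession import build_series, pairwise_permanova, time_decay_rate

logger = logging.getLogger("granulediv")

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline",
           "PROFILES"]

PROFILES = {
    "paper": {"rarefaction_depth": 70492, "n_randomizations": 999},
    "reduced": {"rarefaction_depth": 5000, "n_randomizations": 99},
}

_KNOWN_KEYS = {
    "counts", "metadata", "tree", "simulate", "profile", "rarefaction_depth",
    "orders", "null_model", "variant", "output_dir", "seed", "log_level",
    "phylogenetic", "n_permutations",
}
_NULL_KEYS = {"n_randomizations", "threshold", "pool_scope", "weighting"}


class PipelineError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Fully defaulted parameters of one pipeline run."""

    counts: str | None = None
    metadata: str | None = None
    tree: str | None = None
    simulate: dict | None = None
    rarefaction_depth: int = 70492
    orders: tuple = (0.0, 1.0, 2.0)
    null_model: NullConfig = field(default_factory=NullConfig)
    variant: str = "local"
    phylogenetic: bool = True
    n_permutations: int = 999
    output_dir: str = "granulediv_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        have_paths = any(x is not None for x in (self.counts, self.metadata,
                                                 self.tree))
        if have_paths and self.simulate is not None:
            raise ValueError("config gives both input paths and a simulate block")
        if not have_paths and self.simulate is None:
            raise ValueError("config needs input paths or a simulate block")
        if have_paths and (self.counts is None or self.metadata is None):
            raise ValueError("counts and metadata paths are both required")
        if int(self.rarefaction_depth) <= 0:
            raise ValueError("rarefaction_depth must be >= 1")
        self.rarefaction_depth = int(self.rarefaction_depth)
        self.orders = tuple(float(q) for q in self.orders)
        if any(q < 0 for q in self.orders):
            raise ValueError("diversity orders must be >= 0")


def validate_config(path) -> PipelineConfig:
    """Load, default and validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    profile = raw.pop("profile", None)
    defaults = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ValueError(f"{path}: unknown profile {profile!r}")
        defaults = dict(PROFILES[profile])
    null_raw = dict(raw.pop("null_model", {}) or {})
    bad = set(null_raw) - _NULL_KEYS
    if bad:
        raise ValueError(f"{path}: unknown null_model keys {sorted(bad)}")
    seed = int(raw.get("seed", 0))
    null_cfg = NullConfig(
        n_randomizations=int(null_raw.get(
            "n_randomizations", defaults.get("n_randomizations", 999))),
        threshold=float(null_raw.get("threshold", 2.0)),
        pool_scope=null_raw.get("pool_scope", "all_samples"),
        weighting=null_raw.get("weighting", "frequency_x_abundance"),
        seed=seed,
    )
    kwargs = dict(raw)
    kwargs.setdefault("rarefaction_depth",
                      defaults.get("rarefaction_depth", 70492))
    kwargs["null_model"] = null_cfg
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        from .synthetic_data import SimulationConfig, simulate_study
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        table, metadata, tree, truth = simulate_study(
            SimulationConfig(**sim_kwargs))
        write_counts(table, outdir / "simulated_counts.tsv")
        write_metadata(metadata, outdir / "simulated_metadata.tsv")
        write_newick(tree, outdir / "simulated_tree.nwk")
        return table, metadata, tree, {"simulate": sim_kwargs}
    metadata = read_metadata(config.metadata)
    table = read_counts(config.counts, metadata=metadata)
    validate_metadata(table, metadata)
    tree = None
    checksums = {"counts": _sha256(Path(config.counts)),
                 "metadata": _sha256(Path(config.metadata))}
    if config.tree is not None:
        tree = read_newick(config.tree, required_tips=table.asv_ids)
        checksums["tree"] = _sha256(Path(config.tree))
    return table, metadata, tree, {"input_sha256": checksums}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns {output name: path}.

    Emits alpha.tsv, dissimilarity.tsv, ses.tsv, timedecay.tsv,
    permanova.tsv and manifest.json in ``config.output_dir``.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    table, metadata, tree, provenance = stage("load")(_load_inputs, config,
                                                      outdir)
    use_phylo = config.phylogenetic and tree is not None

    rare = stage("rarefy")(rarefy, table, config.rarefaction_depth,
                           config.seed)
    meta = metadata[metadata["sample_id"].isin(rare.sample_ids)].reset_index(
        drop=True)
    distances = None
    if use_phylo:
        distances = stage("distances")(patristic_distances, tree,
                                       rare.asv_ids)

    alpha = stage("alpha")(alpha_table, rare, config.orders, distances)
    outputs["alpha"] = outdir / "alpha.tsv"
    alpha.to_csv(outputs["alpha"], sep="\t", index=False)

    def all_dissimilarity():
        parts = [dissimilarity_matrix(rare, config.orders, "taxonomic",
                                      variant=config.variant)]
        if use_phylo:
            parts.append(dissimilarity_matrix(rare, config.orders,
                                              "phylogenetic", distances,
                                              config.variant))
        return pd.concat(parts, ignore_index=True)

    dissim = stage("dissimilarity")(all_dissimilarity)
    outputs["dissimilarity"] = outdir / "dissimilarity.tsv"
    dissim.to_csv(outputs["dissimilarity"], sep="\t", index=False)

    def build_all_series():
        parts = [build_series(meta, "successive"),
                 build_series(meta, "between_reactor")]
        if "role" in meta.columns and (meta["role"] == "inoculum").any():
            parts.append(build_series(meta, "vs_inoculum"))
        return pd.concat(parts, ignore_index=True)

    series = stage("series")(build_all_series)

    def all_ses():
        null_cfg = config.null_model
        pool = None
        parts = []
        for kind, grp in series.groupby("kind", sort=True):
            pairs = grp.drop(columns=[c for c in ("day",) if c in grp])
            if null_cfg.pool_scope == "per_reactor" and kind == "successive":
                for r, sub in pairs.groupby("reactor", sort=True):
                    rpool = meta.loc[meta["reactor"] == r, "sample_id"].tolist()
                    parts.append(ses_series(rare, sub, "qRC", null_cfg,
                                            config.orders, pool=rpool,
                                            variant=config.variant))
                    if use_phylo:
                        parts.append(ses_series(rare, sub, "betaNTI", null_cfg,
                                                distances=distances,
                                                pool=rpool))
            else:
                parts.append(ses_series(rare, pairs, "qRC", null_cfg,
                                        config.orders, pool=pool,
                                        variant=config.variant))
                if use_phylo:
                    parts.append(ses_series(rare, pairs, "betaNTI", null_cfg,
                                            distances=distances, pool=pool))
        return pd.concat(parts, ignore_index=True)

    ses = stage("null_models")(all_ses)
    outputs["ses"] = outdir / "ses.tsv"
    ses.to_csv(outputs["ses"], sep="\t", index=False)

    def all_timedecay():
        rows = []
        kinds = ["taxonomic"] + (["phylogenetic"] if use_phylo else [])
        tp = meta[meta["role"] != "inoculum"] if "role" in meta else meta
        for reactor in sorted(tp["reactor"].unique()):
            if (tp["reactor"] == reactor).sum() < 3:
                continue
            for kind in kinds:
                for q in config.orders:
                    fit = time_decay_rate(dissim, meta, reactor, q, kind)
                    rows.append(asdict(fit))
        return pd.DataFrame(rows)

    decay = stage("time_decay")(all_timedecay)
    outputs["timedecay"] = outdir / "timedecay.tsv"
    decay.to_csv(outputs["timedecay"], sep="\t", index=False)

    def all_permanova():
        tp = meta[meta["role"] != "inoculum"] if "role" in meta else meta
        counts_by_reactor = tp["reactor"].value_counts()
        usable = counts_by_reactor[counts_by_reactor >= 2].index
        tp = tp[tp["reactor"].isin(usable)]
        kinds = ["taxonomic"] + (["phylogenetic"] if use_phylo else [])
        parts = []
        for kind in kinds:
            for q in config.orders:
                square = dissimilarity_square(dissim, tp["sample_id"], q, kind)
                res = pairwise_permanova(square, tp["reactor"],
                                         n_permutations=config.n_permutations,
                                         seed=config.seed)
                res.insert(0, "kind", kind)
                res.insert(1, "q", float(q))
                parts.append(res)
        return pd.concat(parts, ignore_index=True)

    perm = stage("permanova")(all_permanova)
    outputs["permanova"] = outdir / "permanova.tsv"
    perm.to_csv(outputs["permanova"], sep="\t", index=False)

    manifest = {
        "package": "granulediv",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "rarefaction_depth": config.rarefaction_depth,
            "orders": list(config.orders),
            "variant": config.variant,
            "phylogenetic": use_phylo,
            "n_permutations": config.n_permutations,
            "null_model": asdict(config.null_model),
            "inputs": {k: getattr(config, k) for k in
                       ("counts", "metadata", "tree")},
        },
        "provenance": provenance,
        "samples_analysed": rare.sample_ids,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    outputs["manifest"] = outdir / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2,
                                              sort_keys=True) + "\n")
    return {k: str(v) for k, v in outputs.items()}
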