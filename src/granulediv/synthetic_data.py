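"""Synthetic granular-sludge reactor communities.

Generates the downstream product of an amplicon time-series study of two
replicate sequencing-batch reactors seeded from a common inoculum: an ASV
count table, sample metadata and a phylogeny, with known ground truth.

The mechanistic model is intentionally minimal.  Biomass is structured
into granules (dense biofilm aggregates), each a finite population of
individuals.  Community turnover has three ingredients:

* neutral drift — every day each granule's composition is resampled
  multinomially (Wright-Fisher), optionally biased by per-ASV selection
  coefficients (probabilities proportional to counts x exp(s));
* disturbance — on scheduled days a fraction of the settled biomass is
  removed; in ``granule`` mode whole granules are discarded at random
  (clustered loss), in ``uniform`` mode every granule loses the same
  fraction of individuals hypergeometrically;
* regrowth — after a disturbance the biomass returns to carrying capacity
  in one composite step: surviving granules are duplicated (founder
  resampling), preserving the within-granule variability that makes
  clustered loss consequential.

Sequencing is emulated by a multinomial read draw from the pooled,
homogenised reactor biomass at each sampling day.

The default configuration mirrors the study design the package analyses:
27 sampling days over 149 days for each of two reactors, disturbances at
days 0/50/100 removing half of the biomass, ~70k reads per sample, and an
inoculum with a few dominant ASVs over a long lognormal tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .community_io import CommunityTable
from .seeding import child_rng

__all__ = [
    "SimulationConfig",
    "SimState",
    "default_sampling_days",
    "simulate_tree",
    "brownian_selection",
    "step_drift_selection",
    "apply_disturbance",
    "simulate_study",
]


def default_sampling_days(n_timepoints: int = 27, span: int = 149) -> tuple:
    """Evenly spread integer sampling days: 27 points over 149 days."""
    return tuple(int(x) for x in
                 np.unique(np.round(np.linspace(0, span, n_timepoints))))


@dataclass
class SimulationConfig:
    """Reactor-community simulation parameters.

    ``individuals_per_granule`` x ``n_granules`` sets the effective
    population size per reactor and hence the drift rate; the defaults
    (50 granules of 200 individuals) give successive-sample dissimilarity
    of the magnitude amplicon reactor series show.  All-zero
    ``selection_coefficients`` (the default) is pure neutral drift;
    ``phylo_signal`` > 0 instead draws coefficients from a Brownian walk
    along the simulated tree (standard deviation ``phylo_signal`` across
    tips), giving selection a phylogenetic signal.
    """

    n_asvs: int = 100
    n_granules: int = 50
    individuals_per_granule: int = 200
    sampling_days: tuple = field(default_factory=default_sampling_days)
    disturbance_days: tuple = (0, 50, 100)
    removal_fraction: float = 0.5
    disturbance_mode: str = "granule"
    selection_coefficients: tuple | None = None
    phylo_signal: float = 0.0
    read_depth: int = 70492
    dominant_shares: tuple = (0.35, 0.15, 0.10)
    tail_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_asvs < 2:
            raise ValueError("n_asvs must be >= 2")
        if self.n_granules < 2:
            raise ValueError("n_granules must be >= 2")
        if self.individuals_per_granule < 1:
            raise ValueError("individuals_per_granule must be >= 1")
        if not 0.0 < self.removal_fraction < 1.0:
            raise ValueError("removal_fraction must be in (0, 1)")
        days = tuple(int(d) for d in self.sampling_days)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sampling_days must be strictly increasing")
        self.sampling_days = days
        self.disturbance_days = tuple(int(d) for d in self.disturbance_days)
        if self.disturbance_mode not in ("granule", "uniform"):
            raise ValueError(f"unknown disturbance mode {self.disturbance_mode!r}")
        if self.selection_coefficients is not None:
            s = tuple(float(x) for x in self.selection_coefficients)
            if len(s) != self.n_asvs:
                raise ValueError("need one selection coefficient per ASV")
            self.selection_coefficients = s
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not 0.0 < sum(self.dominant_shares) < 1.0:
            raise ValueError("dominant_shares must sum to a value in (0, 1)")


@dataclass
class SimState:
    """Granule-resolved reactor state: one integer composition row per granule."""

    granules: np.ndarray      # (n_granules, n_asvs) individual counts
    day: int = 0

    def __post_init__(self):
        g = np.asarray(self.granules, dtype=np.int64)
        if g.ndim != 2:
            raise ValueError("granules must be a 2-D (granule x ASV) array")
        if np.any(g < 0):
            raise ValueError("negative individual counts")
        self.granules = g

    @property
    def n_granules(self) -> int:
        return self.granules.shape[0]

    def pooled(self) -> np.ndarray:
        """Whole-reactor composition (summed over granules)."""
        return self.granules.sum(axis=0)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_asvs: int, seed: int = 0) -> dendropy.Tree:
    """Random rooted bifurcating tree with exponential branch lengths.

    Topology grows by Yule-type splits (a uniformly chosen tip speciates);
    every edge gets an independent Exponential(mean 0.1) length, the
    magnitude typical of 16S amplicon trees.  Tips are labeled
    ASV_1..ASV_n.  Deterministic for a fixed seed.
    """
    if n_asvs < 2:
        raise ValueError("n_asvs must be >= 2")
    rng = child_rng(seed, "simulate_tree", n_asvs)
    taxa = dendropy.TaxonNamespace([f"ASV_{i + 1}" for i in range(n_asvs)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tips = [tree.seed_node]
    while len(tips) < n_asvs:
        parent = tips.pop(int(rng.integers(len(tips))))
        left, right = dendropy.Node(), dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        tips.extend([left, right])
    order = rng.permutation(n_asvs)
    for node, k in zip(tips, order):
        node.taxon = taxa[int(k)]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(0.1))
    return tree


def brownian_selection(tree: dendropy.Tree, sigma: float,
                       seed: int = 0) -> dict:
    """Selection coefficients from a Brownian walk down the tree.

    Each edge adds Normal(0, length) noise to the parent's value; tip
    values are centred and rescaled to standard deviation ``sigma``, so
    closely related ASVs get similar coefficients (phylogenetic signal).
    Returns {tip label: coefficient}.
    """
    rng = child_rng(seed, "brownian_selection")
    value = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(
            max(length, 1e-12)))
    tips = {leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()}
    vals = np.array(list(tips.values()))
    sd = vals.std()
    scale = sigma / sd if sd > 0 else 0.0
    mean = vals.mean()
    return {k: (v - mean) * scale for k, v in tips.items()}


# ---------------------------------------------------------------------------
# Stochastic update rules
# ---------------------------------------------------------------------------

def _fitness_probs(counts: np.ndarray, selection: np.ndarray) -> np.ndarray:
    w = counts * np.exp(selection)
    return w / w.sum()


def step_drift_selection(state: SimState, selection: np.ndarray,
                         rng: np.random.Generator) -> SimState:
    """One Wright-Fisher generation per granule.

    The next generation of each granule is multinomial with probabilities
    proportional to counts x exp(selection); all-zero coefficients give
    pure drift.  Granule totals are preserved; emptied granules (possible
    only if a granule starts empty) are removed.
    """
    selection = np.asarray(selection, dtype=float)
    new = np.empty_like(state.granules)
    keep = []
    for g in range(state.n_granules):
        counts = state.granules[g]
        total = int(counts.sum())
        if total == 0:
            continue
        new[g] = rng.multinomial(total, _fitness_probs(counts, selection))
        keep.append(g)
    return SimState(new[keep], day=state.day + 1)


def _regrow(granules: np.ndarray, n_target: int, capacity: int,
            selection: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Restore granule count/size after a disturbance.

    New granules are founded by resampling a surviving granule's
    composition (chosen uniformly with replacement), so within-granule
    variability persists across disturbances.
    """
    survivors = granules[granules.sum(axis=1) > 0]
    out = np.empty((n_target, granules.shape[1]), dtype=np.int64)
    for i in range(n_target):
        src = survivors[int(rng.integers(len(survivors)))]
        out[i] = rng.multinomial(capacity, _fitness_probs(src, selection))
    return out


def apply_disturbance(state: SimState, removal_fraction: float,
                      mode: str, rng: np.random.Generator,
                      selection: np.ndarray | None = None) -> SimState:
    """Remove a fraction of the biomass, then regrow to carrying capacity.

    ``granule`` mode deletes a uniformly random ceil(fraction x G) subset
    of granules (clustered loss); ``uniform`` mode removes the fraction of
    individuals from every granule hypergeometrically.  Survivors are
    regrown to the previous granule count and size in one composite step.
    """
    if state.n_granules < 2:
        raise ValueError("need >= 2 granules to disturb")
    if selection is None:
        selection = np.zeros(state.granules.shape[1])
    g_count = state.n_granules
    capacity = int(round(state.granules.sum() / g_count))
    if mode == "granule":
        n_remove = int(np.ceil(removal_fraction * g_count))
        if n_remove >= g_count:
            raise ValueError("removal fraction would remove every granule")
        removed = rng.choice(g_count, size=n_remove, replace=False)
        survivors = np.delete(state.granules, removed, axis=0)
    elif mode == "uniform":
        survivors = np.empty_like(state.granules)
        for g in range(g_count):
            total = int(state.granules[g].sum())
            keep = total - int(np.floor(removal_fraction * total))
            survivors[g] = rng.multivariate_hypergeometric(
                state.granules[g], keep)
        survivors = survivors[survivors.sum(axis=1) > 0]
        if len(survivors) == 0:
            raise ValueError("disturbance removed every individual")
    else:
        raise ValueError(f"unknown disturbance mode {mode!r}")
    regrown = _regrow(survivors, g_count, capacity, selection, rng)
    return SimState(regrown, day=state.day)


# ---------------------------------------------------------------------------
# Full study simulation
# ---------------------------------------------------------------------------

def _inoculum_abundances(config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Inoculum ASV proportions: a few dominants over a lognormal tail."""
    n_dom = len(config.dominant_shares)
    tail = rng.lognormal(0.0, config.tail_sigma, config.n_asvs - n_dom)
    tail *= (1.0 - sum(config.dominant_shares)) / tail.sum()
    p = np.concatenate([np.asarray(config.dominant_shares, float), tail])
    return p[rng.permutation(config.n_asvs)]


def simulate_study(config: SimulationConfig):
    """Simulate the two-reactor disturbance study end to end.

    One inoculum community is built and sequenced; its granules are split
    at random between reactors R2 and R3, which then evolve independently
    under daily drift (plus optional selection) with disturbances on the
    scheduled days.  Each sampling day draws a multinomial read sample of
    ``read_depth`` from the pooled reactor biomass.

    Returns ``(table, metadata, tree, truth)`` where ``truth`` records the
    configuration, selection coefficients, inoculum composition and the
    latent (noise-free) relative abundances behind every sample.
    """
    seed = config.seed
    tree = simulate_tree(config.n_asvs, seed)
    asv_ids = [f"ASV_{i + 1}" for i in range(config.n_asvs)]
    if config.selection_coefficients is not None:
        selection = np.asarray(config.selection_coefficients, dtype=float)
    elif config.phylo_signal > 0:
        by_tip = brownian_selection(tree, config.phylo_signal, seed)
        selection = np.array([by_tip[a] for a in asv_ids])
    else:
        selection = np.zeros(config.n_asvs)

    rng_setup = child_rng(seed, "inoculum")
    pi = _inoculum_abundances(config, rng_setup)
    g, k = config.n_granules, config.individuals_per_granule
    inoc_granules = rng_setup.multinomial(k, pi, size=2 * g)
    inoc_state = SimState(inoc_granules, day=0)

    samples: dict[str, np.ndarray] = {}
    meta_rows = []

    def draw_reads(sid: str, pooled: np.ndarray) -> np.ndarray:
        # per-sample read stream: independent of reactor iteration order
        return child_rng(seed, "reads", sid).multinomial(
            config.read_depth, pooled / pooled.sum())

    pooled = inoc_state.pooled()
    inoc_id = "R1_inoc"
    samples[inoc_id] = draw_reads(inoc_id, pooled)
    meta_rows.append({"sample_id": inoc_id, "reactor": "R1", "day": 0,
                      "role": "inoculum"})
    latent = {inoc_id: pooled / pooled.sum()}

    split = child_rng(seed, "split").permutation(2 * g)
    reactors = {"R2": SimState(inoc_granules[split[:g]].copy(), day=0),
                "R3": SimState(inoc_granules[split[g:]].copy(), day=0)}

    last_day = max(config.sampling_days)
    for reactor, state in reactors.items():
        rng = child_rng(seed, "dynamics", reactor)
        for day in range(last_day + 1):
            state.day = day
            if day in config.disturbance_days:
                state = apply_disturbance(state, config.removal_fraction,
                                          config.disturbance_mode, rng,
                                          selection)
            if day in config.sampling_days:
                pooled = state.pooled()
                sid = f"{reactor}_d{day:03d}"
                samples[sid] = draw_reads(sid, pooled)
                meta_rows.append({"sample_id": sid, "reactor": reactor,
                                  "day": day, "role": "timepoint"})
                latent[sid] = pooled / pooled.sum()
            state = step_drift_selection(state, selection, rng)

    sample_ids = list(samples)
    table = CommunityTable(asv_ids, sample_ids,
                           np.column_stack([samples[s] for s in sample_ids]))
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "config": asdict(config),
        "selection_coefficients": selection.tolist(),
        "inoculum_abundances": pi.tolist(),
        "latent_relative_abundances": latent,
    }
    return table, metadata, tree, truth
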