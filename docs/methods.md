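# Methods

`granulediv` analyses community assembly in amplicon time series from
replicate bioreactors: two reactors seeded from a common inoculum, sampled
repeatedly over ~150 days, with scheduled disturbances that remove half of
the granular biomass. The package asks the questions such experiments ask:
how diverse is each sample, how fast does community structure turn over,
do replicate reactors diverge, and is the turnover distinguishable from
chance (stochastic drift) or not (deterministic selection)?

## Diversity model

All statistics operate on an ASV-by-sample count table rarefied to a
common depth (default 70 492 reads per sample, subsampled without
replacement via a multivariate hypergeometric draw; samples below the
depth are dropped with a warning so the equal-depth contract is exact).

**Taxonomic alpha.** Hill numbers
`qTD = (Σ_i p_i^q)^(1/(1−q))` (with the analytic limit `exp(−Σ p ln p)`
at q = 1, never a numerical approach to 1). q = 0 is richness, q = 1 the
effective number of common ASVs, q = 2 of abundant ASVs.

**Phylogenetic alpha.** Distance-based (functional) Hill numbers on the
patristic distance matrix of the input tree: with Rao quadratic entropy
`Q = Σ_ij d_ij p_i p_j`,
`qD(Q) = (Σ_ij (d_ij/Q)(p_i p_j)^q)^(1/(2(1−q)))` and the reported
total effective phylogenetic distance is `qPD = qD(Q)² · Q`. A
single-ASV community has Q = 0 and qPD := 0.

**Beta / dissimilarity.** For a sample pair, gamma diversity of the
evenly pooled pair over the Chiu–Chao mean alpha gives β ∈ [1, 2]; the
two-sample overlap transform maps it to [0, 1] (0 = identical, 1 = no
shared ASVs). The local (C_qN-type) transform
`(1 − β^(1−q)) / (1 − 2^(1−q))` is the default; the regional (U_qN-type)
variant is a switch. Functional beta uses the doubled exponent 2(1−q).
Note that with all off-diagonal distances equal the functional
dissimilarity does **not** reduce exactly to the taxonomic one (the
functional sums exclude the zero diagonal); the two agree at the
identical/disjoint endpoints for every q and converge at q = 1 as
richness grows.

## Null models

Both null models report a standardized effect size
`SES = (observed − mean(null)) / sd(null)` over (by default) 999
randomizations, with |SES| > 2 read as significant: SES < −2 means the
pair is more similar (shares more taxa / is phylogenetically closer) than
the null expectation, SES > 2 more different.

**Raup–Crick (qRC).** Null community pairs are assembled from the
regional pool (all samples by default; per-reactor scope is a switch):
each null sample preserves the observed sample's richness and read
total; ASV identities are drawn without replacement with probability
weights from the pool (occurrence frequency × relative abundance by
default; either alone is a switch) and reads are allocated among the
chosen ASVs by a multinomial proportional to the pool relative
abundances, each chosen ASV keeping at least one read. The exact
assembly recipe used by published implementations is not uniquely
documented; this one is stated here so results are interpretable. A
consequence worth knowing: because read allocation follows the pool
profile, the null distribution of abundance-sensitive (q ≥ 1)
dissimilarities is narrow whenever dominant ASVs are certain to be drawn,
which makes qRC at q ≥ 1 a sharp detector of any abundance drift rather
than a loose stochasticity band (see Limitations).

**βMNTD / βNTI.** The abundance-weighted β mean nearest-taxon distance
`βMNTD = ½[Σ_i p_i^A min_j d(i,j) + Σ_j p_j^B min_i d(j,i)]` (shared
ASVs contribute 0; a presence/absence variant is a switch). βNTI is its
SES under random permutation of ASV labels across the tips of the
regional-pool phylogeny, the same permutation applied to both samples;
only tips occurring in the pool are shuffled. A null standard deviation
at numerical zero (e.g. a star tree) raises a degeneracy flag and the
SES is reported as NaN, never ±∞.

## Succession statistics

**Comparison series.** Successive pairs (adjacent time points within a
reactor), between-reactor pairs (equal days across reactors), and every
time point versus the single inoculum sample.

**Time decay.** Similarity s = 1 − dissimilarity; the decay rate is the
OLS slope of ln s on the day separation over all within-reactor pairs
(natural log, so the slope is a per-day e-folding rate; an optional day
window restricts to a disturbance period). Pairs with s ≤ 0 are dropped
and counted rather than floored, which would bias the slope.

**PERMANOVA.** One-way pseudo-F from the Gower-centred partition of
squared dissimilarities, p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1) under
random relabeling (999 permutations default); pairwise mode reports raw
p per group pair with optional Benjamini–Hochberg adjustment. Note the
attainable p floor is limited by partition-preserving permutations,
which tie the observed F: with two groups of four, p cannot fall below
≈ 0.03; with ten per group the 0.001 floor is reachable.

## Synthetic study generator

The generator emulates the downstream product of the two-reactor
disturbance experiment, not its microbiology: 27 sampling days spread
over 149 days, disturbances at days 0/50/100 removing half of the
biomass, multinomial read sampling at 70 492 reads per sample, and an
inoculum with a few dominant ASVs (shares 0.35/0.15/0.10) over a
lognormal tail (σ = 2, giving abundances spanning ~4 orders of magnitude
so per-sample richness sits well below pool richness, as in real
rarefied tables).

Biomass is 50 granules of 200 individuals each (an *effective* population
size of 10⁴ per reactor — chosen for drift at observable magnitude, not a
census count). Each day every granule is resampled multinomially
(Wright–Fisher; probabilities ∝ counts × e^s, all s = 0 in neutral runs;
optionally s is a Brownian walk down the simulated Yule tree, scaled to a
chosen standard deviation, so selection carries phylogenetic signal).
Granule-mode disturbance deletes a random half of the granules
(clustered loss); uniform mode removes half the individuals from every
granule; either way the biomass regrows to carrying capacity in one
composite founder-resampling step that preserves within-granule
variability. The tree is Yule-topology with Exponential(0.1) branch
lengths, typical of 16S trees.

## What passing tests do and do not show

The generator reproduces the *qualitative* regime of the experiment —
drift-driven divergence of replicates, large transient jumps after
clustered granule loss, declining alpha-diversity, significant time
decay — but not every printed magnitude simultaneously. Without a
migration/mixing term (deliberately absent: the update rule is pure
within-granule Wright–Fisher), granules fixate internally on a timescale
of ~K generations, after which pooled drift stalls; matching observed
successional turnover by shrinking granules instead collapses richness.
Real reactors also stabilize replicate composition through shared
selective conditions that neutral runs deliberately omit, so simulated
between-reactor divergence exceeds what stable replicated reactors show.
Tests passing on this generator therefore validate the statistical
machinery, not the fidelity of the ecological model.

## Numerical choices

- q = 1 always via analytic limits; 0^q := 0 everywhere.
- β clipped to [1, 2] and dissimilarities to [0, 1] against rounding.
- Degenerate nulls: sd ≤ 1e-12·max(1, |mean|) ⇒ flagged, SES = NaN,
  not significant.
- Negative branch lengths are clamped to 0 with a warning.
- Every stochastic operation derives its generator from the master seed
  plus a context key (operation name, sample/pair ids), so results are
  independent of evaluation order and reproducible bit for bit.
- Scaled-down profiles: tests and the acceptance script run at depth
  5000 with 99 randomizations (the `reduced` profile); the
  study-faithful `paper` profile is depth 70 492 with 999.
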