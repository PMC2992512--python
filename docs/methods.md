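# Methods

## The EV statistic

Expression variance (EV) is the sample variance (n−1 denominator) of a
gene's normalized log2 expression across the samples of a compendium.
Two normalization pipelines are implemented, matching the two compendium
designs the analysis supports.

**Tissue-style (`ev_expo`).** Samples are first quantile-normalized:
every column is forced onto the per-rank mean of the column-sorted
values, so all samples share one intensity distribution. Ties within a
column receive the average of the target values at the ranks they
occupy — a standard, deterministic dialect that makes the transform
idempotent. Each row is then divided by its own median and
log2-transformed, giving per-sample deviations from the gene's typical
level; EV is the row variance. `mean_expr`, the abundance covariate, is
the row mean of the quantile-normalized *pre-log* intensities, because
abundance windows (e.g. "average expression between 300 and 350") are
conventionally stated on the intensity scale. Rows whose median is not
strictly positive — or that contain nonpositive values, for which log2
is undefined — are dropped and reported rather than clamped: the data
model gives no intensity floor, and silently clamping would fabricate
variance.

**Treatment-style (`ev_ck`).** Each treatment column is divided
elementwise by its declared control column; controls are discarded; the
ratios are log2-transformed; each remaining column is standardized to
mean 0 and variance 1 (sample variance). A treatment column identical
to its control has zero variance, makes standardization undefined, and
is dropped with a report. EV is again the row variance, now of
standardized log fold changes. `mean_expr` for this pipeline is the mean
raw intensity over all original columns, retained purely as the
abundance covariate.

**Probe collapsing.** Published probe-level tables give no collapse
rule; gene-level EV is taken as the *median* of the gene's probe EVs
(robust to a single aberrant probe). A QC statistic accompanies the
collapse: across genes with at least two probes, the Spearman
correlation of EV between two randomly chosen probes per gene (seeded).
High values indicate EV is a property of the gene, not of probe noise.

## Functional-similarity network

For genes *i, j*, let `K` be the set of GO-style terms annotating both.
If `K` is empty the overlap significance is undefined and no GO-derived
edge is possible (an edge from "no shared annotation" would be
meaningless). Otherwise `s_ij = |⋂_{k∈K} G_k| / n`, where `n` is the
size of an *explicitly declared* gene universe — not the count of
annotated genes — and an edge is added when `s_ij < 0.001`. Because both
genes belong to every intersected set, `s_ij ≥ 2/n`; the rule therefore
requires a universe larger than 2/threshold to fire at all. Genes
sharing a pathway-style term are linked outright, bypassing the
significance rule. Construction iterates an inverted index over terms
(never all gene pairs) but is contract-identical to brute force, which
the tests verify directly.

## Density matrices and the shuffle null

Genes are sorted by (EV, gene id) — the id breaks ties
deterministically — and split into `n_bins` equal-occupancy bins
(default 50), any remainder spread one gene per bin over the leading
bins. With `e_ij` the number of edges between bins *i* and *j* and
`E_i = e_ii + Σ_{j≠i} e_ij` the number of edges incident to bin *i*,
the density is `d_ij = e_ij / (E_i + E_j)` off-diagonal and
`d_ii = e_ii / E_i`. The verbal definition "divided by the total number
of interactions of bins i and j" admits several readings; this one
keeps every density in [0, 1] and is isolated in one function so the
alternative denominator (`E_i + E_j − e_ij`) is a one-line change.
Equal-occupancy (quantile) bins rather than equal-width bins keep every
heatmap row comparable in power.

The null model (`shuffle_nodes`) applies a uniformly random permutation
of node labels to the fixed edge structure, preserving the degree
multiset exactly. Block structure is quantified two ways: the
*contrast* (mean within-block density / mean cross-block density, with
the low- and high-EV halves of the bins as blocks and diagonal cells
counted as within) and the *separation* (mean within − mean cross),
whose collapse toward zero under shuffling measures how much of the
structure is attributable to EV rather than to topology.

## Signaling hierarchy

Levels are derived from seven GO membership lists plus a directed
signaling network:

* `GR = (receptor activity ∪ transmembrane receptor activity) ∩ plasma membrane`.
  The published wording joins the three terms with an ambiguous "and";
  this implementation binds plasma-membrane to the union of the two
  activity terms, since a conjunction of all three would exclude most
  receptors annotated with only one activity term.
* The extracellular pool is the extracellular-space list minus GR.
  `SF` is the pool members with a direct interaction with a receptor;
  `GM` the remaining pool members that interact with an SF gene and
  never with a receptor.
* `RS` is the non-extracellular, non-receptor genes with a direct
  receptor interaction; `RS2` the remaining genes interacting with RS
  but never with a receptor.
* Precedence GR > SF > GM > RS > RS2; everything else is unassigned.

"Direct interaction" counts an edge in **either direction** by default:
curated signaling networks store ligand→receptor edges in both
orientations, and the level definitions never restrict direction. A
strict-downstream mode (`mode="downstream"`, edges leaving the upper
level only, applied to the RS/RS2 rules) is available behind a flag.
The broader extracellular-space pool — not the ligand-activity-restricted
list — seeds the SF/GM rules, because known growth-factor modulators
(e.g. protease- and binding-protein-type genes) lack ligand-activity
annotations; the ligand-defined secreted-factor set
(receptor binding ∪ growth-factor activity ∪ cytokine activity, all ∩
extracellular space) is exposed separately as `ligand_sf_list` for the
SF-vs-GR EV comparison. An empty receptor level with a nonempty network
is a structured error: every lower level is defined relative to GR.

## Statistics

* **Hypergeometric enrichment** is upper-tail only (over-representation),
  with "more than 5 annotated genes" read literally as ≥ 6, a raw
  p-value cutoff of 1e-5 and no multiple-testing correction applied for
  filtering (a Benjamini–Hochberg column is emitted as information).
  The enrichment universe is the intersection of the EV table's genes
  with the annotation universe, declared explicitly since published
  analyses rarely state it.
* **Wilcoxon rank-sum** uses exact null enumeration when the combined
  sample is ≤ 12 without ties, otherwise the normal approximation with
  tie correction and no continuity correction.
* **Spearman** is average-rank-then-Pearson; p-values are exact
  permutation tails for n ≤ 9 and the t approximation otherwise.
  Constant vectors yield an explicit NA result with a reason, never an
  exception.
* **Partial Spearman** applies the first-order partial-correlation
  formula to the rank correlations, with a t approximation on n−3
  degrees of freedom; it is undefined (NA with reason) when the control
  is perfectly rank-correlated with either variable.
* The extreme-EV cutoffs (0.9 / 0.1) in the centrality analyses are
  interpreted as **quantiles** of the current EV distribution by
  default (`quantile_cutoffs=False` switches to absolute values):
  absolute EV values are dataset-scale-dependent, and the quantile
  reading preserves the analysis's meaning across datasets.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so every downstream stage is
testable without external data. One master seed drives per-generator
deterministic streams, so compendia generated in separate calls share
one ground truth.

* **Intensities** are multiplicative-lognormal: per-gene mean drawn
  log-uniform over 4 orders of magnitude (10¹–10⁵, matching the spread
  of real mRNA abundance), times a per-(gene, tissue) lognormal effect
  (SD 0.5 on the natural-log scale), times lognormal noise whose SD is
  set by the gene's planted variance class (low 0.1 / mid 0.35 / high
  1.0). Positivity is guaranteed by construction. The per-(gene, tissue)
  effects give disjoint tissue subsets shared gene-level signal, which
  the subset-EV analyses rely on.
* **Layers** bias the variance classes (GM and SF predominantly high,
  GR mid, RS and RS2 predominantly low) and apply a small per-layer
  multiplier to the noise scale (GM 1.3, RS 0.8) so the planted median
  gradient GM > SF > GR > RS is strict rather than tie-broken.
* **Abundance coupling** (−0.3) scales each gene's noise SD by
  exp(−0.3·z) of its standardized log-abundance, planting the
  "abundant genes are less variable" confound in *both* compendium
  styles; the partial-correlation analysis must, and does, reduce the
  EV/EV correlation without destroying it.
* **Treatment responses**: genes respond to each stimulation
  independently with class-dependent probability (high 0.6, mid 0.15,
  low 0), with log2 amplitude at the gene's noise scale, plus small
  measurement noise (SD 0.1) on every column.
* **Annotations**: 200 terms with log-uniform sizes in [5, 100] (skewed
  small, like real term-size distributions); 90% of terms are drawn
  from a single variance class (planted functional modules) and 25% are
  pathway-style. At a 2,000-gene universe the GO overlap rule cannot
  fire (2/n = 0.001 is not < 0.001), exactly as the formula dictates,
  so the synthetic functional network is carried by the pathway rule;
  the module-pure and pathway fractions are chosen so that planted
  functional modularity dominates the network, which is the premise of
  the density analysis. GO-derived edges are exercised separately on
  fixtures declaring a large (10,000-gene) universe around a small
  annotated core.
* **Signaling network**: construction guarantees mirror the level
  definitions (every SF gene signals to a receptor, every GM gene to an
  SF gene and never to a receptor, every RS gene receives from a
  receptor, every RS2 gene from an RS gene and never touches a
  receptor); extra edges among RS∪RS2 follow Pareto-tail hub weights
  (exponent 2), and with negative EV–degree coupling (default −0.8) the
  hub weights concentrate on low-variance genes.
* **Promoter classes**: each gene has a designated class (low-variance →
  I or III; high-variance → IV, except high-variance RS/RS2 genes → II;
  mid → uniform) and receives it with probability `fidelity` (default
  0.8), each other class with probability (1−fidelity)/3 — so fidelity
  1 is a perfect labeling and fidelity 0.25 is exactly uniform noise.

Not emulated: array-platform artifacts (dye bias, spatial effects),
GO DAG topology (flat term lists suffice for overlap statistics),
batch structure, and missing values. Passing tests therefore show the
pipeline recovers planted statistical structure of the kinds listed
above; they do not certify behavior under platform-specific artifacts.

## Problem sizes and numerical choices

The reference synthetic study is 2,000 genes × 300 samples (tissue) and
100 control/2-treatment groups (treatment style); hierarchy-recovery
checks use 500-gene networks over 3 seeds. Oracle-equivalence tests use
200 random matrices up to 20×8 at 1e-12 relative tolerance; exact-test
oracles enumerate all hypergeometric configurations with universe ≤ 12
and all rank splits for groups up to 6+6. Run manifests hash tables
after formatting floats to 10 significant digits, making hashes stable
across platforms at that precision. Degenerate inputs follow one rule
throughout: impossible statistics become explicit NA results or
structured errors naming the offending field, never silent values.

## Known limitations

* The Fun-Net GO rule is all-or-nothing at the declared threshold; no
  edge weights are retained.
* Hierarchy assignment depends entirely on the membership lists and
  edge set given; no propagation up the GO graph is performed (inputs
  are taken as pre-propagated if the user wishes).
* The degree statistic collapses reciprocal directed edges to one
  interaction and ignores direction, which is the intended reading of
  "number of protein–protein interactions" but discards regulatory
  asymmetry.
* Synthetic EV scales differ from any real platform's; analyses that
  depend on absolute EV cutoffs should use the quantile interpretation.
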