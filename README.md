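# evnet

Expression-variance analysis of gene networks: how strongly each gene's
mRNA level is modulated across conditions, and how that regulatability
relates to promoter architecture, functional-network modularity,
signaling-network hierarchy and interaction centrality.

## The scientific problem

Some human genes hold nearly constant mRNA levels across a wide range of
tissues and stimulations; others are modulated constantly. The
**expression variance (EV)** of a gene summarizes this as the sample
variance of its normalized log2 expression across a compendium of
samples — a genome-wide measure of transcriptional regulatability.
`evnet` implements the complete analysis around that statistic for two
compendium designs:

* **tissue-compendium EV** (`ev_expo`): samples are quantile-normalized
  so every array shares one intensity distribution, each gene's row is
  divided by its median and log2-transformed, and EV is the per-gene
  row variance (n−1 denominator);
* **control-paired EV** (`ev_ck`): each treatment column is divided by
  its paired control column, controls discarded, log2-transformed, each
  column standardized to mean 0 / variance 1, and EV is again the row
  variance — so it measures fold-change variability across stimulations.

Around the EV statistic the package provides:

* a **functional-similarity network** ("Fun-Net"): genes *i, j* are
  linked when the GO-style terms they share jointly annotate a rare
  gene set — `s_ij = |⋂_{k∈K} G_k| / n < 0.001`, with `K` the shared
  terms, `G_k` term *k*'s gene set and `n` the declared universe size —
  or when they share a pathway-style annotation;
* **EV-bin interaction densities**: genes are split into 50
  equal-occupancy EV bins and the density of network edges between bins
  *i, j* is `e_ij / (E_i + E_j)` (diagonal `e_ii / E_i`), with a
  node-label-shuffle null model;
* **signaling-hierarchy assignment**: five levels — growth-factor
  modulators (GM), secreted factors (SF), receptors (GR), receptor
  substrates (RS) and second-tier substrates (RS2) — derived from seven
  GO membership lists plus a directed signaling network, with
  per-level EV profiles and Wilcoxon rank-sum comparisons;
* **enrichment statistics**: upper-tail hypergeometric enrichment of
  the top/bottom 500 EV genes, promoter-class × hierarchy-level
  enrichment heatmaps, Spearman and partial-Spearman correlation
  (rank-based first-order partial correlation, used to show EV
  relationships are not an artifact of mRNA abundance);
* **degree-centrality analyses**: EV vs interaction count over the
  RS∪RS2 levels, 20-bin degree profiles, and extreme-EV subnetwork
  exports;
* a **synthetic-data generator** that plants variance classes, a
  five-layer signaling network, class-pure annotation modules, promoter
  classes and an EV–degree coupling, so every downstream claim is
  testable against known ground truth.

## Worked example

```python
import evnet
from evnet.simulate import (SimConfig, generate_tissue_compendium,
                            generate_signaling_network)
from evnet.hierarchy import HierarchyInputs, assign_levels

cfg = SimConfig(n_genes=500, n_samples=100, n_terms=50,
                layer_sizes={"GM": 20, "SF": 30, "GR": 40,
                             "RS": 70, "RS2": 90, "other": 250},
                seed=42)
tissue, truth = generate_tissue_compendium(cfg)
ev = evnet.ev_expo(tissue)

net, membership = generate_signaling_network(cfg, truth)
assignment = assign_levels(HierarchyInputs.from_annotations(membership, net))
print(evnet.level_ev_profile(assignment, ev).summary.round(3))

report = evnet.ev_degree_analysis(evnet.degrees(net), ev, assignment)
print(f"Spearman EV vs degree over RS+RS2: "
      f"{report.spearman_ev_degree.estimate:.3f} "
      f"(p = {report.spearman_ev_degree.p:.2e}, n = {report.n_genes})")
```

prints

```
             n  median     q1     q3
level
GM          20   3.882  2.709  5.242
SF          30   1.748  1.047  2.997
GR          40   0.736  0.511  1.503
RS          70   0.506  0.359  0.622
RS2         90   0.585  0.409  0.757
unassigned   2   0.512  0.418  0.607

Spearman EV vs degree over RS+RS2: -0.384 (p = 5.33e-07, n = 160)
```

The per-level medians show the planted EV gradient down the signaling
cascade — secreted modulators and ligands are the most variable genes,
receptor substrates the least — and within the substrate levels, EV
falls with the number of interactions: the network's hubs are the
least transcriptionally modulated genes.

## Command line

Each stage is also exposed as a CLI over a YAML run configuration:

```bash
evnet run-all --config run.yaml          # simulate -> ev -> funnet ->
                                         # density -> hierarchy ->
                                         # enrich -> centrality
evnet validate --config run.yaml         # check input files only
```

Every run writes its tables, a log and a `manifest.json` with content
hashes; rerunning the same configuration reproduces identical hashes.

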