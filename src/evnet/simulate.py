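"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a tissue compendium — per-gene mean intensities spanning several
  orders of magnitude, multiplicative lognormal noise whose scale is set
  by a planted variance class, and per-(gene, tissue) effects giving the
  samples block structure;
* a treatment compendium — control/treatment sample groups where planted
  high-variance genes respond to many stimuli and low-variance genes to
  none;
* annotation sets with small-term-skewed sizes, a configurable fraction
  of variance-class-pure terms (planted functional modules) and a
  fraction of pathway-style terms;
* a five-layer directed signaling network (GM -> SF -> GR -> RS -> RS2)
  with hub-skewed extra connectivity among the receptor-substrate
  levels, optionally coupled so that high-variance RS/RS2 genes sit at
  low degree, plus the seven GO membership lists the hierarchy rules
  consume;
* promoter-class labels tied to the planted variance classes.

One integer seed governs everything; each generator draws from its own
deterministic stream split off the seed, so compendia generated in
separate calls share the same ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import AnnotationSet, ExpressionMatrix, GeneNetwork
from .errors import ConfigError
from .hierarchy import (GO_CYTOKINE_ACTIVITY, GO_EXTRACELLULAR_SPACE,
                        GO_GROWTH_FACTOR_ACTIVITY, GO_PLASMA_MEMBRANE,
                        GO_RECEPTOR_ACTIVITY, GO_RECEPTOR_BINDING,
                        GO_TRANSMEMBRANE_RECEPTOR_ACTIVITY)

VARIANCE_CLASSES = ("low", "mid", "high")
LAYERS = ("GM", "SF", "GR", "RS", "RS2")

# deterministic RNG stream ids, combined with the master seed
_STREAM_TRUTH = 0
_STREAM_TISSUE = 1
_STREAM_TREATMENT = 2
_STREAM_ANNOTATION = 3
_STREAM_NETWORK = 4
_STREAM_PROMOTER = 5

#: Per-layer distribution over variance classes. Apical (extracellular)
#: layers are predominantly high-variance, receptor substrates are
#: predominantly low-variance: the planted EV gradient down the cascade.
LAYER_CLASS_PROBS = {
    "GM": {"low": 0.0, "mid": 0.1, "high": 0.9},
    "SF": {"low": 0.0, "mid": 0.3, "high": 0.7},
    "GR": {"low": 0.15, "mid": 0.7, "high": 0.15},
    "RS": {"low": 0.8, "mid": 0.2, "high": 0.0},
    "RS2": {"low": 0.5, "mid": 0.5, "high": 0.0},
}

#: Multiplier on the class noise scale per layer; breaks median ties
#: between layers sharing a dominant class so the planted gradient is
#: strict (GM > SF > GR > RS).
LAYER_SIGMA_MULT = {"GM": 1.3, "SF": 1.0, "GR": 1.0, "RS": 0.8, "RS2": 1.0,
                    "other": 1.0}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults defining the
    reference conditions used throughout the test-suite and acceptance
    analyses.

    Noise scales (``ev_sigma``, ``tissue_effect_sd``, ...) are standard
    deviations of natural-log multiplicative factors. ``ev_degree_coupling``
    in [-1, 0] controls how strongly low-variance RS/RS2 genes attract
    the hub positions of the signaling network (0 = uncoupled).
    ``abundance_coupling`` < 0 makes abundant genes less variable, the
    confound the abundance-control analyses are designed to remove.
    """

    n_genes: int = 2000
    n_samples: int = 300
    n_tissues: int = 10
    abundance_log10_range: tuple = (1.0, 5.0)
    variance_class_fractions: dict = field(
        default_factory=lambda: {"low": 1 / 3, "mid": 1 / 3, "high": 1 / 3})
    ev_sigma: dict = field(
        default_factory=lambda: {"low": 0.1, "mid": 0.35, "high": 1.0})
    tissue_effect_sd: float = 0.5
    n_terms: int = 200
    term_size_range: tuple = (5, 100)
    layer_sizes: dict = field(
        default_factory=lambda: {"GM": 60, "SF": 80, "GR": 120, "RS": 200,
                                 "RS2": 240, "other": 1300})
    hub_exponent: float = 2.0
    ev_degree_coupling: float = -0.8
    seed: int = 0

    # generator details beyond the headline knobs
    module_pure_fraction: float = 0.9
    pathway_term_fraction: float = 0.25
    probes_per_gene_range: tuple = (1, 1)
    probe_noise_sd: float = 0.2
    abundance_coupling: float = -0.3
    measurement_noise_sd: float = 0.1
    treatments_per_group: int = 2
    response_prob: dict = field(
        default_factory=lambda: {"low": 0.0, "mid": 0.15, "high": 0.6})

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_tissues", "n_terms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if set(self.variance_class_fractions) != set(VARIANCE_CLASSES):
            raise ConfigError("variance_class_fractions must cover "
                              f"{VARIANCE_CLASSES}")
        total = sum(self.variance_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"variance_class_fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.variance_class_fractions.values()):
            raise ConfigError("variance_class_fractions must be nonnegative")
        if set(self.ev_sigma) != set(VARIANCE_CLASSES):
            raise ConfigError(f"ev_sigma must cover {VARIANCE_CLASSES}")
        if any(v < 0 for v in self.ev_sigma.values()):
            raise ConfigError("ev_sigma values must be >= 0")
        if self.tissue_effect_sd < 0:
            raise ConfigError("tissue_effect_sd must be >= 0")
        lo, hi = self.abundance_log10_range
        if not lo <= hi:
            raise ConfigError("abundance_log10_range must be (lo, hi) with lo <= hi")
        missing = set(LAYERS) - set(self.layer_sizes)
        if missing:
            raise ConfigError(f"layer_sizes missing levels {sorted(missing)}")
        if any(v < 0 for v in self.layer_sizes.values()):
            raise ConfigError("layer_sizes must be >= 0")
        if sum(self.layer_sizes.values()) > self.n_genes:
            raise ConfigError("layer_sizes sum exceeds n_genes")
        tlo, thi = self.term_size_range
        if not (1 <= tlo <= thi):
            raise ConfigError("term_size_range must satisfy 1 <= lo <= hi")
        if thi > self.n_genes:
            raise ConfigError("term_size_range exceeds n_genes")
        if not -1.0 <= self.ev_degree_coupling <= 0.0:
            raise ConfigError("ev_degree_coupling must lie in [-1, 0]")
        if self.hub_exponent <= 0:
            raise ConfigError("hub_exponent must be > 0")
        if not 0.0 <= self.module_pure_fraction <= 1.0:
            raise ConfigError("module_pure_fraction must lie in [0, 1]")
        if not 0.0 <= self.pathway_term_fraction <= 1.0:
            raise ConfigError("pathway_term_fraction must lie in [0, 1]")
        plo, phi = self.probes_per_gene_range
        if not (1 <= plo <= phi):
            raise ConfigError("probes_per_gene_range must satisfy 1 <= lo <= hi")
        if self.treatments_per_group < 1:
            raise ConfigError("treatments_per_group must be >= 1")

    def genes(self) -> list:
        return [f"G{i:05d}" for i in range(self.n_genes)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """Planted per-gene and per-term truth shared by all generators."""

    variance_class: dict
    hierarchy_level: dict          # gene -> GM/SF/GR/RS/RS2/other
    promoter_class: dict = field(default_factory=dict)  # designated class
    term_module: dict = field(default_factory=dict)     # term -> module id
    gene_sigma: dict = field(default_factory=dict)      # effective noise SD
    gene_abundance: dict = field(default_factory=dict)  # mean intensity

    def layer_genes(self, layer: str) -> list:
        return sorted(g for g, lv in self.hierarchy_level.items() if lv == layer)


def plant_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw the shared planted truth: layers, variance classes, abundances
    and effective noise scales. Deterministic given the config seed."""
    rng = config._rng(_STREAM_TRUTH)
    genes = config.genes()
    order = [genes[i] for i in rng.permutation(config.n_genes)]

    levels: dict = {}
    pos = 0
    for layer in LAYERS:
        for g in order[pos:pos + config.layer_sizes[layer]]:
            levels[g] = layer
        pos += config.layer_sizes[layer]
    for g in order[pos:]:
        levels[g] = "other"

    frac = config.variance_class_fractions
    classes: dict = {}
    for g in genes:
        layer = levels[g]
        probs = LAYER_CLASS_PROBS.get(layer, frac)
        p = np.array([probs[c] for c in VARIANCE_CLASSES], dtype=float)
        p = p / p.sum() if p.sum() > 0 else np.ones(3) / 3
        classes[g] = VARIANCE_CLASSES[rng.choice(3, p=p)]

    lo, hi = config.abundance_log10_range
    log10_mean = rng.uniform(lo, hi, size=config.n_genes)
    abundance = {g: float(10.0 ** m) for g, m in zip(genes, log10_mean)}

    z = log10_mean - log10_mean.mean()
    sd = z.std()
    z = z / sd if sd > 0 else z * 0.0
    sigma = {}
    for g, zi in zip(genes, z):
        base = config.ev_sigma[classes[g]] * LAYER_SIGMA_MULT[levels[g]]
        sigma[g] = float(base * np.exp(config.abundance_coupling * zi))

    return GroundTruth(variance_class=classes, hierarchy_level=levels,
                       gene_sigma=sigma, gene_abundance=abundance)


def _emit_probes(config: SimConfig, rng: np.random.Generator,
                 gene_values: np.ndarray, genes: list):
    """Expand gene-level values into probe rows sharing the gene signal.

    Returns (values array, probe ids, probe_to_gene). With the default
    single-probe range the probe id equals the gene id.
    """
    plo, phi = config.probes_per_gene_range
    if (plo, phi) == (1, 1):
        return gene_values, list(genes), {g: g for g in genes}
    counts = rng.integers(plo, phi + 1, size=len(genes))
    rows, ids, mapping = [], [], {}
    for gi, g in enumerate(genes):
        for k in range(counts[gi]):
            noise = np.exp(rng.normal(0.0, config.probe_noise_sd,
                                      size=gene_values.shape[1]))
            rows.append(gene_values[gi] * noise)
            pid = f"{g}_p{k + 1}"
            ids.append(pid)
            mapping[pid] = g
    return np.vstack(rows), ids, mapping


def generate_tissue_compendium(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Tissue-compendium intensities: mean x tissue effect x lognormal noise.

    Samples are assigned to tissues round-robin; each (gene, tissue)
    pair has a fixed multiplicative effect so tissue-subset EV analyses
    share gene-level signal. All values are strictly positive.
    """
    truth = plant_ground_truth(config)
    rng = config._rng(_STREAM_TISSUE)
    genes = config.genes()
    tissues = [f"T{t:02d}" for t in range(config.n_tissues)]
    sample_ids = [f"S{s:04d}" for s in range(config.n_samples)]
    tissue_of = {s: tissues[i % config.n_tissues] for i, s in enumerate(sample_ids)}

    mean = np.array([truth.gene_abundance[g] for g in genes])
    sigma = np.array([truth.gene_sigma[g] for g in genes])
    tissue_fx = np.exp(rng.normal(0.0, config.tissue_effect_sd,
                                  size=(config.n_genes, config.n_tissues)))
    t_idx = np.array([tissues.index(tissue_of[s]) for s in sample_ids])
    noise = np.exp(rng.normal(0.0, 1.0, size=(config.n_genes, config.n_samples))
                   * sigma[:, None])
    values = mean[:, None] * tissue_fx[:, t_idx] * noise

    values, ids, mapping = _emit_probes(config, rng, values, genes)
    frame = pd.DataFrame(values, index=ids, columns=sample_ids)
    meta = pd.DataFrame({
        "tissue": [tissue_of[s] for s in sample_ids],
        "treatment": "",
        "control_id": "",
    }, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(frame, meta, "intensity", mapping), truth


def generate_treatment_compendium(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Control-paired stimulation experiments.

    Samples come in groups of one control plus ``treatments_per_group``
    treatment columns; each treatment column records its control in the
    metadata. Per (gene, treatment) the gene responds with a class-
    dependent probability, with log2 response amplitude drawn at the
    gene's planted noise scale — high-variance genes respond to many
    stimuli, low-variance genes to essentially none.
    """
    truth = plant_ground_truth(config)
    rng = config._rng(_STREAM_TREATMENT)
    genes = config.genes()
    group_size = 1 + config.treatments_per_group
    n_groups = config.n_samples // group_size
    if n_groups < 1:
        raise ConfigError("n_samples too small for one control/treatment group")

    mean = np.array([truth.gene_abundance[g] for g in genes])
    sigma = np.array([truth.gene_sigma[g] for g in genes])
    resp_p = np.array([config.response_prob[truth.variance_class[g]] for g in genes])

    cols, meta_rows = {}, []
    for gidx in range(n_groups):
        cid = f"C{gidx:03d}"
        ctrl = mean * np.exp(rng.normal(0.0, config.measurement_noise_sd,
                                        size=config.n_genes))
        cols[cid] = ctrl
        meta_rows.append((cid, "", "control", ""))
        for t in range(config.treatments_per_group):
            sid = f"{cid}_T{t + 1}"
            responds = rng.random(config.n_genes) < resp_p
            logfc = np.where(responds,
                             rng.normal(0.0, 1.0, size=config.n_genes) * sigma,
                             0.0)
            treat = (mean * np.exp(logfc * np.log(2.0))
                     * np.exp(rng.normal(0.0, config.measurement_noise_sd,
                                         size=config.n_genes)))
            cols[sid] = treat
            meta_rows.append((sid, "", f"stim{gidx:03d}_{t + 1}", cid))

    sample_ids = [r[0] for r in meta_rows]
    values = pd.DataFrame({s: cols[s] for s in sample_ids}, index=genes)
    meta = pd.DataFrame(
        {"tissue": [r[1] for r in meta_rows],
         "treatment": [r[2] for r in meta_rows],
         "control_id": [r[3] for r in meta_rows]},
        index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(values, meta, "intensity", {g: g for g in genes}), truth


def generate_annotations(config: SimConfig, truth: GroundTruth) -> AnnotationSet:
    """Annotation terms with small-size skew and planted pure modules.

    A ``module_pure_fraction`` of terms draw all genes from a single
    variance class (the planted functional modules recorded in
    ``truth.term_module``); the remainder draw uniformly. A
    ``pathway_term_fraction`` of terms are pathway-style. Genes missing
    from every term are appended to a random term so the union of terms
    covers the gene universe.
    """
    genes = config.genes()
    missing = [g for g in genes if g not in truth.variance_class]
    if missing:
        raise ConfigError(f"ground truth does not cover gene {missing[0]}")
    rng = config._rng(_STREAM_ANNOTATION)
    tlo, thi = config.term_size_range

    by_class = {c: [g for g in genes if truth.variance_class[g] == c]
                for c in VARIANCE_CLASSES}
    n_pathway = int(round(config.pathway_term_fraction * config.n_terms))
    terms: dict = {}
    sources: dict = {}
    for i in range(config.n_terms):
        # log-uniform sizes: skew toward small terms
        size = int(round(np.exp(rng.uniform(np.log(tlo), np.log(thi)))))
        size = max(tlo, min(thi, size))
        pathway = i < n_pathway
        tid = f"P{i:04d}" if pathway else f"T{i:04d}"
        pure = rng.random() < config.module_pure_fraction
        if pure:
            cls = VARIANCE_CLASSES[rng.choice(3)]
            pool = by_class[cls] if by_class[cls] else genes
            truth.term_module[tid] = cls
        else:
            pool = genes
            truth.term_module[tid] = "random"
        size = min(size, len(pool))
        members = rng.choice(len(pool), size=size, replace=False)
        terms[tid] = frozenset(pool[j] for j in members)
        sources[tid] = "pathway_style" if pathway else "GO_style"

    covered = set().union(*terms.values())
    uncovered = [g for g in genes if g not in covered]
    tids = sorted(terms)
    for g in uncovered:
        tid = tids[rng.choice(len(tids))]
        terms[tid] = terms[tid] | {g}
    return AnnotationSet(terms, frozenset(genes), sources)


def generate_signaling_network(
    config: SimConfig, truth: GroundTruth
) -> tuple[GeneNetwork, AnnotationSet]:
    """Layered directed signaling network plus GO membership lists.

    Edges run predominantly down the cascade (GM -> SF -> GR -> RS ->
    RS2) with construction guarantees matching the level definitions:
    every SF gene signals to a receptor, every GM gene to an SF gene and
    never to a receptor, every RS gene receives from a receptor, every
    RS2 gene from an RS gene and never touches a receptor. Extra edges
    among RS∪RS2 follow a hub-skewed weight distribution; with negative
    ``ev_degree_coupling`` the hub weights concentrate on low-variance
    genes.
    """
    rng = config._rng(_STREAM_NETWORK)
    gm = truth.layer_genes("GM")
    sf = truth.layer_genes("SF")
    gr = truth.layer_genes("GR")
    rs = truth.layer_genes("RS")
    rs2 = truth.layer_genes("RS2")
    other = truth.layer_genes("other")
    if not gr:
        raise ConfigError("layer_sizes['GR'] is 0: hierarchy undefined without "
                          "receptors")

    edges: set = set()

    def pick(pool: list, k: int) -> list:
        k = min(k, len(pool))
        return [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]

    for g in gm:
        if sf:
            for t in pick(sf, int(rng.integers(1, 4))):
                edges.add((g, t, "binds"))
    for g in sf:
        for t in pick(gr, int(rng.integers(1, 4))):
            edges.add((g, t, "activates"))
    for g in rs:
        for s in pick(gr, int(rng.integers(1, 3))):
            edges.add((s, g, "activates"))
    for g in rs2:
        if rs:
            for s in pick(rs, int(rng.integers(1, 4))):
                edges.add((s, g, "activates"))

    # hub-skewed extra connectivity among the receptor-substrate levels
    substrates = sorted(set(rs) | set(rs2))
    if len(substrates) >= 2:
        m_extra = 3 * len(substrates)
        u = rng.random(len(substrates))
        weights = np.sort((1.0 - u) ** (-1.0 / config.hub_exponent))[::-1]
        c = abs(config.ev_degree_coupling)
        sig = np.array([truth.gene_sigma[g] for g in substrates])
        sigma_rank = pd.Series(sig).rank(method="first").to_numpy()
        score = c * (-sigma_rank) + (1.0 - c) * len(substrates) * rng.random(len(substrates))
        order = np.argsort(-score)  # best score gets the largest weight
        w = np.empty(len(substrates))
        w[order] = weights
        p = w / w.sum()
        gr_set = set(gr)
        attempts = 0
        added = 0
        existing = {(a, b) for a, b, _ in edges} | {(b, a) for a, b, _ in edges}
        while added < m_extra and attempts < 50 * m_extra:
            attempts += 1
            i, j = rng.choice(len(substrates), size=2, p=p)
            a, b = substrates[i], substrates[j]
            if a == b or (a, b) in existing:
                continue
            # RS2 genes must never touch a receptor; substrate-substrate
            # edges cannot violate that, but keep reciprocals out
            edges.add((a, b, "binds"))
            existing.add((a, b))
            existing.add((b, a))
            added += 1

    nodes = set(gm) | set(sf) | set(gr) | set(rs) | set(rs2)
    network = GeneNetwork.from_edges(edges, directed=True, provenance="signaling",
                                     extra_nodes=nodes)

    def sample_frac(pool: list, frac: float) -> set:
        k = int(round(frac * len(pool)))
        return set(pick(pool, k))

    receptor_activity = set(gr) | sample_frac(other, 0.01)
    transmembrane = set(pick(gr, len(gr) // 2))
    plasma_membrane = set(gr) | sample_frac(rs, 0.2)
    extracellular = set(gm) | set(sf)
    receptor_binding = sample_frac(sf, 0.6) | sample_frac(gm, 0.2)
    growth_factor = sample_frac(sf, 0.3)
    cytokine = sample_frac(sf, 0.2)

    universe = frozenset(config.genes())
    terms = {
        GO_RECEPTOR_ACTIVITY: frozenset(receptor_activity),
        GO_TRANSMEMBRANE_RECEPTOR_ACTIVITY: frozenset(transmembrane or set(gr[:1])),
        GO_PLASMA_MEMBRANE: frozenset(plasma_membrane),
        GO_EXTRACELLULAR_SPACE: frozenset(extracellular) or frozenset(gr[:1]),
        GO_RECEPTOR_BINDING: frozenset(receptor_binding) or frozenset(sf[:1] or gr[:1]),
        GO_GROWTH_FACTOR_ACTIVITY: frozenset(growth_factor) or frozenset(sf[:1] or gr[:1]),
        GO_CYTOKINE_ACTIVITY: frozenset(cytokine) or frozenset(sf[:1] or gr[:1]),
    }
    membership = AnnotationSet({t: g for t, g in terms.items() if g}, universe)
    return network, membership


def generate_promoter_classes(truth: GroundTruth, fidelity: float = 0.8,
                              seed: int = 0) -> dict:
    """Promoter-class labels tied to the planted variance classes.

    Each gene has a designated class — low-variance genes class I or III
    (active promoters), high-variance genes class IV, except high-variance
    intracellular signaling genes (RS/RS2) which are designated class II;
    mid-variance genes draw a uniformly random designation. The gene
    receives its designated class with probability ``fidelity`` and each
    of the other three classes with probability (1 - fidelity)/3, so
    fidelity 1 is a perfect labeling and fidelity 0.25 is uniform noise.
    Designations are recorded in ``truth.promoter_class``.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ConfigError(f"fidelity must lie in [0, 1], got {fidelity}")
    rng = np.random.default_rng([int(seed), _STREAM_PROMOTER])
    classes = ("I", "II", "III", "IV")
    out: dict = {}
    for g in sorted(truth.variance_class):
        vc = truth.variance_class[g]
        layer = truth.hierarchy_level.get(g, "other")
        if vc == "low":
            designated = classes[rng.choice([0, 2])]
        elif vc == "high":
            designated = "II" if layer in ("RS", "RS2") else "IV"
        else:
            designated = classes[rng.choice(4)]
        truth.promoter_class[g] = designated
        p = np.full(4, (1.0 - fidelity) / 3.0)
        p[classes.index(designated)] = fidelity
        out[g] = classes[rng.choice(4, p=p)]
    return out


def default_config(**overrides) -> SimConfig:
    """The reference synthetic-study configuration, with overrides."""
    return replace(SimConfig(), **overrides)
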