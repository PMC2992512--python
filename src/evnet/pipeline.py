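"""End-to-end orchestration: simulate -> EV -> Fun-Net -> density ->
hierarchy -> enrichment -> centrality, with a reproducibility manifest.

A run is described by a :class:`RunConfig` (loadable from YAML). Every
stage writes its tables into the output directory; the manifest records
inputs, parameters, the seed and a content hash of each output (tables
are rounded to 10 significant digits before hashing, so reruns with the
same config produce identical hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centrality as centrality_mod
from . import density as density_mod
from . import ev as ev_mod
from . import funnet as funnet_mod
from . import hierarchy as hierarchy_mod
from . import io as io_mod
from . import simulate as sim_mod
from . import stats as stats_mod
from .datatypes import HierarchyAssignment, validate_promoter_classes
from .errors import EVNetError, PipelineError, ValidationError

log = logging.getLogger(__name__)

STAGES = ("simulate", "ev", "funnet", "density", "hierarchy", "enrich", "centrality")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str = "evnet_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate block (used when stages['simulate'] is on)
    simulate: dict = field(default_factory=dict)
    promoter_fidelity: float = 0.8
    # input paths (used when simulate is off)
    inputs: dict = field(default_factory=dict)
    # analysis parameters
    n_bins: int = 50
    funnet_threshold: float = 0.001
    top_k: int = 500
    min_term_size: int = 6
    enrich_p_cutoff: float = 1e-5
    ev_hi: float = 0.9
    ev_lo: float = 0.1
    quantile_cutoffs: bool = True
    degree_bins: int = 20
    hierarchy_mode: str = "either"

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if not 0 < self.funnet_threshold <= 1:
            raise ValidationError("funnet_threshold must be in (0, 1]")
        if self.n_bins < 2 or self.degree_bins < 2:
            raise ValidationError("bin counts must be >= 2")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> sim_mod.SimConfig:
        block = dict(self.simulate)
        block.setdefault("seed", self.seed)
        for key in ("abundance_log10_range", "term_size_range",
                    "probes_per_gene_range"):
            if key in block and isinstance(block[key], list):
                block[key] = tuple(block[key])
        return sim_mod.SimConfig(**block)


def _hash_table(df: pd.DataFrame) -> str:
    """Content hash of a table, floats rounded to 10 significant digits."""
    def fmt(x):
        if isinstance(x, (float, np.floating)):
            return f"{x:.10g}"
        return str(x)

    text = df.to_csv(sep="\t", float_format="%.10g")
    return hashlib.sha256(text.encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ValidationReport:
    errors: list
    warnings: list

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Check referenced input files parse and cross-cover each other.

    Format violations and missing files are errors; soft issues (partial
    gene overlap) are warnings. With the simulate stage on there is
    nothing to check and the report is empty.
    """
    errors: list = []
    warnings: list = []
    if config.stages.get("simulate", True):
        return ValidationReport(errors, warnings)

    paths = config.inputs
    loaded: dict = {}
    for key in ("expression", "sample_metadata", "annotations", "signaling",
                "promoter_classes", "universe"):
        p = paths.get(key)
        if p is None:
            continue
        if not Path(p).exists():
            errors.append(f"{key}: path {p} does not exist")
            continue
        try:
            if key == "expression":
                loaded[key] = io_mod.read_expression_tsv(
                    p, paths.get("sample_metadata"))
            elif key == "annotations":
                uni = None
                if paths.get("universe") and Path(paths["universe"]).exists():
                    uni = io_mod.read_universe(paths["universe"])
                loaded[key] = io_mod.read_gmt(p, uni)
            elif key == "signaling":
                loaded[key] = io_mod.read_sif(p, directed=True,
                                              provenance="signaling")
            elif key == "promoter_classes":
                loaded[key] = validate_promoter_classes(
                    io_mod.read_gene_map(p, "class"))
        except (EVNetError, OSError, ValueError) as exc:
            errors.append(f"{key}: {exc}")

    expr = loaded.get("expression")
    ann = loaded.get("annotations")
    net = loaded.get("signaling")
    if expr is not None and ann is not None:
        genes = set((expr.probe_to_gene or {}).values()) or set(expr.values.index)
        shared = genes & set(ann.universe)
        if not shared:
            errors.append("expression and annotations share no genes")
        elif len(shared) < 0.5 * len(genes):
            warnings.append("fewer than half the expression genes are in the "
                            "annotation universe")
    if expr is not None and net is not None:
        genes = set((expr.probe_to_gene or {}).values()) or set(expr.values.index)
        if not genes & set(net.nodes):
            errors.append("expression table and signaling network share no genes")
    return ValidationReport(errors, warnings)


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest.

    A stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logging.getLogger().addHandler(fh)

    manifest: dict = {
        "seed": config.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(config).items()
                       if k not in ("stages",)},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    def record(name: str, path: Path, table: pd.DataFrame | None = None) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _hash_table(table) if table is not None else _hash_file(path),
        }

    stage_fns = [
        ("simulate", _stage_simulate),
        ("ev", _stage_ev),
        ("funnet", _stage_funnet),
        ("density", _stage_density),
        ("hierarchy", _stage_hierarchy),
        ("enrich", _stage_enrich),
        ("centrality", _stage_centrality),
    ]
    try:
        for name, fn in stage_fns:
            if not config.stages.get(name, True):
                manifest["stages"][name] = "skipped"
                continue
            try:
                fn(config, state, outdir, record)
            except EVNetError as exc:
                manifest["stages"][name] = f"failed: {exc}"
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = "complete"
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
        logging.getLogger().removeHandler(fh)
        fh.close()
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise ValidationError(f"stage {stage!r} requires {key!r}; enable the "
                              "producing stage or supply it as an input")
    return state[key]


def _stage_simulate(config, state, outdir, record) -> None:
    sim = config.sim_config()
    tissue, truth = sim_mod.generate_tissue_compendium(sim)
    treat, _ = sim_mod.generate_treatment_compendium(sim)
    ann = sim_mod.generate_annotations(sim, truth)
    net, membership = sim_mod.generate_signaling_network(sim, truth)
    classes = sim_mod.generate_promoter_classes(truth, config.promoter_fidelity,
                                                seed=sim.seed)
    state.update(tissue=tissue, treatment=treat, annotations=ann,
                 signaling=net, membership=membership, classes=classes,
                 truth=truth)

    simdir = outdir / "sim"
    simdir.mkdir(exist_ok=True)
    io_mod.write_expression_tsv(tissue, simdir / "tissue_expression.tsv",
                                simdir / "tissue_samples.tsv")
    io_mod.write_expression_tsv(treat, simdir / "treatment_expression.tsv",
                                simdir / "treatment_samples.tsv")
    io_mod.write_gmt(ann, simdir / "annotations.gmt")
    io_mod.write_gmt(membership, simdir / "membership.gmt")
    io_mod.write_sif(net, simdir / "signaling.sif")
    io_mod.write_gene_map(classes, simdir / "promoter_classes.tsv", "class")
    truth_table = pd.DataFrame({
        "variance_class": pd.Series(truth.variance_class),
        "hierarchy_level": pd.Series(truth.hierarchy_level),
        "promoter_class": pd.Series(truth.promoter_class),
    }).rename_axis("gene").sort_index()
    truth_table.to_csv(simdir / "ground_truth.tsv", sep="\t")
    record("ground_truth", simdir / "ground_truth.tsv", truth_table)
    for fname in ("tissue_expression.tsv", "treatment_expression.tsv",
                  "annotations.gmt", "membership.gmt", "signaling.sif",
                  "promoter_classes.tsv"):
        record(fname.rsplit(".", 1)[0], simdir / fname)


def _stage_ev(config, state, outdir, record) -> None:
    if "tissue" not in state and config.inputs.get("expression"):
        state["tissue"] = io_mod.read_expression_tsv(
            config.inputs["expression"], config.inputs.get("sample_metadata"))
    tissue = _require(state, "tissue", "ev")
    probe_ev = ev_mod.ev_expo(tissue)
    mapping = tissue.probe_to_gene or {p: p for p in probe_ev.index}
    gene_ev, probe_qc = ev_mod.collapse_probes(probe_ev, mapping, seed=config.seed)
    state["ev_expo"] = gene_ev
    io_mod.write_ev_table(gene_ev, outdir / "ev_expo.tsv")
    record("ev_expo", outdir / "ev_expo.tsv", gene_ev)

    summary = {"probe_pair_ev_spearman": probe_qc}
    if "treatment" in state:
        ck = ev_mod.ev_ck(state["treatment"])
        state["ev_ck"] = ck
        io_mod.write_ev_table(ck, outdir / "ev_ck.tsv")
        record("ev_ck", outdir / "ev_ck.tsv", ck)
        rho = stats_mod.spearman(gene_ev["ev"], ck["ev"])
        part = stats_mod.partial_spearman(gene_ev["ev"], ck["ev"],
                                          gene_ev["mean_expr"])
        summary.update(ev_expo_ck_spearman=rho.estimate, ev_expo_ck_p=rho.p,
                       ev_expo_ck_partial_given_abundance=part.estimate,
                       n_shared_genes=rho.n)
    (outdir / "ev_summary.json").write_text(json.dumps(summary, indent=2,
                                                       sort_keys=True))
    record("ev_summary", outdir / "ev_summary.json")


def _stage_funnet(config, state, outdir, record) -> None:
    if "annotations" not in state and config.inputs.get("annotations"):
        uni = None
        if config.inputs.get("universe"):
            uni = io_mod.read_universe(config.inputs["universe"])
        state["annotations"] = io_mod.read_gmt(config.inputs["annotations"], uni)
    ann = _require(state, "annotations", "funnet")
    net = funnet_mod.build_funnet(ann, config.funnet_threshold)
    state["funnet"] = net
    io_mod.write_sif(net, outdir / "funnet.sif")
    record("funnet", outdir / "funnet.sif")


def _stage_density(config, state, outdir, record) -> None:
    ev = _require(state, "ev_expo", "density")
    net = _require(state, "funnet", "density")
    bins = density_mod.bin_by_ev(ev, config.n_bins)
    dm = density_mod.density_matrix(net, bins)
    shuffled = density_mod.shuffle_nodes(net, seed=config.seed)
    dm_shuf = density_mod.density_matrix(shuffled, bins)
    state["density"] = dm
    state["density_shuffled"] = dm_shuf
    io_mod.write_density(dm, outdir / "density.tsv")
    io_mod.write_density(dm_shuf, outdir / "density_shuffled.tsv")
    record("density", outdir / "density.tsv", dm.to_frame())
    record("density_shuffled", outdir / "density_shuffled.tsv", dm_shuf.to_frame())
    _heatmap_png(dm, outdir / "density.png")


def _heatmap_png(dm, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(dm.density, origin="lower", cmap="viridis")
    ax.set_xlabel("EV bin")
    ax.set_ylabel("EV bin")
    fig.colorbar(im, ax=ax, label="interaction density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage_hierarchy(config, state, outdir, record) -> None:
    if "signaling" not in state and config.inputs.get("signaling"):
        state["signaling"] = io_mod.read_sif(config.inputs["signaling"],
                                             directed=True, provenance="signaling")
    if "membership" not in state and config.inputs.get("membership"):
        state["membership"] = io_mod.read_gmt(config.inputs["membership"])
    net = _require(state, "signaling", "hierarchy")
    membership = _require(state, "membership", "hierarchy")
    inputs = hierarchy_mod.HierarchyInputs.from_annotations(membership, net)
    assignment = hierarchy_mod.assign_levels(inputs, mode=config.hierarchy_mode)
    state["assignment"] = assignment
    ser = assignment.to_series()
    ser.rename_axis("gene").to_csv(outdir / "hierarchy_assignment.tsv", sep="\t")
    record("hierarchy_assignment", outdir / "hierarchy_assignment.tsv",
           ser.to_frame())
    if "ev_expo" in state:
        profile = hierarchy_mod.level_ev_profile(assignment, state["ev_expo"])
        state["level_profile"] = profile
        profile.summary.to_csv(outdir / "level_ev_summary.tsv", sep="\t")
        profile.tests.to_csv(outdir / "level_ev_tests.tsv", sep="\t", index=False)
        record("level_ev_summary", outdir / "level_ev_summary.tsv", profile.summary)
        record("level_ev_tests", outdir / "level_ev_tests.tsv", profile.tests)


def _stage_enrich(config, state, outdir, record) -> None:
    ev = _require(state, "ev_expo", "enrich")
    ann = _require(state, "annotations", "enrich")
    universe = set(ev.index) & set(ann.universe)
    high, low = stats_mod.top_bottom_sets(ev.loc[sorted(universe)], config.top_k)
    for name, query in (("high", high), ("low", low)):
        table = stats_mod.hypergeom_enrich(query, ann, universe,
                                           config.min_term_size,
                                           config.enrich_p_cutoff)
        table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        record(f"enrichment_{name}", outdir / f"enrichment_{name}.tsv", table)
    if "assignment" in state and "classes" in state:
        heat = stats_mod.class_level_heatmap(state["assignment"], state["classes"])
        heat.to_csv(outdir / "class_level_heatmap.tsv", sep="\t")
        record("class_level_heatmap", outdir / "class_level_heatmap.tsv", heat)


def _stage_centrality(config, state, outdir, record) -> None:
    if "classes" not in state and config.inputs.get("promoter_classes"):
        state["classes"] = validate_promoter_classes(
            io_mod.read_gene_map(config.inputs["promoter_classes"], "class"))
    net = _require(state, "signaling", "centrality")
    ev = _require(state, "ev_expo", "centrality")
    assignment = _require(state, "assignment", "centrality")
    deg = centrality_mod.degrees(net)
    report = centrality_mod.ev_degree_analysis(
        deg, ev, assignment, n_bins=config.degree_bins, hi=config.ev_hi,
        lo=config.ev_lo, quantile_cutoffs=config.quantile_cutoffs,
        promoter_classes=state.get("classes"))
    state["centrality"] = report
    deg.rename_axis("gene").to_csv(outdir / "degrees.tsv", sep="\t")
    report.bin_mean_degree.to_csv(outdir / "degree_by_ev_bin.tsv", sep="\t")
    report.level_interactions.rename_axis("level").to_csv(
        outdir / "level_interactions.tsv", sep="\t")
    summary = {
        "spearman_ev_degree": report.spearman_ev_degree.estimate,
        "spearman_ev_degree_p": report.spearman_ev_degree.p,
        "n_rs_genes": report.n_genes,
        "high_vs_low_degree_p": (report.high_low_test.p
                                 if report.high_low_test else None),
        "class_I_vs_II_degree_p": (report.class_test.p
                                   if report.class_test else None),
    }
    (outdir / "centrality_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    sub, attrs = centrality_mod.export_subnetwork(
        net, ev, assignment, hi=config.ev_hi, lo=config.ev_lo,
        quantile_cutoffs=config.quantile_cutoffs)
    io_mod.write_sif(sub, outdir / "extreme_ev_subnetwork.sif")
    attrs.to_csv(outdir / "extreme_ev_nodes.tsv", sep="\t")
    for name in ("degrees.tsv", "degree_by_ev_bin.tsv", "level_interactions.tsv",
                 "centrality_summary.json", "extreme_ev_subnetwork.sif",
                 "extreme_ev_nodes.tsv"):
        record(name.rsplit(".", 1)[0], outdir / name)
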