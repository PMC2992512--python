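"""Degree-centrality analyses relating EV to interaction counts.

The number of protein-protein interactions of a signaling protein is a
proxy for how many processes it participates in. These analyses test the
hypothesis that highly regulated (high-EV) signaling genes are
functionally peripheral: EV-vs-degree correlation over the receptor
substrate levels, degree profiles over EV-ordered bins, and comparisons
of the extreme EV tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GeneNetwork, HierarchyAssignment, HIERARCHY_LEVELS
from .density import bin_by_ev
from .errors import ValidationError
from .stats import StatResult, spearman, wilcoxon_rank_sum

log = logging.getLogger(__name__)


def degrees(network: GeneNetwork) -> pd.Series:
    """Per-node count of incident interactions, direction ignored.

    Directed edges count once; a reciprocal directed pair represents one
    interaction. Returns an integer Series over all network nodes.
    """
    deg = {n: 0 for n in network.nodes}
    for u, v in network.undirected_pairs():
        deg[u] += 1
        deg[v] += 1
    out = pd.Series(deg, name="degree").sort_index()
    out.attrs["provenance"] = network.provenance
    return out


def _ev_thresholds(ev_vals: pd.Series, hi: float, lo: float, quantile: bool):
    if quantile:
        return float(np.quantile(ev_vals, hi)), float(np.quantile(ev_vals, lo))
    return hi, lo


@dataclass
class EVDegreeReport:
    """Output bundle of :func:`ev_degree_analysis`."""

    spearman_ev_degree: StatResult
    bin_mean_degree: pd.DataFrame          # per EV-ordered bin: n, mean_ev, mean_degree
    high_low_test: StatResult | None       # degrees of high-EV vs low-EV genes
    high_low_note: str
    level_interactions: pd.Series          # total interactions per hierarchy level
    class_test: StatResult | None          # promoter class I vs II degrees
    class_note: str
    n_genes: int


def ev_degree_analysis(
    deg: pd.Series,
    ev: pd.DataFrame,
    assignment: HierarchyAssignment,
    n_bins: int = 20,
    hi: float = 0.9,
    lo: float = 0.1,
    quantile_cutoffs: bool = True,
    promoter_classes: dict | None = None,
) -> EVDegreeReport:
    """Relate EV to interaction counts over the RS∪RS2 levels.

    Computes (a) the Spearman correlation of EV vs degree over RS∪RS2
    genes, (b) mean degree per EV-ordered bin, (c) a rank-sum comparison
    of degrees between genes above the ``hi`` and below the ``lo`` EV
    cutoff (quantiles of the current EV distribution by default, absolute
    values with ``quantile_cutoffs=False``), (d) total interactions per
    hierarchy level, and (e) when promoter classes are supplied, a
    class I vs class II degree comparison within RS∪RS2.
    """
    rs_genes = sorted((assignment.genes_at("RS") | assignment.genes_at("RS2"))
                      & set(ev.index) & set(deg.index))
    if not rs_genes:
        raise ValidationError("no RS/RS2 genes shared between EV table, degrees "
                              "and hierarchy assignment")
    ev_rs = ev.loc[rs_genes, "ev"]
    deg_rs = deg.loc[rs_genes].astype(float)

    rho = spearman(ev_rs, deg_rs)

    sub = ev.loc[rs_genes]
    if len(rs_genes) >= n_bins:
        bins = bin_by_ev(sub, n_bins)
        rows = []
        for b in range(n_bins):
            genes_b = [g for g in rs_genes if bins[g] == b]
            rows.append({
                "bin": b,
                "n": len(genes_b),
                "mean_ev": float(ev_rs.loc[genes_b].mean()),
                "mean_degree": float(deg_rs.loc[genes_b].mean()),
            })
        bin_means = pd.DataFrame(rows).set_index("bin")
    else:
        log.warning("ev_degree_analysis: fewer RS/RS2 genes than bins; "
                    "bin profile skipped")
        bin_means = pd.DataFrame(columns=["n", "mean_ev", "mean_degree"])

    hi_thr, lo_thr = _ev_thresholds(ev_rs, hi, lo, quantile_cutoffs)
    high = deg_rs[ev_rs > hi_thr]
    low = deg_rs[ev_rs < lo_thr]
    if len(high) and len(low):
        hl_test, hl_note = wilcoxon_rank_sum(high, low), ""
    else:
        hl_test = None
        hl_note = f"skipped: empty group (high n={len(high)}, low n={len(low)})"
        log.warning("ev_degree_analysis: %s", hl_note)

    level_counts = pd.Series(
        {lv: int(deg.loc[sorted(assignment.genes_at(lv) & set(deg.index))].sum())
         for lv in HIERARCHY_LEVELS},
        name="total_interactions",
    )

    cls_test, cls_note = None, "promoter classes not supplied"
    if promoter_classes is not None:
        d1 = deg_rs[[g for g in rs_genes if promoter_classes.get(g) == "I"]]
        d2 = deg_rs[[g for g in rs_genes if promoter_classes.get(g) == "II"]]
        if len(d1) and len(d2):
            cls_test, cls_note = wilcoxon_rank_sum(d1, d2), ""
        else:
            cls_note = f"skipped: empty class group (I n={len(d1)}, II n={len(d2)})"
            log.warning("ev_degree_analysis: %s", cls_note)

    return EVDegreeReport(rho, bin_means, hl_test, hl_note, level_counts,
                          cls_test, cls_note, len(rs_genes))


def export_subnetwork(
    network: GeneNetwork,
    ev: pd.DataFrame,
    assignment: HierarchyAssignment,
    hi: float = 0.9,
    lo: float = 0.1,
    quantile_cutoffs: bool = True,
) -> tuple[GeneNetwork, pd.DataFrame]:
    """Induced subgraph on extreme-EV RS∪RS2 genes, with node attributes.

    Selects RS/RS2 genes with EV strictly above the ``hi`` cutoff or
    strictly below the ``lo`` cutoff and returns the induced subnetwork
    plus a node-attribute table (gene, ev, level, ev_group) for use in
    any network viewer. An empty selection yields an empty network with
    a logged warning.
    """
    rs_genes = sorted((assignment.genes_at("RS") | assignment.genes_at("RS2"))
                      & set(ev.index))
    ev_rs = ev.loc[rs_genes, "ev"]
    hi_thr, lo_thr = _ev_thresholds(ev_rs, hi, lo, quantile_cutoffs)
    selected = [g for g in rs_genes if ev_rs[g] > hi_thr or ev_rs[g] < lo_thr]
    sel = set(selected)
    edges = [(u, v, rel) for u, v, rel in network.edges if u in sel and v in sel]
    sub = GeneNetwork.from_edges(edges, directed=network.directed,
                                 provenance=network.provenance, extra_nodes=sel)
    attrs = pd.DataFrame({
        "ev": ev_rs.loc[selected],
        "level": [assignment.levels[g] for g in selected],
        "ev_group": ["high" if ev_rs[g] > hi_thr else "low" for g in selected],
    })
    attrs.index.name = "gene"
    if not selected:
        log.warning("export_subnetwork: empty selection (hi=%s, lo=%s)", hi, lo)
    return sub, attrs
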