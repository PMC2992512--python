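"""Signaling-hierarchy level assignment and per-level EV profiles.

Genes are placed on five levels of the cell-signaling cascade:

* **GR** (receptors): genes annotated with receptor activity or
  transmembrane receptor activity that also localize to the plasma
  membrane.
* **SF** (secreted factors): extracellular-space genes with a direct
  signaling interaction with a receptor.
* **GM** (growth-factor modulators): remaining extracellular genes that
  interact with a secreted factor but not with any receptor.
* **RS** (receptor substrates): intracellular genes with a direct
  interaction with a receptor.
* **RS2**: remaining genes interacting with an RS gene but not with any
  receptor.

Precedence is GR > SF > GM > RS > RS2; everything else is unassigned.
By default "direct signaling interaction" counts an edge in either
direction, since curated networks store ligand-receptor edges in both
orientations; ``mode="downstream"`` restricts the RS/RS2 rules to edges
leaving the upper level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (AnnotationSet, GeneNetwork, HierarchyAssignment,
                        HIERARCHY_LEVELS, UNASSIGNED)
from .errors import HierarchyError, ValidationError
from .stats import wilcoxon_rank_sum

#: GO identifiers of the membership lists the level rules consume.
GO_RECEPTOR_ACTIVITY = "GO:0004872"
GO_TRANSMEMBRANE_RECEPTOR_ACTIVITY = "GO:0004888"
GO_PLASMA_MEMBRANE = "GO:0005886"
GO_EXTRACELLULAR_SPACE = "GO:0005615"
GO_RECEPTOR_BINDING = "GO:0005102"
GO_GROWTH_FACTOR_ACTIVITY = "GO:0008083"
GO_CYTOKINE_ACTIVITY = "GO:0005125"

MEMBERSHIP_TERMS = (
    GO_RECEPTOR_ACTIVITY,
    GO_TRANSMEMBRANE_RECEPTOR_ACTIVITY,
    GO_PLASMA_MEMBRANE,
    GO_EXTRACELLULAR_SPACE,
    GO_RECEPTOR_BINDING,
    GO_GROWTH_FACTOR_ACTIVITY,
    GO_CYTOKINE_ACTIVITY,
)


@dataclass
class HierarchyInputs:
    """The seven GO membership lists plus the directed signaling network."""

    receptor_activity: set
    transmembrane_receptor_activity: set
    plasma_membrane: set
    extracellular_space: set
    receptor_binding: set
    growth_factor_activity: set
    cytokine_activity: set
    network: GeneNetwork

    @classmethod
    def from_annotations(cls, ann: AnnotationSet, network: GeneNetwork) -> "HierarchyInputs":
        """Pull the seven membership lists out of an annotation set by GO id.

        Missing terms become empty sets.
        """
        get = lambda t: set(ann.terms.get(t, frozenset()))
        return cls(
            receptor_activity=get(GO_RECEPTOR_ACTIVITY),
            transmembrane_receptor_activity=get(GO_TRANSMEMBRANE_RECEPTOR_ACTIVITY),
            plasma_membrane=get(GO_PLASMA_MEMBRANE),
            extracellular_space=get(GO_EXTRACELLULAR_SPACE),
            receptor_binding=get(GO_RECEPTOR_BINDING),
            growth_factor_activity=get(GO_GROWTH_FACTOR_ACTIVITY),
            cytokine_activity=get(GO_CYTOKINE_ACTIVITY),
            network=network,
        )

    def gene_space(self) -> set:
        space = set(self.network.nodes)
        for s in (self.receptor_activity, self.transmembrane_receptor_activity,
                  self.plasma_membrane, self.extracellular_space,
                  self.receptor_binding, self.growth_factor_activity,
                  self.cytokine_activity):
            space |= s
        return space


def ligand_sf_list(inputs: HierarchyInputs) -> set:
    """The ligand-defined secreted-factor gene set.

    Genes annotated with receptor binding, growth-factor activity or
    cytokine activity that also localize to the extracellular space —
    the named SF list used for the SF-vs-GR EV comparison, as opposed to
    the broader extracellular pool that seeds the SF/GM level rules.
    """
    return ((inputs.receptor_binding | inputs.growth_factor_activity
             | inputs.cytokine_activity) & inputs.extracellular_space)


def assign_levels(inputs: HierarchyInputs, mode: str = "either") -> HierarchyAssignment:
    """Assign every gene in the gene space to a hierarchy level.

    ``mode="either"`` (default) counts an interaction in either edge
    direction; ``mode="downstream"`` requires the RS/RS2 contact edge to
    leave the upper level (GR -> x for RS, RS -> x for RS2).
    """
    if mode not in ("either", "downstream"):
        raise ValidationError(f"unknown mode {mode!r}")
    net = inputs.network
    space = inputs.gene_space()

    gr = ((inputs.receptor_activity | inputs.transmembrane_receptor_activity)
          & inputs.plasma_membrane)
    if not gr and net.n_edges > 0:
        raise HierarchyError(
            "no receptors: (receptor activity ∪ transmembrane receptor activity)"
            " ∩ plasma membrane is empty, so the lower levels are undefined"
        )

    touch = net.adjacency()  # either-direction contacts
    down = net.out_adjacency()

    def contacts(g, upper: set, restrict_down: bool) -> bool:
        if g not in net.nodes:
            return False
        if restrict_down:
            return any(g in down.get(u, ()) for u in (upper & net.nodes))
        return bool(touch[g] & upper)

    strict = mode == "downstream"
    pool = inputs.extracellular_space - gr
    sf = {g for g in pool if contacts(g, gr, False)}
    gm = {g for g in pool - sf
          if contacts(g, sf, False) and not contacts(g, gr, False)}
    intracellular = space - inputs.extracellular_space - gr
    rs = {g for g in intracellular if contacts(g, gr, strict)}
    assigned = gr | sf | gm | rs
    rs2 = {g for g in space - assigned
           if contacts(g, rs, strict) and not contacts(g, gr, strict)}

    levels = {}
    for g in space:
        if g in gr:
            levels[g] = "GR"
        elif g in sf:
            levels[g] = "SF"
        elif g in gm:
            levels[g] = "GM"
        elif g in rs:
            levels[g] = "RS"
        elif g in rs2:
            levels[g] = "RS2"
        else:
            levels[g] = UNASSIGNED
    return HierarchyAssignment(levels)


@dataclass
class LevelProfile:
    """Per-level EV summaries plus pairwise rank-sum tests."""

    summary: pd.DataFrame
    tests: pd.DataFrame


def level_ev_profile(assignment: HierarchyAssignment, ev: pd.DataFrame) -> LevelProfile:
    """Summarize EV per hierarchy level and test adjacent-level differences.

    Summary columns: n, median, q1, q3 per level (plus the unassigned
    pool). Tests: two-sided Wilcoxon rank-sum for each adjacent level
    pair and each level vs the unassigned pool; comparisons involving a
    group of fewer than 2 EV values are skipped with a note.
    """
    ev_of = {}
    for lv in HIERARCHY_LEVELS + (UNASSIGNED,):
        genes = assignment.genes_at(lv)
        vals = ev.loc[ev.index.intersection(sorted(genes)), "ev"].to_numpy()
        if genes and len(vals) == 0 and lv != UNASSIGNED:
            raise ValidationError(f"no EV values for nonempty level {lv}")
        ev_of[lv] = vals

    rows = []
    for lv, vals in ev_of.items():
        rows.append({
            "level": lv,
            "n": len(vals),
            "median": float(np.median(vals)) if len(vals) else float("nan"),
            "q1": float(np.percentile(vals, 25)) if len(vals) else float("nan"),
            "q3": float(np.percentile(vals, 75)) if len(vals) else float("nan"),
        })
    summary = pd.DataFrame(rows).set_index("level")

    pairs = [(HIERARCHY_LEVELS[i], HIERARCHY_LEVELS[i + 1])
             for i in range(len(HIERARCHY_LEVELS) - 1)]
    pairs += [(lv, UNASSIGNED) for lv in HIERARCHY_LEVELS]
    test_rows = []
    for a, b in pairs:
        if len(ev_of[a]) < 2 or len(ev_of[b]) < 2:
            test_rows.append({"group_a": a, "group_b": b, "W": float("nan"),
                              "p": float("nan"),
                              "note": "skipped: group with <2 EV values"})
            continue
        res = wilcoxon_rank_sum(ev_of[a], ev_of[b])
        test_rows.append({"group_a": a, "group_b": b, "W": res.estimate,
                          "p": res.p, "note": ""})
    tests = pd.DataFrame(test_rows)
    return LevelProfile(summary, tests)
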