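"""Core in-memory containers used across the pipeline.

Tabular results (EV tables, enrichment tables, summaries) are plain
:class:`pandas.DataFrame` objects with documented column contracts; the
classes below exist for the structured objects that need invariants
enforced at construction time: expression matrices, annotation sets and
gene networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Column contract for EV tables (index = gene or probe identifier).
EV_COLUMNS = ["ev", "mean_expr", "n_samples_used", "dataset_tag"]

#: The recognized scales of an expression matrix.
SCALES = ("intensity", "log_ratio")

#: Hierarchy levels in apical-to-basal order, plus the catch-all.
HIERARCHY_LEVELS = ("GM", "SF", "GR", "RS", "RS2")
UNASSIGNED = "unassigned"

#: Promoter classes of the four-way promoter-architecture labeling.
PROMOTER_CLASSES = ("I", "II", "III", "IV")


@dataclass
class ExpressionMatrix:
    """A genes/probes x samples expression table with sample metadata.

    Parameters
    ----------
    values
        Rectangular table; index = probe (or gene) identifiers, columns =
        sample identifiers. On the ``intensity`` scale all values must be
        nonnegative; on the ``log_ratio`` scale values are signed.
    samples
        Per-sample metadata indexed by sample id. Recognized columns:
        ``tissue``, ``treatment``, ``control_id`` (empty string for
        samples that are themselves controls or untyped).
    scale
        ``"intensity"`` or ``"log_ratio"``.
    probe_to_gene
        Optional probe id -> gene id mapping when rows are probe-level.
    """

    values: pd.DataFrame
    samples: pd.DataFrame | None = None
    scale: str = "intensity"
    probe_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate row identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers in expression matrix")
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:5]}")
        if self.scale == "intensity":
            arr = self.values.to_numpy()
            if np.isnan(arr).any():
                raise ValidationError("missing values in intensity matrix")
            if (arr < 0).any():
                raise ValidationError("negative values on intensity scale")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to the given sample columns (order kept)."""
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            scale=self.scale,
            probe_to_gene=self.probe_to_gene,
        )


@dataclass
class AnnotationSet:
    """Named term -> gene-set mapping over an explicit gene universe.

    Each term carries a source tag: ``"GO_style"`` terms enter the
    overlap-significance rule, ``"pathway_style"`` terms grant an edge to
    every co-annotated pair outright.
    """

    terms: dict[str, frozenset]
    universe: frozenset
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        for t, genes in self.terms.items():
            if not genes:
                raise ValidationError(f"empty term {t!r}")
            extra = genes - self.universe
            if extra:
                raise ValidationError(
                    f"term {t!r} has genes outside the universe: {sorted(extra)[:5]}"
                )
        for t in self.terms:
            self.sources.setdefault(t, "GO_style")

    @property
    def n(self) -> int:
        """Size of the declared gene universe."""
        return len(self.universe)

    def terms_of_source(self, source: str) -> dict[str, frozenset]:
        return {t: g for t, g in self.terms.items() if self.sources[t] == source}

    def gene_index(self, source: str | None = None) -> dict[str, set]:
        """Inverted index gene -> set of term ids (optionally one source)."""
        idx: dict[str, set] = {}
        for t, genes in self.terms.items():
            if source is not None and self.sources[t] != source:
                continue
            for g in genes:
                idx.setdefault(g, set()).add(t)
        return idx


def _canonical_edge(u, v, relation: str, directed: bool):
    if directed or u <= v:
        return (u, v, relation)
    return (v, u, relation)


@dataclass
class GeneNetwork:
    """A simple gene graph, directed (signaling) or undirected (functional/PPI).

    Undirected edges are stored with lexicographically ordered endpoints;
    self-loops are rejected and duplicates collapse. ``edges`` holds
    ``(source, target, relation)`` triples.
    """

    nodes: frozenset
    edges: frozenset
    directed: bool = False
    provenance: str = "funnet"

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        canon = set()
        for u, v, rel in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            canon.add(_canonical_edge(u, v, rel, self.directed))
        self.edges = frozenset(canon)
        endpoints = {u for u, _, _ in self.edges} | {v for _, v, _ in self.edges}
        if not endpoints <= self.nodes:
            raise ValidationError("edge endpoints outside node set")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        directed: bool = False,
        provenance: str = "funnet",
        extra_nodes: Iterable | None = None,
    ) -> "GeneNetwork":
        """Build from (u, v) or (u, v, relation) tuples; self-loops dropped."""
        triples = set()
        nodes = set(extra_nodes or ())
        for e in edges:
            if len(e) == 2:
                u, v = e
                rel = "binds"
            else:
                u, v, rel = e
            nodes.update((u, v))
            if u == v:
                continue
            triples.add(_canonical_edge(u, v, rel, directed))
        return cls(frozenset(nodes), frozenset(triples), directed, provenance)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def undirected_pairs(self) -> set:
        """Edge set as unordered endpoint pairs (direction and relation dropped).

        Reciprocal directed edges collapse onto one pair: they represent a
        single interaction when counting interactions per protein.
        """
        return {tuple(sorted((u, v))) for u, v, _ in self.edges}

    def adjacency(self) -> dict:
        """node -> set of neighbors, ignoring direction."""
        adj: dict = {n: set() for n in self.nodes}
        for u, v, _ in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def out_adjacency(self) -> dict:
        """node -> set of direct targets (directed networks)."""
        adj: dict = {n: set() for n in self.nodes}
        for u, v, _ in self.edges:
            adj[u].add(v)
            if not self.directed:
                adj[v].add(u)
        return adj

    def to_networkx(self):
        """Export as a networkx (Di)Graph with relation edge attributes."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, rel in self.edges:
            g.add_edge(u, v, relation=rel)
        return g


@dataclass
class HierarchyAssignment:
    """gene -> signaling-hierarchy level over a declared gene space."""

    levels: dict

    def __post_init__(self) -> None:
        valid = set(HIERARCHY_LEVELS) | {UNASSIGNED}
        bad = {lv for lv in self.levels.values() if lv not in valid}
        if bad:
            raise ValidationError(f"unknown hierarchy levels: {sorted(bad)}")

    def genes_at(self, level: str) -> set:
        return {g for g, lv in self.levels.items() if lv == level}

    def to_series(self) -> pd.Series:
        return pd.Series(self.levels, name="level").sort_index()


def validate_promoter_classes(classes: Mapping) -> dict:
    """Check a gene -> promoter-class map uses only classes I-IV."""
    bad = {c for c in classes.values() if c not in PROMOTER_CLASSES}
    if bad:
        raise ValidationError(f"unknown promoter classes: {sorted(bad)}")
    return dict(classes)
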