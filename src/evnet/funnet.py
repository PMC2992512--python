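"""Functional-similarity network (Fun-Net) construction.

Two genes are functionally linked when either

* the GO-style terms they share jointly annotate a rare slice of the
  genome: ``s_ij = |intersection of all shared terms' gene sets| / n``
  is below a threshold (default 0.001), where ``n`` is the size of the
  declared gene universe; or
* they share at least one pathway-style term (metabolic-pathway
  membership grants an edge outright).

When two genes share no GO-style term, ``s_ij`` is undefined and no
GO-derived edge is possible. Since both genes belong to every shared
term's gene set, a defined ``s_ij`` is always at least ``2/n``; GO-derived
edges therefore require ``2/n < threshold`` (a large declared universe).
"""

from __future__ import annotations

import itertools
import logging

from .datatypes import AnnotationSet, GeneNetwork
from .errors import ValidationError

log = logging.getLogger(__name__)


def overlap_significance(gene_i, gene_j, annotations: AnnotationSet) -> float | None:
    """Significance of annotation overlap s_ij, or None when undefined.

    ``s_ij = |⋂_{k∈K} G_k| / n`` with K the GO-style terms annotating
    both genes. Symmetric; bounded in [2/n, 1] when defined.
    """
    for g in (gene_i, gene_j):
        if g not in annotations.universe:
            raise ValidationError(f"gene {g!r} not in the declared universe")
    go_terms = annotations.terms_of_source("GO_style")
    shared = [t for t, genes in go_terms.items() if gene_i in genes and gene_j in genes]
    if not shared:
        return None
    inter = None
    # intersect smallest-first: the running set only shrinks
    for t in sorted(shared, key=lambda t: len(go_terms[t])):
        inter = go_terms[t] if inter is None else inter & go_terms[t]
    return len(inter) / annotations.n


def build_funnet(annotations: AnnotationSet, threshold: float = 0.001) -> GeneNetwork:
    """Build the undirected functional-similarity network.

    Edge (i, j) iff ``s_ij`` is defined and strictly below ``threshold``,
    or i and j share a pathway-style term. Nodes are the annotation
    universe. Candidate pairs are enumerated through an inverted index
    over terms; the result is identical to brute force over all pairs.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    n = annotations.n
    edges: set[tuple] = set()

    for term, genes in annotations.terms_of_source("pathway_style").items():
        for u, v in itertools.combinations(sorted(genes), 2):
            edges.add((u, v, "binds"))

    # GO-derived edges need |intersection| < threshold * n, and the
    # intersection always contains both genes: skip when 2 >= threshold*n.
    if 2 < threshold * n:
        go_terms = annotations.terms_of_source("GO_style")
        gene_terms = annotations.gene_index("GO_style")
        seen: set[tuple] = set()
        for term, genes in go_terms.items():
            for u, v in itertools.combinations(sorted(genes), 2):
                if (u, v) in seen:
                    continue
                seen.add((u, v))
                shared = gene_terms[u] & gene_terms[v]
                inter = None
                for t in sorted(shared, key=lambda t: len(go_terms[t])):
                    inter = go_terms[t] if inter is None else inter & go_terms[t]
                if len(inter) / n < threshold:
                    edges.add((u, v, "binds"))
    else:
        log.debug("build_funnet: GO rule cannot fire (2/n >= threshold); "
                  "only pathway edges considered")

    return GeneNetwork.from_edges(edges, directed=False, provenance="funnet",
                                  extra_nodes=annotations.universe)
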