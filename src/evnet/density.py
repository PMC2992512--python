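"""EV-binned interaction-density matrices and node-shuffle null model.

Genes are split into equal-occupancy EV bins; for every bin pair the
density of network interactions is the number of edges between the two
bins normalized by the bins' total incident edge counts. A label-shuffle
null (random permutation of node identities over the fixed edge
structure) shows how much of the observed bin structure is attributable
to EV rather than to network topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneNetwork
from .errors import ValidationError

log = logging.getLogger(__name__)


def bin_by_ev(ev: pd.DataFrame, n_bins: int = 50) -> dict:
    """Assign each gene to one of ``n_bins`` equal-occupancy EV bins.

    Genes are sorted ascending by (ev, gene id) — the id breaks ties
    deterministically — and split so any remainder is spread one extra
    gene per bin over the leading (lowest-EV) bins. Bin indices run from
    0 (lowest EV) to n_bins - 1 (highest).
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    n = len(ev)
    if n < n_bins:
        raise ValidationError(f"fewer genes ({n}) than bins ({n_bins})")
    ordered = ev.assign(_gene=ev.index).sort_values(["ev", "_gene"], kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    bins: dict = {}
    pos = 0
    for i, size in enumerate(sizes):
        for g in ordered.index[pos:pos + size]:
            bins[g] = i
        pos += size
    return bins


@dataclass
class DensityMatrix:
    """Symmetric bin-by-bin interaction densities.

    ``density[i, j] = e_ij / (E_i + E_j)`` off-diagonal and
    ``e_ii / E_i`` on the diagonal, where ``e_ij`` counts edges between
    bins i and j and ``E_i`` counts edges with at least one endpoint in
    bin i. All densities lie in [0, 1].
    """

    density: np.ndarray
    edge_counts: np.ndarray
    incident_counts: np.ndarray
    occupancy: np.ndarray
    n_unbinned: int

    @property
    def n_bins(self) -> int:
        return self.density.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = [f"bin{i:02d}" for i in range(self.n_bins)]
        return pd.DataFrame(self.density, index=idx, columns=idx)


def density_matrix(network: GeneNetwork, bins: dict) -> DensityMatrix:
    """Interaction densities between EV bins on an undirected network.

    Nodes without a bin assignment are ignored (counted and logged).
    Bins with no incident edges get an all-zero density row.
    """
    if network.directed:
        raise ValidationError("density_matrix requires an undirected network")
    n_bins = max(bins.values()) + 1 if bins else 0
    if n_bins == 0:
        raise ValidationError("empty bin assignment")
    e = np.zeros((n_bins, n_bins), dtype=float)
    unbinned_nodes = {n for n in network.nodes if n not in bins}
    skipped = 0
    for u, v in network.undirected_pairs():
        if u in bins and v in bins:
            bu, bv = bins[u], bins[v]
            e[bu, bv] += 1
            if bu != bv:
                e[bv, bu] += 1
        else:
            skipped += 1
    if unbinned_nodes:
        log.info("density_matrix: %d unbinned nodes, %d edges skipped",
                 len(unbinned_nodes), skipped)
    # E_i = e_ii + sum_{j != i} e_ij: every bin-i-incident edge counted once
    incident = e.sum(axis=1)
    d = np.zeros_like(e)
    for i in range(n_bins):
        if incident[i] == 0:
            log.info("density_matrix: bin %d has no incident edges", i)
            continue
        for j in range(n_bins):
            if i == j:
                d[i, i] = e[i, i] / incident[i]
            elif incident[j] > 0:
                d[i, j] = e[i, j] / (incident[i] + incident[j])
    occupancy = np.zeros(n_bins, dtype=int)
    for b in bins.values():
        occupancy[b] += 1
    return DensityMatrix(d, e, incident, occupancy, len(unbinned_nodes))


def shuffle_nodes(network: GeneNetwork, seed: int) -> GeneNetwork:
    """Apply a uniformly random permutation of node labels to the fixed
    edge structure. The degree multiset is preserved exactly."""
    rng = np.random.default_rng(seed)
    nodes = sorted(network.nodes)
    perm = rng.permutation(len(nodes))
    relabel = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    edges = [(relabel[u], relabel[v], rel) for u, v, rel in network.edges]
    return GeneNetwork.from_edges(edges, directed=network.directed,
                                  provenance=network.provenance,
                                  extra_nodes=network.nodes)


def _block_masks(dm: DensityMatrix, boundary: int):
    n = dm.n_bins
    if not (0 < boundary < n):
        raise ValidationError(f"boundary must split the bins, got {boundary} of {n}")
    low = np.arange(n) < boundary
    within = np.concatenate([
        dm.density[np.ix_(low, low)].ravel(),
        dm.density[np.ix_(~low, ~low)].ravel(),
    ])
    cross = dm.density[np.ix_(low, ~low)].ravel()
    return within, cross


def block_separation(dm: DensityMatrix, boundary: int) -> float:
    """Mean within-block density minus mean cross-block density.

    Zero (up to noise) for a network with no EV-related structure; the
    label-shuffle null collapses this quantity toward zero.
    """
    within, cross = _block_masks(dm, boundary)
    return float(within.mean() - cross.mean())


def block_contrast(dm: DensityMatrix, boundary: int) -> float:
    """Mean within-block density over mean cross-block density.

    Bins below ``boundary`` form the low-EV block, the rest the high-EV
    block; diagonal cells count as within-block. A contrast well above 1
    indicates that interactions preferentially connect genes of similar
    EV. Returns NaN when the cross-block mean is zero.
    """
    within, cross = _block_masks(dm, boundary)
    if cross.mean() == 0:
        return float("nan")
    return float(within.mean() / cross.mean())
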