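"""Per-frame interaction networks: Voronoi adjacency and distance weights.

Voronoi neighbors (equivalently, Delaunay-adjacent individuals) are a
standard proxy for visual interaction partners in fish schools; pairwise
social forces are averaged over them with weights proportional to the
inverse metric distance, so closer neighbors exert more influence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError


class DegenerateConfigurationError(ValueError):
    """Positions admit no Delaunay triangulation (collinear/duplicate)."""


@dataclass
class NeighborGraph:
    """Voronoi adjacency for one frame.

    Attributes
    ----------
    adjacency : (n, n) bool array, symmetric, zero diagonal.
    nearest : (n,) int array, index of each individual's nearest neighbor.
    weights : (n, n) float array or None; row i holds w_ij over i's
        interacting set (set by :func:`social_weights`).
    """

    adjacency: np.ndarray
    nearest: np.ndarray
    weights: Optional[np.ndarray] = None

    @property
    def edges(self) -> set:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return set(zip(i.tolist(), j.tolist()))


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def nearest_neighbor_indices(positions: np.ndarray) -> np.ndarray:
    d = pairwise_distances(positions)
    np.fill_diagonal(d, np.inf)
    return d.argmin(1)


def voronoi_adjacency(positions: np.ndarray) -> NeighborGraph:
    """Build the Voronoi (Delaunay) adjacency of a point configuration.

    Fewer than 3 points fall back to all-pairs adjacency; degenerate
    configurations raise :class:`DegenerateConfigurationError` rather
    than being silently jittered.
    """
    positions = np.asarray(positions, float)
    n = len(positions)
    adj = np.zeros((n, n), bool)
    if n < 3:
        adj[:] = ~np.eye(n, dtype=bool)
        return NeighborGraph(adjacency=adj,
                             nearest=nearest_neighbor_indices(positions))
    try:
        tri = Delaunay(positions)
    except QhullError as exc:
        raise DegenerateConfigurationError(
            "degenerate point configuration (collinear or duplicate "
            "positions)") from exc
    if tri.coplanar.size:
        raise DegenerateConfigurationError("duplicate/coplanar input points")
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                adj[simplex[a], simplex[b]] = True
                adj[simplex[b], simplex[a]] = True
    return NeighborGraph(adjacency=adj,
                         nearest=nearest_neighbor_indices(positions))


def social_weights(graph: NeighborGraph, positions: np.ndarray,
                   interacting: Optional[np.ndarray] = None,
                   normalize: bool = True) -> np.ndarray:
    """Inverse-distance weights w_ij over each individual's interacting set.

    Parameters
    ----------
    interacting : (n, n) bool array, optional
        Per-individual interacting set (row i = neighbors i listens to);
        defaults to the full Voronoi adjacency.
    normalize : bool
        If True, rows are normalized to sum to one (weighted mean); an
        individual with an empty interacting set keeps an all-zero row.

    The weight matrix is stored on ``graph.weights`` and returned.
    """
    positions = np.asarray(positions, float)
    if interacting is None:
        interacting = graph.adjacency
    d = pairwise_distances(positions)
    if np.any(d[interacting] < 1e-12):
        raise ValueError("zero distance between interacting individuals")
    with np.errstate(divide="ignore"):
        inv = np.where(interacting, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    if normalize:
        norm = inv.sum(1, keepdims=True)
        inv = np.divide(inv, norm, out=np.zeros_like(inv), where=norm > 0)
    graph.weights = inv
    return inv
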