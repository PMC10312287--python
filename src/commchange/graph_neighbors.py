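"""Sparsity-thresholded graph and per-edge neighbor sets.

An edge's neighborhood is split into three mutually exclusive sets: nodes
adjacent to both endpoints (the shared neighbors ``n_shared``, whose BOLD
variance proxies shared network input) and nodes adjacent to only one
endpoint (``n_only_i`` / ``n_only_j``, proxying idiosyncratic input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EdgeNeighborhood", "threshold_graph", "neighbor_sets"]


@dataclass(frozen=True)
class EdgeNeighborhood:
    """Shared/idiosyncratic neighbor sets of the edge (i, j)."""

    i: int
    j: int
    n_shared: frozenset[int]  # adjacent to both i and j
    n_only_i: frozenset[int]  # adjacent to i only
    n_only_j: frozenset[int]  # adjacent to j only

    def __post_init__(self) -> None:
        sets = (self.n_shared, self.n_only_i, self.n_only_j)
        union = set().union(*sets)
        if sum(len(s) for s in sets) != len(union):
            raise ValueError("neighbor sets must be pairwise disjoint")
        if self.i in union or self.j in union:
            raise ValueError("edge endpoints cannot be their own neighbors")


def threshold_graph(
    mean_fc: np.ndarray, sparsity: float, absolute: bool = False
) -> np.ndarray:
    """Retain the strongest edges of a symmetric connectivity matrix.

    Exactly ``floor(sparsity * P*(P-1)/2)`` upper-triangle edges with the
    largest values are kept (signed values by default; set ``absolute`` to
    rank by magnitude).  Ties at the cutoff are broken by lexicographic
    (i, j) order so the result is deterministic.

    Returns a symmetric boolean adjacency matrix with a zero diagonal.
    """
    m = np.asarray(mean_fc, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {m.shape}")
    if np.any(np.isnan(m)):
        raise ValueError("connectivity matrix contains NaN")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")

    p = m.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = np.abs(m[iu, ju]) if absolute else m[iu, ju]
    n_keep = int(np.floor(sparsity * p * (p - 1) / 2))
    # Sort by value descending, then (i, j) ascending for deterministic ties.
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_keep]
    adj = np.zeros((p, p), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return adj


def neighbor_sets(adjacency: np.ndarray, i: int, j: int) -> EdgeNeighborhood:
    """Partition the joint neighborhood of (i, j) into shared and exclusive sets.

    Every node adjacent to i or j (excluding i and j themselves) falls in
    exactly one of ``n_shared``, ``n_only_i``, ``n_only_j``.
    """
    adj = np.asarray(adjacency, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if i == j:
        raise ValueError("edge endpoints must differ")
    ni = adj[i].copy()
    nj = adj[j].copy()
    ni[[i, j]] = False
    nj[[i, j]] = False
    return EdgeNeighborhood(
        i=i,
        j=j,
        n_shared=frozenset(np.flatnonzero(ni & nj).tolist()),
        n_only_i=frozenset(np.flatnonzero(ni & ~nj).tolist()),
        n_only_j=frozenset(np.flatnonzero(nj & ~ni).tolist()),
    )
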