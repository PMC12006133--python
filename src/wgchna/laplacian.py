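"""Hypergraph Laplacians, the induced gene-gene affinity, and the TOM.

For an incidence matrix H (genes x hyperedges), edge weight diagonal W, node
hyperdegree diagonal Dv (weighted: d(v) = sum_e W_e h(v,e)) and edge degree
diagonal De, the package computes

    unnormalized Laplacian   L  = Dv - H W De^-1 H^T
    normalized Laplacian     Ln = I - Dv^-1/2 H W De^-1 H^T Dv^-1/2
    affinity                 A  = Dv^-1/2 H W De^-1 H^T Dv^-1/2, diag zeroed

The weighted hyperdegree convention makes every row of L sum to zero (the
defining Laplacian property), and Ln's spectrum lies in [0, 1].

The topological overlap matrix is the classic unsigned TOM evaluated on the
affinity A rather than on a correlation adjacency:

    TOM_ij = (A_ij + sum_{k != i,j} A_ik A_kj) / (min(d_i, d_j) + 1 - A_ij)

with d_i = sum_{j != i} A_ij.  Note the off-diagonal entries of a normalized
Laplacian are <= 0, so plugging Laplacian entries into this formula directly
would yield a negative, meaningless "similarity"; the affinity A = I - Ln
(off-diagonal) is the nonnegative similarity the overlap formula expects, and
it reduces the construction to the standard TOM over the hypergraph-induced
adjacency.  dissTOM = 1 - TOM drives the downstream hierarchical clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hypergraph import WeightedHypergraph, edge_degrees, node_hyperdegrees

logger = logging.getLogger(__name__)


@dataclass
class LaplacianSet:
    """Unnormalized and normalized hypergraph Laplacians plus the affinity."""

    unnormalized: np.ndarray
    normalized: np.ndarray
    affinity: np.ndarray
    node_ids: list[str]
    hyperdegrees: np.ndarray  # diagonal of Dv (weighted)


@dataclass
class TOMatrix:
    """Symmetric topological overlap in [0, 1] with unit diagonal."""

    tom: np.ndarray
    degrees: np.ndarray  # affinity row sums excluding the diagonal
    node_ids: list[str]


@dataclass
class DissTOM:
    """Elementwise 1 - TOM; zero diagonal; the clustering dissimilarity."""

    diss: np.ndarray
    node_ids: list[str]


def laplacians(hg: WeightedHypergraph) -> LaplacianSet:
    """Compute L, Ln and the affinity A from a weighted hypergraph."""
    d = node_hyperdegrees(hg)
    delta = edge_degrees(hg)
    if (d <= 0).any():
        bad = [hg.node_ids[i] for i in np.where(d <= 0)[0]]
        raise ValueError(f"zero weighted hyperdegree for nodes {bad}")
    H = hg.incidence
    # S = H W De^-1 H^T, assembled without forming the diagonal matrices
    S = (H * (hg.edge_weights / delta)) @ H.T
    L = np.diag(d) - S
    inv_sqrt = 1.0 / np.sqrt(d)
    A_full = S * np.outer(inv_sqrt, inv_sqrt)
    Ln = np.eye(hg.n_nodes) - A_full
    A = A_full.copy()
    np.fill_diagonal(A, 0.0)
    return LaplacianSet(L, Ln, A, list(hg.node_ids), d)


def tom(lap: LaplacianSet) -> TOMatrix:
    """Topological overlap of the affinity matrix.

    Output is clamped to [0, 1]; any clamping (a numerical artifact only)
    is counted and logged.
    """
    A = lap.affinity
    d = A.sum(axis=1)
    numerator = A + A @ A  # diag(A)=0 excludes k=i and k=j automatically
    denominator = np.minimum.outer(d, d) + 1.0 - A
    if (denominator <= 0).any():
        raise ValueError("non-positive TOM denominator; invalid affinity")
    T = numerator / denominator
    np.fill_diagonal(T, 1.0)
    clamped = int(((T < 0) | (T > 1)).sum())
    if clamped:
        logger.info("tom: clamped %d entries into [0, 1]", clamped)
    T = np.clip(T, 0.0, 1.0)
    T = (T + T.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(T, 1.0)
    return TOMatrix(T, d, list(lap.node_ids))


def diss_tom(t: TOMatrix) -> DissTOM:
    """Dissimilarity transform: diss = 1 - TOM (zero diagonal)."""
    return DissTOM(1.0 - t.tom, list(t.node_ids))
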