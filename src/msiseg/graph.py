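"""Thresholded 8-neighbor spot graph and its symmetric normalization.

Spots are nodes on the pixel lattice; candidate edges connect each spot
to its Moore (8-)neighbors only, and a candidate becomes an edge iff the
Euclidean distance between the two spots' embedding vectors is strictly
below a user-chosen cut-off.  The graph convolution then operates on the
renormalized adjacency  A_hat = D_hat^(-1/2) (A + I) D_hat^(-1/2)  with
D_hat the degree matrix of A + I.

Restricting candidates to lattice neighbors keeps graph construction
linear in the number of spots while still letting edges encode "these
adjacent pixels look spectrally alike".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .embed import Embedding

__all__ = [
    "SpatialGraph",
    "NormalizedAdjacency",
    "neighbor_candidate_pairs",
    "build_adjacency",
    "normalize_adjacency",
    "suggest_cutoff",
]

# unordered Moore-neighborhood offsets (each candidate pair listed once)
_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class SpatialGraph:
    """Binary symmetric adjacency over on-tissue spots."""

    adjacency: sp.csr_matrix  # (n, n) binary symmetric, zero diagonal
    cutoff: float
    grid_shape: tuple[int, int]
    pixel_index: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        """Number of undirected edges."""
        return int(self.adjacency.nnz // 2)

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of undirected edges (u < v)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.stack([coo.row, coo.col], axis=1)

    def save_edge_csv(self, path) -> None:
        """Write the undirected edge list with grid coordinates for inspection."""
        import pandas as pd

        edges = self.edge_list()
        pd.DataFrame(
            {
                "u": edges[:, 0],
                "v": edges[:, 1],
                "u_row": self.pixel_index[edges[:, 0], 0],
                "u_col": self.pixel_index[edges[:, 0], 1],
                "v_row": self.pixel_index[edges[:, 1], 0],
                "v_col": self.pixel_index[edges[:, 1], 1],
            }
        ).to_csv(path, index=False)


@dataclass
class NormalizedAdjacency:
    """A_hat = D_hat^(-1/2) (A + I) D_hat^(-1/2); always well defined."""

    matrix: sp.csr_matrix
    degrees: np.ndarray  # degrees of A + I

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


def neighbor_candidate_pairs(
    grid_shape: tuple[int, int], pixel_index: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered on-tissue 8-neighbor spot pairs (u, v) as index arrays."""
    nr, nc = grid_shape
    grid = np.full((nr, nc), -1, dtype=np.int64)
    grid[pixel_index[:, 0], pixel_index[:, 1]] = np.arange(len(pixel_index))
    us, vs = [], []
    for dr, dc in _OFFSETS:
        r0 = max(0, -dr)
        r1 = nr - max(0, dr)
        c0 = max(0, -dc)
        c1 = nc - max(0, dc)
        a = grid[r0:r1, c0:c1]
        b = grid[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        us.append(a[ok])
        vs.append(b[ok])
    if not us:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(us), np.concatenate(vs)


def build_adjacency(emb: Embedding, cutoff: float) -> SpatialGraph:
    """Connect 8-neighbor spots whose embedding distance is strictly below cutoff."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    u, v = neighbor_candidate_pairs(emb.grid_shape, emb.pixel_index)
    if u.size:
        d = np.linalg.norm(emb.values[u] - emb.values[v], axis=1)
        keep = d < cutoff  # strict inequality at the cut-off
        u, v = u[keep], v[keep]
    n = emb.n_spots
    data = np.ones(u.size, dtype=np.float64)
    A = sp.coo_matrix((data, (u, v)), shape=(n, n))
    A = (A + A.T).tocsr()
    return SpatialGraph(A, float(cutoff), emb.grid_shape, emb.pixel_index.copy())


def normalize_adjacency(g: SpatialGraph) -> NormalizedAdjacency:
    """Symmetric renormalization with self-loops added before degrees."""
    n = g.n_nodes
    A_hat = g.adjacency + sp.identity(n, format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return NormalizedAdjacency((D @ A_hat @ D).tocsr(), deg)


def suggest_cutoff(emb: Embedding, quantile: float = 0.5) -> float:
    """Suggest a cut-off as a quantile of candidate 8-neighbor distances.

    The median (default) connects roughly half of all lattice-neighbor
    pairs; since within-region neighbor distances are typically far below
    between-region ones, this tends to keep within-region edges and drop
    boundary-crossing ones.  Note the strict inequality in
    :func:`build_adjacency`: a cutoff exactly equal to the maximum
    distance does not connect that pair.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if emb.n_spots < 2:
        raise ValueError("need at least 2 spots")
    u, v = neighbor_candidate_pairs(emb.grid_shape, emb.pixel_index)
    if u.size == 0:
        raise ValueError("no 8-neighbor candidate pairs on this grid")
    d = np.linalg.norm(emb.values[u] - emb.values[v], axis=1)
    value = float(np.quantile(d, quantile))
    if value <= 0.0:
        warnings.warn(
            "all candidate neighbor distances at this quantile are zero; "
            "returning the smallest positive float"
        )
        return float(np.finfo(np.float64).tiny)
    return value
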