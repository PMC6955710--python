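"""Weighted directed graph metrics for thresholded connectivity networks.

The band-averaged PDC matrix W (entry (i, j) = flow j -> i, zero
diagonal) is thresholded either at absolute values (study grid 0.0, 0.1,
0.15, 0.2, 0.25, 0.3) or proportionally to a target sparsity (10-30% of
the strongest edges, step 5%), and the following indices are computed:

* nodal degree: d_tot(i) = d_in(i) + d_out(i) from the binary adjacency;
* nodal strength: NS(i) = sum_j w_ij + sum_j w_ji;
* local clustering (Fagiolo's weighted directed form, cube-root weights):
  C_i = [(W^(1/3) + (W^T)^(1/3))^3]_ii / (2 [d_tot (d_tot - 1) - 2 d_bi]),
  with d_bi the number of reciprocal neighbor pairs of i;
* global clustering CC = mean_i C_i;
* characteristic path length PL: mean over ordered pairs of directed
  shortest-path costs with edge length = 1 / weight, finite pairs only
  (the fraction of unreachable pairs is reported alongside);
* trapezoidal integrals of CC / PL over the sparsity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ThresholdedGraph",
    "threshold_absolute",
    "threshold_proportional",
    "nodal_degree",
    "nodal_strength",
    "clustering_local",
    "clustering_global",
    "path_length",
    "sparsity_integral",
    "normalized_degree",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_SPARSITIES",
]

DEFAULT_THRESHOLDS = (0.0, 0.1, 0.15, 0.2, 0.25, 0.3)
DEFAULT_SPARSITIES = (0.10, 0.15, 0.20, 0.25, 0.30)
DISPLAY_THRESHOLD = 0.2


@dataclass
class ThresholdedGraph:
    """Weights after thresholding plus the derived binary adjacency."""

    W: np.ndarray
    scheme: str  # e.g. "absolute T=0.2" or "sparsity s=0.15"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")

    @property
    def A(self) -> np.ndarray:
        """Binary adjacency: a_ij = 1 iff w_ij != 0."""
        return (self.W != 0).astype(int)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def _as_weight_matrix(W) -> np.ndarray:
    W = np.asarray(getattr(W, "W", W), dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    return W


def threshold_absolute(W, T: float) -> ThresholdedGraph:
    """Zero out entries strictly below T (T = 0 keeps all nonzeros)."""
    if T < 0:
        raise ValueError("threshold must be nonnegative")
    W = _as_weight_matrix(W).copy()
    W[W < T] = 0.0
    np.fill_diagonal(W, 0.0)
    return ThresholdedGraph(W=W, scheme=f"absolute T={T:g}")


def threshold_proportional(W, sparsity: float) -> ThresholdedGraph:
    """Keep the floor(sparsity * m * (m-1)) largest off-diagonal weights.

    Ties at the cut are broken deterministically by (row, column) index
    order: among equal weights the lower index pair is kept.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    W = _as_weight_matrix(W)
    m = W.shape[0]
    k = int(np.floor(sparsity * m * (m - 1)))
    rows, cols = np.nonzero(~np.eye(m, dtype=bool))
    weights = W[rows, cols]
    # sort by weight descending, then row, then column (stable tie order)
    order = np.lexsort((cols, rows, -weights))
    keep = order[:k]
    out = np.zeros_like(W)
    out[rows[keep], cols[keep]] = weights[keep]
    return ThresholdedGraph(W=out, scheme=f"sparsity s={sparsity:g}")


def nodal_degree(g: ThresholdedGraph | np.ndarray) -> dict[str, np.ndarray]:
    """In-, out- and total degree per node.

    With orientation row = receiver: d_in(i) = sum_j A[i, j] (senders
    into i), d_out(i) = sum_j A[j, i].
    """
    A = g.A if isinstance(g, ThresholdedGraph) else (np.asarray(g) != 0).astype(int)
    d_in = A.sum(axis=1)
    d_out = A.sum(axis=0)
    return {"d_in": d_in, "d_out": d_out, "d_tot": d_in + d_out}


def nodal_strength(W) -> np.ndarray:
    """NS(i) = row-sum + column-sum of the weight matrix at node i."""
    W = _as_weight_matrix(W)
    return W.sum(axis=1) + W.sum(axis=0)


def clustering_local(W) -> np.ndarray:
    """Fagiolo weighted directed clustering coefficient per node.

    C_i = [(W^(1/3) + (W^T)^(1/3))^3]_ii
          / (2 [d_tot(i) (d_tot(i) - 1) - 2 d_bi(i)]),

    where d_bi(i) = (A A)_ii counts i's reciprocal neighbor pairs.
    Weights must be nonnegative (cube roots of weights appear in the
    triangle geometric means); weights in [0, 1] keep C_i in [0, 1].
    Nodes whose denominator is zero (fewer than two neighbors, or all
    pairs reciprocal) get C_i = 0.
    """
    W = _as_weight_matrix(W)
    if np.any(W < 0):
        raise ValueError("clustering requires nonnegative weights")
    A = (W != 0).astype(float)
    deg = nodal_degree(W)
    d_tot = deg["d_tot"].astype(float)
    d_bi = np.diag(A @ A)
    S = np.cbrt(W) + np.cbrt(W.T)
    numer = np.diag(S @ S @ S)
    denom = 2.0 * (d_tot * (d_tot - 1.0) - 2.0 * d_bi)
    out = np.zeros_like(d_tot)
    ok = denom > 0
    out[ok] = numer[ok] / denom[ok]
    return out


def clustering_global(C: np.ndarray) -> float:
    """Global clustering coefficient: arithmetic mean of local values."""
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        raise ValueError("empty clustering vector")
    return float(C.mean())


def path_length(W) -> tuple[float, float]:
    """Characteristic path length of a weighted directed graph.

    Edge lengths are reciprocals of edge weights; directed shortest-path
    costs L_ij are computed by Dijkstra's algorithm.  Returns
    ``(PL, unreachable_fraction)`` where PL is the mean of the finite
    L_ij over ordered pairs i != j and the fraction counts pairs with no
    directed path.
    """
    W = _as_weight_matrix(W)
    if np.any(W < 0):
        raise ValueError("path length requires nonnegative weights")
    m = W.shape[0]
    lengths = np.zeros_like(W)
    nz = W != 0
    lengths[nz] = 1.0 / W[nz]
    # csgraph convention: graph[i, j] = cost of edge i -> j.  Our W has
    # row = receiver, so transpose to get sender -> receiver costs.
    D = dijkstra(csr_matrix(lengths.T), directed=True)
    off = ~np.eye(m, dtype=bool)
    finite = np.isfinite(D) & off
    n_pairs = m * (m - 1)
    if not finite.any():
        raise ValueError("graph has no connected ordered pair")
    pl = float(D[finite].mean())
    unreachable = 1.0 - finite.sum() / n_pairs
    return pl, float(unreachable)


def sparsity_integral(values, grid=DEFAULT_SPARSITIES) -> float:
    """Trapezoidal integral of a metric over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or values.shape[0] != grid.size:
        raise ValueError("need >= 2 grid points matching the values")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(values, grid))


def normalized_degree(d_tot, m: int):
    """Total degree normalized by its maximum 2(m-1); lies in [0, 1]."""
    if m < 2:
        raise ValueError("need at least 2 nodes")
    return np.asarray(d_tot, dtype=float) / (2.0 * (m - 1))
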