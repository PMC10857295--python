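"""Six weighted graph metrics on thresholded FNC graphs.

Local: weighted node degree, participation coefficient (against the
functional-domain partition), closeness centrality. Global: global
efficiency, characteristic path length, weighted clustering coefficient
(Onnela geometric-mean-of-triangles form).

Conventions, applied uniformly:

* Signed FNC weights enter every metric through their absolute value
  (``negative_weights="absolute"``, the default); ``"discard"`` drops
  negative edges instead. Path lengths and cube roots require nonnegative
  weights, and magnitude is what proportional thresholding ranks by.
* The weight-to-length map for shortest paths is ``length = 1 / |w|``.
* Unreachable pairs contribute 0 to global efficiency and are excluded
  (with a count) from the characteristic path length; an isolated node has
  closeness 0 and participation 0.
* The clustering coefficient normalizes weights by max |w| before the cube
  roots and divides by the binary degree (neighbor count), keeping each
  node's value in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import NMCouplingError

logger = logging.getLogger(__name__)

NODAL_METRICS = ("degree", "closeness_centrality", "participation_coefficient")
GLOBAL_METRICS = ("global_efficiency", "characteristic_path_length",
                  "clustering_coefficient")
ALL_METRICS = GLOBAL_METRICS + NODAL_METRICS


def effective_weights(w, negative_weights: str = "absolute") -> np.ndarray:
    """Nonnegative weight matrix under the configured sign convention."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if negative_weights == "absolute":
        a = np.abs(w)
    elif negative_weights == "discard":
        a = np.where(w > 0, w, 0.0)
    else:
        raise ValueError(f"unknown negative_weights policy {negative_weights!r}")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def weighted_degree(w, negative_weights: str = "absolute") -> np.ndarray:
    """k_i = sum_j |w_ij| (row sums of the effective weights)."""
    return effective_weights(w, negative_weights).sum(axis=1)


def participation_coefficient(w, assignment: Sequence,
                              negative_weights: str = "absolute") -> np.ndarray:
    """y_i = 1 - sum_m (k_i(m) / k_i)^2 over modules m.

    Zero when all of a node's weight lies inside its own module, and (by
    convention) zero for an isolated node. Bounded by 1 - 1/|M|.
    """
    a = effective_weights(w, negative_weights)
    labels = np.asarray(assignment)
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition does not cover every node")
    k = a.sum(axis=1)
    y = np.zeros_like(k)
    nz = k > 0
    ssq = np.zeros_like(k)
    for m in np.unique(labels):
        km = a[:, labels == m].sum(axis=1)
        ssq[nz] += (km[nz] / k[nz]) ** 2
    y[nz] = 1.0 - ssq[nz]
    return np.clip(y, 0.0, 1.0)


def shortest_path_matrix(w, negative_weights: str = "absolute") -> np.ndarray:
    """All-pairs shortest weighted path lengths, edge length = 1/|w|.

    Unreachable pairs are +inf; the diagonal is 0. A fully disconnected
    node yields an all-infinite row (logged, not an error).
    """
    a = effective_weights(w, negative_weights)
    n = a.shape[0]
    lengths = np.zeros_like(a)
    nz = a > 0
    lengths[nz] = 1.0 / a[nz]
    d = dijkstra(csr_matrix(lengths), directed=False)
    isolated = int((~nz).all(axis=1).sum())
    if isolated:
        logger.info("distance matrix: %d isolated node(s)", isolated)
    np.fill_diagonal(d, 0.0)
    return d


def closeness_centrality(w=None, distances: Optional[np.ndarray] = None,
                         negative_weights: str = "absolute") -> np.ndarray:
    """(n-1) / sum of shortest path lengths to reachable nodes; 0 if none."""
    d = shortest_path_matrix(w, negative_weights) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(d) & off
    total = np.where(reach, d, 0.0).sum(axis=1)
    out = np.zeros(n)
    ok = total > 0
    out[ok] = (n - 1) / total[ok]
    return out


def global_efficiency(w=None, distances: Optional[np.ndarray] = None,
                      negative_weights: str = "absolute") -> float:
    """Mean of 1/d over ordered node pairs, with 1/inf = 0."""
    d = shortest_path_matrix(w, negative_weights) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def characteristic_path_length(w=None, distances: Optional[np.ndarray] = None,
                               negative_weights: str = "absolute") -> float:
    """Mean shortest path length over reachable ordered pairs.

    Unreachable pairs are excluded (their count is logged); a graph with no
    reachable pair has no defined path length and raises.
    """
    d = shortest_path_matrix(w, negative_weights) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(d)
    n_unreach = int(off.sum() - reach.sum())
    if n_unreach:
        logger.info("characteristic path length: %d unreachable ordered pair(s) "
                    "excluded", n_unreach)
    if not reach.any():
        raise NMCouplingError("characteristic path length undefined: no reachable pair")
    return float(d[reach].mean())


def clustering_coefficient(w, negative_weights: str = "absolute"
                           ) -> Tuple[float, np.ndarray]:
    """Weighted clustering (geometric mean of triangle weights).

    t_i = (1/2) sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with weights normalized
    by max |w|; C_i = 2 t_i / (k_i (k_i - 1)) with k_i the neighbor count,
    0 when k_i < 2. Returns (mean over nodes, per-node values).
    """
    a = effective_weights(w, negative_weights)
    mx = a.max()
    n = a.shape[0]
    if mx == 0:
        return 0.0, np.zeros(n)
    cbrt = np.cbrt(a / mx)
    t = np.einsum("ij,ih,jh->i", cbrt, cbrt, cbrt) / 2.0
    kb = (a > 0).sum(axis=1)
    ci = np.zeros(n)
    ok = kb >= 2
    ci[ok] = 2.0 * t[ok] / (kb[ok] * (kb[ok] - 1.0))
    return float(ci.mean()), ci


@dataclass
class GraphMetrics:
    """All six metrics for one subject's graph."""

    nodal: Dict[str, np.ndarray]
    global_: Dict[str, float]


def compute_all(w, assignment: Sequence,
                negative_weights: str = "absolute") -> GraphMetrics:
    """Compute the six metrics in one pass, sharing the distance matrix."""
    d = shortest_path_matrix(w, negative_weights)
    cw, _ = clustering_coefficient(w, negative_weights)
    return GraphMetrics(
        nodal={
            "degree": weighted_degree(w, negative_weights),
            "closeness_centrality": closeness_centrality(distances=d),
            "participation_coefficient": participation_coefficient(
                w, assignment, negative_weights),
        },
        global_={
            "global_efficiency": global_efficiency(distances=d),
            "characteristic_path_length": characteristic_path_length(distances=d),
            "clustering_coefficient": cw,
        },
    )
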