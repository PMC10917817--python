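"""Weighted graph metrics: Onnela clustering, efficiency, and AUC integration.

All metrics operate on nonnegative symmetric weight matrices with zero
diagonal (the output of :mod:`fcgraph.network`). Clustering uses the
Onnela geometric-mean form with weights scaled by the graph maximum, the
formulation used by the Brain Connectivity Toolbox family; efficiency
uses shortest paths over edge lengths 1/w.

Because graph metrics depend on density, each metric is computed at
every proportional threshold and then summarized by the area under the
metric-versus-density curve (trapezoidal rule), giving one integrated
value per matrix (and per node, for nodal metrics).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix

from .network import ThresholdedGraphSet, WeightedGraph

__all__ = [
    "nodal_clustering",
    "global_clustering",
    "shortest_path_lengths",
    "global_efficiency",
    "local_efficiency",
    "auc_over_thresholds",
    "metrics_over_thresholds",
]


def _as_weights(G) -> np.ndarray:
    w = G.weights if isinstance(G, WeightedGraph) else np.asarray(G, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights present")
    return w


def nodal_clustering(G) -> np.ndarray:
    """Weighted clustering coefficient per node (Onnela form).

    Weights are first scaled by the maximum weight of the graph,
    ``w_hat = w / max(w)``. For node ``i`` with degree ``k_i``::

        C_i = sum_{j,h} (w_hat_ij * w_hat_ih * w_hat_jh)^(1/3) / (k_i (k_i - 1))

    Nodes with fewer than two neighbours have no neighbour pairs and get
    ``C_i = 0``. Values lie in [0, 1]; on binary graphs this reduces to
    the classic unweighted clustering coefficient.
    """
    w = _as_weights(G)
    mx = w.max()
    if mx == 0.0:
        return np.zeros(w.shape[0])
    w_hat = w / mx
    cbrt = np.cbrt(w_hat)
    # (cbrt^3)_ii sums the geometric-mean triangle intensities around i
    triangles = np.diag(cbrt @ cbrt @ cbrt)
    k = np.count_nonzero(w, axis=1).astype(float)
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def global_clustering(G) -> float:
    """Mean nodal clustering over all nodes (isolated nodes included)."""
    return float(np.mean(nodal_clustering(G)))


def shortest_path_lengths(G) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/w.

    Stronger connections are shorter. Unreachable pairs have infinite
    distance; the diagonal is zero. Disconnection is a valid state, not
    an error.
    """
    w = _as_weights(G)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def global_efficiency(G) -> float:
    """Mean inverse shortest-path length over all node pairs.

    ``E_glob = mean_{i != j} 1 / d(i, j)`` with ``1/inf = 0``. Equals 1 on
    a complete unit-weight graph and 0 on a fully disconnected one.
    """
    w = _as_weights(G)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = shortest_path_lengths(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].mean())


def local_efficiency(G) -> np.ndarray:
    """Local efficiency per node: global efficiency of its neighbourhood.

    For each node the subgraph induced by its neighbours (the node itself
    excluded) is extracted and its global efficiency computed. Nodes with
    fewer than two neighbours get 0.
    """
    w = _as_weights(G)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(w[i])[0]
        if nb.size < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        out[i] = global_efficiency(sub)
    return out


def auc_over_thresholds(values, densities) -> float | np.ndarray:
    """Trapezoidal area under the metric-versus-density curve.

    ``values`` may be 1-D (one value per density) or 2-D with one row per
    density (nodal metrics), in which case a per-node AUC vector is
    returned. Densities must be strictly increasing.
    """
    densities = np.asarray(densities, dtype=float)
    values = np.asarray(values, dtype=float)
    if densities.ndim != 1 or densities.size < 2:
        raise ValueError("need at least 2 densities")
    if np.any(np.diff(densities) <= 0):
        raise ValueError("densities must be strictly increasing")
    if values.shape[0] != densities.size:
        raise ValueError(
            f"{values.shape[0]} value rows for {densities.size} densities"
        )
    return np.trapezoid(values, densities, axis=0)


def metrics_over_thresholds(
    graphs: ThresholdedGraphSet,
    metrics=("clustering", "efficiency_global", "efficiency_local"),
    integrate: bool = True,
) -> pd.DataFrame:
    """Compute the requested metrics at every density of a graph set.

    Returns a long-format frame with columns ``density`` (dropped for AUC
    rows), ``roi`` (node index, or -1 for global values), ``metric`` and
    ``value``. With ``integrate=True`` an AUC row per node/metric is
    appended with ``density`` set to NaN.
    """
    densities = graphs.densities
    rows = []
    per_density: dict[str, list[np.ndarray]] = {m: [] for m in metrics}
    for p in densities:
        g = graphs[p]
        for m in metrics:
            if m == "clustering":
                v = nodal_clustering(g)
            elif m == "efficiency_global":
                v = np.array([global_efficiency(g)])
            elif m == "efficiency_local":
                v = local_efficiency(g)
            else:
                raise ValueError(f"unknown metric {m!r}")
            per_density[m].append(v)
            roi = [-1] if v.size == 1 else list(range(v.size))
            rows.extend(
                {"density": p, "roi": r, "metric": m, "value": float(x)}
                for r, x in zip(roi, v)
            )
    df = pd.DataFrame(rows)
    if integrate and len(densities) >= 2:
        auc_rows = []
        for m in metrics:
            stacked = np.vstack(per_density[m])
            auc = auc_over_thresholds(stacked, densities)
            auc = np.atleast_1d(auc)
            roi = [-1] if auc.size == 1 else list(range(auc.size))
            auc_rows.extend(
                {"density": np.nan, "roi": r, "metric": m, "value": float(x)}
                for r, x in zip(roi, auc)
            )
        df = pd.concat([df, pd.DataFrame(auc_rows)], ignore_index=True)
    return df
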