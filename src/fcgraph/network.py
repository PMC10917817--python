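"""Construction of weighted undirected brain graphs from connectivity matrices.

Condition-wise ROI-to-ROI matrices (Fisher-z transformed Pearson
correlations) are turned into nonnegative weighted graphs by zeroing
negative weights and retaining only the strongest fraction of edges
("proportional thresholding") at one or several target densities.
Retained edges keep their original weights; the analysis downstream is
fully weighted, never binarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Edge densities used throughout the pipeline: the strongest 10%..50% of edges.
DEFAULT_DENSITIES: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)

_SYMMETRY_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """One participant x condition ROI-to-ROI Fisher-z matrix.

    Attributes
    ----------
    participant : str
        Participant identifier.
    attention : str
        Attended dimension, ``"melody"`` or ``"sentence"``.
    degradation : str
        Degraded acoustic dimension, ``"spectral"`` or ``"temporal"``.
    cutoff : int
        Degradation strength step, 1 (strongest) .. 5 (mildest).
    weights : ndarray of shape (n, n)
        Symmetric Fisher-z connectivity, zero diagonal.
    labels : list of str
        ROI names, one per row/column.
    """

    participant: str
    attention: str
    degradation: str
    cutoff: int
    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {w.shape}")
        if not np.allclose(w, w.T, atol=_SYMMETRY_TOL, rtol=0.0):
            raise ValueError("connectivity matrix is asymmetric beyond tolerance 1e-08")
        if self.labels and len(self.labels) != w.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for a {w.shape[0]}-node matrix"
            )
        self.weights = w

    @property
    def n_roi(self) -> int:
        return self.weights.shape[0]

    @property
    def condition(self) -> tuple[str, str, int]:
        return (self.attention, self.degradation, self.cutoff)


@dataclass
class WeightedGraph:
    """Nonnegative weighted undirected graph retained at one edge density."""

    weights: np.ndarray
    density: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        """Upper-triangular (i, j) pairs with nonzero weight."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return set(zip(i.tolist(), j.tolist()))


@dataclass
class ThresholdedGraphSet:
    """Graphs of one source matrix retained at several nested densities."""

    graphs: dict[float, WeightedGraph]

    @property
    def densities(self) -> list[float]:
        return sorted(self.graphs)

    def __getitem__(self, density: float) -> WeightedGraph:
        return self.graphs[density]

    def __iter__(self):
        return (self.graphs[p] for p in self.densities)


def fisher_z(r):
    """Fisher z-transform, ``arctanh(r)``, of a correlation coefficient.

    Variance-stabilizes correlations so they can be treated as unbounded
    edge weights. Odd function; defined only on the open interval (-1, 1).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def timeseries_to_connectivity(
    series: np.ndarray,
    participant: str = "",
    attention: str = "",
    degradation: str = "",
    cutoff: int = 0,
    labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI time series, Fisher-z transformed.

    Parameters
    ----------
    series : ndarray of shape (n_roi, n_timepoints)
        One BOLD-like time series per ROI. Constant rows are rejected
        because their correlation with anything is undefined.

    Returns
    -------
    ConnectivityMatrix
        Symmetric Fisher-z matrix with zero diagonal.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (n_roi, n_timepoints)")
    n_roi, t = series.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    if np.any(np.std(series, axis=1) == 0.0):
        raise ValueError("constant time series: correlation undefined")
    r = np.corrcoef(series)
    np.fill_diagonal(r, 0.0)
    off = r[~np.eye(n_roi, dtype=bool)]
    if np.any(np.abs(off) >= 1.0 - 1e-12):
        raise ValueError("perfectly correlated ROI pair: Fisher z diverges")
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    return ConnectivityMatrix(
        participant=participant,
        attention=attention,
        degradation=degradation,
        cutoff=cutoff,
        weights=z,
        labels=list(labels) if labels is not None else [],
    )


def zero_negative_weights(matrix: np.ndarray) -> np.ndarray:
    """Set negative weights to zero, keeping only positive connectivity.

    Standard practice before weighted graph metrics, avoiding polarity
    ambiguities in path- and triangle-based measures. Idempotent.
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {w.shape}")
    return np.maximum(w, 0.0)


def proportional_threshold(matrix: np.ndarray, density: float) -> WeightedGraph:
    """Retain the strongest fraction ``density`` of edges, weights unchanged.

    The density is counted over the full set of n(n-1)/2 off-diagonal
    pairs of the matrix (zeros included in the denominator), so a density
    of 0.1 keeps the strongest 10% of all possible edges. Ties at the cut
    are broken deterministically by (weight descending, row index
    ascending, column index ascending), making the output bit-reproducible.

    Parameters
    ----------
    matrix : (n, n) nonnegative symmetric array
    density : float in (0, 1]

    Returns
    -------
    WeightedGraph
        Symmetric, zero diagonal; exactly ``ceil(density * n(n-1)/2)``
        off-diagonal upper-triangular entries nonzero (fewer if the input
        has fewer positive entries than that).
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {w.shape}")
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must be in (0, 1], got {density}")
    if np.any(w < 0):
        raise ValueError("negative weights present; call zero_negative_weights first")
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    n_pairs = vals.size
    k = int(np.ceil(density * n_pairs))
    # lexsort: primary weight desc, then row asc, then col asc
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    keep = keep[vals[keep] > 0.0]  # never retain zero-weight "edges"
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return WeightedGraph(weights=out, density=density)


def threshold_series(
    matrix: np.ndarray, densities=DEFAULT_DENSITIES
) -> ThresholdedGraphSet:
    """Threshold one matrix at each density in ``densities``.

    Edge sets are nested by construction: the strongest-k edges at a lower
    density are a subset of the strongest-k' at any higher density.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("densities list is empty")
    return ThresholdedGraphSet(
        graphs={p: proportional_threshold(matrix, p) for p in densities}
    )
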