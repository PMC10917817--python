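"""Degree- and strength-preserving surrogate networks for metric normalization.

Raw graph metrics confound topology with basic connectivity statistics
(degree and strength distributions). Each empirical graph is therefore
compared against an ensemble of randomized surrogates that keep the
degree sequence and the weight multiset exactly, and approximate the
strength sequence: topology is randomized by degree-preserving
double-edge swaps, then the original weights are re-assigned to the new
edges by rank-matching the expected strengths of their endpoints. An
empirical metric is normalized by the mean of the same metric over the
ensemble (ratio convention; z-scoring available).

Since the pipeline zeroes negative weights before this stage, the
sign-aware variant of this null model reduces to the positive-weight
case implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NullEnsemble", "randomize_network", "null_ensemble", "normalize_metric"]

#: Surrogates per graph and rewiring passes over the edge list.
DEFAULT_N_SURROGATES = 100
DEFAULT_REWIRING_ITERATIONS = 10


@dataclass
class NullEnsemble:
    """Surrogate weight matrices for one source graph."""

    surrogates: list[np.ndarray]
    rewiring_iterations: int
    seed: int | None

    def __len__(self) -> int:
        return len(self.surrogates)


def _double_edge_swap(
    edges: np.ndarray, n_nodes: int, n_passes: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomize topology by repeated degree-preserving double-edge swaps.

    A swap picks two edges (a, b), (c, d) and rewires them to (a, d),
    (c, b) when this creates neither self-loops nor duplicate edges.
    ``n_passes`` full passes over the edge list are attempted.
    """
    edges = edges.copy()
    m = edges.shape[0]
    present = set(map(tuple, np.sort(edges, axis=1).tolist()))
    n_attempts = n_passes * m
    e1 = rng.integers(0, m, size=n_attempts)
    e2 = rng.integers(0, m, size=n_attempts)
    flip = rng.integers(0, 2, size=n_attempts)
    for t in range(n_attempts):
        i, j = e1[t], e2[t]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in present or new2 in present:
            continue
        present.discard(tuple(np.sort(edges[i])))
        present.discard(tuple(np.sort(edges[j])))
        edges[i] = new1
        edges[j] = new2
        present.add(new1)
        present.add(new2)
    return edges


def randomize_network(
    weights: np.ndarray,
    rewiring_iterations: int = DEFAULT_REWIRING_ITERATIONS,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One degree- and weight-preserving surrogate of a weighted graph.

    Parameters
    ----------
    weights : (n, n) nonnegative symmetric array, zero diagonal
    rewiring_iterations : int
        Passes over the edge list during topology randomization.
    seed : int, Generator or None
        Source of randomness; fixed seeds give reproducible surrogates.

    Returns
    -------
    ndarray
        Surrogate weight matrix. The degree sequence and the multiset of
        edge weights equal the source exactly; node strengths are
        approximated by assigning the largest weights to the edges whose
        endpoints had the largest original strength product.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be square")
    if np.any(w < 0):
        raise ValueError("negative weights present")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    edges = np.column_stack([iu[mask], ju[mask]])
    wvals = w[iu, ju][mask]
    if edges.shape[0] < 2:
        raise ValueError("need at least 2 edges to randomize")
    new_edges = _double_edge_swap(edges, n, rewiring_iterations, rng)
    # Strength-rank weight reassignment: weights are placed in descending
    # order, each onto the remaining edge whose endpoints have the largest
    # residual strength budget; residuals shrink as weights are assigned.
    residual = w.sum(axis=1)
    remaining = np.arange(new_edges.shape[0])
    order = np.argsort(-wvals, kind="stable")
    out = np.zeros_like(w)
    for wv in wvals[order]:
        ei, ej = new_edges[remaining, 0], new_edges[remaining, 1]
        pick = int(np.argmax(residual[ei] * residual[ej]))
        i, j = ei[pick], ej[pick]
        out[i, j] = out[j, i] = wv
        residual[i] -= wv
        residual[j] -= wv
        remaining = np.delete(remaining, pick)
    return out


def null_ensemble(
    weights: np.ndarray,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    rewiring_iterations: int = DEFAULT_REWIRING_ITERATIONS,
    seed: int | None = None,
) -> NullEnsemble:
    """Generate ``n_surrogates`` independent surrogates of one graph."""
    rng = np.random.default_rng(seed)
    surrogates = [
        randomize_network(weights, rewiring_iterations, rng)
        for _ in range(n_surrogates)
    ]
    return NullEnsemble(
        surrogates=surrogates, rewiring_iterations=rewiring_iterations, seed=seed
    )


def normalize_metric(empirical, null_values, how: str = "ratio"):
    """Normalize an empirical metric against its null distribution.

    ``how="ratio"`` (default) divides by the null mean, the convention of
    the toolbox family this pipeline mirrors; ``how="zscore"`` returns
    ``(empirical - mean) / sd``; ``how="none"`` passes through.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0 or not np.all(np.isfinite(null_values)):
        raise ValueError("null values must be finite and non-empty")
    if how == "none":
        return empirical
    mean = null_values.mean(axis=0)
    if how == "ratio":
        if np.any(mean == 0):
            raise ValueError("null mean is zero; ratio normalization undefined")
        return empirical / mean
    if how == "zscore":
        sd = null_values.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("null sd is zero; z-score normalization undefined")
        return (empirical - mean) / sd
    raise ValueError(f"unknown normalization {how!r}")
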