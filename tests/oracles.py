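"""Independent brute-force oracles for graph quantities.

Deliberately naive implementations (triple loops, exhaustive path and
partition enumeration) used only to cross-check the vectorized library
code on tiny graphs. They share no code with the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_brute(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triangle enumeration."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    mx = w.max()
    if mx == 0:
        return np.zeros(n)
    what = w / mx
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def distances_brute(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths (lengths 1/w) by simple-path enumeration."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = list(range(n))
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best = np.inf
            for r in range(0, n - 1):
                for mid in itertools.permutations(
                    [x for x in nodes if x not in (s, t)], r
                ):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok:
                        best = min(best, length)
            d[s, t] = best
    return d


def global_efficiency_brute(w: np.ndarray) -> float:
    d = distances_brute(w)
    n = w.shape[0]
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def local_efficiency_brute(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        out[i] = global_efficiency_brute(w[np.ix_(nb, nb)])
    return out


def modularity_brute(w: np.ndarray, assignment, gamma: float = 1.0) -> float:
    """Pairwise-sum evaluation of weighted modularity at resolution gamma."""
    w = np.asarray(w, dtype=float)
    a = np.asarray(assignment)
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    s = w.sum(axis=1)
    q = 0.0
    n = w.shape[0]
    for i in range(n):
        for j in range(n):
            if a[i] == a[j]:
                q += w[i, j] - gamma * s[i] * s[j] / two_m
    return q / two_m


def _set_partitions(items):
    """All set partitions of a small collection (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_brute(w: np.ndarray, gamma: float = 1.0):
    """Exhaustive modularity maximization over all partitions (n <= ~8)."""
    n = w.shape[0]
    best_q, best_assign = -np.inf, None
    for part in _set_partitions(range(n)):
        assign = np.empty(n, dtype=int)
        for label, block in enumerate(part, start=1):
            for node in block:
                assign[node] = label
        q = modularity_brute(w, assign, gamma)
        if q > best_q:
            best_q, best_assign = q, assign
    return best_assign, best_q


def agreement_brute(assignments) -> np.ndarray:
    arrays = [np.asarray(a) for a in assignments]
    n = arrays[0].shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.mean([a[i] == a[j] for a in arrays])
    return out


def unweighted_clustering_brute(adj: np.ndarray) -> np.ndarray:
    """Classic binary clustering coefficient (triangle / triple count)."""
    adj = (np.asarray(adj) > 0).astype(float)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(adj[u, v] for u, v in itertools.combinations(nb, 2))
        out[i] = 2.0 * links / (k * (k - 1))
    return out
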