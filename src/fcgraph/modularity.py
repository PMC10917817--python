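"""Community structure: Louvain partitions, consensus clustering, Q and hub z.

Modular decomposition of weighted graphs by the Louvain heuristic with a
resolution parameter, repeated from many random node orders. Because
single Louvain runs are stochastic, partitions are aggregated into a
co-classification (agreement) matrix whose entry (i, j) is the fraction
of runs placing i and j in the same module; a consensus partition is the
fixed point of repeatedly clustering the thresholded agreement matrix.

Per-node within-module degree z quantifies hub-ness relative to the
node's own module: the z-score of its within-module strength among the
strengths of its module mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Partition",
    "ConsensusResult",
    "modularity_q",
    "louvain",
    "agreement_matrix",
    "consensus_partition",
    "within_module_degree_z",
]

DEFAULT_GAMMA = 1.0
DEFAULT_REPS = 1000
DEFAULT_TAU = 0.5
CONSENSUS_MAX_ROUNDS = 50


@dataclass
class Partition:
    """Node-to-module assignment with its modularity value.

    ``assignment`` holds integer module labels, contiguous from 1.
    """

    assignment: np.ndarray
    q: float
    gamma: float = DEFAULT_GAMMA
    seed: int | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.assignment))

    def relabel(self) -> "Partition":
        """Canonical labels: 1, 2, ... in order of first appearance."""
        _, idx = np.unique(self.assignment, return_index=True)
        mapping = {
            self.assignment[i]: k + 1 for k, i in enumerate(sorted(idx))
        }
        new = np.array([mapping[a] for a in self.assignment])
        return Partition(new, self.q, self.gamma, self.seed)


@dataclass
class ConsensusResult:
    """Consensus partition with the agreement matrix it was derived from."""

    agreement: np.ndarray
    consensus: Partition
    within_module_z: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    rounds: int = 0


def modularity_q(weights: np.ndarray, assignment, gamma: float = DEFAULT_GAMMA) -> float:
    """Weighted Newman-Girvan modularity with resolution ``gamma``.

    Q = (1/2m) * sum_ij [A_ij - gamma * s_i s_j / (2m)] * delta(c_i, c_j)

    where s is node strength and 2m the total weight. Equivalently, in
    edge-fraction form, Q = sum_c [e_c/m - gamma (d_c/2m)^2]. Q of the
    one-module partition is 0 at gamma = 1.
    """
    w = np.asarray(weights, dtype=float)
    a = np.asarray(assignment)
    if a.shape[0] != w.shape[0]:
        raise ValueError("assignment length does not match matrix size")
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    s = w.sum(axis=1)
    same = a[:, None] == a[None, :]
    expected = gamma * np.outer(s, s) / two_m
    return float(((w - expected) * same).sum() / two_m)


def _matrix_to_graph(weights: np.ndarray) -> nx.Graph:
    w = np.asarray(weights, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    i, j = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(zip(i.tolist(), j.tolist(), w[i, j].tolist()))
    return g


def louvain(
    weights: np.ndarray,
    gamma: float = DEFAULT_GAMMA,
    seed: int | np.random.Generator | None = None,
) -> Partition:
    """One Louvain run: greedy modularity maximization at resolution gamma.

    The node visiting order is randomized from ``seed``; distinct seeds
    explore distinct local optima. Returns the partition together with
    its modularity Q (recomputed from the definition, not trusted from
    the optimizer).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty graph")
    if np.any(w < 0):
        raise ValueError("negative weights present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = _matrix_to_graph(w)
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=gamma, seed=nx_seed
    )
    assignment = np.empty(w.shape[0], dtype=int)
    for label, nodes in enumerate(communities, start=1):
        for node in nodes:
            assignment[node] = label
    q = modularity_q(w, assignment, gamma)
    return Partition(assignment=assignment, q=q, gamma=gamma).relabel()


def louvain_ensemble(
    weights: np.ndarray,
    reps: int = DEFAULT_REPS,
    gamma: float = DEFAULT_GAMMA,
    seed: int | np.random.Generator | None = None,
) -> list[Partition]:
    """``reps`` independent Louvain runs, each from its own seed substream."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [louvain(weights, gamma, rng) for _ in range(reps)]


def agreement_matrix(partitions: list[Partition] | list[np.ndarray]) -> np.ndarray:
    """Co-classification frequency: fraction of partitions joining each pair.

    Symmetric with unit diagonal; entries in [0, 1].
    """
    if not partitions:
        raise ValueError("no partitions given")
    arrays = [
        p.assignment if isinstance(p, Partition) else np.asarray(p) for p in partitions
    ]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("partitions cover different node sets")
    acc = np.zeros((n, n))
    for a in arrays:
        acc += a[:, None] == a[None, :]
    return acc / len(arrays)


def consensus_partition(
    agreement: np.ndarray,
    tau: float = DEFAULT_TAU,
    reps: int = 100,
    gamma: float = DEFAULT_GAMMA,
    seed: int | np.random.Generator | None = None,
    max_rounds: int = CONSENSUS_MAX_ROUNDS,
) -> ConsensusResult:
    """Fixed-point consensus clustering of a co-classification matrix.

    Each round zeroes agreement entries below ``tau``, runs Louvain
    ``reps`` times on the thresholded matrix, and rebuilds the agreement
    from those runs; iteration stops when all runs agree (the partition
    is its own consensus). Non-convergence within ``max_rounds`` is
    reported on the result, never silent.
    """
    ag = np.asarray(agreement, dtype=float)
    if ag.ndim != 2 or ag.shape[0] != ag.shape[1]:
        raise ValueError("agreement matrix must be square")
    if np.any(ag < 0) or np.any(ag > 1 + 1e-12):
        raise ValueError("agreement entries must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = ag.copy()
    for round_no in range(1, max_rounds + 1):
        thresholded = np.where(current >= tau, current, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        runs = [louvain(thresholded, gamma, rng) for _ in range(reps)]
        first = runs[0].relabel().assignment
        if all(np.array_equal(first, r.relabel().assignment) for r in runs[1:]):
            part = Partition(first, modularity_q(ag, first, gamma), gamma)
            return ConsensusResult(
                agreement=ag, consensus=part.relabel(), converged=True, rounds=round_no
            )
        current = agreement_matrix(runs)
    part = runs[0].relabel()
    return ConsensusResult(
        agreement=ag, consensus=part, converged=False, rounds=max_rounds
    )


def within_module_degree_z(weights: np.ndarray, partition) -> np.ndarray:
    """Within-module strength z-score per node (hub index).

    ``z_i = (k_i - mean_module) / sd_module`` where ``k_i`` is node i's
    summed weight to members of its own module and mean/sd are taken over
    that module. Modules with zero strength variance (including
    singletons) yield z = 0.
    """
    w = np.asarray(weights, dtype=float)
    a = partition.assignment if isinstance(partition, Partition) else np.asarray(partition)
    if a.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover all nodes")
    z = np.zeros(w.shape[0])
    for label in np.unique(a):
        members = np.nonzero(a == label)[0]
        kappa = w[np.ix_(members, members)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return z
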