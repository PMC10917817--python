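"""End-to-end orchestration: matrices -> metric tables -> inference.

Ties the stages together the way the study design requires: every
condition-level matrix is negative-zeroed, proportionally thresholded at
the five densities, measured (Onnela clustering per node, global
clustering, global and local efficiency), optionally normalized against
degree/strength-preserving surrogates, and AUC-integrated over density.
The resulting long table keys every value by participant, attention,
degradation and cutoff, ready for the mixed-model stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as gm
from . import modularity as mod
from .network import DEFAULT_DENSITIES, ConnectivityMatrix, threshold_series, zero_negative_weights
from .nulls import null_ensemble, normalize_metric

__all__ = ["MetricConfig", "compute_metric_table", "ModularityConfig", "compute_modularity_table"]


@dataclass
class MetricConfig:
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    metrics: tuple[str, ...] = ("clustering", "efficiency_global")
    normalization: str = "none"  # "none", "ratio" or "zscore"
    n_surrogates: int = 100
    rewiring_iterations: int = 10
    seed: int | None = None


def _measure(graph_w: np.ndarray, metric: str) -> np.ndarray:
    if metric == "clustering":
        return gm.nodal_clustering(graph_w)
    if metric == "efficiency_global":
        return np.array([gm.global_efficiency(graph_w)])
    if metric == "efficiency_local":
        return gm.local_efficiency(graph_w)
    raise ValueError(f"unknown metric {metric!r}")


def compute_metric_table(
    matrices: list[ConnectivityMatrix], config: MetricConfig | None = None
) -> pd.DataFrame:
    """AUC-integrated metric values for every matrix of a dataset.

    Returns a long-format frame with one row per matrix x metric x node
    (``roi = -1`` for global values), columns ``participant, attention,
    degradation, cutoff, roi, metric, value, normalized``. With
    normalization enabled, each metric at each density is divided by its
    mean over a surrogate ensemble of that graph before integration.
    """
    config = config or MetricConfig()
    densities = list(config.densities)
    rng = np.random.default_rng(config.seed)
    rows = []
    for m in matrices:
        w = zero_negative_weights(m.weights)
        graphs = threshold_series(w, densities)
        for metric in config.metrics:
            values = []
            for p in densities:
                gw = graphs[p].weights
                v = _measure(gw, metric)
                if config.normalization != "none":
                    nulls = null_ensemble(
                        gw,
                        n_surrogates=config.n_surrogates,
                        rewiring_iterations=config.rewiring_iterations,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    null_vals = np.vstack([_measure(s, metric) for s in nulls.surrogates])
                    v = normalize_metric(v, null_vals, how=config.normalization)
                values.append(v)
            auc = np.atleast_1d(gm.auc_over_thresholds(np.vstack(values), densities))
            rois = [-1] if auc.size == 1 else list(range(auc.size))
            rows.extend(
                {
                    "participant": m.participant,
                    "attention": m.attention,
                    "degradation": m.degradation,
                    "cutoff": m.cutoff,
                    "roi": r,
                    "metric": metric,
                    "value": float(x),
                    "normalized": config.normalization != "none",
                }
                for r, x in zip(rois, auc)
            )
    return pd.DataFrame(rows)


@dataclass
class ModularityConfig:
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    reps: int = mod.DEFAULT_REPS
    gamma: float = mod.DEFAULT_GAMMA
    tau: float = mod.DEFAULT_TAU
    consensus_reps: int = 100
    seed: int | None = None


@dataclass
class ModularityOutput:
    table: pd.DataFrame
    assignments: pd.DataFrame
    group_consensus: dict = field(default_factory=dict)


def compute_modularity_table(
    matrices: list[ConnectivityMatrix], config: ModularityConfig | None = None
) -> ModularityOutput:
    """Participant-level consensus modularity per matrix, then group level.

    For each matrix, Louvain runs ``reps`` times on each thresholded
    graph; the agreement matrix pooled across the five densities feeds
    consensus clustering, yielding the partition, its modularity Q
    (evaluated on the agreement matrix) and the per-node within-module
    strength z. Group-level consensus per attention x degradation x
    cutoff condition is the consensus over that condition's
    participant-level partitions.
    """
    config = config or ModularityConfig()
    rng = np.random.default_rng(config.seed)
    rows, assign_rows = [], []
    by_condition: dict[tuple, list[np.ndarray]] = {}
    for m in matrices:
        w = zero_negative_weights(m.weights)
        graphs = threshold_series(w, list(config.densities))
        partitions = []
        for p in graphs.densities:
            partitions.extend(
                mod.louvain_ensemble(graphs[p].weights, config.reps, config.gamma, rng)
            )
        ag = mod.agreement_matrix(partitions)
        cons = mod.consensus_partition(
            ag, tau=config.tau, reps=config.consensus_reps, gamma=config.gamma, seed=rng
        )
        z = mod.within_module_degree_z(w, cons.consensus)
        rows.append(
            {
                "participant": m.participant,
                "attention": m.attention,
                "degradation": m.degradation,
                "cutoff": m.cutoff,
                "q": cons.consensus.q,
                "n_modules": cons.consensus.n_modules,
                "converged": cons.converged,
            }
        )
        assign_rows.extend(
            {
                "participant": m.participant,
                "attention": m.attention,
                "degradation": m.degradation,
                "cutoff": m.cutoff,
                "roi": i,
                "module": int(lab),
                "within_module_z": float(zz),
            }
            for i, (lab, zz) in enumerate(zip(cons.consensus.assignment, z))
        )
        by_condition.setdefault(m.condition, []).append(cons.consensus.assignment)
    group = {}
    for cond, parts in by_condition.items():
        ag = mod.agreement_matrix(parts)
        group[cond] = mod.consensus_partition(
            ag, tau=config.tau, reps=config.consensus_reps, gamma=config.gamma, seed=rng
        )
    return ModularityOutput(
        table=pd.DataFrame(rows),
        assignments=pd.DataFrame(assign_rows),
        group_consensus=group,
    )
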