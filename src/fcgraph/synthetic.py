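"""Synthetic study generator: design, stimuli, behaviour, connectivity.

Emulates a 2 (attention: melody/sentence) x 2 (degradation:
spectral/temporal) x 5 (degradation cutoff, 1 = strongest) within-subject
fMRI study of sung speech with 15 participants, i.e. 300 condition-level
connectivity matrices, plus the accompanying behavioural same-different
experiment (4 blocks of 50 degraded trials and one 40-trial non-degraded
baseline block per participant).

Connectivity matrices are sampled through latent modular factor time
series: nodes load on their module's factor (plus a weak global factor
tying modules together), and the observed matrix is the Fisher-z
transformed correlation of the simulated series. This guarantees every
matrix is a valid correlation structure. A condition-dependent effect is
planted by loading a small target-ROI neighbourhood onto an extra shared
factor whose strength grows with degradation (decreases with cutoff), so
local clustering at the target ROIs rises with degradation strength in
the flagged conditions only — a known ground truth for parameter-recovery
tests of the whole downstream pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import ConnectivityMatrix, timeseries_to_connectivity

__all__ = [
    "StudyDesign",
    "StimulusCatalog",
    "GeneratorParams",
    "PerformanceParams",
    "generate_design",
    "generate_stimulus_catalog",
    "generate_behavioral_trials",
    "generate_block_schedule",
    "generate_connectivity_dataset",
    "planted_two_module_graph",
    "RESPONSE_SCALE",
]

ATTENTION_LEVELS = ("melody", "sentence")
DEGRADATION_LEVELS = ("spectral", "temporal")
CUTOFFS = (1, 2, 3, 4, 5)

#: Six-point confidence scale of the behavioural same-different task.
RESPONSE_SCALE = (
    "Same",
    "Maybe Same",
    "Same not sure",
    "Different not sure",
    "Maybe Different",
    "Different",
)


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial crossing of participants x attention x degradation x cutoff."""

    participants: tuple[str, ...]
    attention_levels: tuple[str, ...] = ATTENTION_LEVELS
    degradation_levels: tuple[str, ...] = DEGRADATION_LEVELS
    cutoffs: tuple[int, ...] = CUTOFFS

    def cells(self) -> list[tuple[str, str, str, int]]:
        """All (participant, attention, degradation, cutoff) cells; 20 per participant."""
        return list(
            itertools.product(
                self.participants,
                self.attention_levels,
                self.degradation_levels,
                self.cutoffs,
            )
        )

    @property
    def n_cells(self) -> int:
        return (
            len(self.participants)
            * len(self.attention_levels)
            * len(self.degradation_levels)
            * len(self.cutoffs)
        )


@dataclass(frozen=True)
class StimulusCatalog:
    """Sung-speech stimulus inventory: 10 melodies x 10 sentences.

    Melodies carry number codes and sentences letter codes; their full
    crossing gives 100 base a-cappella songs, each degraded along 2
    acoustic dimensions at 5 cutoffs -> 1000 degraded stimuli.
    """

    melodies: tuple[str, ...]
    sentences: tuple[str, ...]

    def base_stimuli(self) -> list[tuple[str, str]]:
        return list(itertools.product(self.melodies, self.sentences))

    def degraded_stimuli(self) -> list[tuple[str, str, str, int]]:
        return [
            (m, s, d, c)
            for (m, s), d, c in itertools.product(
                self.base_stimuli(), DEGRADATION_LEVELS, CUTOFFS
            )
        ]


def generate_design(n_participants: int, seed: int | None = None) -> StudyDesign:
    """Enumerate the study design for ``n_participants`` participants.

    The crossing is deterministic; 15 participants yield the study-scale
    300 participant x condition cells (20 per participant).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    participants = tuple(f"sub-{i:02d}" for i in range(1, n_participants + 1))
    return StudyDesign(participants=participants)


def generate_stimulus_catalog() -> StimulusCatalog:
    """The 10 x 10 melody-by-sentence stimulus crossing."""
    return StimulusCatalog(
        melodies=tuple(str(i) for i in range(1, 11)),
        sentences=tuple("ABCDEFGHIJ"),
    )


@dataclass
class PerformanceParams:
    """Psychometric profile of the behavioural same-different task.

    Accuracy declines with degradation strength only when the degraded
    dimension carries the task-crucial information: temporal degradation
    impairs sentence judgements, spectral degradation impairs melody
    judgements; the complementary pairings stay near baseline. ``p`` is
    linear in cutoff from ``floor`` (cutoff 1, strongest degradation) to
    ``baseline`` (cutoff 5, mildest).
    """

    baseline: float = 0.9
    floor: float = 0.55

    def p_correct(self, task: str, degradation: str, cutoff) -> float:
        if degradation == "none":
            return self.baseline
        crucial = (task == "sentence" and degradation == "temporal") or (
            task == "melody" and degradation == "spectral"
        )
        if not crucial:
            return self.baseline
        p = self.floor + (self.baseline - self.floor) * (int(cutoff) - 1) / 4.0
        return p

    def validate(self) -> None:
        for t, d, c in itertools.product(
            ("melody", "sentence"), ("spectral", "temporal", "none"), CUTOFFS
        ):
            p = self.p_correct(t, d, c)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p(correct)={p} outside [0, 1] for {(t, d, c)}")


def _response_label(truth: str, correct: bool, rng: np.random.Generator) -> str:
    """Map truth x correctness to one of the six confidence labels."""
    answered = truth if correct else ("different" if truth == "same" else "same")
    side = RESPONSE_SCALE[:3] if answered == "same" else RESPONSE_SCALE[3:]
    return side[rng.integers(0, 3)]


def generate_behavioral_trials(
    design: StudyDesign,
    perf_params: PerformanceParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the behavioural trial table for every participant.

    Per participant: 4 blocks of 50 degraded trials in which each
    degradation x cutoff cell occurs 20 times (balanced over task and
    same/different truth, distributed uniformly over the blocks), plus a
    final baseline block of 40 non-degraded trials. Correctness is
    Bernoulli with the probabilities of ``perf_params``; the 6-point
    response is drawn on the answered side and collapses back to the
    sampled correctness.
    """
    perf = perf_params or PerformanceParams()
    perf.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for participant in design.participants:
        # 200 degraded trials: 2 deg x 5 cutoff x (2 task x (5 same + 5 diff))
        trials = [
            (task, deg, cut, truth)
            for deg in design.degradation_levels
            for cut in design.cutoffs
            for task in ("melody", "sentence")
            for truth in ("same",) * 5 + ("different",) * 5
        ]
        order = rng.permutation(len(trials))
        for pos, idx in enumerate(order):
            task, deg, cut, truth = trials[idx]
            block = pos // 50 + 1
            p = perf.p_correct(task, deg, cut)
            correct = rng.random() < p
            rows.append(
                (participant, block, task, deg, cut, truth,
                 _response_label(truth, correct, rng), int(correct))
            )
        # baseline block: 40 original stimuli
        base = [
            (task, truth)
            for task in ("melody", "sentence")
            for truth in ("same",) * 10 + ("different",) * 10
        ]
        for task, truth in base:
            p = perf.p_correct(task, "none", 0)
            correct = rng.random() < p
            rows.append(
                (participant, 5, task, "none", 0, truth,
                 _response_label(truth, correct, rng), int(correct))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "block", "task", "degradation", "cutoff",
            "truth", "response6", "correct",
        ],
    )


def generate_block_schedule(design: StudyDesign, seed: int | None = None) -> pd.DataFrame:
    """Per-participant fMRI block schedule: 2 runs of 55 blocks each.

    Each run presents every degradation x cutoff combination five times
    (50 stimulation blocks, attention cued per block and balanced within
    each combination), plus four silence blocks and one white-noise
    block, for 110 blocks per participant in total.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for participant in design.participants:
        for run in (1, 2):
            blocks: list[tuple[str, str, int | None]] = []
            for deg, cut in itertools.product(design.degradation_levels, design.cutoffs):
                # five repetitions, attention near-balanced within the cell
                atts = ["melody", "melody", "sentence", "sentence",
                        "melody" if (run + cut) % 2 else "sentence"]
                blocks.extend(("stimulation:" + att, deg, cut) for att in atts)
            blocks.extend([("silence", "none", None)] * 4)
            blocks.append(("noise", "none", None))
            order = rng.permutation(len(blocks))
            for pos, idx in enumerate(order, start=1):
                kind, deg, cut = blocks[idx]
                attention = kind.split(":", 1)[1] if ":" in kind else "none"
                rows.append(
                    (participant, run, pos, kind.split(":", 1)[0], attention, deg, cut)
                )
    return pd.DataFrame(
        rows,
        columns=["participant", "run", "position", "block_type",
                 "attention", "degradation", "cutoff"],
    )


@dataclass
class GeneratorParams:
    """Parameters of the latent-factor connectivity generator.

    Attributes
    ----------
    n_roi : int
        Nodes per matrix. 64 by default (desk scale); use
        :meth:`full_scale` for the 358-ROI study-scale preset.
    n_modules : int
        Planted modules; nodes are split into contiguous blocks.
    within_corr, between_corr : float
        Mean Pearson correlation of node pairs within / between modules;
        requires ``0 <= between < within < 1``.
    loading_spread : float
        Half-width of the uniform distribution of node loadings around
        ``sqrt(within_corr)``. Heterogeneous loadings create hub pairs
        whose weights anchor the upper tail of the weight distribution,
        so the graph's maximum weight (the Onnela scaling constant) is
        stable across conditions instead of tracking the planted effect.
    participant_sd : float
        SD of the per-participant offset on the module-factor loading
        (shared across that participant's 20 conditions), creating
        participant-level random intercepts in every derived metric.
    target_rois : tuple of int
        Nodes carrying the planted condition effect.
    neighbour_rois : tuple of int
        Designated neighbourhood co-loading with the targets; the
        clustering increase at the targets comes from triangles through
        these nodes.
    neighbourhood_base : float
        Baseline variance share of the shared neighbourhood factor,
        present in every condition. It keeps the neighbourhood's edges
        above the retention threshold at all cutoffs, so the planted
        effect modulates edge weights rather than edge membership and
        does not crowd other ROIs' edges out of the thresholded graphs.
    clustering_slope : float
        beta: the planted correlation increment among the target
        neighbourhood is ``beta * (6 - cutoff)`` in the flagged
        conditions, so the effect is strongest at cutoff 1 and local
        clustering declines with increasing cutoff.
    effect_conditions : tuple of (attention, degradation)
        Conditions carrying the planted effect; default: attending the
        dimension whose crucial cues are degraded.
    n_timepoints : int
        Length of the latent series (>= 30).
    seed : int
        Master seed; every matrix uses its own spawned substream.
    """

    n_roi: int = 64
    n_modules: int = 4
    within_corr: float = 0.42
    between_corr: float = 0.10
    loading_spread: float = 0.22
    participant_sd: float = 0.05
    target_rois: tuple[int, ...] = (0, 1, 2, 3, 4)
    neighbour_rois: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15)
    neighbourhood_base: float = 0.30
    clustering_slope: float = 0.025
    effect_conditions: tuple[tuple[str, str], ...] = (
        ("sentence", "temporal"),
        ("melody", "spectral"),
    )
    anchor_loading: float = 0.93
    n_timepoints: int = 400
    seed: int = 0
    module_assignment: np.ndarray | None = None

    @property
    def anchor_rois(self) -> tuple[int, int]:
        """Two fixed high-loading nodes (last two of the parcellation).

        Their mutual edge is the strongest weight of every matrix in
        every condition, like the near-ceiling homotopic connections of
        real connectomes. Because Onnela clustering scales weights by
        the graph maximum, a stable anchor edge keeps the scaling
        constant independent of the planted condition effect.
        """
        return (self.n_roi - 2, self.n_roi - 1)

    @classmethod
    def full_scale(cls, **overrides) -> "GeneratorParams":
        """Study-scale preset: 358 ROIs (multimodal cortical parcellation size)."""
        overrides.setdefault("n_roi", 358)
        return cls(**overrides)

    def modules(self) -> np.ndarray:
        if self.module_assignment is not None:
            m = np.asarray(self.module_assignment, dtype=int)
            if m.shape[0] != self.n_roi:
                raise ValueError("module_assignment length != n_roi")
            return m
        return np.minimum(
            np.arange(self.n_roi) * self.n_modules // self.n_roi, self.n_modules - 1
        )

    def validate(self) -> None:
        if not (0.0 <= self.between_corr < self.within_corr < 1.0):
            raise ValueError("require 0 <= between_corr < within_corr < 1")
        if self.n_timepoints < 30:
            raise ValueError("n_timepoints must be >= 30")
        if not np.isfinite(self.clustering_slope):
            raise ValueError("clustering_slope must be finite")
        planted = set(self.target_rois) | set(self.neighbour_rois)
        if planted and (min(planted) < 0 or max(planted) >= self.n_roi):
            raise ValueError("target/neighbour ROI ids outside the parcellation")
        if (np.sqrt(self.within_corr) + self.loading_spread) ** 2 >= 0.95:
            raise ValueError("loading_spread too large: hub pair correlation near 1")
        planted_peak = (0.85 * np.sqrt(self.within_corr)) ** 2 + self.neighbourhood_base \
            + abs(self.clustering_slope) * 5.0
        anchor_corr = self.anchor_loading**2
        if anchor_corr >= 0.95:
            raise ValueError("anchor_loading too large: anchor correlation near 1")
        if planted_peak >= anchor_corr - 0.05:
            raise ValueError(
                "planted peak correlation reaches the anchor edge: the Onnela "
                "scaling constant would track the condition effect"
            )
        if set(self.anchor_rois) & (set(self.target_rois) | set(self.neighbour_rois)):
            raise ValueError("anchor nodes overlap the planted neighbourhood")
        b2_max = self.neighbourhood_base + abs(self.clustering_slope) * 5.0
        a2_planted = (0.85 * np.sqrt(self.within_corr)) ** 2
        if a2_planted + b2_max >= 0.95:
            raise ValueError(
                "planted variance budget exhausted: within_corr, "
                "neighbourhood_base and 5*|clustering_slope| sum too close to 1 "
                "(correlation construction invalid)"
            )


def _base_loadings(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Study-level module-factor loading per node.

    Loadings are uniform around sqrt(within_corr) (heterogeneous hubs);
    planted nodes get a fixed moderate loading so their total variance
    budget leaves room for the neighbourhood factor at every cutoff.
    """
    root_w = np.sqrt(params.within_corr)
    a = rng.uniform(
        root_w - params.loading_spread, root_w + params.loading_spread, size=params.n_roi
    )
    planted = list(set(params.target_rois) | set(params.neighbour_rois))
    if planted:
        a[planted] = 0.85 * root_w
    a[list(params.anchor_rois)] = params.anchor_loading
    return a


def _simulate_cell_series(
    params: GeneratorParams,
    modules: np.ndarray,
    base_loadings: np.ndarray,
    loading_offset: float,
    effect_b2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent-factor series for one participant x condition cell."""
    t, n = params.n_timepoints, params.n_roi
    rho_g = params.between_corr / params.within_corr if params.within_corr > 0 else 0.0
    g = rng.standard_normal(t)
    locals_ = rng.standard_normal((params.n_modules, t))
    factors = np.sqrt(rho_g) * g + np.sqrt(1.0 - rho_g) * locals_
    h = rng.standard_normal(t)
    noise = rng.standard_normal((n, t))

    a = np.clip(base_loadings + loading_offset, 0.05, 0.95)
    b = np.zeros(n)
    planted = list(set(params.target_rois) | set(params.neighbour_rois))
    if planted:
        b[planted] = np.sqrt(params.neighbourhood_base + effect_b2)
    c2 = 1.0 - a**2 - b**2
    if np.any(c2 <= 0):
        raise ValueError("loadings exceed unit variance; reduce effect size")
    series = (
        a[:, None] * factors[modules]
        + b[:, None] * h
        + np.sqrt(c2)[:, None] * noise
    )
    return series


def generate_connectivity_dataset(
    design: StudyDesign, params: GeneratorParams
) -> list[ConnectivityMatrix]:
    """One Fisher-z connectivity matrix per design cell with planted structure.

    Every matrix is the Fisher-z transformed correlation matrix of
    simulated latent-factor time series (hence symmetric with zero
    diagonal and a valid correlation structure). In the flagged
    conditions the target-ROI neighbourhood receives an extra shared
    factor of variance ``beta * (6 - cutoff)``, raising mutual
    correlations — and thereby Onnela clustering at the target ROIs —
    with degradation strength. Reproducible: the master seed spawns one
    independent substream per matrix.
    """
    params.validate()
    modules = params.modules()
    labels = [f"ROI{i + 1:03d}" for i in range(params.n_roi)]
    cells = design.cells()
    ss = np.random.SeedSequence(params.seed)
    study_stream = np.random.default_rng(ss.spawn(1)[0])
    base_loadings = _base_loadings(params, study_stream)
    offsets = {
        p: study_stream.normal(0.0, params.participant_sd)
        for p in design.participants
    }
    effect_set = set(params.effect_conditions)
    matrices = []
    cell_seeds = ss.spawn(len(cells))
    for (participant, attention, degradation, cutoff), child in zip(cells, cell_seeds):
        rng = np.random.default_rng(child)
        b2 = 0.0
        if (attention, degradation) in effect_set and params.clustering_slope != 0.0:
            b2 = params.clustering_slope * (6 - cutoff)
        series = _simulate_cell_series(
            params, modules, base_loadings, offsets[participant], b2, rng
        )
        matrices.append(
            timeseries_to_connectivity(
                series,
                participant=participant,
                attention=attention,
                degradation=degradation,
                cutoff=cutoff,
                labels=labels,
            )
        )
    return matrices


def planted_two_module_graph(
    n_nodes: int = 30,
    within_mean: float = 0.6,
    between_mean: float = 0.2,
    noise_sd: float = 0.08,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete weighted graph with two planted modules (3:1 weight contrast).

    Returns the weight matrix and the ground-truth assignment (labels 1
    and 2). Used as the canonical recovery benchmark for community
    detection: within-module weights average three times the
    between-module weights by default.
    """
    rng = np.random.default_rng(seed)
    half = n_nodes // 2
    truth = np.array([1] * half + [2] * (n_nodes - half))
    same = truth[:, None] == truth[None, :]
    mean = np.where(same, within_mean, between_mean)
    w = mean + rng.normal(0.0, noise_sd, size=(n_nodes, n_nodes))
    w = np.clip((w + w.T) / 2.0, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w, truth
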