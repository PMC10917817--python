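# Methods

`fcgraph` implements a graph-theoretical analysis of condition-wise
fMRI functional connectivity for a 2 (attention: melody/sentence) × 2
(degradation: spectral/temporal) × 5 (degradation cutoff, 1 = strongest)
within-subject design with 15 participants — 300 condition-level
ROI×ROI matrices — together with the behavioural normalized-score
analysis of the accompanying same–different experiment. Because the
human data are not redistributable, the package ships a synthetic-data
generator with known (planted) ground truth; every downstream stage is
validated by parameter recovery against that truth and by brute-force
oracles on tiny graphs.

## Network construction

Condition-level matrices hold Fisher-z transformed Pearson correlations
(`arctanh r`) between ROI time series, symmetric with zero diagonal.
Before any graph measure:

1. **Negative weights are set to zero.** Path- and triangle-based
   measures are not interpretable on signed weights.
2. **Proportional thresholding** retains the strongest
   `⌈p·n(n−1)/2⌉` off-diagonal edges at densities
   p ∈ {0.1, 0.2, 0.3, 0.4, 0.5}, weights kept (never binarized).
   Density is counted over all possible node pairs, zeros included in
   the denominator. Ties at the cut are broken by (weight descending,
   row index, column index), making graphs bit-reproducible. Edge sets
   are nested across densities by construction.

## Graph measures

- **Clustering (Onnela form).** Weights are scaled by the graph maximum,
  ŵ = w/max(w); then C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)),
  with C_i = 0 for degree < 2. On binary graphs this reduces to the
  classic triangle fraction. Global clustering is the mean over all
  nodes; isolated nodes stay in the mean so the denominator is fixed at
  n across densities.
- **Efficiency.** Shortest paths use edge lengths 1/w (Dijkstra);
  E_glob is the mean inverse distance over node pairs with 1/∞ = 0, and
  local efficiency of node i is E_glob of the subgraph induced by its
  neighbours. Disconnection is a valid state, not an error.
- **AUC integration.** Each metric measured at the five densities is
  summarized by the trapezoidal area under the metric-versus-density
  curve, giving one integrated value per node (or graph) per matrix.
  A metric bounded by 1 therefore has AUC bounded by 0.4 (the density
  span).

## Null models

Surrogates preserve the degree sequence and weight multiset exactly and
approximate the strength sequence: topology is randomized by
degree-preserving double-edge swaps (default 10 passes over the edge
list), then the original weights are re-assigned in descending order,
each onto the remaining edge with the largest residual-strength product
(residuals decremented as weights are placed). On 20-node random graphs
the mean relative strength error is ~2%. Defaults: 100 surrogates per
graph. Metrics are normalized by the null mean (ratio convention;
z-score available). Since inputs are negative-zeroed, the sign-aware
variant of this null model coincides with the positive-weight case.

## Modularity

Louvain maximizes weighted Newman–Girvan modularity
Q = Σ_c [e_c/m − γ(d_c/2m)²] at resolution γ = 1.0 by default; the
returned Q is always recomputed from this definition, never trusted
from the optimizer. Per matrix, Louvain runs repeatedly (default 1000
repetitions, each with an independent seed substream) on each of the
five thresholded graphs; the pooled co-classification (agreement)
matrix feeds consensus clustering: entries below τ = 0.5 are zeroed,
Louvain is run on the thresholded agreement matrix, and the loop
repeats until all runs agree (cap 50 rounds; non-convergence is
reported on the result, never silent). Group-level consensus per
condition is the consensus over participant-level consensus partitions.
Per-node within-module strength z (hub index) is
(κ_i − mean_module κ)/sd_module κ, 0 for zero-variance or singleton
modules. τ and the equal pooling of partitions across densities are
choices the upstream method leaves open; both are configurable.

## Mixed-model inference

The response is one AUC-integrated metric value per participant ×
attention × degradation × cutoff (× ROI for nodal metrics). The full
model has the factorial attention × degradation × cutoff fixed effects;
the null model is intercept-only with the identical random structure.
All LRT-compared fits use maximum likelihood (REML is invalid for
comparing fixed effects), and all fixed-effect inference goes through
χ² likelihood-ratio tests; F-tests with approximated (Satterthwaite
style) denominator degrees of freedom are deliberately not offered —
they are estimator-specific approximations, and the χ² route is the
exact analogue of comparing nested ML fits. Cutoff enters numerically (1..5, one slope;
the interaction deletion then has 1 df) or as a 5-level factor (the
full–null comparison then has 19 df at study scale and the three-way
interaction 4 df); both codings are supported and recorded.

Random structure: per-participant intercept by default, with
`uncorrelated_slopes` (diagonal covariance) and `slopes` (unstructured)
available. Slope structures that fail or go singular fall back down the
ladder and the structure actually used is recorded. The intercept
default for the per-ROI pipeline is the correctly specified model for
the synthetic generator (whose participant effect is a pure intercept
shift) and keeps 128 fits per dataset fast.

Numerics: metric AUCs have variances around 1e-3, which makes the
mixed-model optimizer's Hessian nearly singular; the fitter therefore
standardizes the response internally, corrects the log-likelihood by
the Jacobian term (−n log s, which cancels in every LRT) and transforms
estimates back. Optimizers are tried in the order bfgs → powell → cg.

Pipeline per ROI: full–null LRT → Benjamini–Hochberg FDR across ROIs at
q = 0.05 → on survivors, marginality-respecting single-term deletion of
the three-way interaction and post-hoc per-condition cutoff-slope
models (response ~ cutoff with participant random intercept, one model
per MS/MT/SS/ST condition) with their own BH correction across all
ROI × condition tests. Per-ROI failures are flagged and skipped, never
fatal. Diagnostics: generalized VIFs (Fox–Monette determinant form) on
the interaction-free fixed design, leave-one-participant-out stability
ranges of fixed estimates, percentile parametric bootstrap CIs
(default 1000 draws), and Nakagawa–Schielzeth R²m/R²c with the
random-effect variance computed as the mean of z′Gz over observations
(exact under random slopes).

## Behavioural analysis

Responses on the 6-point scale collapse to same/different (first three
→ same). Per participant × task × degradation × cutoff cell, the raw
score is the proportion correct and the normalized score is
(raw − chance)/(baseline − chance) − 1 with chance = 0.5 and the
baseline taken per participant × task from the non-degraded block: 0 at
baseline performance, −1 at chance. Cell proportions are the
integration rule because they yield exactly one value per cell — 300
observations at study scale, matching the model's residual degrees of
freedom; a within-cell linear-trend alternative was considered and
rejected for that reason. The interaction model is OLS with
cutoff (5-level factor) × task × degradation (20 coefficients),
F-compared against the main-effects-only reduction: (13, 280) df at
study scale. Power for the omnibus F-test uses the noncentral F with
f² = R²/(1−R²) and λ = f²(u+v+1); at R² = 0.1533, u = 19, n = 300,
α = 0.05 the power is 0.999.

## Synthetic-data generator

Connectivity is simulated through latent factor time series (default
400 timepoints), so every matrix is a valid correlation structure by
construction. Nodes split into 4 contiguous modules and load on their
module factor; module factors share a global factor so that mean
within- and between-module correlations hit the targets (defaults 0.42
and 0.10). Per-participant loading offsets (SD 0.05, shared across that
participant's 20 conditions) create random intercepts in every derived
metric. The desk-scale default is 64 ROIs; a 358-ROI preset matches the
study-scale multimodal cortical parcellation.

The planted effect: a target set (5 ROIs) and its designated
neighbourhood (11 further ROIs, completing the first module) co-load on
an extra shared factor with variance b0 + β(6 − cutoff) in the two
"crucial" conditions (sentence×temporal and melody×spectral) and b0
elsewhere, with b0 = 0.30 and β = 0.025. Mutual correlations among the
planted nodes — and hence Onnela clustering at the target ROIs — thus
rise with degradation strength in the flagged conditions only, with a
negative clustering-versus-cutoff slope as ground truth.

Two design features exist specifically to keep the planted effect from
leaking into unrelated ROIs through the measurement chain itself:

- **Anchor edge.** Onnela clustering divides by the per-matrix maximum
  weight; if planted edges reached the maximum, the scaling constant
  would track the condition and every ROI would inherit an artefactual
  effect. Two fixed high-loading nodes (loading 0.93, like near-ceiling
  homotopic connections in real connectomes) provide a stable maximum
  in every matrix. Heterogeneous node loadings (uniform ±0.22 around
  √within) fill in a realistic hub-weighted upper tail below it.
- **Baseline neighbourhood factor.** b0 keeps the planted edges above
  the 10%-density retention threshold at every cutoff, so the effect
  modulates edge *weights* rather than edge *membership* and does not
  crowd other ROIs' edges out of the thresholded graphs.

These parameters were fixed by calibrating against those two artefacts
and then frozen. What the generator does **not** emulate: BOLD
autocorrelation and haemodynamics, scanner/motion artefacts, spatial
embedding (distance-dependent connectivity), heavy-tailed or negatively
skewed weight distributions, and condition effects on efficiency or
modularity (only clustering carries planted structure). Passing
recovery tests therefore demonstrates that the pipeline detects the
planted kind of effect at realistic noise levels — not that every
artefact of real fMRI is survived.

The behavioural generator reproduces the trial bookkeeping exactly
(4 × 50 degraded trials with each degradation × cutoff cell occurring
20 times, a 40-trial non-degraded baseline block, a 110-block fMRI
schedule of 2 runs × [50 stimulation + 4 silence + 1 noise]) and draws
correctness Bernoulli from a psychometric profile in which accuracy
declines linearly from 0.9 to 0.55 across degradation strength only
when the degraded dimension is task-crucial.

## Problem sizes used in the shipped checks

Recovery and error-control simulations run at 64 ROIs, 15 participants,
50 seeds (tests) or 8 seeds (acceptance script); oracle equivalence
uses all random graphs of ≤ 6 nodes over 200 seeds; consensus recovery
uses 30-node two-module graphs with 20 Louvain repetitions per seed.
These sizes make the full suite reproducible on a laptop while keeping
every statistical assertion at conventional Monte-Carlo precision.

## Known limitations

- The strength sequence of null-model surrogates is approximated, not
  preserved exactly (≈2% mean relative error at desk scale); this is
  inherent to swap-based randomization with weight reassignment.
- Full unstructured random-slopes fits with the 20-coefficient
  categorical fixed design are almost always singular with 15
  participants (as mixed-model folklore predicts); the fallback ladder
  makes this explicit rather than hiding it.
- Empirical FDR in planted-recovery simulations is evaluated against
  the planted neighbourhood (targets ∪ neighbours): the neighbourhood
  genuinely carries the effect, so flagging it is a true positive even
  though only the 5 targets are scored for power.
- χ² reference distributions for LRTs are asymptotic; with 15
  participants they are mildly approximate (the shipped null
  simulations measure the realized type-I rate at ≈0.04–0.05).
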