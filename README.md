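# fcgraph

Graph-theoretical analysis of condition-wise fMRI functional
connectivity, built for within-subject auditory attention studies of
degraded sung speech: 15 participants × 2 attended dimensions
(melody/sentence) × 2 acoustic degradations (spectral/temporal) × 5
degradation cutoffs → 300 ROI×ROI Fisher-z connectivity matrices.

The package is for researchers who want the full analysis chain as
tested, scriptable Python:

- **Network construction** — negative-weight zeroing and proportional
  thresholding (strongest 10–50% of edges, weights retained) of Fisher-z
  correlation matrices.
- **Weighted graph measures** — Onnela clustering coefficient
  C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3}/(k_i(k_i−1)) with max-weight
  scaling, global/local efficiency over 1/w shortest paths, and
  area-under-the-curve integration across thresholds.
- **Null models** — degree/strength-preserving surrogates (double-edge
  swaps + strength-ranked weight reassignment) for metric
  normalization.
- **Modularity** — repeated Louvain (resolution γ), agreement-matrix
  consensus clustering, modularity Q, within-module degree z.
- **Inference** — per-ROI Gaussian mixed models (attention ×
  degradation × cutoff fixed effects, participant random effects), ML
  likelihood-ratio tests, Benjamini–Hochberg FDR across ROIs, post-hoc
  per-condition cutoff slopes, VIF/stability/bootstrap diagnostics and
  Nakagawa–Schielzeth R²m/R²c.
- **Behavioural analysis** — normalized scores
  (raw − chance)/(baseline − chance) − 1, the cutoff × task ×
  degradation interaction model, and noncentral-F power analysis.
- **Synthetic data** — a latent-factor generator that reproduces the
  full study design with a planted, condition-dependent clustering
  effect, so every stage has a parameter-recovery test surface.

## Worked example

Simulate a study, compute clustering AUCs, and run the per-ROI
mixed-model pipeline:

```python
from fcgraph import synthetic as syn
from fcgraph.pipeline import compute_metric_table, MetricConfig
from fcgraph.inference import per_roi_pipeline, InferenceConfig, inference_summary

design = syn.generate_design(15)                      # 300 cells
params = syn.GeneratorParams(n_roi=64, seed=1)        # targets = ROIs 0..4
matrices = syn.generate_connectivity_dataset(design, params)
table = compute_metric_table(matrices, MetricConfig(metrics=("clustering",)))
results = per_roi_pipeline(table[table.roi >= 0], InferenceConfig())
summary = inference_summary(results)
print(summary[summary.significant][["roi", "chi2", "df", "p_fdr", "slope"]].head())
```

```
   roi        chi2  df         p_fdr     slope
0    0  192.054025   7  3.531186e-36 -0.013183
1    1  157.791437   7  5.985019e-30 -0.010743
2    2  141.423018   7  1.169469e-26 -0.011069
3    3  160.443804   7  1.839665e-30 -0.012683
4    4  140.724568   7  1.528950e-26 -0.010761
```

The five planted target ROIs are recovered with strongly negative
cutoff slopes: local clustering falls as the degradation weakens
(cutoff 1 → 5), i.e. rises with degradation strength, exactly as
planted. The same pipeline is available from the shell:

```bash
fcgraph simulate --participants 15 --n-roi 64 --seed 1 --out out/matrices
fcgraph metrics  --matrices out/matrices --out out/metric_table.tsv
fcgraph infer    --metric-table out/metric_table.tsv --out out/roi_inference.tsv
fcgraph behavior --participants 15 --seed 1 --out out/behavior
```

Behavioural power for the study's omnibus test:

```python
from fcgraph import power_f2, PowerSpec
power_f2(PowerSpec(r_squared=0.1533, u=19, n=300, alpha=0.05))  # 0.9991
```

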