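# omicsurv

Multi-omics survival analysis toolkit: univariate Cox (Wald) feature
screening, denoising-autoencoder data integration (early and late),
elastic-net Cox survival modeling with cross-validated penalty selection,
Harrell C-index evaluation, and K-means survival-subtype discovery with
differential expression/methylation — plus a synthetic multi-omics cohort
generator with planted ground truth so every stage is testable offline.

## Layout

| module | purpose |
|---|---|
| `omicsurv.simulate` | synthetic cohorts: latent-factor omics, NB counts, logit-normal methylation betas, Weibull PH survival with tuned censoring, planted subtypes |
| `omicsurv.preprocess` | missingness/follow-up filters, train-fitted median imputation + z-scoring, 3-step methylation probe pipeline, beta→M transform, clinical encoding |
| `omicsurv.feature_selection` | per-feature univariate Cox Wald tests (vectorized Newton on the Breslow partial likelihood), per-modality top-k caps (500/500/300/300) |
| `omicsurv.autoencoder` | basic / denoising-zeros / denoising-Gaussian autoencoders (numpy, Adam, MSE, early stopping), hyperparameter grid |
| `omicsurv.survival` | elastic-net Cox (FISTA proximal gradient, lambda path, CV by C-index), O(n²) and O(n log n) Harrell C-index |
| `omicsurv.pipeline` | stratified 80/20 resplits, 5-run protocol, modality-combination sweeps, early vs. late integration, PCA/LFS-only/AE-only baselines, Welch t-test comparisons |
| `omicsurv.subtypes` | K-means on elastic-net-retained features, silhouette K selection (2–10), Kaplan–Meier + log-rank, NB-Wald differential expression, ANOVA on gene-level M-values |

## CLI

A single YAML file drives everything:

```yaml
simulation:
  n_patients: 400
  features_per_modality: {mrna: 1000, mirna: 300, lncrna: 500, methylation: 1500}
  subtype_shift: 1.0
  seed: 7
experiment:
  modalities: [mrna, mirna, lncrna, methylation, clinical]
  integration: early         # or late
  dr_method: lfs_ae          # or pca | lfs_only | ae_only
  n_runs: 5
  k_caps: {mrna: 150, methylation: 150, mirna: 90, lncrna: 90}
  ae_overrides: {max_epochs: 20}
subtypes:
  n_restarts: 25
```

```bash
omicsurv simulate   --config cfg.yaml --out data/        # TSVs + ground truth
omicsurv preprocess --data data/ --out prep/             # scaled matrices + scaler JSON
omicsurv run        --data data/ --config cfg.yaml --out report.json
omicsurv sweep      --data data/ --config cfg.yaml --out sweep.tsv
omicsurv compare    report_a.json report_b.json
omicsurv subtype    --data data/ --config cfg.yaml --out subtypes/
```

All randomness flows from explicit seeds; identical config + seeds
reproduce every number bit-for-bit.
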