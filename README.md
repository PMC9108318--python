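# baycomm

Community-assembly analysis of presence/absence eDNA metabarcoding data
across two water layers and two seasons.

## The scientific problem

Seasonal bottom-water hypoxia is one of the sharpest environmental
gradients a coastal fish community experiences: in summer, stratification
drives bottom dissolved oxygen (DO) below the conventional 2 mg/L
threshold while surface water stays oxygenated. The species-sorting view
of metacommunities predicts that such heterogeneity should make surface
and bottom communities *more* different — only tolerant species persist
below the oxycline. The competing mass-effect view predicts the opposite:
when conditions get severe enough, mobile organisms flee the bottom
regardless of their identity, mixing composition across layers.

Distinguishing these regimes from monthly presence/absence surveys
requires separating genuine assembly signal from the sampling effects of
richness (alpha) and species-pool size (gamma). `baycomm` implements the
complete statistical workflow:

- **Season classification** — a month is *hypoxia* iff its minimum DO over
  all samples is strictly below a threshold (default 2 mg/L).
- **Beta diversity** — pairwise Jaccard dissimilarity
  d(a, b) = 1 − |a∩b| / |a∪b| on the binary community matrix, ordinated by
  nonmetric multidimensional scaling (NMDS) minimizing Kruskal's stress-1
  via isotonic regression and the Guttman transform.
- **PERMANOVA with interactions** — sequential (Type I) partitioning of
  tr(G), G = −½·C·D∘D·C, over crossed factors, covariates and interaction
  terms, with free-permutation p-values. One-way tools cannot fit the
  season × layer interaction this question needs.
- **Fixed-fixed null model** — per-month checkerboard-swap randomization
  preserving every sample's richness and every species' occurrence total;
  each same-month pair's observed Jaccard value is located as a mid-rank
  quantile in its 999-draw null distribution, and the hypoxia vs normoxia
  quantiles are compared by a Wilcoxon rank-sum test. Quantiles below 0.5
  mean pairs are *more similar* than sampling effects explain.
- **Hierarchical occupancy models** — Laplace-approximation GLMMs:
  Poisson (log link) species richness with a site random intercept, and
  Bernoulli (logit link) species occurrence

  logit p<sub>i,s</sub> = β₀,ᵢ + β₁,ᵢ·Season<sub>s</sub> + β₂,ᵢ·Layer<sub>s</sub> + β₃,ᵢ·Season<sub>s</sub>·Layer<sub>s</sub>

  (hypoxia = 0 / normoxia = 1, surface = 0 / bottom = 1) with
  species-level random intercept and slopes, plus a likelihood-ratio test
  for whether the season × layer response is species-specific.
- **Synthetic metacommunity generator** — study-shaped datasets
  (14 sites × 12 months × 2 layers, ~170 species, summer bottom-DO
  collapse) under switchable assembly scenarios (`neutral_avoidance`,
  `sorting`, `null`), so the entire pipeline is testable without any
  download.

## Worked example

```python
from baycomm import (SimulationConfig, simulate_dataset, build_community_matrix,
                     classify_seasons, NullModelConfig, pairwise_null_quantiles,
                     compare_quantiles_by_season)

ds = simulate_dataset(SimulationConfig(scenario="neutral_avoidance", seed=1))
matrix = build_community_matrix(ds.detection, ds.metadata)
seasons = classify_seasons(ds.environment, ds.metadata)   # threshold 2 mg/L
print(seasons.hypoxia_months)

res = pairwise_null_quantiles(matrix, seasons, NullModelConfig(n_null=999, seed=2))
cmp_ = compare_quantiles_by_season(res, seasons)
print(f"{cmp_.n_pairs_hypoxia} hypoxia pairs, mean quantile "
      f"{cmp_.quantiles_hypoxia.mean():.3f}")
print(f"{cmp_.n_pairs_normoxia} normoxia pairs, mean quantile "
      f"{cmp_.quantiles_normoxia.mean():.3f}")
print(f"rank-sum p = {cmp_.p_value:.2e}")
```

prints

```
[6, 7, 8, 9]
1512 hypoxia pairs, mean quantile 0.502
3024 normoxia pairs, mean quantile 0.540
rank-sum p = 2.89e-05
```

The four summer months are classified hypoxic from the simulated DO
collapse. Under the mass-effect scenario the hypoxia-season pairs sit
near the null expectation (≈0.5 — composition as mixed as sampling
effects predict) while normoxia pairs sit above it (habitat segregation
makes communities more dissimilar than chance); the rank-sum test
detects the seasonal drop. The full workflow — ordination, PERMANOVAs,
richness and occurrence GLMMs, report files — runs from one config:

```bash
baycomm run --config config.yaml --out results/
baycomm simulate --scenario sorting --seed 7 --out data/
```

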