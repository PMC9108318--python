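# Methods

This note documents the statistical models implemented in `baycomm`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the package's known limitations.

## Season classification

A month is labelled *hypoxia* when the minimum dissolved oxygen over all
of that month's samples — both layers, all sites — is strictly below the
threshold (default 2.0 mg/L, the conventional coastal hypoxia level).
The comparison is strict (`<`), so a monthly minimum exactly at the
threshold is normoxic. All samples of a labelled month share the label,
including oxygenated surface samples: treating each month as one unit is
what lets within-month compositional variation be attributed to the
contemporaneous environmental contrast rather than to seasonal turnover.

## Environmental PCA

The three environmental variables (DO in mg/L, temperature in °C,
salinity in PSU) carry incommensurable units, so the default is
correlation-matrix PCA (center and scale each variable before the
eigendecomposition); `standardize=False` switches to covariance-matrix
PCA. Component signs are fixed by requiring each component's
largest-magnitude loading to be positive — an arbitrary but deterministic
convention needed for reproducible plots and reports.

## Dissimilarity and NMDS

Jaccard dissimilarity on presence/absence, d = 1 − |a∩b|/|a∪b|. A pair of
two empty samples has an undefined index; the default raises, and
`on_empty_union="zero"` defines d = 0 (the convention used inside the
null model, where row sums are fixed so the choice affects observed and
null draws identically and cancels from the quantile).

NMDS minimizes Kruskal stress-1,
`sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²)` over configurations, where `d_ij` are
configuration distances and `d̂_ij` the disparities from a monotone
(isotonic) regression of configuration distances on input
dissimilarities. Numerical scheme:

- isotonic step: pool-adjacent-violators over tie-block means; tied input
  dissimilarities (which Jaccard on sparse matrices produces in bulk) are
  averaged — stress values depend on this choice, so it is fixed rather
  than configurable;
- update step: Guttman transform; disparities are rescaled to the current
  configuration's total squared distance each iteration so the transform
  stays well-conditioned;
- initialization: classical (Torgerson) scaling for the first restart,
  classical scaling plus Gaussian jitter (SD = 25% of the coordinate SD)
  for the rest; default 20 restarts, best final stress wins;
- convergence: relative stress decrease below 1e-6 (default) within 500
  iterations; a non-converged run still returns its best configuration,
  flagged `converged=False`;
- scale convention: the returned configuration is centered and scaled so
  its total squared pairwise distance equals that of the input
  dissimilarities. Stress-1 is scale-invariant, but group-centroid
  distances are not, and without a convention they would be arbitrary.

Group separation in ordination space is summarized by the Euclidean
distance between per-group centroid coordinates over the first k axes.

## PERMANOVA

The distance matrix is Gower-centered, G = −½·C·(D∘D)·C with
C = I − 11ᵀ/n; tr(G) is the total sum of squares. Terms enter in the
user-given order and receive sequential (Type I) sums of squares
tr((H_j − H_{j−1})G), where H_j projects onto the column space of the
design matrix through term j. The design builder dummy-codes factors
(season: hypoxia = 0/normoxia = 1; layer: surface = 0/bottom = 1; other
factors drop-first in sorted level order) and centers continuous
covariates before interactions are formed, decorrelating main-effect and
interaction columns. Pseudo-F uses the full-model residual; p-values
come from free permutation of sample labels,
p = (1 + #{F* ≥ F}) / (1 + n_perm). Rank bookkeeping raises a named
error when a term is aliased with earlier ones. Restricted permutation
(strata), marginal (Type II/III) tests and dispersion diagnostics are
out of scope.

The implementation agrees with `vegan::adonis2(..., by="terms")` to
numerical precision and collapses to the classical one-way ANOVA F in
the univariate Euclidean case (both are test oracles).

## Fixed-fixed null model

Within each month's sample × species submatrix, trial swaps pick two
random rows and two random columns and flip the 2×2 submatrix iff it is
a checkerboard — preserving every row and column sum exactly. One
sequential chain per month is burned in for 10× the number of presences
and thinned at 1× the number of presences between the 999 recorded
draws; months with fewer than 3 samples are skipped. Chain mechanics
(one thinned chain vs independent restarts) are not dictated by the
pair-count bookkeeping, so the cheaper thinned chain is used.

For every unordered same-month pair, the observed Jaccard value is
placed in its null distribution as a mid-rank quantile,
(#{null < obs} + ½·#{null = obs}) / n_null — the mid-rank handles the
heavy ties of Jaccard on small binary matrices. The 10–90% band uses
`numpy` linear-interpolation quantiles of the null draws; note that with
discrete null distributions the inclusive band absorbs the atoms at its
endpoints, so its empirical coverage under the null runs above the
nominal 80% (the calibrated guarantees are the one-sided exceedances,
each ≤ 10%). Pairs sharing a sample are not independent; the rank-sum
comparison between seasons ignores this dependence by design, replicating
the analysis convention rather than correcting it — its p-values are
therefore anticonservative in absolute terms and are best read
comparatively across scenarios.

The season comparison uses the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 12 values and no cross-group ties,
otherwise the tie-corrected normal approximation with continuity
correction.

## Hierarchical occupancy models

Both families (Poisson log-link richness, Bernoulli logit-link
occurrence) are fitted by maximizing the Laplace-approximated marginal
likelihood: for each group (site or species) the joint log-density is
maximized over the group's random effects by damped Newton iterations
(batched over groups when group sizes are equal), and the random-effect
integral is replaced by the Gaussian integral at the mode. Fixed effects
and log-SD variance parameters are then optimized by L-BFGS-B, started
from the pooled (no random effect) IRLS fit and log σ = log 0.5; log-SDs
are bounded in [−6, 4], and a fit at the lower bound is reported as a
boundary fit, not an error. Wald standard errors come from the observed
information (finite-difference Hessian of the marginal log-likelihood);
p-values are two-sided normal. Random effects are independent normals by
default (`independent_random_effects=False` estimates a full Cholesky
covariance). The Laplace approximation can deviate from adaptive
quadrature for very small groups; against `glmmTMB` (also Laplace) the
implementation agrees to ~1e-3 in coefficients, SEs, random-effect SDs
and log-likelihood on shared data.

The likelihood-ratio test between the full model (random intercept and
all three random slopes) and the reduced model (no random interaction
slope) reports χ² = max(0, 2Δll) with df = parameter-count difference
(one variance component, df = 1). Testing a variance at zero puts the
null on the boundary of the parameter space, so the χ² reference is
conservative; this convention is kept because it is the standard
reporting style for such comparisons.

## Synthetic metacommunity generator

The generator produces the three input tables (detections, metadata,
environment) for a study-shaped campaign: 14 sites with log-spaced depths
6–70 m, 12 monthly visits, surface + bottom samples, a 170-species pool.

**Environment.** Deterministic seasonal curves plus Gaussian noise:
surface DO ~ 7.5 ± 0.8 mg/L; bottom DO drops to 1.2 ± 0.4 mg/L in the
trough months (June–September; the configured trough guarantees monthly
minima below 2 mg/L, so the season classifier recovers the trough months
exactly); temperature follows a sinusoid peaking in August with strong
bottom cooling during stratification; salinity a weak inverse sinusoid.
Truncation at zero for DO and salinity.

**Occupancy.** Species i in sample s is occupied with probability
expit(η) where

η = β₀ᵢ + β₁ᵢ·Season + β₂ᵢ·Layer + β₃ᵢ·Season·Layer + aLᵢ·hL·pLᵢ + aSᵢ·hS·pSᵢ

in the normoxia = 1 / bottom = 1 coding, and detection thins occupancy at
0.85. Baseline logits β₀ᵢ are a two-component commonness mixture: a
generalist head (12% of the pool, logit −0.3 ± 0.4 — the handful of
ubiquitous small pelagics every sample detects) and a rare tail
(−5.4 ± 1.8). Effect coefficients are normal across species with means
(layer 0.25, season −0.4, interaction 0.65) and SDs (0.70, 0.68, and a
scenario-dependent interaction SD) matching the magnitudes this kind of
occupancy analysis reports for coastal fish. The last two terms are
habitat-fidelity affinities: each species has a preferred layer and a
preferred site group (shallow vs deep half), with magnitudes
|N(0, 4.0)| gated to zero for common species (gate
expit(−1.5·(β₀ + 3))) and capped so that no specialist's boosted logit
exceeds 0 — specialists can dominate their preferred habitat but never
outrank the generalist head in overall frequency, keeping the top-10%
species set (the occurrence-GLMM stratum) effectively affinity-free.

**Scenarios.**

- `neutral_avoidance` (mass effect): interaction mean +0.65 with modest
  SD 0.573, and during hypoxic months every affinity's habitat sign is
  re-drawn uniformly per cell (`hypoxia_mixing=1`): displacement
  unrelated to preference. The symmetric re-draw preserves each species'
  expected occupancy in every layer and season — richness patterns are
  governed purely by the regression part — while dissolving the habitat
  segregation that the fixed-fixed null detects.
- `sorting`: interaction coefficients mean 0, SD 1.5 (mixed signs:
  species-specific seasonal responses) and habitat fidelity expressed
  year-round.
- `null`: every effect, affinity and mixing set to zero.

**Why segregation, not coefficients, carries the null-model signal.**
The per-month null preserves row and column sums, and the total pairwise
intersection count of a binary matrix is a function of the column sums
alone — so any deviation between observed and null dissimilarities is
zero-sum across a month's pairs. Marginal coefficient differences between
seasons therefore cannot move the pooled quantile mean; what can is
consistent habitat structure, which segregates the matrix (most pairs
more dissimilar than the fixed-marginal shuffle) when expressed and
collapses to null-like mixing when scrambled. This is precisely the
species-sorting vs mass-effect contrast the analysis is designed to
detect.

**What the generator does not emulate.** eDNA transport, degradation and
vertical mixing (detection is plain Bernoulli thinning); read counts,
PCR/sequencing error and taxonomic misassignment (filter lists are
inputs, applied to names); missing field samples (the synthetic design is
complete; the October n = 2 month of the emulated campaign is exercised
through fixtures, and months below the 3-sample minimum are excluded from
distance-based stages in any case); spatial autocorrelation beyond the
two-level site grouping; temporal autocorrelation between months.
Per-sample richness in the default configuration (≈ 20) sits above a
typical sparse field survey (≈ 8–10): the desk-scale calibration and
discrimination checks need the extra pairwise resolution, and the
analysis pipeline itself is richness-agnostic. An avoidance-as-mortality
variant (bottom loss without surface gain) can be emulated by setting a
negative season effect with `hypoxia_mixing=0`.

## Pipeline conventions

- Sub-seeds per stage are derived by hashing the master seed with the
  stage name, so adding a stage never shifts another stage's stream;
  reports are byte-identical under a fixed config + seed.
- Months with fewer than `min_samples_per_month` (default 3) samples are
  excluded from ordination, PERMANOVA and null-model stages; richness
  summaries and season classification use all samples.
- Richness cell summaries use the sample SD (n − 1); single-sample cells
  report a missing SD.
- Top-fraction species selection takes the ceiling (0.10 × 168 → 17),
  with ties broken lexicographically by species name.
- Species filters apply the unmatched-name list before the
  habitat-exclusion list; a name on both lists is counted under the
  first.
- The pipeline operates on the samples that have complete metadata and
  environmental records; detections from other samples are dropped at
  ingest.

## Known limitations

- PERMANOVA offers free permutation only; designs needing restricted
  permutation (repeated measures on sites across months) are outside the
  contract and their p-values should be read accordingly.
- The GLMM optimizer uses numerical derivatives; pathological designs
  (quasi-separation in a small species set) can end at the variance
  boundary, which is reported but not remedied.
- NMDS stress for a given dataset depends on the tie-handling and restart
  conventions above; comparisons with other software should compare
  configurations, not raw stress values.
- The null model's pair quantiles are dependent across pairs sharing a
  sample; season comparisons inherit that dependence.
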