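# Methods

## Scoring model

Every framework variable is a deterministic, additive composite of ordinal
trait encodings:

| variable | formula | range |
|---|---|---|
| concealability | trappable(0/1) + size(small 3, medium 2, large 1) | 1–4 |
| abundance (default) | trend(decr 1, stable 2, incr 3) + threat abundance rank(LC 5 … CR 1) | 2–8 |
| abundance (`medan_compat`) | threat abundance rank alone | 1–5 |
| habitat access | Σ access score over major-importance habitat classes (wetland 1, forest 2, shrub/grass 3, anthropogenic 4) | 1–10 |
| focal island | indicator of natural presence on the market's island | 0–1 |
| removability | locomotion(1–3) + diel(1–2) + group-living(0/1) | 2–6 |
| teeth removal | indicator | 0–1 |
| replaceability | number of markets where found | 0–N |
| success in captivity | diet flexibility(1–3) + no-teeth-removal(0/1) | 1–4 |
| multiple uses | indicator of >1 distinct use | 0–1 |
| enjoyability | size(1–3, small high) + traded age group(1–3) | 2–6 |
| economic value | mean price | ≥0 |
| ecological value | indicator | 0–1 |
| conservation value | threat rarity rank(LC 1 … CR 5) + endemism(0/1) | 1–6 |
| symbolic value | indicator | 0–1 |

Abundance is dual-mode because the bundled worked example's printed
abundance column equals the threat rank alone; the trend term evidently was
not applied there. The default stays faithful to the declared composite
(`composite`); `medan_compat` is used for fixture reproduction and is
documented wherever it appears. Body-size intervals are closed at the upper
edge (small = [0.03, 5.0] kg, medium = (5.0, 10.0], large > 10.0) so every
mass is classifiable.

Missing inputs (no price, no per-market spread, no trend in `composite` mode,
no traded-age data) produce missing score markers with recorded reasons;
matrix assembly drops any variable missing for any species and logs it.
Nothing is imputed — this mirrors how incomplete survey variables are
handled in practice. Matrix columns follow the worked example's
left-to-right variable order, then extras alphabetically, so loadings are
reproducibly ordered.

## Bundled worked example

The fixture covers the 10 primate species recorded in urban wildlife
markets of Medan, North Sumatra over 1997–2008 (66 surveys, 3 markets,
1953 individuals). The published source provides the per-species *scores*
and counts; the underlying raw trait table shipped here was reconstructed:
trait values (masses, quota status, habitat sets, guilds, endemism, uses,
age groups) were chosen to be biologically accurate for each species and to
reproduce every published score cell exactly under the scoring rules. The
four species encoded as legally trappable (both macaques, the silvered leaf
monkey, the Sumatran leaf monkey) are the assignment implied by the
concealability column together with the report that harvest quotas existed
for four species. Red List statuses at the time of study are used for all
scores; 2022 statuses are carried for context only. Population trend is set
to decreasing for all ten species (consistent with regional assessments);
it does not enter `medan_compat` scores.

## Analysis conventions

- Standardization: column z-scores with sample SD (n−1). Zero-variance
  columns raise an error naming the column.
- PCA: thin SVD of the standardized (correlation mode, default) or merely
  centered (covariance mode) matrix. Correlation mode is the default
  because the variables sit on heterogeneous ordinal scales (0–1 up to
  1–10); it is also the mode that reproduces the worked example's
  statistics. Eigenvalue_k equals the sample variance of score column k;
  scores are raw projections (variance = eigenvalue), not unit-scaled.
- Sign convention: within each loading column the largest-magnitude entry
  is made positive (ties broken by lowest variable index), then every
  component is flipped, if needed, to correlate non-negatively with the
  counts. All reported acceptance statistics (R², F, residual SE,
  intercept, |t|) are invariant to score scaling and sign; raw coefficients
  are reported but depend on the score-scaling convention.
- Regression: OLS (statsmodels) of counts on intercept + first k scores,
  k = 2 by default; two-sided p from t(n−k−1); overall F against
  intercept-only. Counts enter as a plain numeric response — no Poisson or
  negative-binomial model and no transformation — matching the linear-model
  statistics the framework's worked example reports. With n = 10 species
  this is a descriptive decomposition, not a causal model.
- Variable–component correlations are plain Pearson correlations of each
  standardized variable with each score column; under correlation-mode PCA
  they equal loading × √eigenvalue (property-tested for components with
  non-zero variance; the identity is vacuous for null components of a
  rank-deficient matrix).

## Synthetic data generator

`generate_traits` draws each categorical trait independently from a
configurable probability table (uniform over each enum by default,
Bernoulli(0.5) for booleans); body mass is drawn uniformly within the drawn
size class so mass and class always agree. `generate_counts` forms
y = max(0, round(α + Σ β_j z_j + ε)), ε ~ N(0, σ²), over the
column-standardized scores of the pool (a log-linear link is available for
realism experiments). Rounding + truncation, rather than a Poisson draw, is
used so the generative model matches the Gaussian-OLS analysis model.
Default weights load positively on abundance, habitat access,
concealability, multiple uses and ecological value and negatively on
conservation value — the sign structure a market-vulnerability axis is
expected to show — with α = 195 (the worked example's mean count) and
σ = 50.

With independently drawn traits, a weight vector on a few variables does
not lie in the span of the leading principal components, so R² of the
k-component regression does not approach 1 even without noise. The
`align_weights_to_pc1` option therefore places all signal on the pool's
first principal axis — the "single dominant latent-vulnerability axis"
scenario the analysis is designed for — making the noise-free R² → 1 limit
exact and intercept coverage nominal. Recovery experiments use n = 200
species, axis scale 250 and intercept 2000 (keeping the linear predictor
away from the truncation at zero and the rounding error negligible), with
σ = 40 for the "small noise" condition; these sizes were chosen as the
smallest at which truncation and rounding artifacts are irrelevant.

What the generator does *not* emulate: overdispersed/zero-inflated counts,
correlated trait draws (real ecological traits co-vary), multi-market
allocation, temporal dynamics, and observation error in the surveys.
Passing recovery tests therefore show the pipeline is internally
consistent, not that real market counts follow a linear-Gaussian model.

Randomness: one global seed spawns per-stage seed sequences (traits,
noise, replicates) via `numpy.random.SeedSequence`, so stages are
independently regenerable and every output is byte-reproducible.

## Known limitations

- n = 10 species in the worked example leaves 7 residual df for the
  two-component fit; p-values near the 0.05 boundary (PC2) should not be
  over-read.
- The framework's ordinal composites weight all constituent traits
  equally; no reweighting or scale calibration is attempted.
- Species are joined by exact scientific-name match; no synonym or
  taxonomy resolution is performed.
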