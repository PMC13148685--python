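# Methods

## Model and assumptions

The package operationalises a country's health-financing vulnerability to
external-aid shocks as a weighted composite of four ordinal "levels of
exposure": current health expenditure per capita (CHE, 4 levels), foreign
aid dependency (FAD, share of CHE from external sources, 5 levels),
budget space potential (BSP, the projected trajectory of real general
government expenditure, 3 levels) and capacity to borrow (CTB, the
inverse of IMF/World Bank debt-distress risk, 4 levels). Higher levels
always encode higher propensity to vulnerability. The composite for a
country with levels `x_j`, normalising denominators `d_j` and percentage
weights `W_j` is

    V = Σ_j x_j / d_j · W_j ,   Σ_j W_j = 100 ,

so V lives on a 0–100 scale. The implicit measurement assumption, made
explicit in the weighting stage, is that the ordinal indicators are
coarsened observations of latent continuous traits that are jointly
normal — the standard polychoric model.

## Exposure banding

Band boundaries are half-open, lower-inclusive on the risk-increasing
side. Published prose band definitions overlap at some edges and leave
gaps at others (e.g. aid-dependency bands quoted as "15–25%", "25–44%"
and "above 45%"); these are resolved deterministically to
[15, 25), [25, 45), ≥ 45, a choice consistent with every reference
country assignment. The CHE cut-points (55 / 85 / 180 US$) are fixed
dollar values — originally the 20/40/60th percentiles of the 2022
regional distribution — so results are reproducible on new data;
`che_cutpoints_from_percentiles` re-estimates them from a supplied
distribution when relative banding is wanted. Bands are configurable
from YAML (`BandConfig.from_file`).

The optional fifth factor, multidimensional poverty prevalence, has no
published banding rule; the package bands it by sample quintiles into
levels 1–5 and documents this as a non-reproducing extension.

## Recovering levels from published component scores

The bundled reference data carry each country's *weighted component
scores* at two decimals, not its raw levels. Since
`component = level / d · W`, the level is recovered as
`round(component / W · d)`; the recovered value must fall within the
propagated print tolerance (±0.005 · d / W) of an integer, otherwise the
cell is flagged as inconsistent rather than silently rounded. Round-trip
tests confirm all 47 × 4 reference cells invert exactly and re-score to
the printed values.

## Polychoric correlation

Pairwise latent correlations use the two-step (Olsson) estimator:
thresholds per variable are set from the marginal cumulative proportions,
`t_k = Φ⁻¹(P(X ≤ k))`, for *observed* categories only; the latent
correlation ρ then maximises the multinomial log-likelihood of the
observed contingency table under bivariate-normal rectangle
probabilities, thresholds held fixed. Choices that matter numerically:

- **Bivariate normal CDF**: evaluated by the single-integral
  (Drezner–Wesolowsky) identity with a fixed 24-node Gauss–Legendre rule,
  vectorised over the threshold grid; agreement with scipy's rectangle
  integrator is ~1e-12 for |ρ| ≤ 0.95 and ~1e-7 at |ρ| = 0.999, well
  inside the likelihood's resolution at these sample sizes.
- **Optimiser**: deterministic bounded scalar minimisation on
  (−0.999, 0.999), absolute tolerance 1e-6, no random starts; on the rare
  non-convergence the value from a 0.01-step grid scan is returned and
  flagged.
- **Cell floor**: rectangle probabilities are floored at 1e-12 so sparse
  tables (the reference dataset has 47 rows across up to 5 × 5 cells)
  cannot yield −∞ log-likelihoods.
- **Degenerate variables** (one observed category) are excluded from the
  matrix and reported, not imputed.
- **PSD repair**: pairwise assembly need not be positive semi-definite;
  if the matrix has a negative eigenvalue it is smoothed by clipping
  eigenvalues at 1e-6 and rescaling to unit diagonal, and the result is
  flagged `smoothed`.

Correctness is checked against an exhaustive grid-search oracle over the
same likelihood (agreement within 0.01 on every test pair) and by
parameter recovery on synthetic latent-Gaussian data (mean estimate over
100 seeds within 0.05 of the generating correlation at n = 2000; mean
bias below 0.03 over 200 replicates at n = 500).

## Weighting

- **Polychoric PCA** (primary): the first eigenvector `v₁` of the
  polychoric matrix, oriented so its first element is non-negative;
  weights are the squared loadings normalised to percent, which for a
  unit-norm eigenvector is simply `100 · v₁²`. The transform from
  loadings to the published weight vector is not fully determined by its
  source; squared loadings are the standard variance-contribution
  reading and reproduce the published vector only approximately (the
  acceptance suite reports the per-factor discrepancy — largest for the
  budget-space factor, whose near-zero PC1 loading contrasts with its
  published 7.6). A tie between the two leading eigenvalues (no dominant
  shared-variance direction, e.g. an identity matrix) falls back to equal
  weights, flagged.
- **EFA**: single-factor principal-axis factoring — communalities
  initialised at squared multiple correlations, reduced-correlation
  eigendecomposition iterated to 1e-4 (max 100 iterations); Heywood
  communalities clipped at 0.999 and flagged; weights are squared factor
  loadings normalised to 100. For an exact one-factor structure this
  agrees with the PCA weights to machine precision, a property the tests
  assert.
- **Entropy**: the classical formulation on the raw level matrix —
  column shares `p_ij = x_ij / Σ_i x_ij`, normalised entropy
  `e_j = −(1/ln n) Σ_i p_ij ln p_ij` (0·ln 0 := 0), diversification
  `d_j = 1 − e_j`, weights ∝ `d_j`. A constant column gets weight 0
  (flagged); an all-constant matrix is an error. Whether the published
  sensitivity analysis ran this on levels or on normalised scores is
  unstated; raw levels are used and documented.
- **Equal** and **user** weights complete the set; user vectors not
  summing to 100 are rescaled with the original kept in diagnostics.

All methods return non-negative weights summing to 100 (±1e-6).

## Scoring, modes and archetypes

Two normalisation modes are provided because the published equation and
the published numbers disagree on one denominator. Every published CTB
component (23.68 / 17.76 / 11.84 / 5.92) equals `level/5 × 29.6`, and the
published unweighted scores confirm division by 5, although the printed
equation normalises CTB by 4. `reproduction` mode (default) therefore
uses each factor's `norm_denominator` — (4, 5, 3, 5) — prioritising
fidelity to the published results; `eq1_literal` normalises by the scale
maxima (4, 5, 3, 4), under which a worst-on-everything country scores
exactly 100. Under reproduction with the reference weights the attainable
range is [22.62, 94.08].

Archetype boundaries are 40 / 59.5 / 73 with half-open-from-below
intervals and 73 itself classified High; the published prose is
boundary-ambiguous (it also mentions a ≥ 75 reading tied to an SD
argument), but 40 / 59.5 / 73 with this convention is the unique rule
consistent with all 47 published labels, so no SD-based re-derivation is
attempted.

Reported values are rounded **half-up** to 2 decimals (`round2`);
IEEE-754 bankers' rounding would turn e.g. the exact 27.685 into 27.68
where the published tables print 27.69. Internal arithmetic is
unrounded; totals are sums of unrounded components.

## Validity and method agreement

`correlate` wraps a simple OLS regression (scipy `linregress`): Pearson
r, slope, intercept, R² = r², two-sided t-test p-value; incomplete pairs
are dropped and counted. `method_agreement` correlates each scoring
variant against a base column. Outcome series (e.g. the UHC service
coverage index) are user-supplied and joined on normalised country names
with an alias table; the published validity coefficients themselves
(r = −0.56 vs UHC SCI, r = 0.573 vs impoverishment) are not reproducible
without those external series, and the tests substitute a synthetic
outcome-recovery property instead (below).

## Synthetic data generator

`generate_country_table` draws latent traits from a multivariate normal
with a configurable correlation matrix, discretises them through
per-factor thresholds (ties at a threshold take the higher level — the
model under which the polychoric estimator is consistent), then draws raw
indicators uniformly inside the band each level implies, so re-banding
reproduces the levels by construction. Unbounded bands are truncated at
documented caps: CHE at US$800 (regional maximum ≈ US$727) and aid share
at 70% (regional maximum ≈ 65%).

Defaults emulate the reference study conditions: n = 47; marginal level
probabilities set to the observed 47-country proportions; a rounded PSD
latent correlation patterned on the structure estimated from the
reference levels (CHE–FAD 0.67, CHE–CTB 0.57, FAD–CTB 0.65, BSP weakly
or negatively related); outcome target R² = 0.314 with a negative slope
(−8 per composite SD-ish unit, intercept 44, on the scale of the UHC
coverage index).

The outcome is `intercept + slope · c + ε` where `c` is the equal-weight
latent composite. Because the sample R² of a regression is biased upward
at small n, the noise variance is calibrated through the exact
bivariate-normal expectation
`E[r²] = 1 − ((n−2)/(n−1))(1−ρ²)·₂F₁(1, 1; (n+1)/2; ρ²)`,
inverted numerically for the population ρ² that makes the *estimated* R²
unbiased for the requested target at the generated sample size; targets
below the null expectation 1/(n−1) map to ρ = 0. A single integer seed
drives all randomness in a fixed order (latent matrix, band draws,
outcome noise).

What the generator does **not** emulate: real GHED-style indicator
distributions inside bands (draws are uniform), missing data, reporting
lags, or any spatial/regional clustering. Passing tests therefore show
the pipeline is correct under its own measurement model, not that the
model describes any particular real dataset.

## Problem sizes in the test suite

Simulation-based tests are sized to make sampling error negligible
relative to their tolerances while staying quick: grid-oracle pair
comparisons at n = 800–5000; estimator bias at 200 replicates × n = 500;
latent-correlation recovery over 100 seeds × n = 2000 (compared on the
mean across seeds, the scale at which the ±0.05 band is meaningful —
single-seed estimates at n = 2000 carry ~0.02–0.03 sampling error, so
their per-seed maximum over 600 pair estimates occasionally exceeds
0.05); outcome-R² recovery over 500 replicates at n = 47, matching the
reference sample size. The whole suite runs in well under a minute.

## Known limitations

- The polychoric stage assumes latent normality; with 47 observations
  and sparse cells, estimates are noisy and occasionally boundary-bound
  (clamped at ±0.999).
- The published weight vector cannot be reproduced exactly; the package
  reports, rather than hides, the per-factor discrepancy of its squared-
  loading transform.
- Poverty banding and the poverty-augmented index variant are package
  choices without a published counterpart; the poverty-augmented column
  of the reference method-score table is bundled for agreement analysis
  but not regenerated.
- No imputation: countries with missing indicators must be handled
  upstream; validity joins drop unmatched countries with a count.
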