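# Methods

## Model and assumptions

`mome` operates on recursive path models: a set of linear regression
equations whose dependency graph is a DAG. Variables appearing as outcomes
are *endogenous*; predictor-only variables are *exogenous*. Interactions
enter as product columns w·u with coefficient d; a product column is never
a graph edge (the moderator contributes an edge only through its own main
effect), which is what makes the conditional-coefficient algebra
b + Σ_k d_k·w_k exact for every moderated edge.

All inference is conditional on correct specification of the equations and
i.i.d. sampling of cases. Estimation is per-equation OLS on one shared
complete-case set: because effects multiply coefficients across equations,
every equation must be fitted to exactly the same cases (checked by case
id, not by count). Missing data are removed by explicit listwise deletion
(`complete_cases`); no likelihood-based missing-data handling is attempted.

Effects are products of (conditional) coefficients along a validated path.
Path validation distinguishes a *missing* edge from mediators supplied in
the *wrong causal order* (the reversed sequence would be a valid path).
Path enumeration returns all simple directed paths, shortest first and then
lexicographic — the ordering of tied-length paths is a convention of this
package — and is capped at 10,000 paths as a guard against pathological
dense DAGs.

## Confidence intervals

**Percentile bootstrap.** R with-replacement resamples of the shared case
set; in each resample every equation is refitted and every variable's mean
and SD recomputed (n−1 denominator). An effect's replicate vector applies
the identical algebra to each replicate — in particular, a standardized
effect multiplies each replicate by that replicate's SD ratio, never the
point-estimate ratio. The CI is the (α/2, 1−α/2) percentile interval using
linear-interpolation ("type 7") quantiles; the quantile rule is a
documented choice, and CI checks in the test suite are property-based
(calibration, oracle equivalence) rather than digit-exact. Resamples with a
rank-deficient design (e.g. a resampled constant column) are redrawn and
counted in `failures`, with a hard stop at 10R attempts.

**Monte Carlo.** Each equation's coefficient vector is drawn from a
multivariate normal centred at the estimates with that equation's OLS
sampling covariance ψ̂(XᵀX)⁻¹; draws are independent across equations
(block-diagonal), an asymptotically justified approximation for recursive
OLS systems. Residual variances are drawn as ψ̂·χ²_df/df with df = n − p,
and the exogenous covariance (product columns included) from a Wishart with
scale S_exo/(n−1) and n−1 degrees of freedom. Replicate SDs come from each
replicate's implied covariance: exogenous SDs from the Wishart draw's
diagonal, endogenous SDs through the recursive identity
Σ_endo = (I−B)⁻¹(Γ S_exo Γᵀ + Ψ)(I−B)⁻ᵀ. Treating product columns as
exogenous in this identity is an approximation when a product involves an
endogenous variable; for centred predictors the neglected cross-moments are
third moments of near-normal variables and small.

**Determinism and parallelism.** Replicates are generated in chunks with
per-chunk seeds spawned from the top-level seed, so a store's contents are
bit-identical for any worker count (at a fixed chunk size). Two effects may
combine replicate vectors only when they carry the same (method, R, seed)
provenance tag; sums and differences form their CI from the combined
replicate vector, never from combining interval endpoints.

## Moderator levels

Continuous moderators default to mean ± 1 SD (three levels — +1 SD, mean,
−1 SD — for a single moderator; two levels each for two or more), or the
16th/50th/84th percentiles on request, or explicit values. Moments come
from the same complete-case set used for fitting, so levels are fixed at
their point-estimate values across replicates. Categorical moderators use
k−1 dummy columns with the first level (sorted or supplied order) as the
all-zero reference; level tables merge by Cartesian product with the first
moderator varying slowest. The indices of moderated (moderated) mediation
use moderator values exactly 1 and 0 — a one-unit change — holding any
other moderators on the path at 0; an SD-scaled change is available as the
difference between two table rows. When a queried path crosses a moderated
edge and no moderator value is supplied, the value defaults to 0 with a
warning: the "unconditional" effect is then the effect at moderators = 0.

The proportion of effect mediated is computed only when no x → y pathway is
moderated and all pathway effects share one sign; otherwise the function
refuses rather than picking a conditioning convention.

## Synthetic data

The generator draws exogenous variables from a multivariate normal
(Cholesky transform of a positive-definite covariance), then builds each
endogenous variable from its equation in causal order, materializing
product columns from the current data, plus independent normal error; the
truth record stores every coefficient and error SD. Defaults for the
demonstration model: unit-variance exogenous variables with 0.2
equicorrelation; coefficients near typical reported estimates of such a
model (a₁₁ = 0.35, d₁ = 0.15, b₁₂ = 0.55, b₂₁ = 0.83, d₂ = 0.80, plus
small control-variable effects of 0.10); error SDs 0.9 for mediators and
y2 and 1.2 for y1, giving realistic R² around 0.2–0.6; and case-level MCAR
missingness at rate 0.155, which at n = 200 yields about 31 incomplete
cases (each incomplete case blanks a random nonempty subset of columns).

What the generator does *not* emulate: non-normal or heteroskedastic
errors, measurement error, MAR/MNAR missingness, clustering, or categorical
outcomes. Passing calibration tests therefore demonstrates correctness of
the algebra and resampling under the stated sampling model, not robustness
to those violations. Binning for categorical moderators uses half-open
(lo, hi] intervals — a boundary value falls in the lower bin.

## Numerical choices and problem sizes

- OLS solves the normal equations after an explicit rank check; residual
  variance uses the unbiased denominator n − p; coefficient covariance is
  ψ̂(XᵀX)⁻¹. The batched bootstrap solver flags a resample as degenerate
  when the smallest eigenvalue of XᵀX falls below 1e−10 of the largest.
- Registered product columns are verified row-wise against moderator ×
  focal within 1e−8 at fit time.
- Reports round effect values to 3 decimals and computation-line
  coefficients to 5; internal computation is full precision. A "Sig" flag
  marks CIs excluding zero; no p-values are derived from them.
- Variables are not auto-centred; effects are invariant to centring while
  conditional values are not, so centring is left to the user's
  preprocessing.
- Test-suite problem sizes: parameter recovery at n = 100,000 (tolerance
  0.02), implied-covariance versus sample covariance at n = 10⁶ (1%),
  bootstrap calibration with 500 simulation replications of n = 200 at
  R = 1000 (coverage band 0.93–0.97), Monte Carlo versus Wald at
  R = 100,000 (2%). These sizes make the whole suite run in well under a
  minute of numerical work thanks to the batched solvers.

## Known limitations

- Regression backend only: no latent variables, no FIML or multiple
  imputation for missing data, no model-fit statistics.
- No three-way interactions (moderated moderation), no categorical or
  ordered outcomes/mediators, no robust or weighted least squares.
- Percentile intervals only; bias-corrected/accelerated variants are not
  implemented.
- Monte Carlo draws ignore cross-equation coefficient covariance and treat
  product columns as exogenous (see above); for strongly endogenous
  products the bootstrap is the safer method.
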