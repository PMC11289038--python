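# mome

Indirect effects, conditional effects, and conditional indirect effects —
standardized or not — in recursive path models, with percentile bootstrap
and Monte Carlo confidence intervals.

## Who this is for

Behavioral and health researchers routinely test **mediation** (an effect of
x on y transmitted through mediators), **moderation** (an effect whose size
depends on a moderator w), and **moderated mediation** (a mediation pathway
whose size depends on moderators). `mome` implements a two-stage workflow
for these analyses on any recursive (acyclic) path model estimated by
per-equation ordinary least squares:

1. **Stage 1 — estimate once.** Fit every regression equation of the path
   model on one shared case set, and (optionally) generate *R* replicate
   parameter sets by nonparametric case-resampling bootstrap or by Monte
   Carlo draws from the estimates' sampling distribution. The replicates
   are stored and reused.
2. **Stage 2 — query any path.** Compute the effect along *any* path,
   conditional on *any* moderator levels, standardized or not, without
   refitting or resampling: each effect is an algebraic function of the
   stored coefficients, re-evaluated replicate-wise to form a percentile
   confidence interval.

## The effect algebra

For a path x → m₁ → … → m_k → y the indirect effect is the product of the
component path coefficients, *a b₁ ⋯ b_k*. When an edge u → v is moderated
by w (via the product term w·u with coefficient d), its coefficient is the
**conditional coefficient** b + d·w, so a conditional indirect effect is
the same product with conditional coefficients, e.g.

  ind(w₁, w₂) = (a₁ + d₁w₁) · b · (b₂ + d₂w₂).

The **standardized** effect multiplies by SD(x)/SD(y) (partial
standardization uses only one SD). Crucially, in every bootstrap resample
the SDs are recomputed along with the coefficients, so the CI of a
standardized effect reflects the sampling variability of the SDs — the
correct bootstrap for standardized (conditional) indirect effects.

Derived quantities, all with replicate-based CIs:

- **Index of moderated mediation**: the change in the indirect effect per
  one-unit increase of a moderator, ind(w=1) − ind(w=0).
- **Index of moderated moderated mediation**: the double difference
  (ind(1,1) − ind(1,0)) − (ind(0,1) − ind(0,0)) over two moderators.
- **Differences between any two conditional indirect effects** (a 1-SD
  change in the moderator gives the *z-index* of moderated mediation).
- **Sums and differences of effects** (total indirect effect, total
  effect), with CIs from the combined replicate vectors — never from
  combining interval endpoints.
- **Proportion of effect mediated**, ab/(ab + c′), refused when path
  effects have mixed signs or the path is moderated.

Categorical moderators are handled through dummy coding (`factor2var`) and
per-group moderator-level rows; continuous moderators default to mean ± 1 SD
levels (three levels for one moderator, two each for several) or
16th/50th/84th percentiles.

## Worked example

Simulate the demonstration model (two predictors x1–x2, three mediators
m1–m3, two outcomes y1–y2, moderators w1 on x1 → m1 and w2 on m2 → y1, two
control variables, n = 200 with ~16% incomplete cases), fit it, bootstrap
once, and query effects:

```python
import mome
from mome.synthetic_data import MODEL1_SYNTAX, MODEL1_PRODUCTS, model1_spec, generate
from mome.report import render_effect, render_table

data, truth = generate(model1_spec(n=200, missing_rate=0.155, seed=42))
model = mome.parse_model(MODEL1_SYNTAX, products=MODEL1_PRODUCTS)
complete = mome.complete_cases(model, data)          # listwise deletion
est = mome.fit_equations(model, complete)            # n = 168 shared cases
store = mome.bootstrap_estimates(model, complete, R=5000, seed=43143)

e = mome.indirect_effect(est, "x2", ["m3"], "y2", store=store)
print(render_effect(e))
```

```
== Indirect Effect ==

 Path: x2 -> m3 -> y2
 Indirect Effect: 0.224
 95.0% Bootstrap CI: [0.132 to 0.322]

Computation Formula: (b.m3~x2)*(b.y2~m3)
Computation: (0.49750)*(0.45005)
```

The indirect effect of x2 on y2 through m3 is 0.224 (the product of the two
component slopes), significant because the 95% percentile bootstrap CI
excludes zero. Conditional indirect effects along the doubly moderated path
reuse the same replicates — no refitting:

```python
table = mome.cond_indirect_effects(est, ["w1", "w2"], "x1", ["m1", "m2"], "y1",
                                   store=store)
print(render_table(table))
```

```
row     [w1]     [w2]    (w1)    (w2)     ind   CI.lo  CI.hi  Sig  m1~x1  m2~m1   y1~m2
  1  M+1.0SD  M+1.0SD   0.935   1.067   0.444   0.265  0.641  Sig  0.615  0.462   1.560
  2  M+1.0SD  M-1.0SD   0.935  -0.966  -0.011  -0.101  0.081       0.615  0.462  -0.037
  3  M-1.0SD  M+1.0SD  -1.008   1.067   0.082  -0.033  0.199       0.114  0.462   1.560
  4  M-1.0SD  M-1.0SD  -1.008  -0.966  -0.002  -0.023  0.020       0.114  0.462  -0.037
```

The indirect effect of x1 on y1 through m1 and m2 grows with both
moderators and is significant only when both sit 1 SD above their means —
the per-row component columns show which conditional coefficients drive
this. Effect algebra on published coefficient tables (no raw data) works
through `ParamEstimates.from_coefficients`.

A `mome` command-line tool wraps the same operations
(`mome simulate | fit | ind | cond | mome | momome | diff | total | prop`);
see `mome --help`.

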