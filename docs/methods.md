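# Methods

## Setting and validity

One observation is a subject scan `(X, Y)` with covariates `X = (age, sex)`
and a continuous phenotype `Y` in native units. A reference interval at
miscoverage `α` is a band `C(x) = [L(x), U(x)]`; we call it *valid* for a
new population when a new observation falls below `L` with probability at
most `α/2` and above `U` with probability at most `α/2` (boundary values
count as outside). The reference sample that produced the interval and the
new sample may differ arbitrarily in distribution — different scanners,
field strengths, demographics, preprocessing. The only assumption the
calibration step needs is that the calibration set and the new observation
are exchangeable draws from the same (new) population.

## Conformal calibration

Given a naive interval and calibration records `(X_i, Y_i), i = 1..n_C`,
the conformity scores are the lower residuals `E_i = L(X_i) − Y_i` and
upper residuals `R_i = Y_i − U(X_i)`. Each tail's calibration constant is
the conformal empirical quantile at level `1 − α/2`: the k-th smallest
value with `k = ⌈(1 − α/2)(n_C + 1)⌉`. The calibrated interval is
`[L(x) − ĉ_lower, U(x) + ĉ_upper]`. Constants may be negative, which
*tightens* a bound — common when the reference population is noisier than
the target. Under exchangeability and continuous residuals the per-tail
miscoverage lies in `[α/2 − 1/(n_C+1), α/2]`, so the mean total FPR lies in
`[α − 2/(n_C+1), α]`; at `n_C = 400` that band is half a percentage point
wide, which is what the acceptance simulation reproduces.

Numerical and convention choices:

* **Tail level.** The default `half_alpha` convention uses level `1 − α/2`
  per tail, which is what the per-tail validity definition above requires.
  A `full_alpha` option uses `1 − α` in both tails instead (a convention
  that appears in parts of the CQR literature); it yields smaller
  constants and is provided for comparison, not as the default guarantee.
* **Order-index overflow.** When `k > n_C` (99% intervals with small
  calibration sets: `n_C ≤ 199` at `α = 0.01` under `half_alpha`), the
  constant falls back to the most extreme residual and the event is
  counted in `CalibrationConstants.overflow_events`. The strict guarantee
  would require an infinite adjustment; the fallback matches what
  practitioners do and makes the sensitivity to calibration outliers
  explicit.
* **Ties** are handled by the deterministic k-th order statistic; no
  randomized tie-breaking (residuals from continuous phenotypes are
  almost surely distinct).
* **Crossed bounds** after calibration (possible when a constant is very
  negative) are retained as an empty interval and noted in the interval's
  provenance; clamping would silently break the guarantee.
* Calibration touches the naive interval only through its bound
  functions, so a chart exchanged as a gridded CSV (age grid × sex →
  lower/upper) calibrates identically to the in-memory model; bounds are
  interpolated linearly in age between grid nodes.

## Naive chart models

**Box-Cox t (BCT) location–scale–shape regression.** `Y > 0` follows
`BCT(μ, σ, ν, τ)` when `z = ((Y/μ)^ν − 1)/(νσ)` (or `log(Y/μ)/σ` at
`ν = 0`) is Student-t with `τ` df, truncated to keep `Y` positive. `μ` is
the (approximate) median, `σ` a coefficient of variation, `ν` the skewness
power, `τ` the tail weight. The regression puts a penalised cubic B-spline
smooth over age plus a fixed sex offset in both `μ` (identity link) and
`log σ`, with constant `ν` and `τ` — batch effects deliberately live in
the comparators, not here. Fitting maximises the penalised log-likelihood
(including the truncation normaliser) by L-BFGS over all coefficients plus
`(ν, log τ)`, initialised from a penalised least-squares location fit,
residual coefficient of variation, `ν = 1`, `τ = 10`; convergence when the
objective changes by less than 1e−6 or after 200 iterations, and
non-convergence raises a structured fit error carrying the objective
trace.

**Additive quantile regression.** One curve per quantile level, same
design (spline over age + sex offset), minimising the penalised pinball
loss by majorise–minimise iteratively reweighted least squares: `ρ_τ(r) =
|r|/2 + (τ − ½)r`, with `|r|` majorised by a quadratic around the current
residuals floored at a smoothing `δ` annealed from 1e−2·sd(y) down to
1e−9. Every step is a closed-form weighted ridge solve — deterministic, no
line search — and the final curve sits within ~1e−8 of the exact
check-loss minimiser. The exact penalised check loss is recorded after
each annealing stage and is non-increasing.

**Smoothing.** Interior knots sit at age quantiles; the count adapts to
sample size (one knot per 50 observations, minimum 2, capped at 10) so
that calibration-sized refits stay estimable while large reference fits
keep full flexibility. The roughness penalty is a second-order difference
penalty on spline coefficients with fixed weight λ = 1 by default. For the
quantile fitter, `FitConfig(penalty_search=True)` instead selects λ from a
log-spaced grid by a Schwarz-type criterion
`log(mean check loss) + edf·log(n)/(2n)`, which reproduces the
near-constant fits that auto-smoothing quantile packages produce on
signal-free data. Fitted curves extend flat (constant) beyond the training
age range.

## Comparator strategies

* **Refit** delegates the naive fit to the calibration set alone. Its fit
  errors are structured so a sweep records them as failed trials.
* **Harmonization** estimates a shared penalised mean model (spline over
  age + sex) with per-batch location shifts, then either one residual SD
  per batch (`scalar_scale`) or per-batch offsets around a shared
  covariate-dependent log-scale model fitted by Gaussian ML
  (`covariate_scale`). Records map to the reference scale via
  `y* = m_ref(x) + (y − m_b(x))·s_ref(x)/s_b(x)`. Single-outcome by
  construction — no empirical-Bayes pooling across outcomes. The
  "reference scale" is the sample-weighted pooled batch by default; a
  designated reference batch overrides it. Unseen batches are rejected
  rather than imputed. When the reference data is a single batch, the
  harness scores harmonized records against the chart fitted on raw
  reference data (they live on the same scale); with a multi-site
  reference the chart is refit on harmonized data.
* **Batch-adjusted LSS** adds per-batch offsets to `μ` and `log σ` in the
  pooled BCT fit, ridge-penalised with weight `1/sd²` for prior SDs of
  0.1 mm (location) and 0.2 (log-scale) — a deterministic shrinkage
  stand-in for Gaussian random effects. The interval for a target batch
  uses that batch's offsets; with one batch the model collapses to the
  plain fit.

## Synthetic data

The generator emulates multi-site cortical-thickness-like tables:
`value = μ(age, sex) + δ_b − Δ·[CASE] + γ_b·σ(age)·ε` with defaults
`μ = 3.8 − 0.012·age + 4·10⁻⁵·age² + 0.05·[M]` mm, `σ(age) = 0.12 +
0.0006·age` mm, ages uniform on [20, 95], 45% male. Noise families:
standard normal, raw Student-t (heavy tails), or a standardised unit-median
BCT draw (skew). Scenario presets fix the study conditions: a large
reference-vs-target shift (δ = +0.3 mm, γ = 1.5), a small one (+0.08 mm,
1.1), and a 22-site reference (site effects drawn once from N(0, 0.1) /
log-normal(0, 0.1) with a fixed internal seed) plus a disease subgroup
(Δ = 0.3 mm, drawn 10 years older). One master seed drives everything;
per-trial streams are spawned by counter so trials are independently
reproducible.

What the generator does *not* emulate: longitudinal correlation, non-random
site–demographic confounding, floor/ceiling and segmentation artifacts,
and covariate shift between calibration and validation beyond what batch
effects induce. Passing tests therefore demonstrate the methods'
statistical behaviour under controlled shift, not performance on any real
consortium sample.

## Evaluation harness

Each trial draws a reference subset from the reference dataset and a
calibration subset from the target dataset (both without replacement,
healthy records only); validation is every remaining healthy target
record, and the disease positive rate (PR) is scored on the full disease
set when present. Naive fits are cached per drawn reference set, so the
"full" reference size fits once per sweep. Failed fits become
`status=fit_error` rows, excluded from medians/IQRs but counted.
One-sample and paired Wilcoxon signed-rank tests (two-sided or one-sided)
drop zero differences and use the exact null for n ≤ 25 without ties,
otherwise a normal approximation with continuity correction — the exact
small-sample values are pinned against an enumeration oracle in the tests.
A window filter retains trials where every compared method's FPR lies
within `α ± 0.2α` for matched-specificity PR comparisons.

Problem sizes in the shipped tests and acceptance script are chosen
desk-scale: 500 trials for the coverage simulation (reference 1000,
`n_C = 400`, validation 1000) and 200 trials for the directional
comparisons, with Monte-Carlo tolerances set from the empirical
across-trial standard errors (assertions use 3 SEs).

## Known limitations

* FPR is controlled marginally over age and sex, not within demographic
  bins; conditional-coverage extensions are out of scope.
* The BCT optimizer uses finite-difference gradients; fits with many
  batches are correspondingly slower.
* `ν` and `τ` are constant across covariates, and the quantile-curve
  pathway does not repair crossing between independently fitted levels —
  crossings are detected and reported instead.
* Harmonization of a batch unseen at fit time is rejected by design.
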