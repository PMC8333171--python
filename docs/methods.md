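# Methods

## The measurement model

A household is in catastrophic health expenditure (CHE) when its
out-of-pocket health spending `oop` reaches a fraction `threshold` of its
capacity to pay. The construction, per household h with total expenditure
`exp_h`, food expenditure `food_h`, size `n_h` and sampling weight `w_h`:

1. **Food share**: `fs_h = food_h / exp_h`.
2. **Subsistence line** (per equivalent adult): the weighted 45th and 55th
   percentiles p45, p55 of the food-share distribution are computed; over the
   households with `fs_h ∈ [p45, p55]` (closed window; boundary ties are
   common with discretized expenditures and inclusion maximizes the window
   sample) the line is the weighted mean of equivalized food expenditure
   `food_h / n_h**eq_scale`.
3. **Household subsistence spending**: `se_h = line · n_h**eq_scale`.
4. **Capacity to pay**: `ctp_h = exp_h − se_h` when `food_h ≥ se_h`, else
   `exp_h − food_h` (households eating below the subsistence line have their
   actual food spending deducted, never more than they spend).
5. **Indicator**: `che_h = 1{ oop_h / ctp_h ≥ threshold }`.

Defaults: `threshold = 0.40`, `eq_scale = 0.56` (the Xu et al. economy-of-
scale exponent), window (0.45, 0.55). The threshold boundary is inclusive; a
`strict` toggle switches to a strict inequality, so `threshold = 1, strict`
recovers the literal "health spending exceeds capacity to pay" rule.
Households with `ctp_h ≤ 0` (food-dominated budgets below the line cannot
produce this; it arises when `se_h ≥ exp_h`) are *flagged*: excluded from
incidence and from the regression sample with a logged count, never silently
dropped. Zero-OOP households are retained with `che = 0`.

**Weighted quantile convention.** CDF inversion with linear interpolation
between cumulative-weight midpoints `(C_j − w_j/2)/W`, computed after pooling
tied values (summing their weights). Pooling is what makes the convention
*exactly* equivalent to replicating each observation `w` times for integer
weights — without it, a weight-4 observation and four unit copies of the same
value interpolate differently. Quantile requests outside the first/last
midpoint clamp to the minimum/maximum. The construction is invariant to
rescaling the currency and to rescaling all weights.

**Quintiles** for incidence reporting are weighted quintiles of total
expenditure with ties assigned to the lower quintile.

## The heteroskedastic probit

Latent model: `c_i = 1{ y_i′β + ε_i > 0 }` with `ε_i ~ N(0, σ_i²)`,
`σ_i = exp(x_i′τ)`. The variance design `x` has **no intercept**: `exp(0)=1`
pins the scale, which is what identifies β (standard location–scale
identification). A constant column in `x` is rejected as an identification
error. Variance covariates may also appear in the mean equation; the default
pipeline puts scaled total expenditure in both.

Weighted log-likelihood, score and fitting:

* `lnL = Σ w_i [ c_i ln Φ(z_i) + (1−c_i) ln(1−Φ(z_i)) ]`, `z_i = y_i′β/σ_i`,
  evaluated with `log_ndtr` so extreme indices stay finite.
* Analytic gradient: with `λ_i = φ(z_i)/Φ(z_i)` for successes and
  `−φ(z_i)/(1−Φ(z_i))` for failures (computed in log space),
  `∂lnL/∂β = Σ w_i λ_i y_i/σ_i` and `∂lnL/∂τ = −Σ w_i λ_i z_i x_i`.
* Optimizer: BFGS on the weight-normalized objective `lnL / Σw` (so the
  gradient tolerance is scale-free in n and in the weight normalization),
  gtol 1e-7, one restart from a jittered start on failure, followed by
  damped Newton polish steps on the exact first-order conditions until
  `max|∂lnL/∂θ|/Σw < 1e-8` or the relative log-likelihood change falls
  below 1e-10; at most 200 quasi-Newton iterations. Start values: β from
  the probit fit (itself started at the intercept-only closed form
  `Φ⁻¹(weighted mean)`), τ = 0. The latent index is clipped at |z| ≤ 1e7
  purely so that line-search probes into absurd regions return finite
  (terrible) likelihoods instead of overflowing.
* Degenerate inputs: an all-0 or all-1 outcome is refused (the likelihood
  has no interior maximum). Perfect separation is flagged when one class's
  fitted indices all exceed 30 in magnitude *or* every observation's fitted
  probability of its observed outcome exceeds 0.999; the error names the
  covariates with the largest standardized coefficients.

**Covariance.** Default: inverse observed information, with the Hessian
obtained by central differences of the analytic score (step 1e-5, scaled by
parameter magnitude). A Huber sandwich `A⁻¹BA⁻¹` (`B = Σ s_i s_iᵀ` of
per-observation weighted scores) is available via `vcov_kind="sandwich"`.
The sandwich is the appropriate frequentist covariance when heterogeneous
sampling weights multiply an otherwise independent-per-household likelihood
— inverse information understates it by roughly `sqrt(E[w²]/E[w]²)` — and it
is what the delta-method-versus-bootstrap validation uses. If the Hessian is
singular at the optimum the fit is flagged (not converged) and a
pseudo-inverse covariance is reported with a warning.

**Expenditure scaling.** Total expenditure enters the model in units of
10,000 currency by default (`PipelineConfig.exp_divisor`). Inside
`exp(x′τ)`, raw-currency magnitudes make the optimizer fragile and the
coefficient unreadably small; rescaling is a pure reparameterization.

## Marginal effects and tests

* Continuous `w_z`: per-observation `φ(z_i)(β_z − y_i′β·g_z)/σ_i`, where
  `g_z` is the variance-equation coefficient (0 when `w_z` is mean-only).
  The `−y_i′β·g_z` term is how a shared covariate's effect can flip sign
  relative to β_z.
* Dummy `w_z`: `Φ(z_i|w=1) − Φ(z_i|w=0)` with the dummy toggled in *both*
  designs. A covariate is a dummy iff its observed support is exactly {0,1};
  proportions on [0,1] are continuous.
* Averaging: sampling-weighted average of per-observation effects (AME) by
  default; effects at weighted covariate means as an option. AME is the
  modern default and the per-observation formulas above are what it
  averages. Effects are reported per design column (age and squared age, if
  both present, each get their own row).
* Delta-method SE: `sqrt(J V Jᵀ)` with J the central-difference Jacobian of
  the averaged effect in the stacked (β, τ), step 1e-6, with one Richardson
  refinement if rounding drives the quadratic form negative. Effects are
  defined only for mean-equation covariates (the continuous formula
  presupposes β_z exists).
* LR tests: `2(lnL_u − lnL_r)` clipped at zero against χ²(df) — df = number
  of variance covariates for the homoscedasticity test, number of slope
  parameters for the overall test. An unrestricted likelihood below the
  restricted one by more than 1e-6 raises an error (it signals optimizer
  failure, not evidence).
* Fit statistics: `AIC = 2k − 2lnL`, `BIC = k ln n − 2lnL` with k all free
  parameters (|β|+|τ|), McFadden `R² = 1 − lnL/lnL₀` with lnL₀ from the
  intercept-only probit. p-values are two-sided normal for effects and χ²
  for LR tests; no multiple-testing adjustment is applied.

## The synthetic generator

Structural mode emulates the features of a rural household-expenditure
survey that the method relies on, with defaults chosen as plausible for such
a survey: total expenditure log-normal(μ=10.2, σ=0.8) — strongly
right-skewed (sample skewness ≈ 3–4); food share
`logistic(3.37 − 0.35·ln exp + N(0, 0.3))`, i.e. near one half at the median
budget and falling with the budget (an Engel curve); household size
1 + Poisson(4); weights 0.25 + Gamma(2.25, 1/3) (positive, mean 1,
heterogeneous); OOP spending log-normal with log-mean `−2.6 + ln exp`
(≈ 7–9% of the budget) and log-sd `−0.5 + 0.15·ln exp` (dispersion growing
with the budget — the heteroskedasticity the model targets), with a 3%
point mass at zero. Binary/proportion covariates carry rural-style
prevalences (e.g. 80% male heads, 32% insured). The `hh_size_spec` field
exists because household size is a required output column but not a model
covariate.

Latent-index mode draws the outcome directly from
`Bernoulli(Φ(y′β/exp(x′τ)))` at the configured true coefficients; the
default recovery configuration uses four mean covariates with
β = (−0.8, 0.5, 0.4, −0.6, 0.3) and one shared variance covariate with
τ = 0.3, giving ≈ 22% incidence.

Every column is drawn from its own child random stream keyed by
(seed, column name) in a fixed order, so adding a covariate never perturbs
existing columns. Identical (config, seed) yields byte-identical fixtures.

**What the generator does not emulate** — and hence what passing tests do
not establish about real surveys: stratified multi-stage sampling designs
(weights here are i.i.d., and design effects on variances are out of scope),
correlation between covariates and the budget, questionnaire-specific
measurement error, and any country's actual covariate distributions.
Parameter-recovery results validate the estimator under its own law, not the
measurement model's fit to any real population.

## Problem sizes and tolerances in the validation suite

Oracle equivalence uses a printed 8-observation fixture against a dense grid
search (coarse 0.005 pass over [−3,3]², 0.001 refinement; agreement 1e-5).
Parameter recovery: one fit at n = 20,000 (each coefficient within 3
reported SEs) plus 50-replicate MAE comparison at n = 2,000 vs 20,000.
Delta-method validation: n = 5,000 against a 200-replicate parametric
bootstrap, 15% band, sandwich covariance (see above). LR-test calibration:
1,000 null replicates at n = 2,000 (size within [0.03, 0.07] at the 5%
level) and 300 replicates under τ = 0.5 (power > 0.9). The measurement
pipeline is checked against independent loop-based recomputation on a
printed 20-household fixture, plus exact currency-, weight- and
threshold-monotonicity invariances.

## Known limitations

* Observed-information SEs assume correct specification; the sandwich option
  mitigates but cluster-level dependence is not modelled.
* The subsistence line is a plug-in estimate: its sampling variability is
  not propagated into the model stage.
* No survey-design variance estimation (linearization or replicate weights);
  weights are used as given, with normalization left to the user.
* Only the probit link; no selection or endogeneity corrections.
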