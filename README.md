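# cheprobit

Measurement and modelling of **catastrophic health expenditure (CHE)** from
household survey microdata, for health economists and epidemiologists studying
financial protection. The package implements two stages as a tested, reusable
pipeline:

1. **CHE measurement** (capacity-to-pay methodology). A household's
   subsistence spending is estimated from the weighted average equivalized
   food expenditure of households whose food share lies between the 45th and
   55th weighted percentiles; capacity to pay is total expenditure net of
   subsistence spending (or net of actual food spending for households eating
   below the line); out-of-pocket (OOP) health spending is catastrophic when
   it reaches 40% of capacity to pay. Household size is equivalized as
   `size**0.56`.

2. **Sampling-weighted multiplicative heteroskedastic probit**. The plain
   probit, Pr(c_i = 1) = Φ(y_i′β), assumes a unit-variance latent error;
   when the error scale varies with covariates (health spending is far more
   dispersed among rich households than poor ones), its estimates are biased
   and inconsistent. The location–scale model lets

       σ_i = exp(x_i′τ),    Pr(c_i = 1) = Φ( y_i′β / exp(x_i′τ) ),

   with no intercept in x (exp(0) = 1 identifies β). Both models are fitted
   by maximizing the weighted log-likelihood

       lnL = Σ_{c_i=1} w_i ln Φ(z_i) + Σ_{c_i=0} w_i ln(1 − Φ(z_i)),
       z_i = y_i′β / exp(x_i′τ),

   with analytic gradients. The package reports average marginal effects —
   for a continuous covariate w_z appearing with coefficient β_z in the mean
   equation and g_z in the variance equation,

       ∂Pr/∂w_z = φ(z_i) · (β_z − y_i′β·g_z) / exp(x_i′τ),

   and for a dummy the exact probability difference with the dummy toggled in
   both equations — together with delta-method standard errors, the LR test
   of homoscedasticity (χ² with one df per variance covariate), the overall
   LR test, McFadden pseudo R², AIC and BIC.

A synthetic survey generator provides the test bed: a *structural* mode
(right-skewed log-normal budgets, Engel-curve food shares, OOP spending whose
dispersion grows with the budget) and a *latent-index* mode that draws the
outcome directly from the heteroskedastic probit law for clean parameter
recovery.

## Worked example

```python
import cheprobit as cp

survey = cp.generate(cp.default_structural_config(n_households=6000, seed=42))
result, summary = cp.run_che_pipeline(survey)
print(f"weighted CHE incidence: {100*summary['incidence']:.2f}%")

cfg = cp.PipelineConfig(mean_covariates=(
    "male_head", "head_illiterate", "insured", "chronic",
    "prop_female", "prop_elderly", "total_exp_scaled"))
bundle = cp.run_full_analysis(cfg, data=survey)
print(cp.format_table(bundle))
```

prints

```
weighted CHE incidence: 12.81%
variable                     probit coef       probit ME        het coef          het ME
intercept               -1.107*** (0.097)                -0.943*** (0.128)
male_head                 -0.020 (0.052)  -0.004 (0.011)  -0.013 (0.065)  -0.002 (0.011)
...
total_exp_scaled          -0.006 (0.006)  -0.001 (0.001)-0.150*** (0.039)-0.009** (0.003)
ln_sigma:total_exp_scaled                                0.069*** (0.014)
----------------------------------------------------------------------------------------
LogL: probit -2272.948   hetprobit -2266.870
Het-test chi2(1) = 12.156***
AIC: 4561.895 / 4551.739   BIC: 4615.491 / 4612.035   McFadden R2: 0.001 / 0.004
N = 6000
```

Reading the footer: the heteroskedasticity LR test rejects homoscedasticity
(χ²(1) = 12.2, p < 0.001) and both information criteria prefer the
location–scale model. Total expenditure (in units of 10,000) is insignificant
in the plain probit but strongly significant in *both* equations of the
heteroskedastic model — larger budgets lower the CHE propensity while
inflating its latent dispersion — which is exactly the kind of inference
reversal the model exists to expose.

The same pipeline is available from the shell:

```bash
cheprobit simulate gen_config.yaml survey.csv   # synthetic fixture
cheprobit measure survey.csv                    # CHE construction only
cheprobit run survey.csv --mean male_head --mean total_exp_scaled --out out/
```

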