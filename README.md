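# idmrates

Estimation of age-specific **incidence** and **remission** rates of a
remitting chronic condition from **repeated cross-sectional prevalence
surveys**, using the illness-death (three-state) multistate model — with a
synthetic-study generator, survey-weighted prevalence modelling, percentile
bootstrap confidence bands, and a mortality-rate-ratio sensitivity analysis.

## Who this is for

Epidemiologists who have age-, sex-, and region-specific *prevalence* of a
condition at two (or more) survey waves — for example moderate-to-severe
anxiety or depressive symptoms defined by a screening cut-off (GAD-7 ≥ 10,
PHQ-9 ≥ 10) — plus general mortality rates (life tables) and mortality rate
ratios for the condition, and who want the *transition rates* that no
longitudinal data exist for.

## The model

The population is in one of three states: susceptible, diseased, dead.
Transitions occur at the incidence rate `i(a)`, remission rate `r(a)`, and
mortality rates `m0(a)` (susceptible) and `m1(a)` (diseased).  Along a birth
cohort, point prevalence `p` obeys

```
(∂t + ∂a) p = (1 − p)·i − p·r − p(1 − p)(m1 − m0)
```

Since `m0` is rarely observed, the general mortality `m = (1−p)m0 + p·m1`
and the mortality rate ratio `R = m1/m0` substitute for the state-specific
rates:

```
(∂t + ∂a) p = (1 − p)·i − p·r − p(1 − p)·m(R − 1)/(1 + p(R − 1))
```

The pipeline:

1. fits the logit of prevalence as a polynomial in age (degrees of freedom
   chosen by leave-one-cell-out cross-validation) plus a linear calendar-time
   term, sex, and study-center effects, by survey-weighted binomial
   maximum likelihood;
2. differentiates the fitted surface analytically along cohort lines;
3. smooths tabulated mortality rates and rate ratios into log-linear age
   curves;
4. represents `i(a)` and `r(a)` each as a Gaussian in age,
   `θ1·exp(−((a−θ2)/θ3)²)`, and finds the six coefficients minimizing the
   sum of squared deviations between the fitted derivative and the model
   right-hand side over a grid of ages;
5. reports incidence per 1,000 person-years and remission per 100
   person-years, truncating negative estimates to zero, with percentile
   bootstrap 95% bands (participants resampled within center × period).

A misclassification (Rogan–Gladen) adjustment,
`(p_obs + spec − 1)/(sens + spec − 1)`, is provided for screening-instrument
inaccuracy, flagging out-of-range results.

## Worked example

```python
import numpy as np
import idmrates as m

truth = m.default_truth()                      # known ground-truth rates
records = m.sample_study(truth, 25000, centers=["Hamburg"], seed=1)

st = truth.stratum("female", "anxiety")
m_curve = m.fit_log_mortality(st.mortality_table("female"))
r_curve = m.fit_mrr(st.mrr_table("anxiety"))

fit = m.fit_logit_polynomial(records, "anxiety", df=3)
grid = m.EvaluationGrid(sex="female", center="Hamburg")
params, report = m.estimate_rates(fit, m_curve, r_curve, grid)
table = m.rates_table(params, ages=grid.ages)
print(table.peak_incidence, table.peak_remission)
```

prints (seed 1)

```
(23.0, 3.054282642683544) (73.0, 5.539960648114476)
```

i.e. incidence peaks at age 23 with 3.05 cases per 1,000 person-years and
remission is highest at the old end of the observable range (5.54 per 100
person-years at 73) — against generating-truth values of 4.0 per 1,000 PY
at age 20 and a remission mode at age 72.  Bootstrap bands come from
`m.bootstrap_rates(...)` + `m.percentile_band(...)`.

The same analysis runs from a YAML config on the command line:

```
idmrates simulate --config config.yaml --out data/
idmrates fit --config config.yaml --out results/ --bootstrap 200
idmrates sensitivity --config config.yaml --out sens/   # MRR ×0.85 / ×1.15
```

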