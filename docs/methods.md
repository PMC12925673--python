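# Methods

## Model

The illness-death model places a population of age `a` at time `t` into
three states — susceptible, diseased, dead — with transition rates:
incidence `i(a)` (per person-year at risk among the susceptible), remission
`r(a)` (per person-year among the diseased), and mortality `m0(a)` /
`m1(a)` in the susceptible and diseased states.  Point prevalence `p(t, a)`
(the diseased share of the living) satisfies, along cohort lines,

    (∂t + ∂a) p = (1 − p) i − p r − p (1 − p)(m1 − m0).

Because state-specific mortality is rarely observed, the implementation
works with the general mortality `m = (1 − p) m0 + p m1` and the mortality
rate ratio `R = m1/m0`, which give the algebraically identical form

    (∂t + ∂a) p = (1 − p) i − p r − p (1 − p) m (R − 1) / (1 + p (R − 1)).

The identity of the two forms (given consistent inputs) is enforced by a
property test at 1e−12.

### Rate parameterization

Incidence and remission are each a three-parameter Gaussian in age,

    i(a) = θ1 exp(−((a − θ2)/θ3)²),   r(a) = θ4 exp(−((a − θ5)/θ6)²),

the minimal unimodal positive-peak family: one amplitude (rate at the
mode), one location (age of the mode, years), one width (years, strictly
positive).  Whether a width parameter of this kind should enter as σ or σ²
is a pure reparameterization; we fix the form above and document it as an
assumption of this package.  Amplitudes are *unconstrained* during
optimization; negative estimates are truncated to zero only in reporting,
with per-age truncation flags.  This reproduces the convention of printing
rates and confidence bounds as "0.00" rather than constraining the fit.

### Estimation

1. **Prevalence surface.**  The logit of prevalence is a polynomial in
   centered/scaled age (`x = (a − 46.5)/27.5`; df = degree, default 3),
   plus a linear calendar-time term (only when more than one survey wave is
   present), a sex indicator, study-center indicators, and by default a
   full age-polynomial × sex interaction (each sex gets its own age shape;
   results are reported per sex).  Centered/scaled monomials are used
   rather than an orthogonal basis: the fitted surface is identical and
   the exact analytic derivative is a plain power series.  The model is
   maximized by weighted binomial likelihood (statsmodels GLM,
   `var_weights` = survey weights) on cells aggregated per
   (center, sex, period, age) — equivalent up to a constant to the
   participant-level weighted likelihood, and invariant to rescaling all
   weights.  Complete-case filtering (dropping records with missing case
   status for the analyzed condition) precedes aggregation; no imputation
   is performed.

2. **df selection.**  Leave-one-cell-out cross-validation: each aggregated
   cell is held out in turn, the model refit, and the held-out cell's
   prevalence predicted; the df (candidates 1–5) minimizing the unweighted
   mean squared prediction error on the probability scale wins, ties to
   the smaller df.  The inner refits use a dedicated IRLS routine
   (verified against statsmodels to 1e−6) because several thousand refits
   per selection would otherwise dominate runtime.  df is *not* re-selected
   inside bootstrap replicates.

3. **Directional derivative.**  `(∂t + ∂a) p = p(1 − p)(∂η/∂t + ∂η/∂a)`
   with `η` the linear predictor — exact chain-rule differentiation of the
   fitted surface, never finite differences (a test checks agreement with
   central differences to 1e−6).

4. **Mortality inputs.**  Tabulated general mortality and rate-ratio
   curves are smoothed as log-linear (Gompertz-type) functions of age by
   least squares on the log scale; log-linearity guarantees positivity and
   describes adult mortality well.  For the rate ratio it is a smoothness
   assumption only.  The robustness analysis multiplies the fitted R̂(a)
   by a constant (±15% by convention); we scale R itself, not (R − 1).

5. **Least squares.**  The six coefficients minimize the sum of squared
   residuals between the fitted derivative and the model right-hand side
   over integer ages 20–73 (strictly inside the observable 19–74, so the
   derivative is always interpolated) at the calendar midpoint between the
   two waves (t = 2017.0).  Residuals are unweighted.  Minimization is
   Nelder–Mead from eight deterministic starts (locations sweeping
   {20, 45, 70}, two sign-flipped amplitudes), widths on the log scale,
   best final objective wins (ties to the lowest start index), followed by
   simplex-restart polishing.  Estimation is fully deterministic.

6. **Bootstrap.**  Participants are resampled with replacement within
   (center, period) strata, carrying weights; each replicate re-runs
   complete-case filtering, the prevalence fit (fixed df), and the
   estimation, warm-started at the point estimate (a single simplex start;
   standard bootstrap practice that keeps B = 200–2,000 runs tractable).
   Replicate b draws from `default_rng([master_seed, b])`, so ensembles
   are identical for any execution order or worker count.  95% bands are
   per-age empirical 2.5th/97.5th percentiles (numpy linear-interpolation
   rule); negatives are truncated to zero *after* the percentile
   computation, and only in reported bands, not in stored replicates.
   Replicates that fail to converge are dropped and counted; more than 20%
   failures aborts the ensemble.

7. **Misclassification adjustment.**  Apparent prevalence from an
   imperfect screener is corrected as
   `(p_obs + spec − 1)/(sens + spec − 1)`; results outside [0, 1] are
   flagged invalid and must not be propagated (with sensitivities and
   specificities typical of depression/anxiety screeners, low apparent
   prevalences map to negative adjusted values).

## Synthetic-data generator

The generator emulates the structure of a large multi-center survey of
anxiety/depressive symptoms: two cross-sections with calendar midpoints
2015.5 and 2018.5, five study centers, ages 19–74, per-participant
correction weights, and per-condition binary case status.  The truth is an
illness-death model with time-constant rates: both waves then share one
prevalence curve `p(a)` (computed by a fixed-step RK4 cohort solver, step
0.1 y, output clamped to [0, 1]), and the directional derivative equals
dp/da — the cleanest identifiable test-bed.  Default truth: incidence
amplitude 0.004/PY at age 20, width 18 y; remission amplitude 0.04/PY at
age 72, width 20 y; susceptible mortality 1e−4·e^{0.09(a−19)}; R ≡ 2;
p(19) = 0.05.  Sampling: ages uniform on {19..74} (a neutral stand-in for
age-stratified sampling), case status Bernoulli at the truth prevalence,
weights gamma with mean 1 and coefficient of variation 0.3 (the weight
distribution of real surveys is unspecified; any positive mean-1 family
serves), 6% independent item missingness per condition.

What the generator does **not** emulate: real sampling frames and response
propensities, item-level screener data (only the dichotomized cut-off),
center-specific prevalence differences (centers share the truth by
default), or time trends in the true rates.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to design features of any real survey.

## Numerical choices

- RK4 with fixed step ≤ 0.1 y: smooth rates, no adaptive-step
  nondeterminism; matches constant-rate closed forms to well below 1e−6
  over 55 years of integration.
- Ages centered at 46.5 and scaled by 27.5 before polynomial expansion for
  conditioning; calendar time centered at 2017.0.
- Optimizer log-width caps at e^{±30} keep the simplex away from
  overflow/degenerate-width territory.
- Evaluation grid integer ages 20–73; reporting tables default to the same
  grid, peak entries are the maxima of the reported (truncated) curves
  over that grid, while `find_peaks` returns the continuous argmax of the
  Gaussians clamped to [19, 74] (a mode outside the observable range
  reports the boundary age — the true peak may lie beyond it).

## Known limitations

- **Boundary smoothing bias.**  A low-df polynomial on the logit scale
  attenuates the prevalence derivative near the age boundaries.  With the
  default truth (incidence mode at age 20, the young edge of the range),
  the df = 3 surface places the recovered incidence peak near age 23.5
  even at infinite n, and inflates mid-age incidence relative to truth.
  Consequences measured on synthetic studies: peak-age recovery is
  systematically a few years late, and percentile-bootstrap bands —
  which cannot cover bias exceeding the sampling spread — undercover
  mid-age incidence.  Remission and old-age behavior are much less
  affected.  Users whose condition has onset concentrated at one end of
  the observed age range should treat peak locations as upper/lower
  bounds and consider higher df.
- Identifiability rests on the Gaussian family: where the data are
  uninformative (flat, noisy derivative) the six parameters can drift to
  tail-fitting configurations (mode far outside the range) that represent
  the same curve on the grid; reported rate curves remain meaningful,
  individual coefficients need not.
- The two-wave design identifies only a linear calendar-time trend; the
  estimated rates are treated as time-constant.
- Mortality and rate-ratio curves are held fixed in the bootstrap (they
  come from external tabulations, not the resampled survey), so the bands
  reflect survey sampling uncertainty only.
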