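# Methods

`cflandmark` implements dynamic prediction of survival by landmarking for
adults in a longitudinal disease registry, developed around the setting of
cystic fibrosis (CF): roughly annual reviews of lung function,
anthropometry, infections and comorbidities, deaths as the outcome of
interest, lung transplantation as an intercurrent event, and
administrative censoring at the end of a fixed study window.

## The landmarking model

At each landmark age `L` on an integer grid (default 18–50, 33 ages), the
cohort is restricted to patients alive, untransplanted, diagnosed and
under registry observation at `L`, with the age-`L` date inside the study
window. Residual survival is measured from `L` on the
time-since-landmark scale `t`, administratively censored at the horizon
`w` (default 10 years). Covariate histories are summarized at `L` by
last observation carried forward (LOCF); optionally (two-stage
landmarking) by fitted values and slopes at `L` from mixed models fitted
to the pre-`L` measurement history.

The landmark datasets are stacked and Cox proportional-hazards models are
fitted to the stack. The central model (variant 2, the *supermodel*) is

    h(t | L, x) = h0L(t) · exp(β′x),

with a separate (stratified) baseline hazard `h0L` per landmark age and
coefficients `β` common across landmark ages. Because one patient
contributes rows to many landmark datasets, standard errors use a robust
(cluster sandwich) estimator clustered on patient. Six variants are
provided:

1. separate Cox models per landmark age;
2. the stratified supermodel (common `β`, per-`L` baselines);
3. variant 2 plus interactions of every predictor with a polynomial basis
   in `u = (L − 18)/32` (coefficients vary smoothly with landmark age);
4. variant 2 plus predictor × time-since-landmark interactions
   (time-varying coefficients via a deterministic basis `f(t)` evaluated
   at event times inside the partial likelihood; linear `f(t) = t/w` by
   default, B-spline optional, optionally restricted to FEV1%);
5. a common unstratified baseline with `u, u²` regression terms carrying
   the effect of landmark age;
6. variant 2 plus mixed-model fitted values and slopes at `L` for FEV1%,
   FVC% and weight (with the LOCF terms retained by default).

Predicted survival is `S(t | L, x) = exp(−H0L(t)·exp(β′x))` from the
Breslow baseline cumulative hazard, or, with time-varying terms,
`exp(−Σ_k ΔH0L(t_k)·exp(lp(t_k)))` accumulated over baseline jumps.

### Numerical choices

* Partial likelihood maximized by Newton–Raphson with step-halving;
  Breslow tie handling by default (death times in annual-scale registry
  data rarely tie), Efron optional. Convergence requires the score
  max-norm below `1e-9 × max(1, number of events)` (the score scales with
  the event count); non-convergence raises an error carrying the
  iteration trace, and rank-deficient designs raise an error naming the
  collinear terms.
* Covariates are centered at the dataset means before fitting; exported
  baselines refer to the centered reference and the centering vector is
  serialized with the fit (JSON: terms, coefficients, robust SEs,
  per-stratum baseline breakpoints/values).
* Strata with zero events get a flat baseline and a warning.
* Eligibility boundary conventions: a death exactly at `L` makes the
  patient ineligible; a death exactly at `L + w` is an event with
  `time = w`; a transplant at or before `L` excludes the patient from the
  age-`L` dataset, while deaths after a post-`L` transplant count as
  events. LOCF has no staleness limit, but per-variable lags are kept as
  diagnostics.

## Two-stage mixed model

For each landmark age, a trivariate linear mixed model is fitted by
maximum likelihood to all pre-`L` measurements of FEV1%, FVC% and weight
of the eligible cohort: outcome-specific fixed intercept and slope in
`(age − L)`, patient-level random intercepts and slopes jointly Gaussian
across the three outcomes (unstructured 6×6 covariance), independent
residuals with outcome-specific variances. Outcomes are z-scored on the
pre-`L` data before joint fitting (conditioning of the covariance) and
estimates are reported back on the original scales. Estimation is an
expectation–maximization iteration with a generalized-least-squares step
for the fixed effects; the log-likelihood increases at every step and a
non-positive-definite covariance iterate is repaired by diagonal
inflation. A REML criterion (direct optimization over a Cholesky
parameterization) is available behind a flag; ML is the default so that
likelihoods are comparable across models. Empirical-Bayes (BLUP)
estimates give each patient's fitted value and slope at `L`; these are
matrix (not scalar) shrinkage estimates, so a BLUP can slightly overshoot
the componentwise interval between the patient's own least-squares fit
and the population mean when intercepts and slopes are correlated.

## Evaluation

* **Discrimination** — truncated Harrell C-index at each horizon
  `τ ∈ {2, 5, 10}`: outcomes are administratively censored at `τ`, a pair
  is evaluable iff the smaller observed time is an event (at equal times,
  event vs censored), concordance compares predicted risks
  `1 − S(τ | L, x)`, risk ties count ½. Computed per landmark age and
  pooled over all records ("overall").
* **Prediction error** — IPCW Brier score at `τ`: deaths before `τ`
  weighted by `1/G(t−)`, survivors by `1/G(τ)`, censored-before-`τ`
  records weight 0, with `G` the Kaplan–Meier estimate of the censoring
  distribution per landmark dataset (pooled scores reuse the per-landmark
  weights). Percentage reduction is reported against the per-landmark
  Kaplan–Meier prediction: `100·(1 − Brier_model/Brier_KM)`.
* **Validation protocol** — an 80/20 split assigns whole patients (all of
  a patient's landmark rows together), so no individual informs both
  training and holdout; with large per-age patient counts the per-age
  record shares stay close to 80% (stratification in expectation). An
  exact record-level stratified split is available. Monte-Carlo
  cross-validation repeats an inner 80/20 patient split, refits, and
  summarizes metric means and SDs; failed repetitions are recorded and
  more than 50% failures abort.
* **Calibration** — decile bins of predicted survival vs Kaplan–Meier
  observed survival at the horizon with Greenwood standard errors.

## Synthetic registry generator

The generator emulates the structure of a national adult CF registry
observed 2005–2015: birth cohorts 1955–1997, infant-dominated diagnosis
ages with an adult-diagnosis tail, registry entry from 1995, and jittered
annual review times. Continuous variables (FEV1%, FVC%, height, weight)
follow latent linear-in-age trajectories with correlated patient-level
random intercepts and slopes plus measurement noise; seven binary states
(four infections, CF-related diabetes, pancreatic insufficiency, other
hospitalization) evolve as discrete-time Markov chains at review times;
IV-antibiotic days (hospital/home) are zero-inflated annual counts. The
death hazard is a piecewise-constant-in-age baseline times
`exp(Σ c_v·(x_v − ref_v) + γ·(year − 2010.5))` on the *current latent*
values, so LOCF predictors are error-prone proxies, as in reality.
Within each inter-review interval the covariates are held at their
interval-start values while the age baseline is integrated exactly
(piecewise-exact inversion sampling); with frozen covariates the model is
then exactly proportional hazards, which the recovery and
prediction-oracle checks exploit. Transplantation competes with death at
an intensity decreasing in current FEV1%; after transplant no further
reviews are generated and the death hazard switches to a constant. Loss
to follow-up is an independent constant hazard, 0 by default (mirroring
registries with near-complete follow-up). Default magnitudes are chosen
for adult-CF realism — population FEV1% ≈ 75 − 1.5/yr with
between-patient slope SD 1.5, ~15–25% ten-year mortality among adults,
higher FEV1%/FVC%/weight protective, B. cepacia, CF-related diabetes and
hospital IV days harmful — and are configuration, not claims.

A survival oracle returns the generative conditional probability
`S(L + t | state at L)` by integrating the configured hazard along the
conditional-mean latent path for continuous variables and marginalizing
the binary chains and IV redraws by Monte Carlo with a fixed inner seed.
The oracle assumes no transplantation (the landmark analyses count
post-transplant deaths as events of a single process, which a conditional
oracle of the death hazard alone does not represent).

What the generator does **not** emulate: pediatric (<18) dynamics,
nonlinear trajectories, reference-equation computation of
percent-predicted values from raw spirometry, treatment effects, calendar
shocks, or informative visit timing. Passing tests therefore demonstrate
correctness of the machinery under a known truth and qualitative
agreement with the patterns expected of these models on registry data,
not quantitative performance on any real registry.

## Validation experiments (problem sizes)

The test-suite experiments use the following sizes, chosen to give clear
signal at desk scale:

* Cox engine oracle: five hand-written datasets (≤8 subjects), brute-force
  likelihood maximization to 1e−6; cross-checks against lifelines on
  simulated stacks (coefficients, clustered robust SEs, Efron ties).
* Parameter recovery: 20 replicates of n = 2000 patients from a frozen-
  covariate (proportional-hazards) truth; every log hazard ratio within
  3 robust SEs on the reference replicate, with pooled 95%-interval
  coverage ≥ 90% across replicates.
* Prediction oracle: one landmark age with full ten-year follow-up for
  every subject (birth cohort 1975–76), n = 800,000, so estimator noise
  is small against the oracle tolerance 3·√(S(1−S)/100,000); ten
  covariate profiles spanning the 5th–95th linear-predictor percentiles
  at t = 2, 5, 10.
* Supermodel-vs-separate-fits pattern: 10 replicates of n = 2000 under
  the realistic configuration, patient-level 80/20 holdout scoring; the
  pooled supermodel should win on overall C-index and Brier (majority of
  replicates), with the Brier gap larger at landmark ages ≥ 40 than
  ≤ 28, and short horizons easier than long.
* Two-stage recovery: n = 1000, landmark age 30; BLUP slopes vs the
  generator's latent slopes, correlation > 0.8 per outcome.
* Calibration: outcomes redrawn from a fitted supermodel's own predicted
  curves; decile points within 3 binomial SEs in ≥ 9/10 deciles.

## Known limitations

* Variant 1 at sparse older landmark ages often cannot support the full
  predictor set (degenerate columns, separation); those ages fall back to
  the covariate-free Nelson–Aalen model and are flagged. This is the
  intended contrast with the supermodel, not an error state.
* The Cox engine does not handle time-dependent covariates within the
  post-landmark window, penalized fits, interval censoring or competing
  risks; the mixed model assumes linear trajectories and ignores
  informative dropout (patients' measurement histories end at death,
  which biases naive trajectory summaries — one reason the two-stage
  features add little here, as in the landmarking literature).
* Pooled "overall" metrics pool evaluable pairs/weights across landmark
  ages; a per-landmark-averaged alternative would weight ages
  differently.
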