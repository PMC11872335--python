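# Methods

This note documents the statistical machinery in `proimpute`: the data
model, the imputation and weighting procedures, the synthetic-trial
generator that the validation studies run on, and the numerical and
design choices that were genuinely open.

## Data model and estimand

The unit of analysis is the visit row: patient `i` at scheduled cycle `j`
(1 cycle = 3 weeks; cycles 1–10 tri-weekly, then alternate cycles to 40 by
default).  Rows exist exactly while the patient is alive, so death is
handled *structurally*: there is no such thing as a missing PRO after
death, and no imputation engine can create one — completed datasets have
bit-for-bit the same row set as their input.

The primary estimand is while-alive: for each cycle, the mean PRO among
patients alive at that cycle, always reported with the Kaplan–Meier
survival probability (a mean among survivors is uninterpretable without
knowing how many survive).  Composite ("carry 0 after death"),
while-on-treatment (rows at or before treatment discontinuation) and
responder-dichotomised variants are dataset transforms applied to each
completed copy before summarising, so pooling is unchanged.

Each row carries the patient's position on several timescales: forward
time `j`; time-to-death-or-censoring `s = S - j`; and time-distances to
progression (PD) and treatment discontinuation (TD), `t_pd` and `t_td`.
After the event, `t_td` is held at 0 and `t_pd` at -3 (configurable caps):
beyond those points there are almost no observed scores, so a constant
conditional effect is assumed rather than extrapolating a spline into
empty data space.  The event-by-now indicators `e_pd_now`, `e_td_now`
switch on at `j >= T_k` — the event cycle counts as post-event, matching
`t = 0` at the event — and never switch on at a censoring time.
Event/censoring status enters through interactions (e.g.
`rcs(s) x death_ind`), so the outcome's relation to a *death* time can
differ from its relation to a *censoring* time.

## Missingness assumptions

Missing scores are assumed missing at random given cycle, the observed
scores of the same patient, baseline covariates, and the occurrence and
timing of ICEs — including events observed *after* the missed visit.
This is exactly why a separate missing-data model is needed: conditioning
an analysis model on future events would wreck its interpretation, but an
imputation (or weight) model may and should use them.  Intermittent gaps
are allowed (missing at one cycle, observed later); censoring is assumed
non-informative, as in trials where censoring is administrative.

## Imputation engines

Quality of life is the only incomplete variable, so fully conditional
specification reduces to a single conditional model and no chained
iteration is required.

* **`lmm_normal`** (spec `model3`): linear mixed model with a random
  patient intercept, fitted by REML (statsmodels `MixedLM`) on observed
  rows.  A draw is: coefficients from N(beta_hat, Cov_hat); the patient's
  empirical-Bayes intercept plus a draw from its conditional variance
  `1/(1/tau^2 + n_i/sigma^2)` (patients with no observed score draw from
  the marginal N(0, tau^2) — their count is reported in the diagnostics);
  plus residual noise.  Variance-component uncertainty is *not*
  propagated; this understates between-imputation variance slightly and
  is a known approximation shared by common prediction-interval tools.
* **`lmm_pmm`** (spec `model2`, B-splines): same mixed model; each missing
  cell copies the observed value of one of `k_donors = 5` rows nearest in
  the coefficient-perturbed linear predictor (donor chosen uniformly).
  Imputed values therefore always lie in the observed support.
* **`boot_gam_normal` / `boot_gam_pmm`** (spec `model45`): fixed-effects
  additive (spline) model refitted on a patient-level bootstrap resample
  for every imputation; the clustered bootstrap carries the multilevel
  structure instead of a random effect.  Draws are normal residual draws
  or PMM against the original observed rows.
* **`naive_lmm`**: random intercept + spline of cycle + baseline
  covariates, no ICE information.  Kept as the benchmark whose upward
  bias the validation studies quantify.

The number of imputations defaults to the percentage of missing cells
(floor 5) — e.g. 40% missing -> M = 40.  Normal draws are not clipped to
the 0–100 scale by default (clipping biases means; PMM is the bounded
alternative); a `clip_to_scale` flag exists.

### Model formulas and fallbacks

All time variables enter through restricted cubic splines (natural
truncated-power basis, linear beyond the boundary knots) with four knots
placed 1, 4, 9 and 20 cycles before the event for the `t`/`s` variables.
Forward time has no event anchor; its knots are quantile-placed (5 knots).
When the rcs basis is too collinear for the mixed-model fit (condition
number above a threshold, default 1e8), the fitter switches to clamped
B-splines with the same interior knots and data-range boundary knots,
then — if REML still fails — drops the highest-order interaction; every
fallback is logged.  The `e_pd_now x pd_ind` interaction is structurally
aliased with its main effect (the indicator only fires for observed
events) and is pruned by the rank check with a diagnostic; genuinely
duplicated main-effect columns raise instead, naming the columns.  The
`t_pd x pd_ind` interaction is deliberately absent from `model3`: with
the event-anchored caps it over-parameterises the model.

## IPW route

The observation model is a logistic regression of the observedness flag
on the same covariate vocabulary as the imputation models (never the
outcome itself), fitted over all alive rows.  Weights are stabilised by
the marginal per-cycle observation fraction — making the observed-row
mean weight ~1 — and truncated at the 1st/99th percentiles (configurable;
absolute caps also supported).  Weighted per-cycle means with
patient-clustered sandwich SEs are the IPW-GEE estimates.  When a cycle's
observation probability approaches zero the weights explode and the
estimator destabilises; the stress study below measures this.

## Estimation and pooling

With cycle as a categorical covariate and independence working
correlation, the GEE point estimates are exactly the per-cycle (weighted)
sample means, and the cluster-robust variance for one row per patient per
cycle is `sum((w r)^2) / (sum w)^2`.  The implementation computes this
closed form and is cross-checked against statsmodels' GEE to 1e-10.
Rubin's rules combine the M per-imputation means: `T = W + (1 + 1/M) B`
with the classical large-sample df `(M-1)(1 + W/((1+1/M)B))^2`; when
B = 0 the interval is normal.  The motivating setting has hundreds of
patients, so the small-sample df adjustment is omitted.  Kaplan–Meier
curves use the hand-rolled product-limit estimator with Greenwood
variance (deaths before censorings at ties), validated against lifelines
to 1e-8.

## Synthetic-trial generator

The generator emulates the structure of a single-arm advanced-cancer
trial:

* survival: exponential (default rate 0.025/cycle, ~63% deaths by cycle
  40; Weibull optional), left-truncated at the first cycle (enrolled
  patients are alive at baseline) and administratively censored at 42
  cycles — survival follow-up extends past the last PRO cycle, as it does
  when survival is tracked after questionnaires stop;
* PD: exponential hazard 0.06/cycle, censored at end of follow-up; TD:
  PD plus an exponential lag (mean 3 cycles), observed for everyone and
  never after death;
* scores: baseline mean 65, slope -0.15/cycle, a 5-point drop after PD,
  and a 15-point linear decline over the final 6 cycles before death
  (decedents only); random intercept SD 10, residual SD 8; scores clipped
  to [0, 100];
* missingness (MAR_ICE): `logit P(miss) = -1.2 - 0.18 min(s, 8)
  + 0.7 e_pd_now + 5 e_td_now`, baseline always observed.  This gives a
  near-death odds ratio of ~3, ~90% missingness after TD, roughly 40%
  missing overall, and non-monotone gaps.

Effect sizes are the package's own choices, set once so the selection
biases are detectable at a few hundred patients.  What the generator does
*not* emulate: measurement floor/ceiling pile-up, informative censoring,
MNAR mechanisms, treatment arms, item-level missingness.  Passing the
validation studies therefore shows the machinery is correct under a
faithful MAR-given-ICE world, not that MAR holds in any real trial — the
assumption remains untestable and sensitivity analysis is still advised.

## Validation studies and problem sizes

`proimpute.study` runs the replicate experiments used by the test suite
and the acceptance script: 25 replicate trials of 500 patients on cycles
1–20 (MAR_ICE), `model3` with M = 15, plus a 10-replicate MCAR arm and a
12-replicate stress study where early PD/TD and strong post-TD
missingness push late-cycle observation fractions below 0.1.  These sizes
keep Monte-Carlo error well below the effects measured (truth curves use
30 000 simulated patients) while the full battery completes in a few
minutes on one CPU.  Measured under these conditions: ICE-aware pooled
means recover the truth within ~0.3 points wherever ≥30 patients remain
alive, 95% CI coverage ~0.96–0.99, available-case and naive-LMM analyses
sit 1–3 points above the ICE-aware estimates at late cycles (and agree
under MCAR), IPW tracks MI within the estimators' Monte-Carlo noise at
early cycles and its replicate spread is ~3–5x the MI spread once
observation probabilities collapse.

## Known limitations

* Variance-component uncertainty is not propagated into draws (slight CI
  undercoverage in principle; not visible at the studied sizes).
* Only the outcome may be incomplete; multi-variable chained equations
  are out of scope.
* Two non-terminal ICE types are wired end-to-end (PD, TD); the encoding
  generalises but engines are only exercised with K = 2.
* Single-arm analyses; a treatment term is a one-line spec extension but
  is untested here.
* The 2l.norm-style model with random effects on all predictors and
  heterogeneous within-patient variances is not implemented.
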