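# Methods

`artckd` implements a comparison of antiretroviral regimen types as risk
factors for chronic kidney disease (CKD) in longitudinal HIV-cohort data,
contrasting traditional Cox analyses with a marginal structural Cox model
(MSM) fitted by stabilized inverse-probability-of-treatment-and-censoring
weighting, plus doubly robust variants and negative-binomial models of
regimen discontinuation.  Because no patient-level cohort of this kind is
publicly available, the package ships a synthetic-cohort generator whose
statistical structure reproduces the phenomenon the causal analysis exists
for: treatment–confounder feedback between regimen exposure and renal
function.

## Cohort structure and preparation

Raw inputs are three delimited tables: a patient baseline table, a dated
laboratory table (serum creatinine, CD4, HIV-1 RNA) and a regimen-interval
table.  eGFR is computed with the IDMS-traceable four-variable MDRD equation
(175 · Scr^−1.154 · age^−0.203 · 0.742 if female); the race coefficient is
off by default (it is configurable) because ethnicity is not among the
baseline covariates.  Regimens are grouped into five mutually exclusive
categories by TDF content and anchor class: TDF+/rbPI, TDF+/NNRTI,
TDF−/rbPI, TDF−/NNRTI, and any other combination ("OTHER", used for
adjustment only; its hazard ratios are never reported).

Eligibility: ART initiation on or after 2004-01-01, a baseline eGFR from the
last creatinine in the closed 180-day window before initiation that is
strictly above 60 ml/min/1.73 m², and at least two post-initiation
creatinines.  A CKD event is the first eGFR below 60 confirmed by a later
sub-60 value at least 90 days afterwards with no intervening recovery
(the strictest reading of "confirmed"; `any_later_confirm=True` relaxes the
no-recovery requirement).  Event time is the first sub-60 measurement.

Follow-up is divided into fixed 30.44-day months anchored at ART start
(deterministic and locale-independent, unlike calendar months).  Each
person-month row carries last-value-carried-forward covariate categories
evaluated at the month start (CD4 ≤200 / 201–350 / >350; viral load ≤50 /
51–500 / >500; eGFR ≤50 / 51–70 / 71–90 / >90), the regimen category active
at the month start, the immediately preceding category, and event / switch /
censor indicators.  The printed CD4 band bounds "≤200" and "199–350" overlap
at 199–200, so the conventional split at 200/350 is used.  A switch is a
change of five-level category; within-category drug substitutions do not end
the on-initial state.  Administrative end of data (follow-up reaching the
database close date or the design's maximum duration) is distinguished from
earlier loss to follow-up heuristically from the exported tables; only the
latter feeds the censoring weight models, because a deterministic
administrative cut-off carries no information about the outcome and
modelling it as an event merely destabilises late-month weights.

## Traditional analyses

Standard proportional-hazards models of all CKD events use three exposure
codings: the initial category, the time-varying current category, and
current plus previous category.  Models are adjusted for the baseline
confounder set (age, CD4 nadir, baseline CD4, baseline log10 viral load,
baseline eGFR, calendar year linearly, sex, exposure group, HBV/HCV
co-infection, diabetes, hypertension, cardiovascular disease — continuous
terms linear) and for time-varying CD4 and viral-load categories.  Fits run
on the person-month counting-process data with Efron tie handling (the
monthly grid produces heavy ties, where Efron is markedly more accurate than
Breslow), Wald two-sided p-values, and patient-clustered sandwich standard
errors.

The Cox engine is implemented in the package (Newton–Raphson with step
halving on the weighted Efron partial likelihood, score-residual-based
clustered sandwich) because the analysis requires weighted fits with
clustered robust variances on start–stop data at Monte-Carlo replication
scale; its unweighted estimates, standard errors and log-likelihood are
verified against lifelines, its robust variance against `survival::coxph`
in R, and its maximiser against grid search on hand-checkable data.

## Causal analyses

The on-initial analysis censors patients at any category switch and
contrasts four estimators on identical risk sets: crude (covariate-free),
adjusted (full baseline plus time-varying CD4/VL), weighted (the MSM:
covariate-free but weighted by SW(t)), and doubly robust (weighted with the
adjusted covariate set; consistent if either the weight models or the
outcome model are correct).  Weights are normalised to mean one before
fitting (point estimates are scale-invariant); variances are
patient-clustered sandwiches.

Stabilized weights factor into three parts:

* **Baseline treatment**: a polytomous (multinomial) logistic model of the
  initial category on the baseline covariates with linear continuous terms;
  `sw_a` = marginal category share / fitted probability of the observed
  category.
* **Switching**: pooled logistic models on the on-initial person-months,
  stratified by initial category (falling back to a pooled fit with regimen
  main effects when a stratum has fewer than 5 events).  The denominator
  uses a restricted-cubic-spline (3 knots at the realised 10th/50th/90th
  percentiles) time-since-entry intercept, baseline covariate splines,
  calendar year linearly, and the time-varying CD4/VL/eGFR step functions.
* **Censoring**: the same pair of models for loss to follow-up.

SW(t) multiplies `sw_a` by the cumulative product over months of the ratio
of modelled probabilities of remaining unswitched and uncensored.

The outcome model defaults to the Cox partial-likelihood fit on the
person-month counting-process data; `CausalSpec(engine="pooled_logistic")`
fits the equivalent weighted discrete-time hazard model (logistic regression
on the same person-months with a 3-knot spline time intercept), whose
exposure coefficients agree with the Cox log-hazard ratios at the small
monthly risks seen here (equivalence is tested).

**Numerator specification.** The numerator models condition only on time
since entry (and treatment, via stratification).  A numerator that also
carries baseline covariates is only compatible with an outcome model that
adjusts for those covariates; pairing such a numerator with the
covariate-free weighted fit leaves residual covariate-differential censoring
in the pseudo-population and produced a measurable asymptotic bias when
tested on large simulated cohorts.  `stabilize_on_baseline=True` restores
the covariate-stabilized numerators for users fitting covariate-adjusted
MSMs.

Numerical safeguards: fitted probabilities are floored at 1e-6 before ratio
formation; quasi-separated logistic fits (coefficients beyond ±15 on
standardised covariates, or fitted hazards near 1 on non-event rows) are
refitted with a weak ridge penalty and logged.  Pooled logistic fits use a
Newton/IRLS solver (Cholesky normal equations, step halving) which reaches
machine-precision maxima and is roughly an order of magnitude faster than
generic quasi-Newton optimisers at replicate scale.  Symmetric percentile
truncation of SW(t) is available but off by default.  Weight diagnostics
report mean, SD, range, per-month quantiles and the extreme rows; under
correct specification the per-month mean of SW(t) stays within a few
percent of 1 across follow-up.

## Discontinuation models

Switch events and person-time are aggregated into regimen × eGFR-category
cells (optionally with binned baseline adjusters), for all regimen spells or
the initial spell only.  Negative-binomial (NB2, variance μ + αμ²)
regression with a log person-time offset estimates switching IRRs per eGFR
category (reference >90), fitted per regimen category.  α is estimated by
maximum likelihood with an α ≥ 0 boundary: when the NB likelihood does not
exceed the Poisson likelihood the constrained maximum is the Poisson fit,
which also makes the zero-dispersion limit exact.  If the dispersion
estimation fails outright, a Poisson fit with overdispersion-scaled standard
errors is reported and logged.  Cell-splitting invariance of the rate
structure is exact in the Poisson limit and holds to numerical tolerance
under estimated dispersion.

## The synthetic cohort

The generator's defaults are the study conditions and were calibrated once
to the cohort-level targets the analyses assume: initial-category shares
19/37/5/25/14%; baseline marginals with median (IQR) age 39 (32–47) years,
eGFR 101 (86–118), CD4 289 (175–392), nadir 264 (148–358), log10 VL 4.8
(4.2–5.3); 73% male; lab gaps log-normal with median 2.6 months (capped at
12); entry years 2004–2012 with a mid-2014 database lock and 0.8%/month
dropout giving a median follow-up near 3.5 years and about half of patients
ever switching; and a confirmed-CKD incidence near 10 per 1000 person-years
(intercept −8.4 on the monthly log-hazard scale).

Mechanics per month: latent eGFR mean-reverts (rate 1/6 per month) toward a
setpoint equal to baseline eGFR plus a regimen-specific offset
(`drift × taper`: −9 ml for TDF+/rbPI, −3.6 for TDF+/NNRTI, about −1 for
the rest), with innovation SD 1.5 — i.e. the renal effect of a regimen is
front-loaded over roughly the first year and then saturates, and switching
off TDF lets eGFR recover toward a better setpoint.  The front-loaded
(Ornstein–Uhlenbeck) form was chosen over a permanent linear drift because
it is the documented clinical pattern for TDF and because it makes the
marginal hazard ratio essentially time-constant after a short burn-in,
which is what lets a single Cox coefficient summarise the counterfactual
contrast.  Monthly switching log-odds are a regimen base rate (≈1.4%/month)
plus eGFR-category increments (0.35 / 0.8 / 1.1 for 71–90 / 51–70 / ≤50)
scaled per regimen — full strength for TDF+/rbPI, 0.4 for TDF+/NNRTI, zero
for non-TDF regimens — reflecting that clinician response to renal decline
concentrates on TDF with a boosted PI.  Post-switch categories move TDF
regimens to their TDF-free counterpart with probability 0.6, OTHER 0.2, and
the rest evenly.  The CKD outcome is a monthly Bernoulli hazard
exp(b0 + log HR[current regimen] + coef[eGFR category]) (coef 1.2 / 3.0 /
4.0 for 71–90 / 51–70 / ≤50), so a true direct regimen effect exists as an
explicit parameter and the eGFR term is the confounding pathway.  Default
direct log-HRs vs TDF+/NNRTI: 0.69 (TDF+/rbPI), 0.50 (TDF−/rbPI), 0.10
(TDF−/NNRTI), 0.30 (OTHER).

Both switching and the outcome hazard respond to the last *measured* eGFR
category, not the latent value: clinicians act on labs, and it makes the
last-value-carried-forward reconstruction in the analysis exactly the
information set of the generating process.  Two devices keep parameter
recovery well-posed: the latent eGFR is floored just above 60 until the
hazard mechanism fires, and an event forces a sub-60 lab at the event day
plus a confirming sub-60 lab 100 days later — so confirmed sub-60 pairs in
the exported files occur exactly when the hazard fired and the confirmation
rule recovers the true event month.  Every patient gets a pre-ART creatinine
and at least two post-ART labs so the default scenario induces no
eligibility exclusions.

Per-patient randomness is pre-drawn in blocks indexed by patient position
from a single seeded PCG64 stream, so a patient's trajectory depends only on
the seed and their index; identical configurations are byte-identical on
export.

What the generator does **not** emulate: within-category drug substitution,
pharmacokinetic detail, mortality as a competing risk, measurement error in
creatinine (available behind `measurement_noise_sd` but off by default),
informative (health-related) dropout, and spontaneous confirmed CKD through
lab noise alone.  Passing tests on this cohort therefore demonstrate that
the estimators recover known truths under the assumed data-generating
structure — not that any specific clinical finding generalises.

## The counterfactual oracle

`simulate_counterfactual_reference` re-runs the engine with switching and
dropout disabled at large n and fits an unadjusted proportional-hazards
model of the true event month on the initial category — the marginal hazard
ratios the weighted MSM targets.  The design's administrative (entry-year)
censoring is retained so the oracle averages any residual time-variation of
the hazard ratio over the same follow-up horizon as the study it
benchmarks.  At n = 50,000 the oracle's own Monte-Carlo standard error for
the main contrast is about 0.06 on the log scale, which bounds how finely
any recovery comparison against it can resolve.

## Monte-Carlo study sizes

The replicate studies use 100 replicates of n = 2,000 for effect recovery
and estimator comparison and 200 replicates for null calibration, with the
oracle at n = 50,000 — sizes at which one full replicate (simulation,
preparation, weight estimation, fitting) takes about two seconds, keeping
the whole suite comfortably reproducible on a single CPU.  At n = 2,000 the
default scenario yields roughly 45–60 on-initial events per replicate, so a
single replicate's weighted log-HR has standard error near 0.5; statements
about estimator bias are therefore made through medians across replicates.

## Known limitations

* With ~50 events per replicate, per-replicate error is noise-dominated:
  the crude and weighted estimators are highly correlated within a
  replicate, and the probability that the crude error exceeds the weighted
  error in absolute value is bounded near 0.6 even for a perfectly
  unbiased weighted estimator, however strongly the crude model is
  confounded.  Median bias across replicates is the sharper comparison
  (crude ≈ −0.2 on the log scale under the default scenario versus near 0
  for the MSM).
* The weighted estimator inherits the usual IPCW positivity sensitivity:
  long uninterrupted low-eGFR TDF exposure accumulates large (correct but
  variance-inflating) weights.  Under the default calibration SW(t) stays
  within about (0.1, 10) untruncated.
* Robust (sandwich) confidence intervals are slightly conservative at these
  event counts; null rejection rates sit near 5% (measured 5.5–7% over 200
  replicates).
* The engine assumes unit person-month intervals; general start–stop data
  must be expanded to the monthly grid first.
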