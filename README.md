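# artckd

Antiretroviral regimen type as a risk factor for chronic kidney disease:
traditional and marginal structural survival analyses for longitudinal HIV
cohorts, with a synthetic-cohort generator exhibiting treatment–confounder
feedback.

## The problem

In people living with HIV, tenofovir disoproxil fumarate (TDF) — especially
combined with a ritonavir-boosted protease inhibitor (rbPI) — is suspected
of raising the risk of chronic kidney disease (CKD, a confirmed eGFR below
60 ml/min/1.73 m²).  Estimating that risk from observational cohorts is hard
because renal function is a *time-varying confounder affected by prior
treatment*: TDF lowers eGFR, clinicians switch patients off TDF when eGFR
declines, and low eGFR predicts progression to CKD.  Naive regression that
conditions on follow-up behaviour is then biased, and the field's standard
answer is a marginal structural Cox model (MSM) fitted with stabilized
inverse-probability-of-treatment-and-censoring weights.

`artckd` implements that full comparison for five mutually exclusive regimen
categories (TDF±/rbPI, TDF±/NNRTI, other):

* cohort preparation — MDRD eGFR from dated creatinines, eligibility rules,
  confirmed-CKD detection, expansion into 30.44-day person-months with
  last-value-carried-forward covariate categories;
* traditional Cox models of all CKD events under initial / current /
  current-plus-previous exposure codings (Efron ties, counting-process data,
  patient-clustered robust variances);
* stabilized weights SW(t) = sw_A · Π_k P(stay|t)/P(stay|covariates, t) from
  a polytomous baseline treatment model and pooled logistic switch and
  censoring models with restricted-cubic-spline time intercepts;
* on-initial-regimen crude / adjusted / SW(t)-weighted (MSM) / doubly robust
  proportional-hazards estimators;
* negative-binomial models of regimen switching rates versus current eGFR
  category;
* a calibrated synthetic-cohort generator plus a counterfactual oracle
  (`simulate_counterfactual_reference`) returning the true marginal hazard
  ratios the MSM targets.

See `docs/methods.md` for model details, generator calibration and known
limitations.

## Worked example

```python
from artckd import (SimConfig, simulate_cohort, prepare_cohort,
                    StabilizedIPTW, fit_all_estimators, summarize_incidence)

cohort = simulate_cohort(SimConfig(n_patients=6301, seed=11))
prep = prepare_cohort(cohort.baseline, cohort.labs, cohort.regimens)
pm = prep["person_months"]

print(summarize_incidence(pm)["overall"])
iptw = StabilizedIPTW(pm).fit()
print(iptw.summary())
fits = fit_all_estimators(pm, iptw.weights)
print(fits["weighted"].summary())
```

which prints (seed 11):

```
{'events': 290, 'person_years': 26460.0, 'rate_per_1000py': 10.96,
 'ci_low': 9.73, 'ci_high': 12.30}
stabilized weights SW(t): mean 0.996, SD 0.403, range 0.15 to 8.60 over 200709 person-months
msm[weighted]: 187 events / 200709 person-months  loglik=-1537.686  converged=True
term                           ratio            95% CI        p
initial[TDF_rbPI]               2.83       (1.62-4.96) 0.000268
initial[noTDF_NNRTI]            0.21       (0.05-0.93)     0.04
initial[noTDF_rbPI]             1.68       (0.92-3.08)   0.0896
```

Read: the confirmed-CKD incidence is ~11 per 1000 person-years; the
stabilized weights centre on 1 with a modest spread (no truncation needed);
and under the default effect scenario the weighted MSM attributes a ~2.8-fold
CKD hazard to starting TDF with a boosted PI versus TDF with an NNRTI —
bracketing the generator's counterfactual marginal hazard ratio (~2.6 at
this scenario's parameters), where the crude on-initial model on the same
data is attenuated (hazard ratio 2.16) by eGFR-driven switching.

The same pipeline runs from the shell:

```bash
artckd run-all --out run1 --seed 11 --n-patients 6301
artckd report --results run1/results.json
```

External cohorts are read from `patients.csv`, `labs.csv`, `regimens.csv`
(schemas as written by `artckd simulate`).

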