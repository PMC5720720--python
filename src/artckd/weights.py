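"""Stabilized inverse-probability-of-treatment-and-censoring weights.

Three model layers produce the per-person-month stabilized weight SW(t):

1. a polytomous (multinomial) logistic model for the initial regimen category
   given baseline covariates with linear continuous terms, giving the
   baseline treatment component ``sw_a`` = marginal share / fitted
   probability of the observed category;
2. pooled logistic models on the on-initial person-month data for switching
   away from the initial regimen: the denominator has restricted-cubic-spline
   (3-knot, 10th/50th/90th percentile) time-since-entry intercepts, baseline
   covariate splines, calendar year, and the time-varying CD4/viral-load/eGFR
   step functions; the numerator of the default (covariate-free, marginal)
   MSM conditions on time since entry and treatment only;
3. the same pair for censoring (loss to follow-up).

SW(t) = sw_a * prod_{k<=t} [ (1-num_switch_k)(1-num_cens_k) /
                             ((1-den_switch_k)(1-den_cens_k)) ]

where each factor is the model's probability of remaining unswitched and
uncensored in month k.  Under correct specification E[SW(t)] is 1 at every
month; the diagnostics report mean, SD, range and the per-month
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from . import regimens as rg
from .egfr import CD4_CATEGORIES, EGFR_CATEGORIES, VL_CATEGORIES
from .splines import percentile_knots, rcs_basis

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-6

BASELINE_CONTINUOUS = [
    "age_at_start", "nadir_cd4", "baseline_cd4", "baseline_vl_log10", "baseline_egfr",
]
BASELINE_BINARY = [
    "female", "exposure_heterosexual", "exposure_other",
    "hbv", "hcv", "diabetes", "hypertension", "cvd",
]


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _spline_or_linear(x, name):
    """RCS columns for ``x``; degrade to the linear term when the realised
    10/50/90 percentiles are not strictly increasing.

    Inputs are winsorised at the 0.5/99.5 percentiles first: extreme
    covariate outliers otherwise dominate the linear extrapolation of the
    restricted basis and can drive fitted hazards toward 1, which the
    cumulative weight products amplify catastrophically.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = np.percentile(x, [0.5, 99.5])
    x = np.clip(x, lo, hi)
    try:
        knots = percentile_knots(x)
        basis = rcs_basis(x, knots)
        return basis, [name, f"{name}_rcs"]
    except ValueError:
        return x[:, None], [name]


_STEP_REFERENCE = {"cd4": ">350", "vl": "<=50", "egfr": ">90"}


def _step_dummies(cat_series, categories, name):
    cols, names = [], []
    vals = np.asarray(cat_series.astype(str))
    for c in categories:
        if c == _STEP_REFERENCE[name]:
            continue
        cols.append((vals == c).astype(float))
        names.append(f"{name}[{c}]")
    return np.column_stack(cols), names


def pooled_logistic_design(pm: pd.DataFrame, time_varying: bool,
                           baseline_covariates: bool = True):
    """Design matrix for the pooled logistic switch/censor models.

    Denominator models use ``time_varying=True, baseline_covariates=True``.
    The numerator of a *marginal* (covariate-free) MSM may condition only on
    time since entry and treatment, so it uses ``baseline_covariates=False``;
    numerators that also carry the baseline covariates are only valid when
    the final outcome model adjusts for those same covariates.
    """
    blocks = [np.ones((len(pm), 1))]
    names = ["intercept"]
    b, nm = _spline_or_linear(pm["month"].to_numpy(float), "month")
    blocks.append(b)
    names += nm
    if baseline_covariates:
        for c in BASELINE_CONTINUOUS:
            b, nm = _spline_or_linear(pm[c].to_numpy(float), c)
            blocks.append(b)
            names += nm
        yr = pm["year_of_start"].to_numpy(float)
        if np.ptp(yr) > 0:
            blocks.append(yr[:, None] - yr.mean())
            names.append("year_of_start")
        for c in BASELINE_BINARY:
            v = pm[c].to_numpy(float)
            if np.ptp(v) > 0:
                blocks.append(v[:, None])
                names.append(c)
    if time_varying:
        b, nm = _step_dummies(pm["cd4_cat"], list(CD4_CATEGORIES), "cd4")
        blocks.append(b)
        names += nm
        b, nm = _step_dummies(pm["vl_cat"], list(VL_CATEGORIES), "vl")
        blocks.append(b)
        names += nm
        b, nm = _step_dummies(pm["egfr_cat"], list(EGFR_CATEGORIES), "egfr")
        blocks.append(b)
        names += nm
    return np.column_stack(blocks), names


def _irls_logistic(X, y, ridge=0.0, max_iter=60, tol=1e-12):
    """Newton/IRLS logistic MLE; returns (coef, fitted probabilities).

    Solves the weighted normal equations by Cholesky each step with step
    halving; ``ridge`` adds an L2 penalty (per-coefficient) for the
    quasi-separation fallback.  Quadratic convergence gives fitted values at
    machine precision, which the saturated-cell identities rely on.
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    dev = -2 * (y @ np.log(prob) + (1 - y) @ np.log1p(-prob))
    # the intercept (first column) is never penalised
    pen = np.full(p, ridge)
    pen[0] = 0.0
    P = np.diag(pen)
    for _ in range(max_iter):
        w = prob * (1 - prob) + 1e-12
        g = X.T @ (y - prob) - pen * beta
        H = (X.T * w) @ X + P
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), g)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta = np.clip(X @ cand, -35, 35)
            prob_new = 1.0 / (1.0 + np.exp(-eta))
            with np.errstate(divide="ignore"):
                dev_new = -2 * (y @ np.log(prob_new) + (1 - y) @ np.log1p(-prob_new)) \
                    + pen @ cand**2
            if np.isfinite(dev_new) and dev_new <= dev + 1e-10:
                break
            scale *= 0.5
        beta, prob, delta = cand, prob_new, dev - dev_new
        dev = dev_new
        if abs(delta) < tol * max(1.0, abs(dev)):
            break
    return beta, prob


def _fit_pooled_logistic(X, y, tol=1e-12):
    """Maximum-likelihood logistic fit returning in-sample hazard
    probabilities, with a weak-ridge fallback under quasi-separation."""
    if y.sum() == 0 or y.sum() == len(y):
        return np.clip(np.full(len(y), y.mean()), PROB_FLOOR, 1 - PROB_FLOOR)
    # standardise non-constant columns for conditioning; keep the intercept
    keep = [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    Xk = X[:, keep]
    mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
    Xk = np.column_stack([np.ones(len(y)), (Xk - mu) / sd])
    beta, p = _irls_logistic(Xk, y, tol=tol)
    # monthly switch/censor hazards are small; fitted values near 1 anywhere
    # indicate (quasi-)separation and would explode the weight ratios
    ridge = 0.1
    while (np.abs(beta).max() > 15 or p.max() > 0.5) and ridge < 1e3:
        # quasi-separation: refit with an (escalating) ridge so monthly
        # hazards stay in a plausible range
        logger.warning("quasi-separation in pooled logistic fit; "
                       "applying ridge penalty %.1f", ridge)
        beta, p = _irls_logistic(Xk, y, ridge=ridge, tol=tol)
        ridge *= 10
    return np.clip(p, PROB_FLOOR, 1 - PROB_FLOOR)


# ---------------------------------------------------------------------------
# baseline polytomous treatment model
# ---------------------------------------------------------------------------

def fit_baseline_treatment_model(patients: pd.DataFrame):
    """Per-patient baseline stabilized treatment weight ``sw_a``.

    ``patients`` needs one row per patient with the baseline covariates and
    ``initial_regimen``.  Continuous covariates enter linearly.  Returns
    ``(sw_a: pd.Series indexed by patient_id, info: dict)``.
    """
    cont = BASELINE_CONTINUOUS + ["year_of_start"]
    Xc = patients[cont].to_numpy(float)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = (Xc - Xc.mean(axis=0)) / sd
    Xb = patients[BASELINE_BINARY].to_numpy(float)
    X = np.column_stack([Xc, Xb])
    y = patients["initial_regimen"].to_numpy()

    classes, counts = np.unique(y, return_counts=True)
    marginal = dict(zip(classes, counts / counts.sum()))
    if len(classes) < 2:
        sw_a = pd.Series(1.0, index=patients["patient_id"])
        return sw_a, {"marginal": marginal, "note": "single treatment class"}

    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(X, y)
    if np.abs(clf.coef_).max() > 15:  # quasi-separation guard
        logger.warning("quasi-separation in polytomous treatment model; "
                       "applying weak ridge penalty")
        clf = LogisticRegression(C=10.0, solver="lbfgs", max_iter=5000, tol=1e-10)
        clf.fit(X, y)
    proba = clf.predict_proba(X)
    col = {c: j for j, c in enumerate(clf.classes_)}
    den = np.array([proba[i, col[y[i]]] for i in range(len(y))])
    n_floored = int((den < PROB_FLOOR).sum())
    if n_floored:
        logger.warning("%d fitted treatment probabilities below %.0e floored",
                       n_floored, PROB_FLOOR)
    den = np.clip(den, PROB_FLOOR, None)
    num = np.array([marginal[c] for c in y])
    sw_a = pd.Series(num / den, index=patients["patient_id"], name="sw_a")
    return sw_a, {"marginal": marginal, "n_floored": n_floored, "model": clf}


# ---------------------------------------------------------------------------
# pooled switch / censor models
# ---------------------------------------------------------------------------

def fit_switch_and_censor_models(pm_on_initial: pd.DataFrame, stratify: bool = True,
                                 min_stratum_events: int = 5,
                                 stabilize_on_baseline: bool = False) -> pd.DataFrame:
    """Monthly switch/censor hazard probabilities, numerator and denominator.

    Fits are stratified by initial regimen category; a stratum with fewer
    switch (censor) events than ``min_stratum_events`` falls back to a pooled
    fit with regimen main effects.  Returns the input frame with columns
    ``p_switch_num/den`` and ``p_cens_num/den`` (monthly hazards).
    """
    pm = pm_on_initial.reset_index(drop=True).copy()
    y_sw = pm["switched_this_month"].to_numpy(float)
    y_cs = pm["censored_this_month"].to_numpy(float)
    out = {
        "p_switch_den": np.empty(len(pm)), "p_switch_num": np.empty(len(pm)),
        "p_cens_den": np.empty(len(pm)), "p_cens_num": np.empty(len(pm)),
    }

    strata = []
    if stratify:
        groups = pm.groupby("initial_regimen", observed=True).indices
        small = [c for c, idx in groups.items()
                 if y_sw[idx].sum() < min_stratum_events
                 or y_cs[idx].sum() < min_stratum_events]
        if small:
            logger.warning("strata %s below %d events; pooling all strata",
                           small, min_stratum_events)
            strata = [np.arange(len(pm))]
        else:
            strata = [np.asarray(idx) for idx in groups.values()]
    else:
        strata = [np.arange(len(pm))]
    pooled = len(strata) == 1 and len(pm["initial_regimen"].unique()) > 1

    for idx in strata:
        sub = pm.iloc[idx]
        Xden, _ = pooled_logistic_design(sub, time_varying=True)
        Xnum, _ = pooled_logistic_design(sub, time_varying=False,
                                         baseline_covariates=stabilize_on_baseline)
        if pooled:
            reg_d = pd.get_dummies(sub["initial_regimen"], drop_first=True).to_numpy(float)
            Xden = np.column_stack([Xden, reg_d])
            Xnum = np.column_stack([Xnum, reg_d])
        out["p_switch_den"][idx] = _fit_pooled_logistic(Xden, y_sw[idx])
        out["p_switch_num"][idx] = _fit_pooled_logistic(Xnum, y_sw[idx])
        out["p_cens_den"][idx] = _fit_pooled_logistic(Xden, y_cs[idx])
        out["p_cens_num"][idx] = _fit_pooled_logistic(Xnum, y_cs[idx])

    for k, v in out.items():
        pm[k] = v
    return pm


# ---------------------------------------------------------------------------
# stabilized weights
# ---------------------------------------------------------------------------

def compute_stabilized_weights(sw_a: pd.Series, pm_with_probs: pd.DataFrame,
                               truncate_pct: float | None = None) -> pd.DataFrame:
    """Cumulative stabilized weight per on-initial person-month.

    ``truncate_pct`` (e.g. 1.0) symmetrically truncates SW(t) at the given
    and complementary percentiles; off by default.
    """
    pm = pm_with_probs.sort_values(["patient_id", "month"], kind="stable").copy()
    for c in ("p_switch_den", "p_cens_den"):
        bad = pm[c] >= 1.0
        if bad.any():
            row = pm[bad].iloc[0]
            raise ValueError(
                f"zero remain-probability denominator at patient {row['patient_id']} "
                f"month {int(row['month'])}"
            )
    ratio = ((1 - pm["p_switch_num"]) * (1 - pm["p_cens_num"])
             / ((1 - pm["p_switch_den"]) * (1 - pm["p_cens_den"])))
    pm["cum_ratio"] = ratio.groupby(pm["patient_id"]).cumprod()
    pm["sw_a"] = pm["patient_id"].map(sw_a)
    pm["sw_t"] = pm["sw_a"] * pm["cum_ratio"]
    if truncate_pct is not None:
        lo, hi = np.percentile(pm["sw_t"], [truncate_pct, 100 - truncate_pct])
        pm["sw_t"] = pm["sw_t"].clip(lo, hi)
    cols = ["patient_id", "month", "sw_a",
            "p_switch_num", "p_switch_den", "p_cens_num", "p_cens_den", "sw_t"]
    return pm[cols + [c for c in ("event",) if c in pm.columns]]


def weight_diagnostics(weights: pd.DataFrame, n_extreme: int = 10) -> dict:
    """Summary statistics plus per-month box-plot-ready quantiles."""
    sw = weights["sw_t"].to_numpy(float)
    per_month = weights.groupby("month")["sw_t"].quantile(
        [0.01, 0.25, 0.50, 0.75, 0.99]).unstack()
    per_month.columns = [f"q{int(100 * q)}" for q in per_month.columns]
    per_month["mean"] = weights.groupby("month")["sw_t"].mean()
    extreme = weights.reindex(
        weights["sw_t"].sub(1).abs().sort_values(ascending=False).index
    ).head(n_extreme)[["patient_id", "month", "sw_t"]]
    return {
        "mean": float(sw.mean()),
        "sd": float(sw.std(ddof=1)) if len(sw) > 1 else 0.0,
        "min": float(sw.min()),
        "max": float(sw.max()),
        "n": int(len(sw)),
        "per_month": per_month,
        "extreme": extreme,
    }


def plot_weight_boxes(weights: pd.DataFrame, ax=None, max_months: int = 60):
    """Box plots of SW(t) over follow-up months."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    months = sorted(m for m in weights["month"].unique() if m <= max_months)
    data = [weights.loc[weights["month"] == m, "sw_t"].to_numpy() for m in months]
    ax.boxplot(data, positions=months, showfliers=False, widths=0.6)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("month since ART initiation")
    ax.set_ylabel("stabilized weight SW(t)")
    return ax


# ---------------------------------------------------------------------------
# model-object surface
# ---------------------------------------------------------------------------

@dataclass
class IPTWResults:
    """Fitted stabilized weights with diagnostics."""

    weights: pd.DataFrame
    sw_a: pd.Series
    info: dict = field(default_factory=dict)

    def diagnostics(self) -> dict:
        return weight_diagnostics(self.weights)

    def summary(self) -> str:
        d = self.diagnostics()
        return (
            "stabilized weights SW(t): "
            f"mean {d['mean']:.3f}, SD {d['sd']:.3f}, "
            f"range {d['min']:.2f} to {d['max']:.2f} over {d['n']} person-months"
        )


class StabilizedIPTW:
    """Weight model for the marginal structural analysis.

    Parameters
    ----------
    person_months : DataFrame
        Full person-month table (the model restricts to on-initial rows).
    stratify : bool
        Fit switch/censor models separately per initial regimen category.
    truncate_pct : float or None
        Optional symmetric percentile truncation of SW(t); default off.
    """

    def __init__(self, person_months: pd.DataFrame, stratify: bool = True,
                 truncate_pct: float | None = None,
                 stabilize_on_baseline: bool = False):
        self.person_months = person_months
        self.stratify = stratify
        self.truncate_pct = truncate_pct
        self.stabilize_on_baseline = stabilize_on_baseline

    def fit(self) -> IPTWResults:
        pm = self.person_months
        on_init = pm[pm["on_initial"]].copy()
        baseline = on_init[on_init["month"] == on_init.groupby("patient_id")["month"]
                           .transform("min")]
        baseline = baseline.drop_duplicates("patient_id")
        sw_a, info = fit_baseline_treatment_model(baseline)
        probs = fit_switch_and_censor_models(
            on_init, stratify=self.stratify,
            stabilize_on_baseline=self.stabilize_on_baseline)
        weights = compute_stabilized_weights(sw_a, probs, truncate_pct=self.truncate_pct)
        return IPTWResults(weights=weights, sw_a=sw_a, info=info)
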