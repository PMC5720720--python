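"""Causal analyses of CKD on the initial regimen, censored at any switch.

Four estimators share the same on-initial person-month risk sets:

- ``crude``: unweighted, covariate-free proportional-hazards fit on the
  initial-regimen indicators;
- ``adjusted``: adds the full baseline confounder set plus time-varying
  CD4/viral-load categories (a conditional estimate);
- ``weighted``: the marginal structural model — covariate-free fit weighted
  by the stabilized weights SW(t), which undo both the baseline treatment
  assignment and the eGFR-driven informative censoring-by-switching;
- ``doubly_robust``: the SW(t)-weighted fit with the adjusted covariate set,
  consistent if either the weight models or the outcome model is correct.

All variants report patient-clustered sandwich (robust) standard errors.
Weights are normalized to mean one before fitting (point estimates are
invariant to the scale of the weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regimens as rg
from .cox import fit_cox_person_months
from .results import FitResult
from .survival import adjustment_design, regimen_indicators

ESTIMATORS = ("crude", "adjusted", "weighted", "doubly_robust")


@dataclass
class CausalSpec:
    """Which Table-3-style estimator to fit.

    ``engine`` selects the outcome model: ``"cox"`` (default) maximises the
    weighted Efron partial likelihood on the person-month counting-process
    data; ``"pooled_logistic"`` fits the equivalent weighted discrete-time
    hazard model (logistic regression on the same person-months with a
    3-knot restricted-cubic-spline time intercept), whose coefficients
    approach the Cox log-hazard ratios as the monthly risk becomes small.
    """

    estimator: str = "weighted"
    reference_category: str = rg.REFERENCE_CATEGORY
    engine: str = "cox"

    def __post_init__(self):
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.engine not in ("cox", "pooled_logistic"):
            raise ValueError("engine must be 'cox' or 'pooled_logistic'")


def _weighted_logistic_cluster(X, y, w, cluster, names):
    """Weighted logistic MLE with a cluster-robust sandwich covariance."""
    from scipy.optimize import minimize

    def negll_grad(beta):
        eta = np.clip(X @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        nll = -np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))
        grad = -X.T @ (w * (y - p))
        return nll, grad

    res = minimize(negll_grad, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    beta = res.x
    eta = np.clip(X @ beta, -35, 35)
    p = 1.0 / (1.0 + np.exp(-eta))
    A = (X.T * (w * p * (1 - p))) @ X
    Ainv = np.linalg.pinv(A)
    scores = X * (w * (y - p))[:, None]
    codes, inv = np.unique(cluster, return_inverse=True)
    U = np.zeros((len(codes), X.shape[1]))
    np.add.at(U, inv, scores)
    robust = Ainv @ (U.T @ U) @ Ainv
    return beta, np.sqrt(np.clip(np.diag(Ainv), 0, None)), \
        np.sqrt(np.clip(np.diag(robust), 0, None)), -res.fun, res.success


def fit_msm(person_months: pd.DataFrame, weights: pd.DataFrame | None,
            spec: CausalSpec) -> FitResult:
    """Fit one on-initial-regimen estimator.

    ``weights`` is the WeightSet frame (patient_id, month, sw_t) and is
    required for the weighted and doubly robust estimators.
    """
    pm = person_months[person_months["on_initial"]].reset_index(drop=True)
    needs_w = spec.estimator in ("weighted", "doubly_robust")
    if needs_w:
        if weights is None:
            raise ValueError(f"{spec.estimator} estimator requires a WeightSet")
        pm = pm.merge(weights[["patient_id", "month", "sw_t"]],
                      on=["patient_id", "month"], how="left", validate="one_to_one")
        if pm["sw_t"].isna().any():
            missing = pm[pm["sw_t"].isna()].iloc[0]
            raise ValueError(
                f"WeightSet does not cover patient {missing['patient_id']} "
                f"month {int(missing['month'])}"
            )
        if (pm["sw_t"] <= 0).any():
            raise ValueError("weights must be strictly positive")
        w = pm["sw_t"].to_numpy(float)
        w = w / w.mean()
    else:
        w = None

    X, names = regimen_indicators(pm["initial_regimen"], spec.reference_category,
                                  "initial")
    suppressed = [n for n in names if f"[{rg.OTHER}]" in n]
    if spec.estimator in ("adjusted", "doubly_robust"):
        Xa, na = adjustment_design(pm, include_time_varying=True)
        X = np.column_stack([X, Xa])
        suppressed += na
        names = names + na

    if spec.engine == "pooled_logistic":
        from .splines import percentile_knots, rcs_basis

        month = pm["month"].to_numpy(float)
        tb = rcs_basis(month, percentile_knots(month))
        Xp = np.column_stack([np.ones(len(pm)), tb, X])
        np_names = ["intercept", "month", "month_rcs"] + names
        beta, se, rse, llf, ok = _weighted_logistic_cluster(
            Xp, pm["event"].to_numpy(float),
            np.ones(len(pm)) if w is None else w,
            pm["patient_id"].to_numpy(), np_names)
        res = FitResult.from_estimates(
            np_names, beta, se, robust_se=rse,
            suppressed=suppressed + ["intercept", "month", "month_rcs"],
            n_obs=len(pm), n_events=int(pm["event"].sum()), loglik=llf,
            converged=bool(ok), model=f"msm[{spec.estimator}, pooled logistic]",
        )
        return res

    fit = fit_cox_person_months(
        X, pm["month"].to_numpy(int), pm["event"].to_numpy(bool),
        weights=w, cluster=pm["patient_id"].to_numpy(), names=names,
    )
    return fit.to_result(model=f"msm[{spec.estimator}]", suppressed=suppressed)


def fit_all_estimators(person_months: pd.DataFrame,
                       weights: pd.DataFrame | None) -> dict[str, FitResult]:
    """Crude / adjusted / weighted / doubly robust fits, Table-3 style."""
    out = {}
    for est in ESTIMATORS:
        if est in ("weighted", "doubly_robust") and weights is None:
            continue
        out[est] = fit_msm(person_months, weights, CausalSpec(estimator=est))
    return out


# ---------------------------------------------------------------------------
# replicate comparison harness
# ---------------------------------------------------------------------------

def run_replicate(config, estimators=ESTIMATORS, stratify_weights: bool = True):
    """Simulate one cohort under ``config``, prepare it, fit the requested
    estimators; returns ``{estimator: FitResult}``."""
    from .prep import prepare_cohort
    from .simulate import generate_baseline, simulate_followup
    from .weights import StabilizedIPTW

    cohort = simulate_followup(generate_baseline(config), config)
    prep = prepare_cohort(cohort.baseline, cohort.labs, cohort.regimens)
    pm = prep["person_months"]
    weights = None
    if any(e in ("weighted", "doubly_robust") for e in estimators):
        weights = StabilizedIPTW(pm, stratify=stratify_weights).fit().weights
    out = {}
    for est in estimators:
        out[est] = fit_msm(pm, weights, CausalSpec(estimator=est))
    out["_weights"] = weights
    out["_person_months"] = pm
    return out


def compare_estimators(config, n_replicates: int, seed: int,
                       estimators=ESTIMATORS,
                       contrast: str = rg.TDF_RBPI,
                       oracle_log_hr: float | None = None,
                       n_oracle: int = 50_000) -> pd.DataFrame:
    """Monte-Carlo comparison of the estimators against the counterfactual
    oracle: per-replicate log-HR estimates and robust SEs for one contrast.

    Returns a tidy frame with one row per (replicate, estimator) and the
    oracle log HR in the ``oracle`` column; summarise with
    :func:`summarize_comparison`.
    """
    from .simulate import simulate_counterfactual_reference

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if oracle_log_hr is None:
        oracle = simulate_counterfactual_reference(config.replace(seed=seed),
                                                   n_large=n_oracle)
        oracle_log_hr = oracle["log_hr"][contrast]
    term = f"initial[{contrast}]"
    rows = []
    for r in range(n_replicates):
        rep_cfg = config.replace(seed=(seed + 10_007 * (r + 1)) % (2**31 - 1))
        fits = run_replicate(rep_cfg, estimators=estimators)
        w = fits.get("_weights")
        wstats = {}
        if w is not None:
            sw = w["sw_t"].to_numpy()
            wstats = {"sw_mean": float(sw.mean()), "sw_sd": float(sw.std(ddof=1)),
                      "sw_min": float(sw.min()), "sw_max": float(sw.max())}
        for est in estimators:
            res = fits[est]
            rows.append({
                "replicate": r,
                "estimator": est,
                "log_hr": res.coef(term),
                "robust_se": float(res.table.loc[term, "robust_se"]),
                "n_events": res.n_events,
                "oracle": oracle_log_hr,
                **wstats,
            })
    return pd.DataFrame(rows)


def summarize_comparison(comparison: pd.DataFrame) -> pd.DataFrame:
    """Per-estimator Monte-Carlo bias, RMSE, empirical and mean robust SE,
    and 95% CI coverage of the oracle value."""
    def _summ(g):
        err = g["log_hr"] - g["oracle"]
        cover = (np.abs(err) <= 1.96 * g["robust_se"]).mean()
        return pd.Series({
            "mean_log_hr": g["log_hr"].mean(),
            "median_log_hr": g["log_hr"].median(),
            "bias": err.mean(),
            "median_bias": err.median(),
            "rmse": float(np.sqrt((err**2).mean())),
            "empirical_se": g["log_hr"].std(ddof=1),
            "mean_robust_se": g["robust_se"].mean(),
            "coverage": cover,
            "n_replicates": len(g),
        })
    return comparison.groupby("estimator").apply(_summ, include_groups=False)
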