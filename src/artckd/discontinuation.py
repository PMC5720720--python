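"""Regimen discontinuation rates versus current eGFR (negative binomial).

Switch events and person-time are aggregated into (regimen category x eGFR
category) cells — either for every regimen spell (``any_regimen``) or for the
initial regimen only (``initial_only``) — and a negative-binomial (NB2,
variance mu + alpha*mu^2) regression with a log person-time offset estimates
the incidence rate ratio of switching away per eGFR category, reference
``>90``, separately per regimen category.  Baseline adjusters enter linearly
after within-cell binning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from . import regimens as rg
from .egfr import EGFR_CATEGORIES
from .results import FitResult

logger = logging.getLogger(__name__)

#: baseline adjusters binned into cells (quartile bins for continuous ones)
DEFAULT_ADJUSTERS = ("age_at_start", "baseline_egfr", "female")


def build_switch_counts(person_months: pd.DataFrame, mode: str = "any_regimen",
                        adjusters=DEFAULT_ADJUSTERS) -> pd.DataFrame:
    """Aggregate person-months into switch-count cells.

    Each person-month contributes one month of exposure to the cell of the
    regimen active at its start and the current eGFR category; switch events
    are assigned to the cell active at the switch.
    """
    if mode not in ("any_regimen", "initial_only"):
        raise ValueError("mode must be 'any_regimen' or 'initial_only'")
    pm = person_months if mode == "any_regimen" else person_months[
        person_months["on_initial"]]
    pm = pm.copy()
    keys = ["current_regimen", "egfr_cat"]
    for a in adjusters or ():
        if a not in pm.columns:
            continue
        v = pm[a]
        if v.nunique() > 8:
            pm[f"{a}_bin"] = pd.qcut(v, 4, duplicates="drop").astype(str)
            keys.append(f"{a}_bin")
        else:
            keys.append(a)
    g = pm.groupby(keys, observed=True)
    out = g.agg(
        switch_count=("switched_this_month", "sum"),
        person_time=("switched_this_month", "size"),
    ).reset_index()
    out["switch_count"] = out["switch_count"].astype(int)
    return out


def _fit_one_negbin(y, X, offset_log, names):
    pois0 = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset_log).fit()
    model = NegativeBinomial(y, X, loglike_method="nb2", offset=offset_log)
    try:
        start = np.append(np.asarray(pois0.params), 0.05)
        res = model.fit(start_params=start, disp=False, maxiter=500)
        if not res.mle_retvals.get("converged", True) or not np.isfinite(res.params).all():
            raise RuntimeError("negative binomial did not converge")
        if res.llf <= pois0.llf + 1e-8 or res.params[-1] < 1e-6:
            # the dispersion MLE sits on the alpha = 0 boundary: the
            # constrained maximum is the Poisson fit
            params = np.asarray(pois0.params)
            bse = np.asarray(pois0.bse)
            alpha, llf, method = 0.0, float(pois0.llf), "negbin_boundary"
        else:
            params = res.params[:-1]  # last parameter is alpha
            bse = res.bse[:-1]
            alpha = float(res.params[-1])
            llf = float(res.llf)
            method = "negbin"
    except Exception:
        logger.warning("NB dispersion estimation failed; Poisson with "
                       "overdispersion-scaled SEs")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset_log).fit()
        scale = max(1.0, float(pois.pearson_chi2 / pois.df_resid)) if pois.df_resid > 0 else 1.0
        params = np.asarray(pois.params)
        bse = np.asarray(pois.bse) * np.sqrt(scale)
        alpha, llf, method = 0.0, float(pois.llf), "poisson_scaled"
    return params, bse, alpha, llf, method


def fit_negbin_irr(records: pd.DataFrame, adjusters=DEFAULT_ADJUSTERS,
                   per_regimen: bool = True) -> dict[str, FitResult]:
    """IRRs of switching per eGFR category (reference >90), per regimen.

    ``records`` is the output of :func:`build_switch_counts`.  Returns a dict
    mapping regimen category to a :class:`FitResult` whose terms are the
    non-reference eGFR categories.
    """
    results = {}
    groups = records.groupby("current_regimen", observed=True) if per_regimen \
        else [("all", records)]
    for cat, sub in groups:
        cats_present = [c for c in EGFR_CATEGORIES if c != ">90"
                        and (sub["egfr_cat"].astype(str) == c).any()]
        nz = (sub["person_time"] > 0)
        sub = sub[nz]
        if sub["egfr_cat"].astype(str).nunique() < 2:
            logger.warning("regimen %s: fewer than 2 eGFR categories with "
                           "person-time; skipped", cat)
            continue
        blocks = [np.ones((len(sub), 1))]
        names = ["intercept"]
        vals = sub["egfr_cat"].astype(str).to_numpy()
        for c in cats_present:
            blocks.append((vals == c).astype(float)[:, None])
            names.append(f"egfr[{c}]")
        for col in sub.columns:
            if col.endswith("_bin"):
                d = pd.get_dummies(sub[col], drop_first=True)
                blocks.append(d.to_numpy(float))
                names += [f"{col}={c}" for c in d.columns]
            elif col in (adjusters or ()) and col not in ("current_regimen", "egfr_cat"):
                v = sub[col].to_numpy(float)
                if np.ptp(v) > 0:
                    blocks.append(v[:, None])
                    names.append(col)
        X = np.column_stack(blocks)
        y = sub["switch_count"].to_numpy(float)
        off = np.log(sub["person_time"].to_numpy(float))
        params, bse, alpha, llf, method = _fit_one_negbin(y, X, off, names)
        res = FitResult.from_estimates(
            names, params, bse,
            suppressed=[n for n in names if not n.startswith("egfr[")],
            n_obs=int(sub["person_time"].sum()),
            n_events=int(y.sum()), loglik=llf,
            model=f"negbin switch IRR [{cat}]",
        )
        res.diagnostics.update({"alpha": alpha, "method": method})
        results[str(cat)] = res
    return results


def irr_table(results: dict[str, FitResult]) -> pd.DataFrame:
    """Tidy regimen x eGFR-category IRR table."""
    rows = []
    for cat, res in results.items():
        for term, r in res.table.iterrows():
            if term.startswith("egfr["):
                rows.append({
                    "regimen": cat,
                    "egfr_cat": term[5:-1],
                    "irr": r["ratio"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                })
    return pd.DataFrame(rows)


def plot_irr(results: dict[str, FitResult], ax=None):
    """Forest-style plot of switching IRRs by eGFR category per regimen."""
    import matplotlib.pyplot as plt

    tab = irr_table(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    regimens = list(dict.fromkeys(tab["regimen"]))
    cats = [c for c in EGFR_CATEGORIES if c != ">90"]
    for j, reg in enumerate(regimens):
        sub = tab[tab["regimen"] == reg].set_index("egfr_cat")
        xs = [i + j * 0.12 for i in range(len(cats))]
        ys = [sub["irr"].get(c, np.nan) for c in cats]
        lo = [sub["ci_low"].get(c, np.nan) for c in cats]
        hi = [sub["ci_high"].get(c, np.nan) for c in cats]
        ax.errorbar(xs, ys, yerr=[np.subtract(ys, lo), np.subtract(hi, ys)],
                    fmt="o", capsize=3, label=reg)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(range(len(cats)), cats)
    ax.set_yscale("log")
    ax.set_xlabel("current eGFR category (reference >90)")
    ax.set_ylabel("IRR of switching away")
    ax.legend(fontsize=8)
    return ax
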