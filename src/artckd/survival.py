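"""Traditional proportional-hazards analyses of all CKD events.

Three exposure codings of the five-level regimen category are supported:
``initial`` (the regimen at ART start, fixed over follow-up), ``current``
(time-varying category) and ``current_plus_previous`` (time-varying current
category plus the category immediately preceding it).  Fits run on the
person-month counting-process data with Efron tie handling; the OTHER
category is always included for adjustment but its hazard ratio is
suppressed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import regimens as rg
from .cox import fit_cox_person_months
from .egfr import CD4_CATEGORIES, VL_CATEGORIES
from .results import FitResult

MONTH_DAYS = 30.44

ADJUSTMENT_CONTINUOUS = [
    "age_at_start", "nadir_cd4", "baseline_cd4", "baseline_vl_log10",
    "baseline_egfr", "year_of_start",
]
ADJUSTMENT_BINARY = [
    "female", "exposure_heterosexual", "exposure_other",
    "hbv", "hcv", "diabetes", "hypertension", "cvd",
]


@dataclass
class CoxSpec:
    """Specification of one traditional Cox analysis."""

    exposure_coding: str = "initial"  # initial | current | current_plus_previous
    censor_at_switch: bool = False
    adjusted: bool = True
    reference_category: str = rg.REFERENCE_CATEGORY
    include_time_varying: bool = True  # CD4/VL step functions when adjusted

    def __post_init__(self):
        allowed = {"initial", "current", "current_plus_previous"}
        if self.exposure_coding not in allowed:
            raise ValueError(f"exposure_coding must be one of {sorted(allowed)}")
        if self.exposure_coding == "current_plus_previous" and self.censor_at_switch:
            raise ValueError("current_plus_previous coding requires censor_at_switch=False")


def regimen_indicators(series, reference, prefix):
    cats = [c for c in rg.CATEGORIES if c != reference]
    vals = np.asarray(series.astype(str))
    X = np.column_stack([(vals == c).astype(float) for c in cats])
    return X, [f"{prefix}[{c}]" for c in cats]


def adjustment_design(pm: pd.DataFrame, include_time_varying=True):
    """Baseline confounders (continuous linear) + time-varying CD4/VL steps."""
    blocks, names = [], []
    for c in ADJUSTMENT_CONTINUOUS:
        blocks.append(pm[c].to_numpy(float)[:, None])
        names.append(c)
    for c in ADJUSTMENT_BINARY:
        blocks.append(pm[c].to_numpy(float)[:, None])
        names.append(c)
    if include_time_varying:
        cd4 = np.asarray(pm["cd4_cat"].astype(str))
        for c in CD4_CATEGORIES:
            if c != ">350":
                blocks.append((cd4 == c).astype(float)[:, None])
                names.append(f"cd4[{c}]")
        vl = np.asarray(pm["vl_cat"].astype(str))
        for c in VL_CATEGORIES:
            if c != "<=50":
                blocks.append((vl == c).astype(float)[:, None])
                names.append(f"vl[{c}]")
    return np.column_stack(blocks), names


def fit_cox(person_months: pd.DataFrame, spec: CoxSpec) -> FitResult:
    """Fit one traditional proportional-hazards model per the spec."""
    pm = person_months
    if spec.censor_at_switch:
        pm = pm[pm["on_initial"]]
    pm = pm.reset_index(drop=True)

    if spec.exposure_coding == "initial":
        X, names = regimen_indicators(pm["initial_regimen"], spec.reference_category,
                                      "initial")
    elif spec.exposure_coding == "current":
        X, names = regimen_indicators(pm["current_regimen"], spec.reference_category,
                                      "current")
    else:
        Xc, nc = regimen_indicators(pm["current_regimen"], spec.reference_category,
                                    "current")
        prev = pm["previous_regimen"].fillna("none")
        Xp = np.column_stack([(np.asarray(prev.astype(str)) == c).astype(float)
                              for c in rg.CATEGORIES])
        X = np.column_stack([Xc, Xp])
        names = nc + [f"previous[{c}]" for c in rg.CATEGORIES]

    suppressed = [n for n in names if f"[{rg.OTHER}]" in n]
    if spec.adjusted:
        Xa, na = adjustment_design(pm, include_time_varying=spec.include_time_varying)
        X = np.column_stack([X, Xa])
        suppressed += na
        names = names + na

    fit = fit_cox_person_months(
        X, pm["month"].to_numpy(int), pm["event"].to_numpy(bool),
        cluster=pm["patient_id"].to_numpy(), names=names,
    )
    label = f"cox[{spec.exposure_coding}{', adjusted' if spec.adjusted else ''}" \
            f"{', censored at switch' if spec.censor_at_switch else ''}]"
    return fit.to_result(model=label, suppressed=suppressed)


def _poisson_ci(events: int, person_years: float):
    if events == 0:
        lo = 0.0
    else:
        lo = stats.chi2.ppf(0.025, 2 * events) / 2 / person_years
    hi = stats.chi2.ppf(0.975, 2 * (events + 1)) / 2 / person_years
    return lo * 1000, hi * 1000


def summarize_incidence(person_months: pd.DataFrame) -> dict:
    """Confirmed-CKD incidence per 1000 person-years with exact Poisson CIs,
    overall and while on the initial regimen."""
    out = {}
    for label, pm in (("overall", person_months),
                      ("on_initial", person_months[person_months["on_initial"]])):
        events = int(pm["event"].sum())
        py = len(pm) * MONTH_DAYS / 365.25
        if py <= 0:
            raise ValueError("zero person-time")
        lo, hi = _poisson_ci(events, py)
        out[label] = {
            "events": events,
            "person_years": py,
            "rate_per_1000py": 1000 * events / py,
            "ci_low": lo,
            "ci_high": hi,
        }
    return out
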