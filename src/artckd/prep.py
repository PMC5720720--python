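"""Cohort preparation: from raw tables to the person-month analysis dataset.

Pipeline: MDRD eGFR from dated creatinines, baseline-eGFR selection (last
measurement in the 180 days before ART initiation), eligibility filtering,
five-category regimen classification, confirmed-CKD event detection (two
sub-60 values at least 90 days apart with no intervening recovery), and
expansion of each patient's follow-up into consecutive 30.44-day months with
last-value-carried-forward covariate categories.

All timing is on a fixed 30.44-day month grid anchored at each patient's ART
start date: month ``t`` covers days ``((t-1)*30.44, t*30.44]``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import regimens as rg
from .egfr import cd4_category, egfr_category, mdrd_egfr, vl_category

MONTH_DAYS = 30.44
BASELINE_WINDOW_DAYS = 180  # closed interval [start-180, start]
CONFIRM_GAP_DAYS = 90
MIN_START = pd.Timestamp("2004-01-01")

BASELINE_COVARIATES = [
    "age_at_start", "nadir_cd4", "baseline_cd4", "baseline_vl_log10",
    "baseline_egfr", "year_of_start", "female", "exposure_heterosexual",
    "exposure_other", "hbv", "hcv", "diabetes", "hypertension", "cvd",
]


def attach_egfr(labs: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Add day-since-start and MDRD eGFR columns to a lab table."""
    meta = patients.set_index("patient_id")[["art_start_date", "age_at_start", "sex"]]
    out = labs.merge(meta, left_on="patient_id", right_index=True, how="inner")
    out["day"] = (pd.to_datetime(out["date"]) - pd.to_datetime(out["art_start_date"])).dt.days
    age = out["age_at_start"].to_numpy(float) + out["day"].to_numpy(float) / 365.25
    out["egfr"] = mdrd_egfr(out["scr_mg_dl"].to_numpy(float), age,
                            (out["sex"] == "F").to_numpy())
    return out.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)


def select_baseline_egfr(labs: pd.DataFrame, art_start_date) -> float | None:
    """Baseline eGFR: latest creatinine in the 180 days up to ART start.

    ``labs`` is one patient's table with ``date`` and ``egfr`` (or
    ``scr_mg_dl`` already converted) columns, sorted by date.
    """
    day = (pd.to_datetime(labs["date"]) - pd.Timestamp(art_start_date)).dt.days
    ok = (day >= -BASELINE_WINDOW_DAYS) & (day <= 0)
    if not ok.any():
        return None
    return float(labs.loc[ok[ok].index[-1], "egfr"])


def apply_eligibility(patients: pd.DataFrame, labs: pd.DataFrame):
    """Retain patients meeting the entry rules; log one reason per exclusion.

    Rules in order: (i) ART start on/after 2004-01-01, (ii) a baseline eGFR
    (within the 180-day window) present and > 60, (iii) at least two
    creatinine measurements after ART start.
    """
    labs = labs if "egfr" in labs.columns else attach_egfr(labs, patients)
    base_rows = labs[(labs["day"] >= -BASELINE_WINDOW_DAYS) & (labs["day"] <= 0)]
    base_egfr = (base_rows.sort_values("day", kind="stable")
                 .groupby("patient_id")["egfr"].last())
    n_post = labs[labs["day"] > 0].groupby("patient_id").size()

    pts = patients.copy()
    pts["baseline_egfr"] = pts["patient_id"].map(base_egfr)
    pts["n_post_creat"] = pts["patient_id"].map(n_post).fillna(0).astype(int)
    start_ok = pd.to_datetime(pts["art_start_date"]) >= MIN_START
    base_ok = pts["baseline_egfr"].notna() & (pts["baseline_egfr"] > 60.0)
    post_ok = pts["n_post_creat"] >= 2

    reason = np.select(
        [~start_ok, ~base_ok, ~post_ok],
        ["art_start_before_2004", "no_valid_baseline_egfr", "insufficient_post_creatinine"],
        default="",
    )
    excluded = pts.loc[reason != "", ["patient_id"]].assign(reason=reason[reason != ""])
    retained = pts[reason == ""].drop(columns=["n_post_creat"]).reset_index(drop=True)
    bad_nadir = retained["nadir_cd4"] > retained["baseline_cd4"]
    if bad_nadir.any():
        warnings.warn(f"{int(bad_nadir.sum())} patients with nadir CD4 above baseline CD4",
                      stacklevel=2)
    return retained, excluded.reset_index(drop=True)


def detect_ckd_event(days, values, min_gap_days: int = CONFIRM_GAP_DAYS,
                     any_later_confirm: bool = False):
    """First confirmed sub-60 eGFR: ``(event_day, confirming_day)`` or None.

    An event is the first measurement ``t0`` below 60 confirmed by a later
    sub-60 measurement at least ``min_gap_days`` later with every measurement
    in between also below 60 (strict confirmation; a single recovery >= 60
    voids the candidate and the scan restarts).  ``any_later_confirm``
    relaxes the no-intervening-recovery requirement.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(days)
    i = 0
    while i < n:
        if values[i] >= 60.0:
            i += 1
            continue
        if any_later_confirm:
            for k in range(i + 1, n):
                if values[k] < 60.0 and days[k] >= days[i] + min_gap_days:
                    return float(days[i]), float(days[k])
            i += 1
            continue
        # strict rule: walk the uninterrupted sub-60 run starting at i
        j = i
        while j < n and values[j] < 60.0:
            if days[j] >= days[i] + min_gap_days:
                return float(days[i]), float(days[j])
            j += 1
        # run ended (recovery at j, or data exhausted) without confirmation;
        # the scan restarts after the interruption
        i = j + 1
    return None


def detect_events(labs: pd.DataFrame, patients: pd.DataFrame,
                  any_later_confirm: bool = False) -> pd.DataFrame:
    """Confirmed-CKD events for all patients (post-ART measurements only)."""
    labs = labs if "egfr" in labs.columns else attach_egfr(labs, patients)
    post = labs[labs["day"] > 0]
    candidates = post.groupby("patient_id")["egfr"].min()
    candidates = set(candidates[candidates < 60.0].index)
    rows = []
    for pid, g in post[post["patient_id"].isin(candidates)].groupby("patient_id"):
        hit = detect_ckd_event(g["day"].to_numpy(), g["egfr"].to_numpy(),
                               any_later_confirm=any_later_confirm)
        if hit is not None:
            rows.append((pid, hit[0], hit[1]))
    return pd.DataFrame(rows, columns=["patient_id", "event_day", "confirming_day"])


def classify_regimen_table(regimens: pd.DataFrame) -> pd.DataFrame:
    """Attach a five-level category column, classifying from drug components
    when present, otherwise trusting an existing ``category`` column."""
    out = regimens.copy()
    if "drugs" in out.columns:
        cats = [rg.classify_regimen(rg.parse_drug_field(d)) for d in out["drugs"]]
        out["category"] = cats
    elif "category" not in out.columns:
        raise ValueError("regimen table needs a 'drugs' or 'category' column")
    return out


def _baseline_design(patients: pd.DataFrame) -> pd.DataFrame:
    pts = patients.copy()
    pts["female"] = (pts["sex"] == "F").astype(float)
    pts["exposure_heterosexual"] = (pts["hiv_exposure"] == "heterosexual").astype(float)
    pts["exposure_other"] = (~pts["hiv_exposure"].isin(["homosexual", "heterosexual"])).astype(float)
    for c in ("hbv", "hcv", "diabetes", "hypertension", "cvd"):
        pts[c] = pts[c].astype(float)
    return pts


def expand_person_months(patients: pd.DataFrame, labs: pd.DataFrame,
                         regimens: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """One row per patient-month with LVCF covariate categories.

    Covariates are evaluated at each month start (day ``(t-1)*30.44``) as the
    most recent measurement on or before it; baseline values seed month 1.
    ``current_regimen`` is the category active at the month start;
    ``previous_regimen`` the category immediately before the current spell.
    Months after the event month are dropped.
    """
    labs = labs if "egfr" in labs.columns else attach_egfr(labs, patients)
    regimens = classify_regimen_table(regimens)
    pts = _baseline_design(patients)

    start_by_pid = pts.set_index("patient_id")["art_start_date"]
    regs = regimens[regimens["patient_id"].isin(set(pts["patient_id"]))].copy()
    starts = pd.to_datetime(start_by_pid.loc[regs["patient_id"]].to_numpy())
    regs["start_day"] = (pd.to_datetime(regs["start_date"]) - starts).dt.days.to_numpy()
    regs["stop_day"] = (pd.to_datetime(regs["stop_date"]) - starts).dt.days.to_numpy()
    regs = regs.sort_values(["patient_id", "start_day"], kind="stable")
    regs["previous_regimen"] = regs.groupby("patient_id")["category"].shift(1)
    regs["spell_idx"] = regs.groupby("patient_id").cumcount()

    ev = events.set_index("patient_id")["event_day"] if len(events) else pd.Series(dtype=float)
    end_day = regs.groupby("patient_id")["stop_day"].max()

    pm_meta = pts[["patient_id"]].copy()
    pm_meta["event_day"] = pm_meta["patient_id"].map(ev)
    pm_meta["end_day"] = pm_meta["patient_id"].map(end_day)
    has_event = pm_meta["event_day"].notna()
    T = np.where(
        has_event,
        np.ceil(pm_meta["event_day"].to_numpy(float) / MONTH_DAYS),
        np.floor(pm_meta["end_day"].to_numpy(float) / MONTH_DAYS),
    ).astype(int)
    if (T < 1).any():
        warnings.warn(f"{int((T < 1).sum())} patients with <1 month of follow-up dropped",
                      stacklevel=2)
    keep = T >= 1
    pm_meta, T = pm_meta[keep], T[keep]

    pid = np.repeat(pm_meta["patient_id"].to_numpy(), T)
    month = np.concatenate([np.arange(1, t + 1) for t in T])
    grid = pd.DataFrame({"patient_id": pid, "month": month})
    grid["month_start_day"] = (grid["month"] - 1) * MONTH_DAYS

    # LVCF of lab values at month start
    lab_cols = labs[["patient_id", "day", "egfr", "cd4", "vl_copies"]].copy()
    lab_cols["day"] = lab_cols["day"].astype(float)
    lab_cols = lab_cols.sort_values(["day", "patient_id"], kind="stable")
    g = grid.sort_values(["month_start_day", "patient_id"], kind="stable")
    merged = pd.merge_asof(
        g, lab_cols, left_on="month_start_day", right_on="day",
        by="patient_id", direction="backward",
    )

    # regimen spell active at month start
    rcols = regs[["patient_id", "start_day", "stop_day", "category",
                  "previous_regimen", "spell_idx"]].copy()
    rcols["start_day"] = rcols["start_day"].astype(float)
    rcols = rcols.sort_values(["start_day", "patient_id"], kind="stable")
    merged = pd.merge_asof(
        merged.sort_values(["month_start_day", "patient_id"], kind="stable"),
        rcols, left_on="month_start_day", right_on="start_day",
        by="patient_id", direction="backward",
    )
    gap = merged["category"].isna() | (
        (merged["stop_day"] <= merged["month_start_day"])
        & (merged["month_start_day"] > 0)
    )
    if gap.any():
        warnings.warn(f"{int(gap.sum())} person-months fall in regimen gaps; excluded",
                      stacklevel=2)
        merged = merged[~gap]
    merged = merged.sort_values(["patient_id", "month"], kind="stable").reset_index(drop=True)

    merged = merged.rename(columns={"category": "current_regimen"})
    merged["on_initial"] = merged["spell_idx"] == 0

    # switches occurring within each month (for the full-cohort analyses,
    # every spell change counts, not only the first)
    sw = regs[regs["spell_idx"] >= 1].copy()
    sw["month"] = np.ceil(sw["start_day"] / MONTH_DAYS).astype(int).clip(lower=1)
    sw_counts = sw.groupby(["patient_id", "month"]).size().rename("n_switches")
    merged = merged.merge(sw_counts, left_on=["patient_id", "month"],
                          right_index=True, how="left")
    merged["switched_this_month"] = merged["n_switches"].fillna(0) > 0

    # terminal flags.  Administrative end of data (regimen coverage reaching
    # the database close date) is not a modelled censoring event; only
    # earlier terminations (loss to follow-up) feed the censoring models.
    ev_month = pm_meta.set_index("patient_id")
    merged["event_month_"] = merged["patient_id"].map(
        np.ceil(ev_month["event_day"] / MONTH_DAYS))
    merged["event"] = merged["month"] == merged["event_month_"]
    last_month = merged.groupby("patient_id")["month"].transform("max")
    close_date = pd.to_datetime(regimens["stop_date"]).max()
    last_stop = regs.groupby("patient_id")["stop_date"].max().map(pd.Timestamp)
    starts_all = pts.set_index("patient_id")["art_start_date"].map(pd.Timestamp)
    dur_days = (last_stop - starts_all.reindex(last_stop.index)).dt.days
    # the design's maximum follow-up, taken among non-event patients so the
    # post-event confirmation visit cannot inflate the cap
    ev_ids = set(events["patient_id"]) if len(events) else set()
    non_event_dur = dur_days[~dur_days.index.isin(ev_ids)]
    dur_cap = non_event_dur.max() if len(non_event_dur) else dur_days.max()
    near_close = (close_date - merged["patient_id"].map(last_stop)).dt.days <= 160
    at_cap = merged["patient_id"].map(dur_days) >= dur_cap - 45
    administrative = near_close | at_cap
    merged["censored_this_month"] = (
        (merged["month"] == last_month)
        & ~merged["event"]
        & ~merged["switched_this_month"]
        & ~administrative
    )

    merged["egfr_cat"] = egfr_category(merged["egfr"])
    merged["cd4_cat"] = cd4_category(merged["cd4"])
    merged["vl_cat"] = vl_category(merged["vl_copies"])

    first = regs[regs["spell_idx"] == 0].set_index("patient_id")["category"]
    merged["initial_regimen"] = merged["patient_id"].map(first)

    base = _baseline_design(patients)
    base = base.set_index("patient_id")
    if "baseline_egfr" not in base.columns or base["baseline_egfr"].isna().any():
        raise ValueError("patients must carry baseline_egfr (run apply_eligibility first)")
    for c in BASELINE_COVARIATES:
        if c == "baseline_egfr":
            merged[c] = merged["patient_id"].map(base[c])
        elif c in base.columns:
            merged[c] = merged["patient_id"].map(base[c])

    cols = [
        "patient_id", "month", "month_start_day", "current_regimen",
        "previous_regimen", "initial_regimen", "on_initial", "egfr_cat",
        "cd4_cat", "vl_cat", "event", "switched_this_month",
        "censored_this_month",
    ] + BASELINE_COVARIATES
    return merged[cols]


def prepare_cohort(patients: pd.DataFrame, labs: pd.DataFrame,
                   regimens: pd.DataFrame, any_later_confirm: bool = False) -> dict:
    """Full preparation: eligibility, events, person-month expansion."""
    labs = attach_egfr(labs, patients)
    retained, excluded = apply_eligibility(patients, labs)
    labs_r = labs[labs["patient_id"].isin(set(retained["patient_id"]))]
    events = detect_events(labs_r, retained, any_later_confirm=any_later_confirm)
    person_months = expand_person_months(retained, labs_r, regimens, events)
    return {
        "patients": retained,
        "exclusions": excluded,
        "events": events,
        "person_months": person_months,
    }
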