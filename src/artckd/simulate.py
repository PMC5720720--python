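"""Synthetic longitudinal HIV-cohort generator with treatment-confounder feedback.

The simulator emulates the data-generating structure the regimen/CKD analyses
assume: five initial regimen categories assigned by a polytomous logistic
model on baseline covariates, a latent monthly eGFR trajectory whose drift
depends on the current regimen, regimen switching whose monthly log-odds
depend on the last *measured* eGFR category (the feedback loop: treatment
affects the renal marker, the marker drives treatment changes, and the marker
predicts the outcome), a sparse creatinine/CD4/viral-load lab schedule, a
discrete-time CKD hazard, and dropout plus entry-year administrative
censoring.

Two modelling choices keep parameter recovery well-posed.  First, the CKD
outcome is generated from a monthly Bernoulli hazard

    p_t = 1 - exp(-exp(b0 + log HR[current regimen] + coef[eGFR category]))

so a "true" regimen effect exists as an explicit parameter, with the eGFR
category term providing the confounding pathway.  Second, the latent eGFR is
floored just above the CKD threshold before an event fires, and an event
forces a sub-60 measurement at the event day plus a confirming sub-60
measurement 100 days later; a confirmed sub-60 pair in the exported labs
therefore occurs exactly when the hazard mechanism fired, and the analysis
pipeline's confirmation rule recovers the true event time.

Clinician behaviour is emulated by making both the switch and outcome models
depend on the last observed (lab-measured) eGFR category, which is what the
analysis reconstructs by last-value-carried-forward.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import regimens as rg
from .egfr import EGFR_CATEGORIES, scr_from_egfr

MONTH_DAYS = 30.44

_CAT_INDEX = {c: i for i, c in enumerate(rg.CATEGORIES)}


def _default_log_hr():
    return {
        rg.TDF_NNRTI: 0.0,
        rg.TDF_RBPI: 0.69,
        rg.NOTDF_NNRTI: 0.10,
        rg.NOTDF_RBPI: 0.50,
        rg.OTHER: 0.30,
    }


def _default_drift():
    return {
        rg.TDF_NNRTI: -0.60,
        rg.TDF_RBPI: -1.50,
        rg.NOTDF_NNRTI: -0.15,
        rg.NOTDF_RBPI: -0.25,
        rg.OTHER: -0.25,
    }


def _default_outcome_coef():
    return {">90": 0.0, "71-90": 1.2, "51-70": 3.0, "<=50": 4.0}


def _default_switch_dependence():
    return {">90": 0.0, "71-90": 0.35, "51-70": 0.8, "<=50": 1.1}


def _default_switch_base():
    return {c: -4.25 for c in rg.CATEGORIES}


def _default_transition():
    i = _CAT_INDEX
    M = np.full((5, 5), 0.0)
    M[i[rg.TDF_NNRTI], i[rg.NOTDF_NNRTI]] = 0.6
    M[i[rg.TDF_NNRTI], i[rg.OTHER]] = 0.2
    M[i[rg.TDF_NNRTI], i[rg.TDF_RBPI]] = 0.1
    M[i[rg.TDF_NNRTI], i[rg.NOTDF_RBPI]] = 0.1
    M[i[rg.TDF_RBPI], i[rg.NOTDF_RBPI]] = 0.6
    M[i[rg.TDF_RBPI], i[rg.OTHER]] = 0.2
    M[i[rg.TDF_RBPI], i[rg.TDF_NNRTI]] = 0.1
    M[i[rg.TDF_RBPI], i[rg.NOTDF_NNRTI]] = 0.1
    for c in (rg.NOTDF_NNRTI, rg.NOTDF_RBPI, rg.OTHER):
        row = i[c]
        M[row] = 0.25
        M[row, row] = 0.0
    return M


def _default_marginals():
    # Calibrated to the cohort's printed medians/IQRs (log-normal or normal
    # with sigma from the IQR width on the appropriate scale).
    return {
        "age": {"log_median": float(np.log(39.0)), "sigma": 0.285, "lo": 18.0, "hi": 80.0},
        "egfr": {"log_median": float(np.log(101.0)), "sigma": 0.235, "lo": 61.0, "hi": 180.0},
        "cd4": {"log_median": float(np.log(289.0)), "sigma": 0.598, "lo": 10.0, "hi": 1500.0},
        "nadir_frac_beta": [8.0, 1.2],
        "vl_log10": {"mean": 4.8, "sigma": 0.815, "lo": 1.7, "hi": 7.0},
        "p_female": 0.27,
        "p_exposure": [0.45, 0.45, 0.10],  # homosexual, heterosexual, other
        "p_hbv": 0.05,
        "p_hcv": 0.07,
        "p_hypertension": 0.04,
        "p_cvd": 0.02,
        "p_diabetes": 0.02,
    }


def _default_assignment_coefs():
    return {
        rg.TDF_NNRTI: {"z_cd4": 0.25, "z_nadir": 0.20},
        rg.TDF_RBPI: {"z_cd4": -0.10},
        rg.NOTDF_NNRTI: {"z_egfr": -0.35},
        rg.NOTDF_RBPI: {"female": 0.35, "z_cd4": -0.05},
        rg.OTHER: {},
    }


@dataclass
class SimConfig:
    """Scenario definition for the synthetic cohort.

    Defaults describe the study conditions: initial regimen shares
    19/37/5/25/14%, baseline marginals matching the cohort's Table-1-style
    medians and IQRs, a sparse lab schedule with median inter-measurement gap
    2.6 months, eGFR-dependent switching away from TDF-containing regimens,
    and a confirmed-CKD incidence on the order of 10 per 1000 person-years.
    """

    n_patients: int = 6301
    seed: int = 1
    regimen_shares: tuple = (0.19, 0.37, 0.05, 0.25, 0.14)  # order: rg.CATEGORIES
    true_log_hr_by_regimen: dict = field(default_factory=_default_log_hr)
    egfr_drift_by_regimen: dict = field(default_factory=_default_drift)
    egfr_noise_sd: float = 1.5
    #: the regimen-specific renal effect is front-loaded: latent eGFR
    #: mean-reverts (rate 1/drift_taper_months per month) toward a setpoint
    #: baseline + drift*taper, so ``egfr_drift_by_regimen`` is the initial
    #: mean monthly change and the total effect saturates at drift*taper
    drift_taper_months: int = 6
    egfr_outcome_coef: dict = field(default_factory=_default_outcome_coef)
    event_intercept: float = -8.40
    switch_base_logit: dict = field(default_factory=_default_switch_base)
    switch_dependence: dict = field(default_factory=_default_switch_dependence)
    #: per-regimen scaling of the eGFR dependence of switching (clinician
    #: response to renal decline is strongest for TDF with a boosted PI)
    switch_dependence_scale: dict = field(default_factory=lambda: {
        rg.TDF_NNRTI: 0.4, rg.TDF_RBPI: 1.0, rg.NOTDF_NNRTI: 0.0,
        rg.NOTDF_RBPI: 0.0, rg.OTHER: 0.0})
    transition_matrix: np.ndarray = field(default_factory=_default_transition)
    lab_gap_median_months: float = 2.6
    lab_gap_log_sd: float = 0.9
    lab_gap_cap_months: float = 12.0
    followup_max_months: int = 120
    dropout_hazard_monthly: float = 0.008
    min_followup_months: int = 3
    baseline_marginals: dict = field(default_factory=_default_marginals)
    assignment_coefs: dict = field(default_factory=_default_assignment_coefs)
    measurement_noise_sd: float = 0.0
    entry_years: tuple = (2004, 2012)
    admin_close: str = "2014-06-30"

    def __post_init__(self):
        shares = np.asarray(self.regimen_shares, dtype=float)
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("regimen_shares must sum to 1")
        if np.any(shares < 0) or np.any(shares > 1):
            raise ValueError("regimen_shares must be probabilities")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.dropout_hazard_monthly <= 1):
            raise ValueError("dropout_hazard_monthly must be in [0, 1]")
        for name in ("egfr_noise_sd", "event_intercept", "lab_gap_median_months"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (5, 5) or np.any(self.transition_matrix < 0):
            raise ValueError("transition_matrix must be a nonnegative 5x5 matrix")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_matrix"] = self.transition_matrix.tolist()
        d["regimen_shares"] = list(self.regimen_shares)
        d["entry_years"] = list(self.entry_years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("regimen_shares", "entry_years"):
            if k in d:
                d[k] = tuple(d[k])
        if "transition_matrix" in d:
            d["transition_matrix"] = np.asarray(d["transition_matrix"], dtype=float)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def default_effect_scenario(**kw) -> SimConfig:
    """Effect scenario: direct regimen effects, regimen-dependent eGFR drift,
    eGFR-driven switching, baseline-covariate-driven assignment."""
    return SimConfig(**kw)


def null_scenario(**kw) -> SimConfig:
    """All true regimen log-HRs zero and equal eGFR drifts, with the feedback
    machinery (eGFR-dependent switching, covariate-driven assignment) left on,
    so the marginal regimen effect is truly null but the observational
    structure still confounds naive analyses."""
    cfg = SimConfig(**kw)
    return cfg.replace(
        true_log_hr_by_regimen={c: 0.0 for c in rg.CATEGORIES},
        egfr_drift_by_regimen={c: -0.10 for c in rg.CATEGORIES},
    )


def no_feedback_scenario(**kw) -> SimConfig:
    """Randomised-assignment, no-feedback limit: switching independent of
    eGFR, equal drifts, assignment independent of covariates.  Direct regimen
    effects are kept so estimators must agree on a non-null value."""
    cfg = SimConfig(**kw)
    return cfg.replace(
        switch_dependence={k: 0.0 for k in cfg.switch_dependence},
        egfr_drift_by_regimen={c: -0.10 for c in rg.CATEGORIES},
        assignment_coefs={c: {} for c in rg.CATEGORIES},
    )


SCENARIOS = {
    "default": default_effect_scenario,
    "effect": default_effect_scenario,
    "null": null_scenario,
    "no_feedback": no_feedback_scenario,
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Exported tables plus the latent oracle state.

    ``latent`` holds the true monthly eGFR trajectory and true event/censor
    months; it is never written to the analysis files (only ``oracle.csv``
    when explicitly requested).
    """

    baseline: pd.DataFrame
    labs: pd.DataFrame
    regimens: pd.DataFrame
    latent: dict
    config: SimConfig

    def to_csv(self, outdir, with_oracle=False):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.baseline.to_csv(outdir / "patients.csv", index=False)
        self.labs.to_csv(outdir / "labs.csv", index=False)
        self.regimens.to_csv(outdir / "regimens.csv", index=False)
        if with_oracle:
            oracle = pd.DataFrame(
                {
                    "patient_id": self.baseline["patient_id"],
                    "true_event_month": self.latent["event_month"],
                    "true_terminal_month": self.latent["terminal_month"],
                    "initial_regimen": self.baseline["initial_regimen"],
                }
            )
            oracle.to_csv(outdir / "oracle.csv", index=False)
        return outdir


# ---------------------------------------------------------------------------
# baseline generation
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, n, log_median, sigma, lo, hi):
    out = np.exp(rng.normal(log_median, sigma, size=n))
    for _ in range(50):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = np.exp(rng.normal(log_median, sigma, size=int(bad.sum())))
    return np.clip(out, lo, hi)


def generate_baseline(config: SimConfig) -> pd.DataFrame:
    """One row per patient: covariates fixed at ART initiation plus the
    initial regimen category drawn from a polytomous logistic assignment
    model whose intercepts are tuned to the configured marginal shares."""
    n = config.n_patients
    m = config.baseline_marginals
    rng = np.random.default_rng(config.seed)

    age = _truncated_lognormal(rng, n, **m["age"])
    egfr = _truncated_lognormal(rng, n, **m["egfr"])
    cd4 = _truncated_lognormal(rng, n, **m["cd4"])
    a, b = m["nadir_frac_beta"]
    nadir = np.minimum(cd4, cd4 * rng.beta(a, b, size=n))
    p = m["vl_log10"]
    vl = np.clip(rng.normal(p["mean"], p["sigma"], size=n), p["lo"], p["hi"])
    female = rng.random(n) < m["p_female"]
    pexp = np.asarray(m["p_exposure"], dtype=float)
    pexp = pexp / pexp.sum()
    exposure = np.array(["homosexual", "heterosexual", "other"])[
        (rng.random(n)[:, None] > np.cumsum(pexp)[None, :2]).sum(axis=1)
    ]
    hbv = rng.random(n) < m["p_hbv"]
    hcv = rng.random(n) < m["p_hcv"]
    htn = rng.random(n) < m["p_hypertension"]
    cvd = rng.random(n) < m["p_cvd"]
    dm = rng.random(n) < m["p_diabetes"]

    y0, y1 = config.entry_years
    year = rng.integers(y0, y1 + 1, size=n)
    day_in_year = rng.integers(0, 365, size=n)
    start = pd.to_datetime(year.astype(str)) + pd.to_timedelta(day_in_year, unit="D")

    # polytomous assignment on standardised covariates
    Z = {
        "z_egfr": (egfr - 100.0) / 20.0,
        "z_cd4": (cd4 - 290.0) / 150.0,
        "z_nadir": (nadir - 260.0) / 140.0,
        "z_age": (age - 39.0) / 10.0,
        "female": female.astype(float),
    }
    lp = np.zeros((n, 5))
    for cat, coefs in config.assignment_coefs.items():
        j = _CAT_INDEX[cat]
        for cov, c in coefs.items():
            lp[:, j] += c * Z[cov]
    targets = np.asarray(config.regimen_shares, dtype=float)
    intercepts = np.log(np.clip(targets, 1e-12, None))
    for _ in range(80):
        probs = np.exp(lp + intercepts)
        probs /= probs.sum(axis=1, keepdims=True)
        intercepts += np.log(targets / np.clip(probs.mean(axis=0), 1e-12, None))
    probs = np.exp(lp + intercepts)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cat_idx = (u[:, None] > np.cumsum(probs, axis=1)[:, :4]).sum(axis=1)
    initial = np.array(rg.CATEGORIES)[cat_idx]

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "art_start_date": start.normalize(),
            "age_at_start": np.round(age, 1),
            "sex": np.where(female, "F", "M"),
            "hiv_exposure": exposure,
            "nadir_cd4": np.round(nadir).astype(int),
            "baseline_cd4": np.round(cd4).astype(int),
            "baseline_vl_log10": np.round(vl, 2),
            "baseline_egfr": egfr,  # latent start value; analysis re-derives from labs
            "year_of_start": year,
            "hbv": hbv,
            "hcv": hcv,
            "diabetes": dm,
            "hypertension": htn,
            "cvd": cvd,
            "initial_regimen": initial,
        }
    )


# ---------------------------------------------------------------------------
# follow-up simulation
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_followup(baseline: pd.DataFrame, config: SimConfig,
                      build_labs: bool = True) -> SimulatedCohort:
    """Run the monthly engine over the cohort and assemble exported tables."""
    n = len(baseline)
    T = int(config.followup_max_months)
    rng = np.random.default_rng(config.seed + 1_000_003)

    # pre-drawn randomness blocks, one row per patient
    z_egfr = rng.normal(size=(n, T + 1))
    z_cd4 = rng.normal(size=(n, T + 1))
    u_event = rng.random((n, T + 1))
    u_switch = rng.random((n, T + 1))
    u_dest = rng.random((n, T + 1))
    u_drop = rng.random((n, T + 1))
    u_eventval = rng.random(n)
    max_labs = max(8, int(T / 1.0) + 4)
    gaps = np.exp(rng.normal(np.log(config.lab_gap_median_months),
                             config.lab_gap_log_sd, size=(n, max_labs)))
    gaps = np.clip(gaps, 0.25, config.lab_gap_cap_months)
    lab_month_days = np.cumsum(gaps, axis=1) * MONTH_DAYS
    meas_noise = (
        rng.normal(scale=config.measurement_noise_sd, size=(n, max_labs))
        if config.measurement_noise_sd > 0
        else np.zeros((n, max_labs))
    )

    # lab presence per (patient, month)
    lab_month = np.ceil(lab_month_days / MONTH_DAYS).astype(int)
    lab_present = np.zeros((n, T + 2), dtype=bool)
    rows = np.repeat(np.arange(n), lab_month.shape[1])
    cols = np.clip(lab_month.ravel(), 0, T + 1)
    lab_present[rows, cols] = True

    start = pd.to_datetime(baseline["art_start_date"])
    admin_days = (pd.Timestamp(config.admin_close) - start).dt.days.to_numpy()
    admin_months = np.clip(
        np.floor(admin_days / MONTH_DAYS).astype(int),
        max(config.min_followup_months, 1), T,
    )

    drift = np.array([config.egfr_drift_by_regimen[c] for c in rg.CATEGORIES])
    loghr = np.array([config.true_log_hr_by_regimen[c] for c in rg.CATEGORIES])
    base_sw = np.array([config.switch_base_logit[c] for c in rg.CATEGORIES])
    dep = np.array([config.switch_dependence[c] for c in EGFR_CATEGORIES])
    outc = np.array([config.egfr_outcome_coef[c] for c in EGFR_CATEGORIES])
    dep_mask = np.array([config.switch_dependence_scale[c] for c in rg.CATEGORIES],
                        dtype=float)
    trans = config.transition_matrix.copy()
    rowsum = trans.sum(axis=1, keepdims=True)
    trans = np.divide(trans, rowsum, out=np.zeros_like(trans), where=rowsum > 0)
    trans_cum = np.cumsum(trans, axis=1)

    reg = np.array([_CAT_INDEX[c] for c in baseline["initial_regimen"]])
    egfr_base = baseline["baseline_egfr"].to_numpy(dtype=float)
    kappa = 1.0 / max(config.drift_taper_months, 1)
    egfr_lat = baseline["baseline_egfr"].to_numpy(dtype=float).copy()
    cd4 = baseline["baseline_cd4"].to_numpy(dtype=float).copy()
    vl = baseline["baseline_vl_log10"].to_numpy(dtype=float).copy()
    egfr_obs = egfr_lat.copy()

    active = np.ones(n, dtype=bool)
    event_month = np.zeros(n, dtype=int)          # 0 = no event
    terminal_month = admin_months.copy()
    terminal_day = admin_months * MONTH_DAYS
    event_day = np.full(n, np.nan)
    event_egfr = 42.0 + 14.0 * u_eventval

    latent_traj = np.zeros((n, T + 1), dtype=np.float32)
    latent_traj[:, 0] = egfr_lat
    cd4_traj = np.zeros((n, T + 1), dtype=np.float32)
    cd4_traj[:, 0] = cd4
    vl_traj = np.zeros((n, T + 1), dtype=np.float32)
    vl_traj[:, 0] = vl
    switch_rec = []  # (patient_idx, month, old_cat_idx, new_cat_idx)

    cat_bounds = np.array([50.0 + 1e-9, 70.0 + 1e-9, 90.0 + 1e-9])

    for t in range(1, T + 1):
        if not active.any():
            break
        a = active
        # latent evolution (floored above the CKD threshold pre-event)
        setpoint = egfr_base[a] + drift[reg[a]] * config.drift_taper_months
        egfr_lat[a] = np.clip(
            egfr_lat[a] + kappa * (setpoint - egfr_lat[a])
            + config.egfr_noise_sd * z_egfr[a, t],
            61.0, None,
        )
        cd4[a] = np.clip(cd4[a] + 18.0 * np.exp(-t / 12.0) + 4.0 * z_cd4[a, t], 1.0, None)
        vl[a] = np.maximum(1.3, vl[a] - 0.8)
        latent_traj[a, t] = egfr_lat[a]
        cd4_traj[a, t] = cd4[a]
        vl_traj[a, t] = vl[a]

        # decisions this month depend on the last value measured *before* the
        # month started -- exactly the information LVCF reconstructs
        cat = np.searchsorted(cat_bounds, egfr_obs)  # 0:<=50 .. 3:>90

        # event
        lp_ev = config.event_intercept + loghr[reg] + outc[cat]
        p_ev = 1.0 - np.exp(-np.exp(lp_ev))
        hit = a & (u_event[:, t] < p_ev)
        if hit.any():
            event_month[hit] = t
            event_day[hit] = (t - 0.5) * MONTH_DAYS
            terminal_day[hit] = event_day[hit] + 100.0
            terminal_month[hit] = t
            active[hit] = False

        # switching (not terminal for the cohort; the causal analysis censors)
        can_switch = a & ~hit
        lp_sw = base_sw[reg] + dep[cat] * dep_mask[reg]
        sw = can_switch & (u_switch[:, t] < _logistic(lp_sw))
        if sw.any():
            dest = (u_dest[sw, t][:, None] > trans_cum[reg[sw]][:, :4]).sum(axis=1)
            for i, old, new in zip(np.where(sw)[0], reg[sw], dest):
                switch_rec.append((i, t, int(old), int(new)))
            reg[sw] = dest

        # dropout and administrative censoring
        drop = can_switch & (t >= config.min_followup_months) & \
            (u_drop[:, t] < config.dropout_hazard_monthly)
        admin = a & ~hit & (t >= admin_months)
        cens = drop | admin
        if cens.any():
            terminal_month[cens] = t
            terminal_day[cens] = t * MONTH_DAYS
            active[cens] = False

        # labs drawn during this month become visible from next month on
        has_lab = lab_present[:, t]
        egfr_obs[has_lab] = egfr_lat[has_lab]

    latent = {
        "egfr": latent_traj,
        "cd4": cd4_traj,
        "vl_log10": vl_traj,
        "event_month": event_month,
        "event_day": event_day,
        "terminal_month": terminal_month,
        "terminal_day": terminal_day,
        "event_egfr": event_egfr,
        "switches": switch_rec,
    }

    labs = _assemble_labs(baseline, config, latent, lab_month_days, meas_noise) \
        if build_labs else pd.DataFrame()
    regs = _assemble_regimens(baseline, latent)
    return SimulatedCohort(baseline=baseline, labs=labs, regimens=regs,
                           latent=latent, config=config)


def _assemble_labs(baseline, config, latent, lab_month_days, meas_noise):
    start = pd.to_datetime(baseline["art_start_date"]).to_numpy()
    age0 = baseline["age_at_start"].to_numpy(dtype=float)
    female = (baseline["sex"] == "F").to_numpy()
    egfr0 = baseline["baseline_egfr"].to_numpy(dtype=float)
    traj = latent["egfr"]
    cd4_traj = latent["cd4"]
    vl_traj = latent["vl_log10"]
    ev_day = latent["event_day"]
    ev_month = latent["event_month"]
    term_day = latent["terminal_day"]

    pid_out, day_out, egfr_out, cd4_out, vl_out = [], [], [], [], []
    n = len(baseline)
    for i in range(n):
        days = [-30.0]
        vals = [egfr0[i]]
        sched = lab_month_days[i]
        noise = meas_noise[i]
        lim = ev_day[i] if ev_month[i] else term_day[i]
        k = 0
        post_days, post_vals = [], []
        while k < len(sched) and sched[k] <= lim:
            d = sched[k]
            m = min(int(np.ceil(d / MONTH_DAYS)), traj.shape[1] - 1)
            post_days.append(d)
            post_vals.append(max(61.0, float(traj[i, m]) + noise[k]))
            k += 1
        if ev_month[i]:
            # forced sub-60 measurement at the event day + confirmation 100 d later
            e = float(np.clip(latent["event_egfr"][i], 40.0, 56.0))
            post_days.extend([ev_day[i], ev_day[i] + 100.0])
            post_vals.extend([e, max(30.0, e - 1.5)])
        else:
            # guarantee the two post-initiation measurements eligibility needs
            while len(post_days) < 2:
                d = term_day[i] * (0.5 if not post_days else 1.0)
                m = min(int(np.ceil(d / MONTH_DAYS)), traj.shape[1] - 1)
                post_days.append(max(d, 10.0))
                post_vals.append(max(61.0, float(traj[i, max(m, 1)])))
        days.extend(post_days)
        vals.extend(post_vals)
        mm = [max(0, min(int(np.ceil(d / MONTH_DAYS)), traj.shape[1] - 1)) for d in days]
        pid_out.extend([i] * len(days))
        day_out.extend(days)
        egfr_out.extend(vals)
        cd4_out.extend(float(cd4_traj[i, m]) for m in mm)
        vl_out.extend(float(vl_traj[i, m]) for m in mm)

    pid_out = np.asarray(pid_out)
    day_out = np.round(np.asarray(day_out)).astype(int)
    egfr_arr = np.asarray(egfr_out, dtype=float)
    # age at the (rounded) measurement date, so the analysis-side MDRD
    # computation round-trips the intended eGFR exactly
    age_meas = age0[pid_out] + day_out / 365.25
    scr = scr_from_egfr(egfr_arr, age_meas, female[pid_out])
    dates = start[pid_out] + day_out.astype("timedelta64[D]")
    labs = pd.DataFrame(
        {
            "patient_id": baseline["patient_id"].to_numpy()[pid_out],
            "date": pd.to_datetime(dates),
            "scr_mg_dl": np.round(scr, 4),
            "cd4": np.round(cd4_out).astype(int),
            "vl_copies": np.round(10 ** np.asarray(vl_out)).astype(int),
        }
    )
    return labs.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def _assemble_regimens(baseline, latent):
    start = pd.to_datetime(baseline["art_start_date"])
    n = len(baseline)
    term_day = latent["terminal_day"]
    # per patient: list of (start_day, cat)
    spells = {i: [(0.0, _CAT_INDEX[c])] for i, c in enumerate(baseline["initial_regimen"])}
    for i, t, old, new in latent["switches"]:
        spells[i].append(((t - 0.5) * MONTH_DAYS, new))
    rows = []
    for i in range(n):
        sp = spells[i]
        for j, (d0, cat) in enumerate(sp):
            d1 = sp[j + 1][0] if j + 1 < len(sp) else term_day[i]
            if d1 <= d0:
                continue
            rows.append((i, d0, d1, cat))
    idx = np.array([r[0] for r in rows])
    d0 = np.array([r[1] for r in rows])
    d1 = np.array([r[2] for r in rows])
    cats = np.array([rg.CATEGORIES[r[3]] for r in rows])
    regs = pd.DataFrame(
        {
            "patient_id": baseline["patient_id"].to_numpy()[idx],
            "start_date": (start.to_numpy()[idx]
                           + np.round(d0).astype(int).astype("timedelta64[D]")),
            "stop_date": (start.to_numpy()[idx]
                          + np.round(d1).astype(int).astype("timedelta64[D]")),
            "drugs": [rg.REPRESENTATIVE_DRUGS[c] for c in cats],
            "category": cats,
        }
    )
    return regs.sort_values(["patient_id", "start_date"], kind="stable").reset_index(drop=True)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Convenience wrapper: baseline + follow-up in one call."""
    return simulate_followup(generate_baseline(config), config)


# ---------------------------------------------------------------------------
# counterfactual oracle
# ---------------------------------------------------------------------------

def simulate_counterfactual_reference(config: SimConfig, n_large: int = 50_000):
    """True marginal hazard ratios per initial-regimen contrast.

    Re-runs the engine with switching and dropout disabled (everyone keeps
    the initial regimen; only administrative censoring applies) at large n,
    then fits an unadjusted proportional-hazards model of the true event
    month on the initial regimen category.  The returned log-HRs are the
    estimand the weighted causal analysis targets.
    """
    from .cox import fit_cox_person_months

    if n_large < 10_000:
        warnings.warn(
            f"n_large={n_large} gives a noisy oracle; Monte-Carlo SE attached",
            stacklevel=2,
        )
    cfg = config.replace(
        n_patients=n_large,
        switch_base_logit={c: -np.inf for c in rg.CATEGORIES},
        switch_dependence={k: 0.0 for k in config.switch_dependence},
        dropout_hazard_monthly=0.0,
    )
    base = generate_baseline(cfg)
    cohort = simulate_followup(base, cfg, build_labs=False)
    dur = cohort.latent["terminal_month"]
    ev = cohort.latent["event_month"] > 0

    # person-month expansion of (duration, event) for the unit-interval engine
    reps = dur.astype(int)
    pid = np.repeat(np.arange(len(base)), reps)
    stop = np.concatenate([np.arange(1, d + 1) for d in reps])
    event = np.zeros(len(stop), dtype=bool)
    last = np.cumsum(reps) - 1
    event[last] = ev

    cats = np.array([_CAT_INDEX[c] for c in base["initial_regimen"]])[pid]
    contrasts = [c for c in rg.CATEGORIES if c != rg.REFERENCE_CATEGORY]
    X = np.column_stack([(cats == _CAT_INDEX[c]).astype(float) for c in contrasts])
    fit = fit_cox_person_months(X, stop, event, names=list(contrasts))
    return {
        "log_hr": dict(zip(contrasts, fit.beta)),
        "hr": dict(zip(contrasts, np.exp(fit.beta))),
        "mc_se": dict(zip(contrasts, fit.se)),
        "n_events": fit.n_events,
        "n": n_large,
    }
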