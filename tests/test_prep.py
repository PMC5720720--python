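import numpy as np
import pandas as pd
import pytest

from artckd.prep import (MONTH_DAYS, apply_eligibility, attach_egfr,
                         detect_ckd_event, detect_events,
                         expand_person_months, prepare_cohort,
                         select_baseline_egfr)
from artckd.egfr import scr_from_egfr

START = pd.Timestamp("2008-06-01")


def lab_frame(pid, day_values, age=40.0, female=False):
    """Build a lab table whose MDRD eGFR equals the given values exactly."""
    days, values = zip(*day_values)
    ages = age + np.asarray(days) / 365.25
    return pd.DataFrame({
        "patient_id": pid,
        "date": [START + pd.Timedelta(days=int(d)) for d in days],
        "scr_mg_dl": scr_from_egfr(np.asarray(values, float), ages, female),
        "cd4": 300,
        "vl_copies": 40,
    })


def patient_frame(pids, starts=None, **overrides):
    n = len(pids)
    base = dict(
        patient_id=pids,
        art_start_date=[starts[i] if starts else START for i in range(n)],
        age_at_start=40.0, sex="M", hiv_exposure="homosexual",
        nadir_cd4=200, baseline_cd4=300, baseline_vl_log10=4.5,
        year_of_start=2008, hbv=False, hcv=False, diabetes=False,
        hypertension=False, cvd=False, initial_regimen="TDF_NNRTI",
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestBaselineSelection:
    def test_latest_measurement_in_window_wins(self):
        labs = lab_frame("P1", [(-200, 95.0), (-30, 88.0)])
        labs = attach_egfr(labs, patient_frame(["P1"]))
        assert select_baseline_egfr(labs, START) == pytest.approx(88.0, abs=0.05)

    def test_measurement_outside_six_months_ignored(self):
        labs = attach_egfr(lab_frame("P1", [(-200, 95.0)]), patient_frame(["P1"]))
        assert select_baseline_egfr(labs, START) is None

    def test_window_boundary_day_180_included(self):
        labs = attach_egfr(lab_frame("P1", [(-180, 95.0)]), patient_frame(["P1"]))
        assert select_baseline_egfr(labs, START) == pytest.approx(95.0, abs=0.05)


class TestEligibility:
    def build(self):
        # P1 compliant; P2 starts before 2004; P3 no baseline creatinine;
        # P4 baseline exactly 60 (strict > 60 rule); P5 only one post creatinine
        starts = {"P2": pd.Timestamp("2003-06-01")}
        pts = patient_frame(["P1", "P2", "P3", "P4", "P5"],
                            starts=[starts.get(p, START)
                                    for p in ["P1", "P2", "P3", "P4", "P5"]])
        labs = pd.concat([
            lab_frame("P1", [(-30, 95.0), (40, 90.0), (100, 85.0)]),
            lab_frame("P2", [(-30, 95.0), (40, 90.0), (100, 85.0)]),
            lab_frame("P3", [(40, 90.0), (100, 85.0)]),
            lab_frame("P4", [(-30, 60.0), (40, 90.0), (100, 85.0)]),
            lab_frame("P5", [(-30, 95.0), (40, 90.0)]),
        ])
        # P2 labs are relative to its own (2003) start date
        labs.loc[labs.patient_id == "P2", "date"] -= (START - starts["P2"])
        return pts, labs

    def test_hand_enumerated_exclusions(self):
        pts, labs = self.build()
        labs = attach_egfr(labs, pts)
        # pin P4's baseline measurement at exactly 60 (strict > 60 rule)
        labs.loc[(labs.patient_id == "P4") & (labs.day < 0), "egfr"] = 60.0
        retained, excluded = apply_eligibility(pts, labs)
        assert list(retained.patient_id) == ["P1"]
        reasons = dict(zip(excluded.patient_id, excluded.reason))
        assert reasons == {
            "P2": "art_start_before_2004",
            "P3": "no_valid_baseline_egfr",
            "P4": "no_valid_baseline_egfr",
            "P5": "insufficient_post_creatinine",
        }

    def test_all_compliant_is_identity(self):
        pts = patient_frame(["A", "B"])
        labs = pd.concat([
            lab_frame("A", [(-10, 100.0), (30, 95.0), (90, 92.0)]),
            lab_frame("B", [(-10, 100.0), (30, 95.0), (90, 92.0)]),
        ])
        retained, excluded = apply_eligibility(pts, labs)
        assert len(retained) == 2 and len(excluded) == 0
        assert retained.baseline_egfr.tolist() == pytest.approx([100, 100], abs=0.05)


class TestEventDetection:
    def test_confirmed_event(self):
        hit = detect_ckd_event([0, 100, 200], [90, 55, 52])
        assert hit == (100.0, 200.0)

    def test_recovery_voids_candidate(self):
        assert detect_ckd_event([0, 100, 130, 250], [90, 55, 62, 52]) is None

    def test_all_above_threshold(self):
        assert detect_ckd_event([0, 100, 200], [90, 80, 70]) is None

    def test_confirmation_requires_90_days(self):
        assert detect_ckd_event([0, 50], [55, 54]) is None
        assert detect_ckd_event([0, 90], [55, 54]) == (0.0, 90.0)

    def test_insertion_of_extra_sub60_values_is_invariant(self):
        base = detect_ckd_event([10, 120], [55, 50])
        dense = detect_ckd_event([10, 40, 70, 100, 120], [55, 59, 52, 58, 50])
        assert base[0] == dense[0] == 10.0

    def test_any_later_confirm_relaxation(self):
        days, vals = [0, 100, 130, 250], [90, 55, 62, 52]
        assert detect_ckd_event(days, vals) is None
        assert detect_ckd_event(days, vals, any_later_confirm=True) == (100.0, 250.0)


def regimen_frame(pid, stop_day, category="TDF_NNRTI", start=START):
    return pd.DataFrame({
        "patient_id": [pid],
        "start_date": [start],
        "stop_date": [start + pd.Timedelta(days=int(stop_day))],
        "category": [category],
    })


class TestPersonMonthExpansion:
    def test_event_at_day_100_lands_in_month_4(self):
        pts = patient_frame(["P1"])
        pts["baseline_egfr"] = 100.0
        labs = attach_egfr(lab_frame("P1", [(-30, 100.0), (100, 55.0), (200, 52.0)]),
                           pts)
        events = pd.DataFrame({"patient_id": ["P1"], "event_day": [100.0],
                               "confirming_day": [200.0]})
        pm = expand_person_months(pts, labs, regimen_frame("P1", 200), events)
        assert pm.month.max() == 4  # 3*30.44 < 100 <= 4*30.44
        assert pm.event.tolist() == [False, False, False, True]

    def test_no_switch_24_months_all_on_initial(self):
        pts = patient_frame(["P1"])
        pts["baseline_egfr"] = 100.0
        labs = attach_egfr(lab_frame("P1", [(-30, 100.0), (100, 95.0), (400, 92.0)]),
                           pts)
        pm = expand_person_months(pts, labs, regimen_frame("P1", 24 * MONTH_DAYS + 1),
                                  pd.DataFrame(columns=["patient_id", "event_day"]))
        assert len(pm) == 24
        assert pm.on_initial.all()
        assert (pm.current_regimen == "TDF_NNRTI").all()

    def test_lvcf_category_trace(self):
        # 95 measured before start, 65 measured at day 121 (just before the
        # month-5 boundary at 121.76): months 1-4 read >90, month 5 on 51-70
        pts = patient_frame(["P1"])
        pts["baseline_egfr"] = 95.0
        labs = attach_egfr(lab_frame("P1", [(-30, 95.0), (121, 65.0), (130, 64.0)]),
                           pts)
        pm = expand_person_months(pts, labs, regimen_frame("P1", 8 * MONTH_DAYS + 1),
                                  pd.DataFrame(columns=["patient_id", "event_day"]))
        cats = pm.egfr_cat.astype(str).tolist()
        assert cats[:4] == [">90"] * 4
        assert all(c == "51-70" for c in cats[4:])

    def test_previous_regimen_and_switch_flag(self):
        pts = patient_frame(["P1"])
        pts["baseline_egfr"] = 100.0
        labs = attach_egfr(lab_frame("P1", [(-30, 100.0), (50, 95.0), (300, 93.0)]),
                           pts)
        regs = pd.DataFrame({
            "patient_id": ["P1", "P1"],
            "start_date": [START, START + pd.Timedelta(days=152)],
            "stop_date": [START + pd.Timedelta(days=152),
                          START + pd.Timedelta(days=365)],
            "category": ["TDF_rbPI", "noTDF_rbPI"],
        })
        pm = expand_person_months(pts, labs, regs,
                                  pd.DataFrame(columns=["patient_id", "event_day"]))
        # switch at day 152 falls in month 5 ((4*30.44, 5*30.44])
        assert pm.loc[pm.month == 5, "switched_this_month"].item()
        assert pm.loc[pm.month == 5, "on_initial"].item()  # still initial at month start
        assert not pm.loc[pm.month == 6, "on_initial"].item()
        assert pm.loc[pm.month == 6, "current_regimen"].item() == "noTDF_rbPI"
        assert pm.loc[pm.month == 6, "previous_regimen"].item() == "TDF_rbPI"


class TestOnSimulatedCohort:
    def test_no_exclusions_and_full_recovery(self, small_cohort, prepared):
        assert len(prepared["exclusions"]) == 0
        assert len(prepared["patients"]) == len(small_cohort.baseline)

    def test_detected_events_match_latent_truth(self, small_cohort, prepared):
        lat = small_cohort.latent
        idx = {p: i for i, p in enumerate(small_cohort.baseline.patient_id)}
        truth = {p: lat["event_month"][i] for p, i in idx.items()
                 if lat["event_month"][i] > 0}
        detected = {r.patient_id: int(np.ceil(r.event_day / MONTH_DAYS))
                    for r in prepared["events"].itertuples()}
        assert detected == truth

    def test_followup_conservation(self, small_cohort, prepared):
        """Months per patient match the latent terminal month to +-1."""
        pm = prepared["person_months"]
        lat = small_cohort.latent
        idx = {p: i for i, p in enumerate(small_cohort.baseline.patient_id)}
        per = pm.groupby("patient_id").month.max()
        diffs = np.array([per[p] - lat["terminal_month"][idx[p]] for p in per.index])
        assert np.all(np.abs(diffs) <= 1)

    def test_no_categories_missing_after_month_1(self, prepared):
        pm = prepared["person_months"]
        assert pm[["egfr_cat", "cd4_cat", "vl_cat"]].notna().all().all()

    def test_terminal_flags_mutually_consistent(self, prepared):
        pm = prepared["person_months"]
        per = pm.groupby("patient_id").agg(events=("event", "sum"))
        assert (per.events <= 1).all()
        # no rows after the event month
        ev_rows = pm[pm.event]
        last = pm.groupby("patient_id").month.max()
        assert all(last[r.patient_id] == r.month for r in ev_rows.itertuples())
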