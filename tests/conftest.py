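import warnings

import numpy as np
import pandas as pd
import pytest

from artckd.simulate import SimConfig, generate_baseline, simulate_followup

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def small_config(**kw):
    """A fast-but-realistic scenario for unit tests."""
    defaults = dict(n_patients=400, seed=12345, followup_max_months=72)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    return simulate_followup(generate_baseline(cfg), cfg)


@pytest.fixture(scope="session")
def prepared(small_cohort):
    from artckd.prep import prepare_cohort

    return prepare_cohort(small_cohort.baseline, small_cohort.labs,
                          small_cohort.regimens)


def toy_person_months(rows):
    """Build a minimal person-month frame from per-row dicts.

    Each row needs at least patient_id/month; analysis columns default to
    quiet values so individual tests only specify what they exercise.
    """
    defaults = dict(
        month_start_day=0.0, current_regimen="TDF_NNRTI",
        previous_regimen=None, initial_regimen="TDF_NNRTI", on_initial=True,
        egfr_cat=">90", cd4_cat=">350", vl_cat="<=50", event=False,
        switched_this_month=False, censored_this_month=False,
        age_at_start=40.0, nadir_cd4=250.0, baseline_cd4=300.0,
        baseline_vl_log10=4.5, baseline_egfr=100.0, year_of_start=2008,
        female=0.0, exposure_heterosexual=0.0, exposure_other=0.0,
        hbv=0.0, hcv=0.0, diabetes=0.0, hypertension=0.0, cvd=0.0,
    )
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        d["month_start_day"] = (d["month"] - 1) * 30.44
        out.append(d)
    return pd.DataFrame(out)


def patient_track(pid, months, initial="TDF_NNRTI", event_month=None,
                  switch_month=None, **kw):
    """Person-month rows for one patient with optional terminal event/switch."""
    rows = []
    for m in range(1, months + 1):
        r = dict(patient_id=pid, month=m, initial_regimen=initial,
                 current_regimen=initial, **kw)
        if switch_month is not None and m > switch_month:
            r["on_initial"] = False
        if switch_month is not None and m == switch_month:
            r["switched_this_month"] = True
        if event_month is not None and m == event_month:
            r["event"] = True
        rows.append(r)
        if event_month is not None and m == event_month:
            break
    return rows
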