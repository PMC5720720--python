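import numpy as np
import pandas as pd
import pytest
from scipy import stats

import artckd.regimens as rg
from artckd.simulate import (SimConfig, generate_baseline, no_feedback_scenario,
                             null_scenario, simulate_counterfactual_reference,
                             simulate_followup)

from conftest import small_config


class TestConfig:
    def test_share_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(regimen_shares=(0.5, 0.5, 0.2, 0.1, 0.1))
        with pytest.raises(ValueError, match="probabilities"):
            SimConfig(regimen_shares=(0.6, 0.5, 0.2, -0.1, -0.2))
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)
        with pytest.raises(ValueError, match="finite"):
            SimConfig(event_intercept=float("nan"))
        with pytest.raises(ValueError):
            SimConfig(dropout_hazard_monthly=1.5)

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = small_config(event_intercept=-8.0)
        p = tmp_path / "scenario.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        cfg2 = SimConfig.from_file(p)
        assert cfg2.to_dict() == cfg.to_dict()


class TestBaseline:
    def test_determinism(self):
        cfg = small_config()
        a, b = generate_baseline(cfg), generate_baseline(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_regimen_shares_match_cohort_scale_targets(self):
        cfg = SimConfig(n_patients=6301, seed=77)
        base = generate_baseline(cfg)
        counts = base.initial_regimen.value_counts()
        expected = {"TDF_NNRTI": 1183, "TDF_rbPI": 2360, "noTDF_NNRTI": 285,
                    "noTDF_rbPI": 1606, "OTHER": 867}
        for cat, exp in expected.items():
            share = exp / 6301
            sd = np.sqrt(6301 * share * (1 - share))
            assert abs(counts[cat] - exp) < 4 * sd

    def test_zero_assignment_coefficients_give_independence(self):
        for seed in (1, 2, 3):
            cfg = small_config(
                n_patients=3000, seed=seed,
                assignment_coefs={c: {} for c in rg.CATEGORIES})
            base = generate_baseline(cfg)
            egfr_q = pd.qcut(base.baseline_egfr, 4, labels=False)
            table = pd.crosstab(base.initial_regimen, egfr_q)
            _, p, _, _ = stats.chi2_contingency(table)
            assert p > 0.005

    def test_all_baseline_egfr_above_60(self):
        base = generate_baseline(small_config())
        assert (base.baseline_egfr > 60).all()

    def test_baseline_marginals_near_targets(self):
        base = generate_baseline(SimConfig(n_patients=6301, seed=5))
        assert base.age_at_start.median() == pytest.approx(39, abs=1.5)
        assert base.baseline_egfr.median() == pytest.approx(101, abs=3)
        assert base.baseline_cd4.median() == pytest.approx(289, abs=20)
        assert (base.sex == "M").mean() == pytest.approx(0.73, abs=0.03)


class TestFollowup:
    def test_deterministic_exports(self, small_cohort):
        cfg = small_config()
        again = simulate_followup(generate_baseline(cfg), cfg)
        pd.testing.assert_frame_equal(small_cohort.labs, again.labs)
        pd.testing.assert_frame_equal(small_cohort.regimens, again.regimens)

    def test_terminal_state_consistency(self, small_cohort):
        lat = small_cohort.latent
        ev, term = lat["event_month"], lat["terminal_month"]
        assert (ev >= 0).all()
        assert np.all(term >= 1)          # no terminal state before month 1
        assert np.all(ev[ev > 0] <= term[ev > 0])

    def test_regimen_intervals_contiguous_nonoverlapping(self, small_cohort):
        regs = small_cohort.regimens
        for _, g in regs.groupby("patient_id"):
            g = g.sort_values("start_date")
            assert (g.stop_date.values > g.start_date.values).all()
            if len(g) > 1:
                assert (g.start_date.values[1:] == g.stop_date.values[:-1]).all()

    def test_every_patient_has_baseline_and_two_post_labs(self, small_cohort):
        labs = small_cohort.labs.merge(
            small_cohort.baseline[["patient_id", "art_start_date"]], on="patient_id")
        labs["day"] = (labs.date - labs.art_start_date).dt.days
        pre = labs[(labs.day >= -180) & (labs.day <= 0)].groupby("patient_id").size()
        post = labs[labs.day > 0].groupby("patient_id").size()
        n = len(small_cohort.baseline)
        assert len(pre) == n and len(post) == n
        assert (post >= 2).all()

    def test_lab_gap_median_near_target(self, small_cohort):
        labs = small_cohort.labs
        gaps = labs.groupby("patient_id").date.apply(
            lambda s: s.diff().dt.days.dropna() / 30.44)
        assert gaps.median() == pytest.approx(2.6, abs=0.35)

    def test_exported_files_contain_no_latent_columns(self, small_cohort, tmp_path):
        out = small_cohort.to_csv(tmp_path, with_oracle=False)
        for f in ("patients.csv", "labs.csv", "regimens.csv"):
            cols = pd.read_csv(out / f, nrows=1).columns
            assert not any("true" in c or "latent" in c or "terminal" in c
                           for c in cols)
        assert not (out / "oracle.csv").exists()
        small_cohort.to_csv(tmp_path, with_oracle=True)
        assert (tmp_path / "oracle.csv").exists()

    def test_strong_drift_category_has_highest_event_rate(self):
        drift = {c: 0.0 for c in rg.CATEGORIES}
        drift[rg.OTHER] = -4.0  # severe renal decline for one category only
        cfg = small_config(
            n_patients=2500, seed=9,
            egfr_drift_by_regimen=drift,
            true_log_hr_by_regimen={c: 0.0 for c in rg.CATEGORIES},
            assignment_coefs={c: {} for c in rg.CATEGORIES},
            switch_base_logit={c: -np.inf for c in rg.CATEGORIES},
        )
        coh = simulate_followup(generate_baseline(cfg), cfg)
        ev = pd.Series(coh.latent["event_month"] > 0,
                       index=coh.baseline.initial_regimen)
        rates = ev.groupby(level=0).mean()
        assert rates[rg.OTHER] == rates.max()
        assert rates[rg.OTHER] > 2 * rates.drop(rg.OTHER).max()

    def test_no_feedback_switching_independent_of_egfr(self):
        cfg = no_feedback_scenario(n_patients=2500, seed=11,
                                   followup_max_months=72)
        coh = simulate_followup(generate_baseline(cfg), cfg)
        from artckd.prep import prepare_cohort
        pm = prepare_cohort(coh.baseline, coh.labs, coh.regimens)["person_months"]
        on = pm[pm.on_initial & pm.initial_regimen.isin([rg.TDF_RBPI, rg.TDF_NNRTI])]
        low = on[on.egfr_cat.astype(str).isin(["51-70", "71-90"])]
        high = on[on.egfr_cat.astype(str) == ">90"]
        r_low = low.switched_this_month.mean()
        r_high = high.switched_this_month.mean()
        se = np.sqrt(r_low / max(len(low), 1) + r_high / max(len(high), 1))
        assert abs(r_low - r_high) < 4 * se + 1e-9


class TestCounterfactualOracle:
    def test_null_configuration_gives_unit_hazard_ratios(self):
        cfg = null_scenario(seed=3).replace(
            assignment_coefs={c: {} for c in rg.CATEGORIES})
        oracle = simulate_counterfactual_reference(cfg, n_large=20_000)
        for cat, log_hr in oracle["log_hr"].items():
            assert abs(log_hr) < 3.5 * oracle["mc_se"][cat]

    def test_oracle_stable_across_seeds(self):
        vals, ses = [], []
        for seed in (5, 6):
            o = simulate_counterfactual_reference(SimConfig(seed=seed),
                                                  n_large=15_000)
            vals.append(o["log_hr"][rg.TDF_RBPI])
            ses.append(o["mc_se"][rg.TDF_RBPI])
        combined = np.hypot(*ses)
        assert abs(vals[0] - vals[1]) < 3.5 * combined

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="noisy oracle"):
            simulate_counterfactual_reference(small_config(), n_large=2000)
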