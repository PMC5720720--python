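import numpy as np
import pandas as pd
import pytest

from artckd.weights import (StabilizedIPTW, compute_stabilized_weights,
                            fit_baseline_treatment_model,
                            fit_switch_and_censor_models, weight_diagnostics)

from conftest import toy_person_months


def patients_frame(n, rng, initial):
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "age_at_start": rng.normal(40, 8, n),
        "nadir_cd4": rng.normal(250, 80, n),
        "baseline_cd4": rng.normal(320, 90, n),
        "baseline_vl_log10": rng.normal(4.5, 0.8, n),
        "baseline_egfr": rng.normal(100, 15, n),
        "year_of_start": rng.integers(2004, 2013, n),
        "female": rng.binomial(1, 0.3, n).astype(float),
        "exposure_heterosexual": rng.binomial(1, 0.4, n).astype(float),
        "exposure_other": 0.0,
        "hbv": 0.0, "hcv": 0.0, "diabetes": 0.0, "hypertension": 0.0,
        "cvd": 0.0,
        "initial_regimen": initial,
    })


class TestBaselineTreatmentModel:
    def test_constant_covariates_give_unit_weights(self):
        rng = np.random.default_rng(1)
        pts = patients_frame(400, rng, rng.choice(["A", "B", "C"], 400))
        for c in ("age_at_start", "nadir_cd4", "baseline_cd4",
                  "baseline_vl_log10", "baseline_egfr", "year_of_start",
                  "female", "exposure_heterosexual"):
            pts[c] = 1.0
        sw_a, _ = fit_baseline_treatment_model(pts)
        assert np.allclose(sw_a, 1.0, atol=1e-6)

    def test_saturated_two_class_binary_matches_cell_proportions(self):
        """One binary covariate, two classes: the MLE equals the empirical
        cell proportions, so sw_a is a ratio of marginal to cell share."""
        rng = np.random.default_rng(2)
        n = 400
        pts = patients_frame(n, rng, "A")
        for c in pts.columns:
            if c not in ("patient_id", "initial_regimen", "female"):
                if pts[c].dtype != object:
                    pts[c] = 1.0
        f = pts["female"].to_numpy()
        y = np.where(rng.random(n) < np.where(f > 0, 0.7, 0.3), "A", "B")
        pts["initial_regimen"] = y
        sw_a, info = fit_baseline_treatment_model(pts)
        marg = pd.Series(y).value_counts(normalize=True)
        for fem in (0.0, 1.0):
            for cls in ("A", "B"):
                m = (f == fem) & (y == cls)
                if not m.any():
                    continue
                cell = m.sum() / (f == fem).sum()
                expected = marg[cls] / cell
                got = sw_a[pts.patient_id[m]].to_numpy()
                assert np.allclose(got, expected, atol=1e-9)

    def test_randomised_assignment_concentrates_at_one(self):
        rng = np.random.default_rng(3)
        n = 4000
        pts = patients_frame(n, rng, rng.choice(list("ABCDE"), n))
        sw_a, _ = fit_baseline_treatment_model(pts)
        assert sw_a.mean() == pytest.approx(1.0, abs=0.02)
        assert sw_a.std() < 0.2


class TestSwitchCensorModels:
    def test_saturated_cells_match_empirical_hazards(self):
        """With a single time-varying category driving switching and all
        baseline covariates constant, fitted hazards equal cell means."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(300):
            low = i % 2 == 0
            for m in range(1, 11):
                p = 0.15 if low else 0.04
                sw = rng.random() < p
                rows.append(dict(patient_id=f"P{i}", month=m,
                                 egfr_cat="51-70" if low else ">90",
                                 switched_this_month=sw,
                                 censored_this_month=False,
                                 initial_regimen="TDF_rbPI"))
                if sw:
                    break
        pm = toy_person_months(rows)
        # constant month effect: make 'month' non-informative by duplication
        pm["month"] = 1
        pm["month_start_day"] = 0.0
        probs = fit_switch_and_censor_models(pm, stratify=False)
        for cat in ("51-70", ">90"):
            cell = probs[probs.egfr_cat == cat]
            emp = cell.switched_this_month.mean()
            assert np.allclose(cell.p_switch_den, emp, atol=1e-7)

    def test_sparse_stratum_falls_back_to_pooled(self, caplog):
        rows = []
        for i in range(60):
            reg = "TDF_rbPI" if i < 55 else "OTHER"
            for m in range(1, 6):
                rows.append(dict(patient_id=f"P{i}", month=m,
                                 initial_regimen=reg,
                                 switched_this_month=(i % 11 == 0 and m == 3),
                                 censored_this_month=(i % 13 == 0 and m == 5)))
        pm = toy_person_months(rows)
        import logging
        with caplog.at_level(logging.WARNING):
            probs = fit_switch_and_censor_models(pm, stratify=True)
        assert "pooling" in caplog.text
        assert probs.p_switch_den.between(0, 1).all()


class TestStabilizedWeights:
    def two_month_probs(self):
        return pd.DataFrame({
            "patient_id": ["P1", "P1"],
            "month": [1, 2],
            "p_switch_num": [1 - 0.98, 1 - 0.99],
            "p_switch_den": [1 - 0.95, 1 - 0.97],
            "p_cens_num": [0.0, 0.0],
            "p_cens_den": [0.0, 0.0],
        })

    def test_hand_computed_two_month_product(self):
        sw_a = pd.Series([1.0], index=["P1"])
        ws = compute_stabilized_weights(sw_a, self.two_month_probs())
        expected_m2 = (0.98 * 0.99) / (0.95 * 0.97)  # = 0.9702/0.9215
        assert ws.loc[ws.month == 1, "sw_t"].item() == pytest.approx(0.98 / 0.95, abs=1e-12)
        assert ws.loc[ws.month == 2, "sw_t"].item() == pytest.approx(expected_m2, abs=1e-12)
        assert expected_m2 == pytest.approx(1.0528, abs=1e-3)

    def test_identical_numerator_denominator_gives_unit_weights(self):
        probs = self.two_month_probs()
        probs["p_switch_num"] = probs["p_switch_den"]
        ws = compute_stabilized_weights(pd.Series([1.0], index=["P1"]), probs)
        assert np.allclose(ws.sw_t, 1.0, atol=1e-14)

    def test_shared_covariate_cancels(self):
        # multiplying both hazards' remain-probabilities by a common factor
        # leaves SW(t) unchanged
        probs = self.two_month_probs()
        ws1 = compute_stabilized_weights(pd.Series([1.0], index=["P1"]), probs)
        probs2 = probs.copy()
        probs2["p_cens_num"] = 0.03
        probs2["p_cens_den"] = 0.03
        ws2 = compute_stabilized_weights(pd.Series([1.0], index=["P1"]), probs2)
        assert np.allclose(ws1.sw_t, ws2.sw_t, atol=1e-14)

    def test_zero_denominator_raises_with_location(self):
        probs = self.two_month_probs()
        probs.loc[1, "p_switch_den"] = 1.0
        with pytest.raises(ValueError, match="P1 month 2"):
            compute_stabilized_weights(pd.Series([1.0], index=["P1"]), probs)

    def test_truncation_option(self):
        rng = np.random.default_rng(5)
        probs = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(200)],
            "month": 1,
            "p_switch_num": 0.02,
            "p_switch_den": rng.uniform(0.001, 0.4, 200),
            "p_cens_num": 0.0, "p_cens_den": 0.0,
        })
        sw_a = pd.Series(1.0, index=probs.patient_id)
        free = compute_stabilized_weights(sw_a, probs)
        trunc = compute_stabilized_weights(sw_a, probs, truncate_pct=5.0)
        assert trunc.sw_t.max() < free.sw_t.max()
        assert trunc.sw_t.max() == pytest.approx(np.percentile(free.sw_t, 95), rel=1e-9)


class TestDiagnostics:
    def test_all_unit_weights(self):
        ws = pd.DataFrame({"patient_id": ["a", "b"], "month": [1, 1],
                           "sw_t": [1.0, 1.0]})
        d = weight_diagnostics(ws)
        assert d["mean"] == 1.0 and d["sd"] == 0.0

    def test_moments_match_direct_computation(self):
        rng = np.random.default_rng(6)
        ws = pd.DataFrame({"patient_id": [f"p{i}" for i in range(500)],
                           "month": rng.integers(1, 20, 500),
                           "sw_t": rng.lognormal(0, 0.3, 500)})
        d = weight_diagnostics(ws)
        assert d["mean"] == pytest.approx(ws.sw_t.mean(), abs=1e-12)
        assert d["sd"] == pytest.approx(ws.sw_t.std(ddof=1), abs=1e-12)
        assert d["max"] == ws.sw_t.max()
        # extreme listing finds the true extreme row
        top = d["extreme"].iloc[0]
        truth = ws.loc[(ws.sw_t - 1).abs().idxmax()]
        assert top.patient_id == truth.patient_id

    def test_mean_near_one_on_simulated_cohort(self, prepared):
        iptw = StabilizedIPTW(prepared["person_months"]).fit()
        d = iptw.diagnostics()
        assert 0.9 < d["mean"] < 1.1
        assert d["min"] > 0.0
        assert "SW(t)" in iptw.summary()
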