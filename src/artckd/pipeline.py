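"""End-to-end pipeline orchestration and report generation.

Stages: simulate -> prepare -> traditional Cox fits -> stabilized weights ->
causal fits -> discontinuation -> report.  Every stage persists its outputs
(CSV/JSON) so stages can be re-run independently, and the resolved
configuration is written next to the outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import regimens as rg
from .discontinuation import build_switch_counts, fit_negbin_irr, irr_table
from .estimators import fit_all_estimators
from .prep import prepare_cohort
from .results import _jsonable
from .simulate import SCENARIOS, SimConfig, simulate_cohort
from .survival import CoxSpec, fit_cox, summarize_incidence
from .weights import StabilizedIPTW, weight_diagnostics

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "prepare", "fit-cox", "fit-weights", "fit-msm",
              "fit-nb", "report")


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML/JSON."""

    out_dir: str = "artckd_run"
    input_dir: str | None = None      # read patients/labs/regimens here; else simulate
    scenario: str = "default"
    seed: int = 1
    n_patients: int | None = None
    stages: tuple = ALL_STAGES
    with_oracle: bool = False
    stratify_weights: bool = True
    truncate_weights_pct: float | None = None
    sim_overrides: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def make_baseline_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Descriptive baseline table: median (IQR) for continuous covariates and
    n (%) for categorical ones, overall and by initial regimen category."""
    def describe(sub):
        n = len(sub)
        col = {"N (%)": f"{n} ({100 * n / max(len(patients), 1):.0f})"}
        for label, c in [("Age (years)", "age_at_start"),
                         ("Baseline eGFR", "baseline_egfr"),
                         ("Baseline CD4", "baseline_cd4"),
                         ("Baseline log10 VL", "baseline_vl_log10"),
                         ("Nadir CD4", "nadir_cd4")]:
            if n:
                q1, q2, q3 = sub[c].quantile([0.25, 0.5, 0.75])
                col[f"{label}, median (IQR)"] = f"{q2:.0f} ({q1:.0f}-{q3:.0f})" \
                    if c != "baseline_vl_log10" else f"{q2:.1f} ({q1:.1f}-{q3:.1f})"
            else:
                col[f"{label}, median (IQR)"] = "-"
        male = int((sub["sex"] == "M").sum())
        col["Male, n (%)"] = f"{male} ({100 * male / n:.0f})" if n else "-"
        for label, mask in [
            ("Homosexual", sub["hiv_exposure"] == "homosexual"),
            ("Heterosexual", sub["hiv_exposure"] == "heterosexual"),
            ("Other exposure", ~sub["hiv_exposure"].isin(["homosexual", "heterosexual"])),
            ("Hepatitis B", sub["hbv"].astype(bool)),
            ("Hepatitis C", sub["hcv"].astype(bool)),
            ("Hypertension", sub["hypertension"].astype(bool)),
            ("CVD", sub["cvd"].astype(bool)),
            ("Diabetes", sub["diabetes"].astype(bool)),
        ]:
            k = int(mask.sum())
            col[f"{label}, n (%)"] = f"{k} ({100 * k / n:.0f})" if n else "-"
        return pd.Series(col)

    cols = {"All": describe(patients)}
    for cat in rg.CATEGORIES:
        cols[cat] = describe(patients[patients["initial_regimen"] == cat])
    return pd.DataFrame(cols)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    config.save(out / "resolved_config.yaml")

    bundle: dict = {"config": config}
    results_json: dict = {"seed": config.seed, "scenario": config.scenario}
    timings = {}

    def stage(name):
        return name in config.stages

    try:
        t0 = time.time()
        if config.input_dir is not None:
            d = Path(config.input_dir)
            patients = pd.read_csv(d / "patients.csv", parse_dates=["art_start_date"])
            labs = pd.read_csv(d / "labs.csv", parse_dates=["date"])
            regimens = pd.read_csv(d / "regimens.csv",
                                   parse_dates=["start_date", "stop_date"])
        elif stage("simulate"):
            sim_kw = dict(config.sim_overrides)
            sim_kw["seed"] = config.seed
            if config.n_patients:
                sim_kw["n_patients"] = config.n_patients
            sim_config = SCENARIOS[config.scenario](**sim_kw)
            cohort = simulate_cohort(sim_config)
            cohort.to_csv(out, with_oracle=config.with_oracle)
            bundle["cohort"] = cohort
            patients, labs, regimens = cohort.baseline, cohort.labs, cohort.regimens
        else:
            raise ValueError("no input_dir and simulate stage disabled")
        timings["simulate"] = time.time() - t0

        if stage("prepare"):
            t0 = time.time()
            prep = prepare_cohort(patients, labs, regimens)
            pm = prep["person_months"]
            pm.to_csv(out / "person_months.csv", index=False)
            prep["exclusions"].to_csv(out / "exclusions.csv", index=False)
            bundle["prep"] = prep
            results_json["n_patients"] = len(prep["patients"])
            results_json["n_excluded"] = len(prep["exclusions"])
            results_json["incidence"] = summarize_incidence(pm)
            baseline_table = make_baseline_table(prep["patients"])
            baseline_table.to_csv(out / "table1_baseline.csv")
            bundle["baseline_table"] = baseline_table
            timings["prepare"] = time.time() - t0
        else:
            pm = None

        if stage("fit-cox") and pm is not None:
            t0 = time.time()
            cox_results = {}
            for coding in ("initial", "current", "current_plus_previous"):
                spec = CoxSpec(exposure_coding=coding, adjusted=True)
                cox_results[coding] = fit_cox(pm, spec)
            bundle["cox"] = cox_results
            results_json["all_events_models"] = {
                k: v.to_dict() for k, v in cox_results.items()}
            (out / "table2_all_events.txt").write_text(
                "\n\n".join(v.summary() for v in cox_results.values()))
            timings["fit-cox"] = time.time() - t0

        weights = None
        if stage("fit-weights") and pm is not None:
            t0 = time.time()
            iptw = StabilizedIPTW(pm, stratify=config.stratify_weights,
                                  truncate_pct=config.truncate_weights_pct).fit()
            weights = iptw.weights
            weights.to_csv(out / "weights.csv", index=False)
            diag = weight_diagnostics(weights)
            results_json["weight_diagnostics"] = {
                k: diag[k] for k in ("mean", "sd", "min", "max", "n")}
            diag["per_month"].to_csv(out / "weight_per_month.csv")
            bundle["iptw"] = iptw
            timings["fit-weights"] = time.time() - t0

        if stage("fit-msm") and pm is not None:
            t0 = time.time()
            causal = fit_all_estimators(pm, weights)
            bundle["causal"] = causal
            results_json["on_initial_models"] = {
                k: v.to_dict() for k, v in causal.items()}
            (out / "table3_on_initial.txt").write_text(
                "\n\n".join(v.summary() for v in causal.values()))
            timings["fit-msm"] = time.time() - t0

        if stage("fit-nb") and pm is not None:
            t0 = time.time()
            nb = {}
            for mode in ("any_regimen", "initial_only"):
                recs = build_switch_counts(pm, mode=mode)
                nb[mode] = fit_negbin_irr(recs)
                irr_table(nb[mode]).to_csv(out / f"switch_irr_{mode}.csv", index=False)
            bundle["discontinuation"] = nb
            results_json["switch_irr"] = {
                mode: {cat: res.to_dict() for cat, res in fits.items()}
                for mode, fits in nb.items()}
            timings["fit-nb"] = time.time() - t0

        if stage("report"):
            (out / "results.json").write_text(
                json.dumps(_jsonable(results_json), indent=2, sort_keys=True))
            (out / "timings.json").write_text(
                json.dumps({k: round(v, 2) for k, v in timings.items()}, indent=2))
            logger.info("stage timings (s): %s",
                        {k: round(v, 2) for k, v in timings.items()})
        bundle["results_json"] = results_json
    except Exception as exc:  # persist partial state for debugging
        (out / "FAILED_STAGE.txt").write_text(f"{type(exc).__name__}: {exc}")
        raise
    finally:
        logging.getLogger().removeHandler(fh)
    return bundle
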