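"""End-to-end orchestration: simulate or ingest a trial, run every analysis
stage, and write a report bundle of CSV/JSON/plain-text tables shaped like a
phase II trial publication (demographics, efficacy, safety, PK, Bayesian
decision block, KM summaries).

Regenerating the bundle from the same dataset is byte-identical: all
randomness is seeded and all numbers flow deterministically from the tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayes, endpoints, pk, safety
from ._utils import fmt_count_pct, pct, round_half_up
from .config import TrialConfig
from .datasets import TrialDataset
from .simulate import simulate_trial
from .survival import SurvivalSample, km_estimate, logrank_one_sided

ARMS = ("experimental", "control")


def demographics_table(dataset: TrialDataset) -> pd.DataFrame:
    """Baseline table: per-arm and pooled n (%) for stage and ECOG,
    mean/SD/median/range for age and BSA."""
    p = dataset.patients
    arms_present = tuple(a for a in ARMS if (p["arm"] == a).any())
    sizes = {arm: int((p["arm"] == arm).sum()) for arm in arms_present}
    n_all = len(p)
    rows: list[dict] = []

    def numeric_rows(col: str, label: str) -> None:
        for stat in ("mean", "sd", "median", "range"):
            row = {"parameter": label, "statistic": stat}
            for arm in [*arms_present, "pooled"]:
                vals = p[col] if arm == "pooled" else p.loc[p["arm"] == arm, col]
                vals = vals.dropna()
                if stat == "mean":
                    cell = f"{vals.mean():.1f}"
                elif stat == "sd":
                    cell = f"{vals.std(ddof=1):.1f}" if len(vals) > 1 else "NA"
                elif stat == "median":
                    cell = f"{vals.median():.1f}"
                else:
                    cell = f"{vals.min():.1f}–{vals.max():.1f}"
                row[arm] = cell
            rows.append(row)

    numeric_rows("age", "age_years")
    numeric_rows("bsa", "bsa_m2")

    def categorical_rows(col: str, label: str, cats) -> None:
        for cat in cats:
            row = {"parameter": label, "statistic": str(cat)}
            for arm in [*arms_present, "pooled"]:
                sub = p if arm == "pooled" else p[p["arm"] == arm]
                denom = n_all if arm == "pooled" else sizes[arm]
                count = int((sub[col].astype(str) == str(cat)).sum())
                row[arm] = fmt_count_pct(count, denom)
            rows.append(row)

    if "stage" in p.columns:
        categorical_rows("stage", "stage", ["II", "III", "IV", "Unknown"])
    if "ecog" in p.columns:
        categorical_rows("ecog", "ecog_ps", [0, 1, 2])
    if "sex" in p.columns:
        categorical_rows("sex", "sex", ["Female", "Male"])
    return pd.DataFrame(rows)


def _km_row(curve) -> dict:
    return {
        "median": "NE" if curve.median is None else f"{curve.median:.1f}",
        "range": curve.range_str(),
        "n": curve.n, "n_events": curve.n_events,
    }


def efficacy_tables(dataset: TrialDataset) -> dict:
    """KM medians/ranges for OS and PFS, the one-sided log-rank sensitivity
    p, response/CBR intervals, duration of response, tumor-change p."""
    p = dataset.patients
    out: dict = {"km": {}, "logrank": {}}
    for ep_name, (tcol, ecol) in {"os": ("os_time", "os_event"),
                                  "pfs": ("pfs_time", "pfs_event")}.items():
        curves = {}
        for arm in ARMS:
            curves[arm] = km_estimate(
                SurvivalSample.from_frame(p, arm, tcol, ecol))
        out["km"][ep_name] = {arm: _km_row(c) for arm, c in curves.items()}
        lr = logrank_one_sided(
            SurvivalSample.from_frame(p, "experimental", tcol, ecol),
            SurvivalSample.from_frame(p, "control", tcol, ecol))
        out["logrank"][ep_name] = {
            "z": round(lr.z, 4), "p_one_sided": round(lr.p_one_sided, 4)}

    summary = endpoints.response_summary(dataset)
    resp_rows = []
    for arm, s in summary.arms.items():
        row = {"arm": arm, "n": s.n, **{f"n_{k}": v for k, v in s.counts.items()},
               "orr": s.orr.render(), "cbr": s.cbr.render()}
        if s.duration_of_response is not None:
            c = s.duration_of_response
            row["dor_median"] = "NE" if c.median is None else f"{c.median:.1f}"
            row["dor_range"] = c.range_str()
        else:
            row["dor_median"], row["dor_range"] = "NE", "NE"
        resp_rows.append(row)
    out["response"] = pd.DataFrame(resp_rows)

    deltas = endpoints.tumor_deltas(dataset)
    if all(len(deltas.get(a, ())) >= 2 for a in ARMS):
        out["tumor_change_p"] = round(
            endpoints.tumor_change_test(deltas["experimental"],
                                        deltas["control"]), 4)
    if dataset.ca199 is not None:
        out["ca199"] = endpoints.ca199_summary(dataset)
    return out


def safety_tables(dataset: TrialDataset) -> dict:
    sizes = {arm: int((dataset.patients["arm"] == arm).sum()) for arm in ARMS}
    out: dict = {}
    if dataset.ae is not None and len(dataset.ae):
        out["teae_ge10pct"] = safety.teae_table(dataset.ae, sizes,
                                                min_incidence_pct=10.0)
        out["teae_g34_ge5pct"] = safety.teae_table(
            dataset.ae, sizes, min_incidence_pct=5.0, grade_filter=(3, 4))
        out["any_teae"] = safety.any_teae_row(dataset.ae, sizes)
    if dataset.ecg is not None and len(dataset.ecg):
        out["qtcf_categories"] = safety.qtcf_category_counts(dataset.ecg)
    return out


def pk_tables(dataset: TrialDataset) -> dict | None:
    if dataset.pk is None or len(dataset.pk) == 0:
        return None
    results = pk.nca_cohort(dataset.pk)
    summary = pk.summarize_cohort(results)
    attain = pk.exposure_target_attainment(results)
    return {"summary": summary, "attainment": attain, "n_profiles": len(results)}


@dataclass
class ReportBundle:
    demographics: pd.DataFrame
    efficacy: dict
    safety: dict
    pk: dict | None
    bayes_block: dict
    seed: int | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(out / "table1_demographics.csv", index=False)
        self.efficacy["response"].to_csv(out / "table2_response.csv",
                                         index=False)
        with open(out / "km_logrank.json", "w") as fh:
            json.dump({"km": self.efficacy["km"],
                       "logrank": self.efficacy["logrank"],
                       "tumor_change_p": self.efficacy.get("tumor_change_p")},
                      fh, indent=2, sort_keys=True)
        if "teae_ge10pct" in self.safety:
            self.safety["teae_ge10pct"].to_csv(
                out / "table3_teae.csv", index=False)
            self.safety["teae_g34_ge5pct"].to_csv(
                out / "table4_teae_g34.csv", index=False)
        if "qtcf_categories" in self.safety:
            self.safety["qtcf_categories"].to_csv(
                out / "qtcf_categories.csv", index=False)
        if self.pk is not None:
            self.pk["summary"].table.to_csv(out / "table5_pk.csv", index=False)
            self.pk["attainment"].to_csv(out / "pk_attainment.csv",
                                         index=False)
        with open(out / "bayes_decision.json", "w") as fh:
            json.dump(self.bayes_block, fh, indent=2, sort_keys=True)


def run_pipeline(config: TrialConfig | None = None,
                 dataset: TrialDataset | None = None,
                 seed: int | None = None,
                 a0: float = bayes.DEFAULT_A0,
                 historical=bayes.DEFAULT_HISTORICAL,
                 threshold: float = bayes.DEFAULT_THRESHOLD) -> ReportBundle:
    """Simulate (when no dataset is given) and run every analysis stage."""
    if dataset is None:
        if config is None:
            config = TrialConfig()
        dataset = simulate_trial(config, seed=seed)
    analysis = bayes.analyze_trial(dataset.patients, historical=historical,
                                   a0=a0, threshold=threshold)
    bayes_block = {
        "posterior_prob": round(analysis["posterior_prob"], 4),
        "threshold": threshold,
        "decision_superior": analysis["decision"],
        "a0": a0,
        "posterior_experimental": {
            "shape": analysis["posterior_experimental"].shape,
            "rate": round(analysis["posterior_experimental"].rate, 4)},
        "posterior_control": {
            "shape": analysis["posterior_control"].shape,
            "rate": round(analysis["posterior_control"].rate, 4)},
    }
    return ReportBundle(
        demographics=demographics_table(dataset),
        efficacy=efficacy_tables(dataset),
        safety=safety_tables(dataset),
        pk=pk_tables(dataset),
        bayes_block=bayes_block,
        seed=seed,
    )


def pooled_stage_iv_pct(dataset: TrialDataset) -> float:
    """Pooled Stage IV share, percent (round-half-up, one decimal)."""
    p = dataset.patients
    return pct(int((p["stage"] == "IV").sum()), len(p))
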