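"""Secondary efficacy endpoints.

Exact (Clopper–Pearson) binomial intervals for response rates, overall
response and clinical-benefit rates per arm, duration of response among
responders, a rank-sum comparison of percent tumor-size change, and the
CA19-9 marker-response rule (>50% reduction from an elevated baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import mannwhitneyu

from .config import RESPONSE_CATEGORIES
from .datasets import TrialDataset
from .survival import KMCurve, SurvivalSample, km_estimate
from ._utils import pct


def clopper_pearson(x: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles.

    lower = BetaInv(alpha/2; x, n-x+1) (0 when x = 0),
    upper = BetaInv(1-alpha/2; x+1, n-x) (1 when x = n).
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError("require n >= 1 and 0 <= x <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class BinomialEndpoint:
    successes: int
    denominator: int
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def point_estimate(self) -> float:
        return self.successes / self.denominator

    def render(self) -> str:
        """Table-style cell: 'x (p%; lo–hi)' with half-up 1-decimal rounding."""
        return (f"{self.successes} ({pct(self.successes, self.denominator):.1f}%; "
                f"{_pct1(self.ci_low):.1f}–{_pct1(self.ci_high):.1f})")


def _pct1(frac: float) -> float:
    from ._utils import round_half_up

    return round_half_up(100.0 * frac, 1)


def binomial_endpoint(x: int, n: int, level: float = 0.95) -> BinomialEndpoint:
    lo, hi = clopper_pearson(x, n, level)
    return BinomialEndpoint(successes=x, denominator=n, ci_low=lo,
                            ci_high=hi, level=level)


@dataclass(frozen=True)
class ArmResponseSummary:
    arm: str
    n: int
    counts: dict[str, int]          # per RECIST category
    orr: BinomialEndpoint           # CR + PR
    cbr: BinomialEndpoint           # CR + PR + SD
    duration_of_response: KMCurve | None   # None when not estimable


@dataclass(frozen=True)
class ResponseSummary:
    arms: dict[str, ArmResponseSummary]


def response_summary(dataset: TrialDataset, level: float = 0.95
                     ) -> ResponseSummary:
    """Per-arm best-overall-response tallies with exact intervals."""
    patients = dataset.patients
    bad = set(patients["best_response"].dropna()) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown best_response categories: {sorted(bad)}")
    out = {}
    for arm, sub in patients.groupby("arm", sort=True):
        n = len(sub)
        counts = {c: int((sub["best_response"] == c).sum())
                  for c in RESPONSE_CATEGORIES}
        n_orr = counts["CR"] + counts["PR"]
        n_cbr = n_orr + counts["SD"]
        try:
            dor = duration_of_response(dataset, arm=arm)
        except ValueError:
            dor = None
        out[arm] = ArmResponseSummary(
            arm=arm, n=n, counts=counts,
            orr=binomial_endpoint(n_orr, n, level),
            cbr=binomial_endpoint(n_cbr, n, level),
            duration_of_response=dor)
    return ResponseSummary(arms=out)


def duration_of_response(dataset: TrialDataset, arm: str | None = None
                         ) -> KMCurve:
    """Kaplan–Meier duration of response among CR/PR patients.

    Duration runs from response onset to progression/death; patients
    without a progression event are censored at last follow-up.  Raises
    ``ValueError`` when the arm has no responders ("not estimable").
    """
    patients = dataset.patients
    if arm is not None:
        patients = patients[patients["arm"] == arm]
    resp = patients[patients["best_response"].isin(["CR", "PR"])]
    if len(resp) == 0:
        raise ValueError("no responders: duration of response not estimable")
    if "response_onset_month" not in patients.columns:
        raise ValueError("patients table lacks response_onset_month")
    onset = resp["response_onset_month"].to_numpy(dtype=float)
    if np.isnan(onset).any():
        raise ValueError("responders missing response_onset_month")
    durations = np.maximum(resp["pfs_time"].to_numpy(dtype=float) - onset, 0.0)
    events = resp["pfs_event"].to_numpy(dtype=int)
    return km_estimate(SurvivalSample(durations, events, label="responders"))


def duration_from_samples(durations, events) -> KMCurve:
    """Duration-of-response KM directly from (duration, event) pairs."""
    return km_estimate(SurvivalSample(np.asarray(durations, float),
                                      np.asarray(events, int)))


def tumor_change_test(deltas_e, deltas_c) -> float:
    """Two-sided Wilcoxon rank-sum p for percent tumor-size change.

    Exact enumeration when the combined sample is small (n <= 20) and
    tie-free; the tie-corrected normal approximation otherwise.  Two
    identical constant samples give p = 1 by convention.
    """
    de = np.asarray(deltas_e, dtype=float)
    dc = np.asarray(deltas_c, dtype=float)
    if len(de) < 2 or len(dc) < 2:
        raise ValueError("each arm needs at least 2 values")
    pooled = np.concatenate([de, dc])
    if np.all(pooled == pooled[0]):
        return 1.0
    n = len(pooled)
    has_ties = len(np.unique(pooled)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(de, dc, alternative="two-sided",
                              method=method).pvalue)


def tumor_deltas(dataset: TrialDataset) -> dict[str, np.ndarray]:
    """Percent change in target-lesion sum, baseline -> week 8, per arm."""
    p = dataset.patients
    ok = p["week8_target_sum"].notna() & (p["baseline_target_sum"] > 0)
    deltas = 100.0 * (p["week8_target_sum"] - p["baseline_target_sum"]) \
        / p["baseline_target_sum"]
    return {arm: deltas[ok & (p["arm"] == arm)].to_numpy()
            for arm in p["arm"].unique()}


def ca199_response(baseline: float, series, uln: float
                   ) -> tuple[bool, bool]:
    """(evaluable, responder) under the marker-response rule.

    Evaluable iff baseline exceeds the upper limit of normal; responder iff
    the series nadir falls strictly below half the baseline (>50% reduction).
    """
    series = np.asarray(series, dtype=float)
    if baseline <= 0 or len(series) == 0:
        raise ValueError("baseline must be positive and series non-empty")
    if np.any(series < 0):
        raise ValueError("CA19-9 values must be non-negative")
    evaluable = baseline > uln
    responder = bool(evaluable and series.min() < 0.5 * baseline)
    return evaluable, responder


def ca199_summary(dataset: TrialDataset) -> pd.DataFrame:
    """Per-arm evaluable counts and marker-responder rates."""
    if dataset.ca199 is None:
        raise ValueError("dataset has no CA19-9 series table")
    p = dataset.patients.set_index("patient_id")
    rows = []
    for pid, grp in dataset.ca199.groupby("patient_id"):
        base = float(p.loc[pid, "ca199_baseline"])
        uln = float(p.loc[pid, "uln_ca199"])
        ev, resp = ca199_response(base, grp["value"].to_numpy(), uln)
        rows.append((pid, p.loc[pid, "arm"], ev, resp))
    df = pd.DataFrame(rows, columns=["patient_id", "arm", "evaluable",
                                     "responder"])
    out = df[df["evaluable"]].groupby("arm").agg(
        n_evaluable=("responder", "size"),
        n_responders=("responder", "sum"))
    out["responder_pct"] = [
        pct(int(r), int(n)) for n, r in
        zip(out["n_evaluable"], out["n_responders"])]
    return out.reset_index()
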