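"""Safety tabulation: treatment-emergent adverse-event incidence tables
with incidence/grade filters, and Fridericia-corrected QT analysis.

Counting is patient-level: a patient with several records of the same
preferred term contributes once to that term's incidence.  Preferred terms
match case-insensitively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import pct

QTC_CATEGORIES = ("<=30", "(30,60]", ">60")


def teae_table(records: pd.DataFrame, arm_sizes: dict[str, int],
               min_incidence_pct: float = 10.0,
               grade_filter: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Incidence of adverse events by preferred term and arm.

    A term is retained when its incidence reaches ``min_incidence_pct`` in
    at least one arm; ``grade_filter`` (e.g. ``(3, 4)``) restricts to those
    grades before counting.  Rows are sorted by descending pooled incidence.
    """
    for arm, n in arm_sizes.items():
        if n < 1:
            raise ValueError(f"arm size for {arm!r} must be >= 1")
    unknown = set(records["arm"].unique()) - set(arm_sizes)
    if unknown:
        raise ValueError(f"records reference unknown arms: {sorted(unknown)}")

    df = records.copy()
    df["preferred_term"] = df["preferred_term"].str.lower()
    if grade_filter is not None:
        df = df[df["grade"].isin(grade_filter)]

    arms = sorted(arm_sizes)
    rows = []
    n_pooled = sum(arm_sizes.values())
    for term, grp in df.groupby("preferred_term"):
        counts = {arm: grp.loc[grp["arm"] == arm, "patient_id"].nunique()
                  for arm in arms}
        pcts = {arm: 100.0 * counts[arm] / arm_sizes[arm] for arm in arms}
        if max(pcts.values()) < min_incidence_pct:
            continue
        pooled = grp["patient_id"].nunique()
        row = {"preferred_term": term,
               "pooled_pct": 100.0 * pooled / n_pooled}
        for arm in arms:
            row[f"n_{arm}"] = counts[arm]
            row[f"pct_{arm}"] = pct(counts[arm], arm_sizes[arm])
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["pooled_pct", "preferred_term"],
                              ascending=[False, True], ignore_index=True)
    return out


def any_teae_row(records: pd.DataFrame, arm_sizes: dict[str, int],
                 grade_filter: tuple[int, ...] | None = None) -> dict:
    """Patients with >= 1 qualifying record, per arm ('any TEAE' table row)."""
    df = records
    if grade_filter is not None:
        df = df[df["grade"].isin(grade_filter)]
    out = {}
    for arm, n in arm_sizes.items():
        c = df.loc[df["arm"] == arm, "patient_id"].nunique()
        out[arm] = {"n": c, "pct": pct(c, n)}
    return out


def qtcf(qt_ms, rr_s):
    """Fridericia heart-rate correction: QTcF = QT / RR^(1/3) (QT in ms,
    RR in seconds)."""
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR interval must be positive")
    out = qt / np.cbrt(rr)
    return float(out) if out.ndim == 0 else out


def qtcf_category(delta_ms: float) -> str:
    """Classify a QTcF change from baseline; edges: (30, 60] is the middle
    category, so exactly 60 ms is not '>60'."""
    if delta_ms > 60.0:
        return ">60"
    if delta_ms > 30.0:
        return "(30,60]"
    return "<=30"


def qtcf_change_categories(ecg: pd.DataFrame,
                           baseline_label: str = "baseline"
                           ) -> tuple[pd.DataFrame, int]:
    """Per-patient maximum post-baseline QTcF change and its category.

    Returns ``(table, n_excluded)`` where excluded patients lack either a
    baseline or any post-baseline ECG.
    """
    df = ecg.copy()
    df["qtcf"] = qtcf(df["qt_ms"].to_numpy(), df["rr_s"].to_numpy())
    rows = []
    n_excluded = 0
    for pid, grp in df.groupby("patient_id"):
        base = grp[grp["timepoint"] == baseline_label]
        post = grp[grp["timepoint"] != baseline_label]
        if len(base) == 0 or len(post) == 0:
            n_excluded += 1
            continue
        delta = float(post["qtcf"].max() - base["qtcf"].iloc[0])
        rows.append((pid, delta, qtcf_category(delta)))
    table = pd.DataFrame(rows, columns=["patient_id", "max_delta_qtcf_ms",
                                        "category"])
    return table, n_excluded


def qtcf_category_counts(ecg: pd.DataFrame) -> pd.DataFrame:
    """Counts of patients per QTcF change category."""
    table, n_excluded = qtcf_change_categories(ecg)
    counts = table["category"].value_counts()
    rows = [(cat, int(counts.get(cat, 0))) for cat in QTC_CATEGORIES]
    out = pd.DataFrame(rows, columns=["category", "n_patients"])
    out.attrs["n_excluded"] = n_excluded
    return out
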