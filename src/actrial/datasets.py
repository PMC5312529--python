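"""The TrialDataset container and its CSV round trip.

A trial is held as up to five tidy tables:

``patients`` (one row per randomized patient)
    patient_id, arm ("experimental"/"control"), entry_month,
    os_time (months), os_event (0/1), pfs_time, pfs_event,
    best_response (CR/PR/SD/PD/NE), response_onset_month (NaN unless CR/PR),
    baseline_target_sum (mm), week8_target_sum (mm, NaN if not assessed),
    ca199_baseline (U/mL), uln_ca199 (U/mL),
    age (years), sex, bsa (m^2), stage (II/III/IV/Unknown), ecog (0/1/2)

``pk`` (long format, one row per concentration sample)
    patient_id, cycle, day, time_h (from start of infusion),
    conc_ng_ml, dose_ng, tinf_h

``ae`` (one row per adverse-event record)
    patient_id, arm, preferred_term, grade (1..5), drug_related (bool),
    treatment_emergent (bool)

``ecg`` (one row per ECG)
    patient_id, timepoint ("baseline"/"day2"/"day16"), qt_ms, rr_s

``ca199`` (long format)
    patient_id, cycle, value (U/mL)
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

_TABLES = ("patients", "pk", "ae", "ecg", "ca199")


@dataclass
class TrialDataset:
    patients: pd.DataFrame
    pk: pd.DataFrame | None = None
    ae: pd.DataFrame | None = None
    ecg: pd.DataFrame | None = None
    ca199: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def arm_sizes(self) -> dict[str, int]:
        return self.patients["arm"].value_counts().to_dict()

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "TrialDataset":
        src = Path(in_dir)
        patients_path = src / "patients.csv"
        if not patients_path.exists():
            raise FileNotFoundError(f"required table missing: {patients_path}")
        kwargs = {}
        for name in _TABLES:
            path = src / f"{name}.csv"
            kwargs[name] = pd.read_csv(path) if path.exists() else None
        if kwargs["patients"] is None:  # pragma: no cover - guarded above
            raise FileNotFoundError(patients_path)
        return cls(**kwargs)

    def __post_init__(self) -> None:
        required = {"patient_id", "arm", "os_time", "os_event"}
        missing = required - set(self.patients.columns)
        if missing:
            raise ValueError(f"patients table missing columns: {sorted(missing)}")


__all__ = ["TrialDataset"]
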