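import numpy as np
import pandas as pd
import pytest

from actrial.config import TrialConfig
from actrial.datasets import TrialDataset
from actrial.simulate import simulate_trial


@pytest.fixture(scope="session")
def default_config() -> TrialConfig:
    return TrialConfig()


@pytest.fixture(scope="session")
def trial(default_config) -> TrialDataset:
    """One full synthetic trial reused across read-only tests."""
    return simulate_trial(default_config, seed=12345)


def _patients_row(i, arm, response, stage, onset=np.nan):
    return {
        "patient_id": f"F{i:03d}", "arm": arm, "entry_month": 0.0,
        "os_time": 6.0 + 0.01 * i, "os_event": 1,
        "pfs_time": 3.0 + 0.01 * i, "pfs_event": 1,
        "best_response": response, "response_onset_month": onset,
        "baseline_target_sum": 80.0,
        "week8_target_sum": 50.0 if response in ("CR", "PR") else 85.0,
        "ca199_baseline": 200.0, "uln_ca199": 37.0,
        "age": 64.0, "sex": "Male", "bsa": 1.8, "stage": stage, "ecog": 1,
    }


@pytest.fixture(scope="session")
def published_counts_dataset() -> TrialDataset:
    """Deterministic dataset reproducing the published category counts.

    Experimental arm (n=65): 0 CR, 14 PR, 22 SD, 24 PD, 5 NE; stages
    II/III/IV/Unknown = 6/8/50/1.  Control arm (n=34): 0 CR, 3 PR, 19 SD,
    10 PD, 2 NE; stages 3/5/26/0.  AE table gives 22 experimental-arm
    patients a drug-related nausea record.
    """
    rows = []
    i = 0
    specs = [
        ("experimental", [("PR", 14), ("SD", 22), ("PD", 24), ("NE", 5)],
         [("II", 6), ("III", 8), ("IV", 50), ("Unknown", 1)]),
        ("control", [("PR", 3), ("SD", 19), ("PD", 10), ("NE", 2)],
         [("II", 3), ("III", 5), ("IV", 26)]),
    ]
    for arm, resp_counts, stage_counts in specs:
        responses = [r for r, k in resp_counts for _ in range(k)]
        stages = [s for s, k in stage_counts for _ in range(k)]
        for response, stage in zip(responses, stages):
            onset = 2.0 if response in ("CR", "PR") else np.nan
            rows.append(_patients_row(i, arm, response, stage, onset))
            i += 1
    patients = pd.DataFrame(rows)

    nausea_ids = patients.loc[patients["arm"] == "experimental",
                              "patient_id"].iloc[:22]
    ae = pd.DataFrame({
        "patient_id": nausea_ids, "arm": "experimental",
        "preferred_term": "nausea", "grade": 2,
        "drug_related": True, "treatment_emergent": True,
    })
    return TrialDataset(patients=patients, ae=ae)
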