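"""Trial and population-PK configuration.

Units are explicit throughout the package: survival and accrual times in
months (1 month = 365.25/12 days), PK times in hours, concentrations in
ng/mL, volumes in mL, clearances in mL/h, doses in ng.  The defaults encode
the design of a 2:1 randomized phase II study: 99 patients, exponential
overall survival with control median 7 months and experimental median
9 months, and a 230-mg 1-hour IV infusion of the experimental agent with
sparse sampling at 0, 1, 2, 4 and 25 h from the start of infusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")

#: Best-overall-response frequencies used by the generator (per arm).
DEFAULT_RESPONSE_PROBS_E: dict[str, float] = {
    "CR": 0.0, "PR": 14 / 65, "SD": 22 / 65, "PD": 24 / 65, "NE": 5 / 65,
}
DEFAULT_RESPONSE_PROBS_C: dict[str, float] = {
    "CR": 0.0, "PR": 3 / 34, "SD": 19 / 34, "PD": 10 / 34, "NE": 2 / 34,
}


@dataclass(frozen=True)
class PopulationPK:
    """Two-compartment population model for the experimental agent.

    Geometric means are typical values; inter-individual variability (IIV)
    is log-normal with the given percent CVs.  Inter-occasion variability
    (IOV) perturbs CL and Vc independently on each dosing occasion (day 2
    vs day 16), which is what spreads the intra-cycle accumulation ratio.
    Vc was calibrated (holding Vss = Vc + Vp at 104 L and CL at 7.79 L/h)
    so the simulated cohort geometric-mean Cmax falls in the observed range.
    """

    dose_ng: float = 230e6            # 230 mg flat dose
    infusion_duration_h: float = 1.0
    cl_geomean: float = 7790.0        # mL/h  (7.79 L/h)
    vc_geomean: float = 50_000.0      # mL
    vp_geomean: float = 54_000.0      # mL  -> Vss = 104 L
    q_geomean: float = 15_000.0       # mL/h
    iiv_cv: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 50.0, "vc": 50.0, "vp": 30.0, "q": 30.0}
    )
    iov_cv: float = 25.0              # percent, on CL and Vc per occasion
    sampling_times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 25.0)

    def __post_init__(self) -> None:
        for name in ("dose_ng", "cl_geomean", "vc_geomean", "vp_geomean",
                     "q_geomean", "infusion_duration_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        st = self.sampling_times
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("sampling_times must be strictly increasing")
        if any(cv < 0 for cv in self.iiv_cv.values()) or self.iov_cv < 0:
            raise ValueError("variability CVs must be non-negative")

    @property
    def vss_geomean(self) -> float:
        return self.vc_geomean + self.vp_geomean


def _validate_probs(probs: Mapping[str, float], name: str) -> dict[str, float]:
    probs = dict(probs)
    unknown = set(probs) - set(RESPONSE_CATEGORIES)
    if unknown:
        raise ValueError(f"{name}: unknown response categories {sorted(unknown)}")
    vec = [float(probs.get(c, 0.0)) for c in RESPONSE_CATEGORIES]
    if any(p < 0 or p > 1 for p in vec):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(vec) - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities must sum to 1 (got {sum(vec)!r})")
    return dict(zip(RESPONSE_CATEGORIES, vec))


@dataclass(frozen=True)
class TrialConfig:
    """Design parameters of one simulated trial."""

    n_total: int = 99
    allocation_ratio: tuple[int, int] = (2, 1)   # experimental : control
    median_os_e: float = 9.0     # months
    median_os_c: float = 7.0
    median_pfs_e: float = 3.5
    median_pfs_c: float = 5.6
    accrual_duration: float = 18.0   # months
    followup_duration: float = 6.0   # months after last accrual
    dropout_hazard: float = 0.01     # per month
    weibull_shape: float = 1.0       # 1 = exponential survival
    response_probs_e: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_PROBS_E))
    response_probs_c: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_PROBS_C))
    uln_ca199: float = 37.0          # U/mL
    pk: PopulationPK = field(default_factory=PopulationPK)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if any(r < 1 or int(r) != r for r in self.allocation_ratio):
            raise ValueError("allocation_ratio components must be integers >= 1")
        for name in ("median_os_e", "median_os_c", "median_pfs_e", "median_pfs_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accrual_duration < 0 or self.followup_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.dropout_hazard < 0:
            raise ValueError("dropout_hazard must be non-negative")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        object.__setattr__(
            self, "response_probs_e",
            _validate_probs(self.response_probs_e, "response_probs_e"))
        object.__setattr__(
            self, "response_probs_c",
            _validate_probs(self.response_probs_c, "response_probs_c"))

    @property
    def block_size(self) -> int:
        return int(sum(self.allocation_ratio))

    @property
    def admin_cutoff(self) -> float:
        """Calendar time of the administrative data cutoff, months."""
        return self.accrual_duration + self.followup_duration

    def with_full_followup(self) -> "TrialConfig":
        """Variant with no censoring: every patient followed to death."""
        return replace_config(self, accrual_duration=0.0,
                              followup_duration=math.inf, dropout_hazard=0.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pk_raw = raw.pop("pk", None)
        pk = PopulationPK(**pk_raw) if pk_raw else PopulationPK()
        if "allocation_ratio" in raw:
            raw["allocation_ratio"] = tuple(raw["allocation_ratio"])
        return cls(pk=pk, **raw)


def replace_config(cfg: TrialConfig, **changes) -> TrialConfig:
    import dataclasses

    return dataclasses.replace(cfg, **changes)
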