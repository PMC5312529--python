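"""Frequentist survival analysis: Kaplan–Meier curves, the one-sided
log-rank test, and Schoenfeld-style design power.

The one-sided direction is fixed throughout to "experimental hazard lower":
a negative observed-minus-expected event count in the experimental arm is
evidence for the experimental treatment, and the one-sided p-value is
``Phi(Z)`` with ``Z = (O_e - E_e)/sqrt(V)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from .config import TrialConfig
from .simulate import simulate_survival_arrays


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival observations for one arm."""

    times: np.ndarray
    events: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("times and events must be parallel 1-d arrays")
        if len(t) == 0:
            raise ValueError("at least one observation required")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    @property
    def n(self) -> int:
        return len(self.times)

    @classmethod
    def from_frame(cls, patients, arm: str, time_col: str = "os_time",
                   event_col: str = "os_event") -> "SurvivalSample":
        sub = patients[patients["arm"] == arm]
        return cls(sub[time_col].to_numpy(), sub[event_col].to_numpy(),
                   label=arm)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with the summaries a report table needs."""

    times: np.ndarray           # step-change times (event times)
    survival: np.ndarray        # S(t) just after each step
    median: float | None        # smallest t with S(t) <= 0.5; None if never
    range_min: float
    range_max: float
    range_max_censored: bool
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def range_str(self, ndigits: int = 1) -> str:
        suffix = "+" if self.range_max_censored else ""
        return (f"{self.range_min:.{ndigits}f}"
                f"–{self.range_max:.{ndigits}f}{suffix}")


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan–Meier product-limit estimator for one arm.

    The reported range is (min observed time, max observed time) with a
    flag when the maximum is a censored observation (rendered "19.1+"
    style by :meth:`KMCurve.range_str`).
    """
    if sample.events.sum() == 0 and np.all(sample.times == 0):
        raise ValueError("degenerate sample: all observations censored at 0")
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times, sample.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    below = times[surv <= 0.5]
    median = float(below[0]) if len(below) else None
    tmax_idx = int(np.argmax(sample.times))
    return KMCurve(
        times=times, survival=surv, median=median,
        range_min=float(sample.times.min()),
        range_max=float(sample.times[tmax_idx]),
        range_max_censored=bool(
            sample.events[sample.times == sample.times[tmax_idx]].max() == 0),
        n=sample.n, n_events=int(sample.events.sum()),
    )


@dataclass(frozen=True)
class LogRankResult:
    o_minus_e: float       # observed - expected events, experimental arm
    variance: float        # hypergeometric variance
    z: float               # signed statistic, negative favours experimental
    p_one_sided: float     # P(experimental hazard lower) direction

    @property
    def chi_square(self) -> float:
        return self.z ** 2


def _logrank_core(times: np.ndarray, events: np.ndarray,
                  in_exp: np.ndarray) -> tuple[float, float]:
    """O - E and hypergeometric variance, vectorized over distinct
    event times; ties are handled by the simultaneous-death convention."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_exp[order]
    ev_times = np.unique(t[e == 1])
    n_total = len(t)
    # at-risk counts just before each event time
    n_risk = n_total - np.searchsorted(t, ev_times, side="left")
    te = np.sort(t[g])
    n_risk_e = g.sum() - np.searchsorted(te, ev_times, side="left")
    tev = np.sort(t[e == 1])
    tev_e = np.sort(t[(e == 1) & g])
    d = (np.searchsorted(tev, ev_times, side="right")
         - np.searchsorted(tev, ev_times, side="left"))
    d_e = (np.searchsorted(tev_e, ev_times, side="right")
           - np.searchsorted(tev_e, ev_times, side="left"))
    frac = n_risk_e / n_risk
    o_minus_e = float((d_e - d * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    variance = float(np.nansum(np.where(n_risk > 1, v_terms, 0.0)))
    return o_minus_e, variance


def logrank_one_sided(experimental: SurvivalSample,
                      control: SurvivalSample) -> LogRankResult:
    """One-sided log-rank test in the direction "experimental hazard lower"."""
    times = np.concatenate([experimental.times, control.times])
    events = np.concatenate([experimental.events, control.events])
    if events.sum() == 0:
        raise ValueError("no events in pooled data: log-rank p undefined")
    in_exp = np.concatenate([
        np.ones(experimental.n, dtype=bool),
        np.zeros(control.n, dtype=bool)])
    o_minus_e, variance = _logrank_core(times, events, in_exp)
    if variance <= 0:
        raise ValueError("log-rank variance is zero (all events in one group"
                         " at one time); p undefined")
    z = o_minus_e / math.sqrt(variance)
    return LogRankResult(o_minus_e=o_minus_e, variance=variance, z=z,
                         p_one_sided=float(norm.cdf(z)))


@dataclass(frozen=True)
class DesignPower:
    hazard_ratio: float
    n_events: int
    alloc_fracs: tuple[float, float]
    alpha_one_sided: float
    power: float


def schoenfeld_power(hazard_ratio: float, n_events: int,
                     alloc_fracs: tuple[float, float] = (2 / 3, 1 / 3),
                     alpha_one_sided: float = 0.20) -> DesignPower:
    """Closed-form log-rank power for a given number of events.

    power = Phi( sqrt(d * p1 * p2) * |log HR| - z_{1-alpha} ).  At HR = 1
    the power equals alpha exactly.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    p1, p2 = alloc_fracs
    if abs(p1 + p2 - 1.0) > 1e-9:
        raise ValueError("allocation fractions must sum to 1")
    if not 0 < alpha_one_sided < 1:
        raise ValueError("alpha must be in (0, 1)")
    z_alpha = norm.ppf(1.0 - alpha_one_sided)
    drift = math.sqrt(n_events * p1 * p2) * abs(math.log(hazard_ratio))
    power = float(norm.cdf(drift - z_alpha))
    return DesignPower(hazard_ratio=hazard_ratio, n_events=n_events,
                       alloc_fracs=(p1, p2), alpha_one_sided=alpha_one_sided,
                       power=power)


def simulate_logrank_power(config: TrialConfig | None = None,
                           alpha_one_sided: float = 0.20,
                           n_reps: int = 10_000,
                           seed: int = 0,
                           full_followup: bool = True) -> dict:
    """Monte-Carlo power of the one-sided log-rank test under the design.

    Each replicate draws a fresh trial from the synthetic generator
    (substream ``default_rng([seed, rep])``) and tests at ``alpha_one_sided``.
    Returns the rejection rate with its Monte-Carlo standard error.
    """
    if config is None:
        config = TrialConfig()
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        is_exp, t, e, *_ = simulate_survival_arrays(
            config, rng, full_followup=full_followup)
        o_minus_e, variance = _logrank_core(t, e.astype(int), is_exp)
        z = o_minus_e / math.sqrt(variance)
        if norm.cdf(z) < alpha_one_sided:
            rejections += 1
    rate = rejections / n_reps
    return {"reject_rate": rate, "n_reps": n_reps,
            "mc_standard_error": math.sqrt(rate * (1 - rate) / n_reps),
            "alpha_one_sided": alpha_one_sided, "seed": seed}
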