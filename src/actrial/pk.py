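"""Noncompartmental pharmacokinetic analysis.

Model-free estimation of Cmax, tmax, AUC (linear-up/log-down trapezoid),
the terminal rate constant lambda_z (best-adjusted-R2 log-linear fit),
half-life, clearance, mean residence time with infusion correction, and
steady-state volume, plus geometric-mean/CV cohort summaries and exposure-
target attainment fractions.

Time origin is the start of infusion; the protocol's nominal samples at
"pre-dose, end of infusion, +1 h, +3 h, +24 h" map to 0, 1, 2, 4 and 25 h.
AUC(0–24) is computed over 0–24 h from the start of infusion with
interpolation at the 24-h boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

#: Exposure targets associated with maximal pharmacodynamic effect.
AUC_TARGET = 21_000.0   # ng*h/mL, AUC(0-inf)
CMAX_TARGET = 2_000.0   # ng/mL


@dataclass(frozen=True)
class ConcentrationProfile:
    patient_id: str
    cycle: int
    day: int
    times: np.ndarray            # h from start of infusion, strictly increasing
    concentrations: np.ndarray   # ng/mL, >= 0
    dose: float                  # ng
    infusion_duration: float     # h

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be parallel 1-d")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose <= 0 or self.infusion_duration <= 0:
            raise ValueError("dose and infusion_duration must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


def profiles_from_frame(samples: pd.DataFrame) -> list[ConcentrationProfile]:
    """Split a long-format PK table into per-(patient, cycle, day) profiles."""
    out = []
    for (pid, cycle, day), grp in samples.groupby(
            ["patient_id", "cycle", "day"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(ConcentrationProfile(
            patient_id=str(pid), cycle=int(cycle), day=int(day),
            times=grp["time_h"].to_numpy(),
            concentrations=grp["conc_ng_ml"].to_numpy(),
            dose=float(grp["dose_ng"].iloc[0]),
            infusion_duration=float(grp["tinf_h"].iloc[0])))
    return out


# --------------------------------------------------------------------------
# trapezoidal integration
# --------------------------------------------------------------------------

def _segment_areas(t1, t2, c1, c2, method: str) -> tuple[float, float]:
    """(AUC, AUMC) of one segment.  The log rule applies only when both
    endpoint concentrations are positive and strictly decreasing."""
    dt = t2 - t1
    log_ok = (method == "linuplogdown" and c1 > 0 and c2 > 0 and c2 < c1)
    if log_ok:
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def _interp_conc(t1, t2, c1, c2, t, method: str) -> float:
    if method == "linuplogdown" and c1 > 0 and c2 > 0 and c2 < c1:
        k = math.log(c1 / c2) / (t2 - t1)
        return c1 * math.exp(-k * (t - t1))
    return c1 + (c2 - c1) * (t - t1) / (t2 - t1)


def auc_trapezoid(times, concentrations, method: str = "linuplogdown",
                  t_end: float | None = None, t_start: float | None = None,
                  moment: int = 0) -> float:
    """Piecewise-trapezoidal AUC (``moment=0``) or AUMC (``moment=1``).

    ``method`` is ``"linear"`` or ``"linuplogdown"`` (log rule on strictly
    decreasing positive segments, linear elsewhere).  ``t_end``/``t_start``
    inside the sampled span are handled by interpolation consistent with the
    chosen method.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if method not in ("linear", "linuplogdown"):
        raise ValueError(f"unknown method {method!r}")
    if t_end is None:
        t_end = float(t[-1])
    if t_start is None:
        t_start = float(t[0])
    if t_end < t[0] or t_start < t[0]:
        raise ValueError("integration bounds precede the first sample")
    if t_end > t[-1]:
        raise ValueError("t_end beyond the last sample; extrapolation is"
                         " handled by lambda_z, not the trapezoid")
    if t_start >= t_end:
        return 0.0

    total = 0.0
    for i in range(len(t) - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        if t2 <= t_start or t1 >= t_end:
            continue
        a, b = max(t1, t_start), min(t2, t_end)
        ca = c1 if a == t1 else _interp_conc(t1, t2, c1, c2, a, method)
        cb = c2 if b == t2 else _interp_conc(t1, t2, c1, c2, b, method)
        auc, aumc = _segment_areas(a, b, ca, cb, method)
        total += aumc if moment == 1 else auc
    return total


# --------------------------------------------------------------------------
# terminal phase
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaZFit:
    lambda_z: float
    n_points: int
    adj_r2: float
    intercept: float     # log-concentration intercept at t = 0


def lambda_z_fit(times, concentrations,
                 min_points: int = 3) -> LambdaZFit | None:
    """Log-linear terminal-slope fit.

    Candidate sets are the ``k`` latest positive post-peak samples
    (tmax excluded, k >= ``min_points``); the set with the best adjusted R2
    wins.  Returns ``None`` ("not estimable") with fewer than 3 usable
    points or when no candidate gives a positive lambda_z.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    i_max = int(np.argmax(c))
    mask = (np.arange(len(t)) > i_max) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    if len(tt) < min_points:
        return None
    best: LambdaZFit | None = None
    for k in range(min_points, len(tt) + 1):
        x, y = tt[-k:], cc[-k:]
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2) if k > 2 else r2
        if best is None or adj > best.adj_r2 + 1e-12:
            best = LambdaZFit(lambda_z=float(-slope), n_points=k,
                              adj_r2=float(adj), intercept=float(intercept))
    return best


# --------------------------------------------------------------------------
# per-profile NCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NCAResult:
    patient_id: str
    cycle: int
    day: int
    cmax: float
    tmax: float
    auc0_24: float | None
    cav24: float | None
    auc0_tlast: float
    auc0_inf: float | None
    pct_extrap: float | None
    lambda_z: float | None
    t_half: float | None
    cl: float | None
    mrt: float | None
    vss: float | None
    lambda_z_n_points: int | None
    lambda_z_adj_r2: float | None


def nca_profile(profile: ConcentrationProfile,
                method: str = "linuplogdown") -> NCAResult:
    """Full noncompartmental parameter set for one profile.

    When the terminal slope is not estimable, the extrapolation-dependent
    parameters (AUC0-inf, %extrap, t1/2, CL, MRT, Vss) are reported absent
    while Cmax/tmax/AUC0-24/AUC0-tlast remain available.
    """
    t, c = profile.times, profile.concentrations
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])

    pos = np.nonzero(c > 0)[0]
    if len(pos) == 0:
        tlast, clast = float(t[-1]), 0.0
        auc0_tlast = 0.0
    else:
        tlast, clast = float(t[pos[-1]]), float(c[pos[-1]])
        auc0_tlast = auc_trapezoid(t, c, method, t_end=tlast)

    # AUC over 0-24 h from infusion start; truncated at tlast if sampling
    # stopped earlier (extrapolation belongs to lambda_z, not the trapezoid)
    auc0_24 = auc_trapezoid(t, c, method, t_end=min(24.0, float(t[-1])))
    cav24 = auc0_24 / 24.0

    fit = lambda_z_fit(t, c)
    if fit is None or clast <= 0:
        return NCAResult(
            patient_id=profile.patient_id, cycle=profile.cycle,
            day=profile.day, cmax=cmax, tmax=tmax, auc0_24=auc0_24,
            cav24=cav24, auc0_tlast=auc0_tlast, auc0_inf=None,
            pct_extrap=None, lambda_z=None, t_half=None, cl=None,
            mrt=None, vss=None, lambda_z_n_points=None, lambda_z_adj_r2=None)

    lz = fit.lambda_z
    auc0_inf = auc0_tlast + clast / lz
    aumc0_tlast = auc_trapezoid(t, c, method, t_end=tlast, moment=1)
    aumc0_inf = aumc0_tlast + clast * tlast / lz + clast / lz ** 2
    cl = profile.dose / auc0_inf
    mrt = aumc0_inf / auc0_inf - profile.infusion_duration / 2.0
    return NCAResult(
        patient_id=profile.patient_id, cycle=profile.cycle, day=profile.day,
        cmax=cmax, tmax=tmax, auc0_24=auc0_24, cav24=cav24,
        auc0_tlast=auc0_tlast, auc0_inf=auc0_inf,
        pct_extrap=100.0 * (auc0_inf - auc0_tlast) / auc0_inf,
        lambda_z=lz, t_half=LN2 / lz, cl=cl, mrt=mrt, vss=cl * mrt,
        lambda_z_n_points=fit.n_points, lambda_z_adj_r2=fit.adj_r2)


def nca_cohort(samples: pd.DataFrame,
               method: str = "linuplogdown") -> list[NCAResult]:
    return [nca_profile(p, method) for p in profiles_from_frame(samples)]


# --------------------------------------------------------------------------
# cohort summaries
# --------------------------------------------------------------------------

def geomean_cv(values: Iterable[float]) -> tuple[float, float, int]:
    """Geometric mean, log-scale percent CV (100*sqrt(exp(s^2)-1)) and n.

    Non-positive values are excluded (they have no logarithm); callers can
    compare n against the number of profiles to see how many were dropped.
    """
    x = np.asarray([v for v in values if v is not None and v > 0], dtype=float)
    if len(x) == 0:
        raise ValueError("no positive values to summarize")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    s2 = float(logs.var(ddof=1)) if len(x) > 1 else 0.0
    cv = 100.0 * math.sqrt(math.exp(s2) - 1.0)
    return gm, cv, len(x)


_GEO_PARAMS = ("cmax", "cav24", "auc0_24", "auc0_tlast", "auc0_inf",
               "pct_extrap", "cl", "vss", "t_half")


@dataclass(frozen=True)
class CohortPKSummary:
    table: pd.DataFrame            # parameter x day: geomean, cv_pct, n
    tmax: pd.DataFrame             # day: median, min, max, n
    accumulation: pd.DataFrame | None   # intracycle R_A summary


def summarize_cohort(results: Sequence[NCAResult]) -> CohortPKSummary:
    """Table-shaped cohort summary: geometric mean (CV%) per parameter and
    day, tmax as median (range), and the intracycle accumulation ratio
    R_A = day-16 AUC0-inf / day-2 AUC0-inf per patient."""
    if len(results) == 0:
        raise ValueError("no NCA results to summarize")
    rows = []
    days = sorted({r.day for r in results})
    for day in days:
        sub = [r for r in results if r.day == day]
        for param in _GEO_PARAMS:
            vals = [getattr(r, param) for r in sub]
            try:
                gm, cv, n = geomean_cv(vals)
            except ValueError:
                continue
            rows.append((param, day, gm, cv, n))
    table = pd.DataFrame(rows, columns=["parameter", "day", "geomean",
                                        "cv_pct", "n"])
    tmax_rows = []
    for day in days:
        tm = np.array([r.tmax for r in results if r.day == day])
        tmax_rows.append((day, float(np.median(tm)), float(tm.min()),
                          float(tm.max()), len(tm)))
    tmax = pd.DataFrame(tmax_rows, columns=["day", "median", "min", "max", "n"])

    acc = None
    if {2, 16} <= set(days):
        d2 = {r.patient_id: r.auc0_inf for r in results
              if r.day == 2 and r.auc0_inf}
        d16 = {r.patient_id: r.auc0_inf for r in results
               if r.day == 16 and r.auc0_inf}
        ratios = [d16[p] / d2[p] for p in d2 if p in d16]
        if ratios:
            gm, cv, n = geomean_cv(ratios)
            acc = pd.DataFrame([("ra_intracycle", gm, cv, n)],
                               columns=["parameter", "geomean", "cv_pct", "n"])
    return CohortPKSummary(table=table, tmax=tmax, accumulation=acc)


def exposure_target_attainment(results: Sequence[NCAResult],
                               auc_target: float = AUC_TARGET,
                               cmax_target: float = CMAX_TARGET
                               ) -> pd.DataFrame:
    """Fraction of profiles at or above each exposure target, by day and
    pooled.  Thresholds are inclusive (>=); AUC attainment is computed over
    profiles with an estimable AUC0-inf."""
    rows = []
    days = sorted({r.day for r in results})
    for day in [*days, "pooled"]:
        sub = results if day == "pooled" else [r for r in results
                                               if r.day == day]
        cm = np.array([r.cmax for r in sub])
        au = np.array([r.auc0_inf for r in sub if r.auc0_inf is not None])
        rows.append((day,
                     float((cm >= cmax_target).mean()) if len(cm) else np.nan,
                     len(cm),
                     float((au >= auc_target).mean()) if len(au) else np.nan,
                     len(au)))
    return pd.DataFrame(rows, columns=["day", "frac_cmax_target", "n_cmax",
                                       "frac_auc_target", "n_auc"])
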