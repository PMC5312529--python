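"""Synthetic-trial generator.

Produces patient-level datasets with the statistical structure the analysis
pipeline assumes: permuted-block 2:1 randomization, exponential (optionally
Weibull) overall survival with configurable medians, progression-free
survival coupled to OS through a latent competing-risks construction
(PFS = min(progression, death), with exact configured marginals and
PFS <= OS by construction), administrative + dropout censoring, RECIST
best-response categories, target-lesion sums, CA19-9 series, two-compartment
infusion PK profiles with log-normal inter-individual and inter-occasion
variability, and Bernoulli adverse-event / ECG records.

All randomness flows through ``numpy.random.Generator``; identical
(config, seed) pairs give identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RESPONSE_CATEGORIES, PopulationPK, TrialConfig
from .datasets import TrialDataset

LN2 = math.log(2.0)

ARM_E = "experimental"
ARM_C = "control"


# --------------------------------------------------------------------------
# randomization and survival
# --------------------------------------------------------------------------

def block_randomize(n_total: int, ratio: tuple[int, int],
                    rng: np.random.Generator) -> np.ndarray:
    """Permuted-block treatment assignment.

    Block size is the sum of the ratio components.  A final incomplete block
    is filled by sampling that many assignments from one shuffled block
    without replacement.
    """
    block = np.array([ARM_E] * ratio[0] + [ARM_C] * ratio[1], dtype=object)
    out: list[np.ndarray] = []
    remaining = n_total
    while remaining > 0:
        b = rng.permutation(block)
        out.append(b[:remaining])
        remaining -= len(block)
    return np.concatenate(out)[:n_total]


def _weibull_scale(median: float, shape: float) -> float:
    return median / LN2 ** (1.0 / shape)


def _draw_linked_os_pfs(n: int, median_os: float, median_pfs: float,
                        shape: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (OS, PFS) with exact Weibull(shape) marginals and PFS <= OS.

    PFS is min(progression, death): the latent progression time has survivor
    S_pfs(t)/S_os(t), valid whenever median_pfs <= median_os.  When
    median_pfs >= median_os progression never precedes death and PFS = OS.
    """
    s_os = _weibull_scale(median_os, shape)
    s_pfs = _weibull_scale(min(median_pfs, median_os), shape)
    os_t = s_os * rng.exponential(size=n) ** (1.0 / shape)
    rate_diff = s_pfs ** -shape - s_os ** -shape
    if rate_diff <= 0:
        return os_t, os_t.copy()
    prog = (rng.exponential(size=n) / rate_diff) ** (1.0 / shape)
    return os_t, np.minimum(prog, os_t)


def simulate_survival_arrays(config: TrialConfig, rng: np.random.Generator,
                             full_followup: bool = False):
    """Core survival draw shared by the full generator and the OC simulators.

    Returns ``(is_exp, os_time, os_event, pfs_time, pfs_event, entry)`` as
    numpy arrays.  With ``full_followup`` no censoring is applied (every
    patient is followed to death).
    """
    arms = block_randomize(config.n_total, config.allocation_ratio, rng)
    is_exp = arms == ARM_E
    n = config.n_total
    os_t = np.empty(n)
    pfs_t = np.empty(n)
    for mask, m_os, m_pfs in (
        (is_exp, config.median_os_e, config.median_pfs_e),
        (~is_exp, config.median_os_c, config.median_pfs_c),
    ):
        o, p = _draw_linked_os_pfs(int(mask.sum()), m_os, m_pfs,
                                   config.weibull_shape, rng)
        os_t[mask], pfs_t[mask] = o, p

    if full_followup:
        entry = np.zeros(n)
        ones = np.ones(n, dtype=int)
        return is_exp, os_t, ones, pfs_t, ones.copy(), entry

    entry = rng.uniform(0.0, config.accrual_duration, size=n) \
        if config.accrual_duration > 0 else np.zeros(n)
    admin = np.maximum(config.admin_cutoff - entry, 0.0)
    if config.dropout_hazard > 0:
        dropout = rng.exponential(1.0 / config.dropout_hazard, size=n)
    else:
        dropout = np.full(n, np.inf)
    cens = np.minimum(admin, dropout)
    os_event = (os_t <= cens).astype(int)
    pfs_event = (pfs_t <= cens).astype(int)
    os_obs = np.minimum(os_t, cens)
    pfs_obs = np.minimum(pfs_t, cens)
    return is_exp, os_obs, os_event, pfs_obs, pfs_event, entry


# --------------------------------------------------------------------------
# full trial dataset
# --------------------------------------------------------------------------

def _draw_demographics(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    age = np.clip(np.round(rng.normal(64.0, 9.0, n), 1), 35.0, 90.0)
    sex = np.where(rng.random(n) < 0.63, "Male", "Female")
    bsa = np.clip(np.round(rng.normal(1.8, 0.2, n), 2), 1.2, 2.6)
    stage = rng.choice(["II", "III", "IV", "Unknown"], size=n,
                       p=[0.09, 0.13, 0.77, 0.01])
    ecog = rng.choice([0, 1, 2], size=n, p=[0.42, 0.49, 0.09])
    return {"age": age, "sex": sex, "bsa": bsa, "stage": stage, "ecog": ecog}


def _draw_tumor_sums(responses: np.ndarray, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    n = len(responses)
    baseline = np.round(np.exp(rng.normal(math.log(80.0), 0.4, n)), 1)
    factor = np.empty(n)
    for cat, lo, hi in (("CR", 0.0, 0.05), ("PR", 0.30, 0.75),
                        ("SD", -0.15, 0.25), ("PD", -0.60, -0.20)):
        m = responses == cat
        factor[m] = 1.0 - rng.uniform(lo, hi, int(m.sum()))
    week8 = np.round(baseline * factor, 1)
    week8[responses == "NE"] = np.nan
    return baseline, week8


def _draw_ca199(n: int, rng: np.random.Generator, n_cycles: int = 6
                ) -> tuple[np.ndarray, pd.DataFrame]:
    baseline = np.exp(rng.normal(math.log(400.0), 1.3, n))
    # ~65% of patients show a >50% marker reduction regardless of arm
    deep = rng.random(n) < 0.65
    nadir_factor = np.where(deep, rng.uniform(0.10, 0.45, n),
                            rng.uniform(0.55, 1.50, n))
    rows = []
    cycles = np.arange(1, n_cycles + 1)
    # geometric decline to a nadir at cycle 3, then mild regrowth
    for i in range(n):
        path = np.where(
            cycles <= 3,
            baseline[i] * nadir_factor[i] ** (cycles / 3.0),
            baseline[i] * nadir_factor[i] * 1.15 ** (cycles - 3),
        )
        noise = np.exp(rng.normal(0.0, 0.10, n_cycles))
        for c, v in zip(cycles, path * noise):
            rows.append((i, int(c), float(max(v, 0.1))))
    series = pd.DataFrame(rows, columns=["_idx", "cycle", "value"])
    return np.round(baseline, 1), series


def simulate_trial(config: TrialConfig, seed: int | None = None) -> TrialDataset:
    """Generate one complete synthetic trial as a :class:`TrialDataset`."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    is_exp, os_t, os_e, pfs_t, pfs_e, entry = simulate_survival_arrays(config, rng)
    n = config.n_total
    arms = np.where(is_exp, ARM_E, ARM_C)

    responses = np.empty(n, dtype=object)
    probs_e = [config.response_probs_e[c] for c in RESPONSE_CATEGORIES]
    probs_c = [config.response_probs_c[c] for c in RESPONSE_CATEGORIES]
    responses[is_exp] = rng.choice(RESPONSE_CATEGORIES, int(is_exp.sum()), p=probs_e)
    responses[~is_exp] = rng.choice(RESPONSE_CATEGORIES, int((~is_exp).sum()), p=probs_c)

    # responders get an onset near the first post-baseline assessment (~8 wk)
    onset = np.full(n, np.nan)
    resp_mask = np.isin(responses, ("CR", "PR"))
    onset[resp_mask] = rng.uniform(1.6, 2.2, int(resp_mask.sum()))
    onset[resp_mask] = np.minimum(onset[resp_mask], 0.9 * pfs_t[resp_mask])

    baseline_sum, week8_sum = _draw_tumor_sums(responses, rng)
    ca_base, ca_series = _draw_ca199(n, rng)
    demo = _draw_demographics(n, rng)

    ids = np.array([f"P{i + 1:03d}" for i in range(n)])
    patients = pd.DataFrame({
        "patient_id": ids,
        "arm": arms,
        "entry_month": np.round(entry, 4),
        "os_time": np.round(os_t, 4),
        "os_event": os_e,
        "pfs_time": np.round(pfs_t, 4),
        "pfs_event": pfs_e,
        "best_response": responses,
        "response_onset_month": np.round(onset, 3),
        "baseline_target_sum": baseline_sum,
        "week8_target_sum": week8_sum,
        "ca199_baseline": ca_base,
        "uln_ca199": config.uln_ca199,
        **demo,
    })
    ca_series["patient_id"] = ids[ca_series.pop("_idx").to_numpy()]
    ca_series = ca_series[["patient_id", "cycle", "value"]]
    ca_series["value"] = ca_series["value"].round(1)

    exp_ids = ids[is_exp]
    pk_samples, _ = simulate_pk_profiles(
        config.pk, len(exp_ids), rng=rng, patient_ids=list(exp_ids))
    ae, ecg = simulate_ae_and_ecg_frames(patients, rng=rng)

    return TrialDataset(patients=patients, pk=pk_samples, ae=ae, ecg=ecg,
                        ca199=ca_series,
                        meta={"seed": seed, "config": config})


# --------------------------------------------------------------------------
# pharmacokinetics
# --------------------------------------------------------------------------

def two_compartment_infusion(times: np.ndarray, dose: float, tinf: float,
                             cl: float, vc: float, vp: float, q: float
                             ) -> np.ndarray:
    """Closed-form central-compartment concentration for a constant-rate
    IV infusion into a two-compartment system (micro-constants
    k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp)."""
    k10, k12, k21 = cl / vc, q / vc, q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    r0 = dose / tinf
    ca = (alpha - k21) / (alpha * (alpha - beta))
    cb = (k21 - beta) / (beta * (alpha - beta))
    t = np.asarray(times, dtype=float)
    during = (r0 / vc) * (ca * (1.0 - np.exp(-alpha * t))
                          + cb * (1.0 - np.exp(-beta * t)))
    after = (r0 / vc) * (
        ca * (1.0 - math.exp(-alpha * tinf)) * np.exp(-alpha * (t - tinf))
        + cb * (1.0 - math.exp(-beta * tinf)) * np.exp(-beta * (t - tinf)))
    return np.where(t <= tinf, during, after)


def macro_rates(cl: float, vc: float, vp: float, q: float) -> tuple[float, float]:
    """(alpha, beta) hybrid rate constants of the two-compartment system."""
    k10, k12, k21 = cl / vc, q / vc, q / vp
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    return (s + disc) / 2.0, (s - disc) / 2.0


def _lognormal_sigma(cv_pct: float) -> float:
    return math.sqrt(math.log(1.0 + (cv_pct / 100.0) ** 2))


@dataclass
class PKSimulation:
    samples: pd.DataFrame     # long format: patient_id, cycle, day, time_h, ...
    parameters: pd.DataFrame  # individual CL/Vc/Vp/Q draws (truth, for checks)

    def __iter__(self):
        return iter((self.samples, self.parameters))


def simulate_pk_profiles(pop: PopulationPK, n_patients: int,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         days: Sequence[int] = (2, 16),
                         patient_ids: Sequence[str] | None = None
                         ) -> PKSimulation:
    """Simulate per-patient concentration profiles at the protocol times.

    Inter-individual variability is log-normal on CL, Vc, Vp, Q;
    inter-occasion variability (log-normal, ``pop.iov_cv``) perturbs CL and
    Vc independently on each sampled day.  The pre-dose sample is exactly 0
    (first dose of the agent; weekly dosing with a ~10 h half-life leaves no
    carry-over at later occasions either).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if patient_ids is None:
        patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]

    geo = {"cl": pop.cl_geomean, "vc": pop.vc_geomean,
           "vp": pop.vp_geomean, "q": pop.q_geomean}
    sig = {k: _lognormal_sigma(pop.iiv_cv.get(k, 0.0)) for k in geo}
    indiv = {k: geo[k] * np.exp(rng.normal(0.0, sig[k], n_patients))
             for k in geo}
    sig_occ = _lognormal_sigma(pop.iov_cv)

    times = np.asarray(pop.sampling_times, dtype=float)
    rows = []
    for i, pid in enumerate(patient_ids):
        for day in days:
            occ_cl = indiv["cl"][i] * math.exp(rng.normal(0.0, sig_occ))
            occ_vc = indiv["vc"][i] * math.exp(rng.normal(0.0, sig_occ))
            conc = two_compartment_infusion(
                times, pop.dose_ng, pop.infusion_duration_h,
                occ_cl, occ_vc, indiv["vp"][i], indiv["q"][i])
            conc = np.maximum(conc, 0.0)
            conc[times == 0.0] = 0.0   # pre-dose
            for t, c in zip(times, conc):
                rows.append((pid, 1, int(day), float(t), float(c),
                             pop.dose_ng, pop.infusion_duration_h))
    samples = pd.DataFrame(rows, columns=[
        "patient_id", "cycle", "day", "time_h", "conc_ng_ml",
        "dose_ng", "tinf_h"])
    params = pd.DataFrame({"patient_id": list(patient_ids), **indiv})
    return PKSimulation(samples=samples, parameters=params)


# --------------------------------------------------------------------------
# adverse events and ECGs
# --------------------------------------------------------------------------

#: Drug-related TEAE incidence (fraction of patients) per (term, arm),
#: patterned on a gemcitabine +/- CHK1-inhibitor safety profile.
DEFAULT_AE_INCIDENCE: dict[str, tuple[float, float]] = {
    # term: (experimental, control)
    "thrombocytopenia": (0.323, 0.412),
    "nausea": (0.338, 0.235),
    "fatigue": (0.246, 0.294),
    "neutropenia": (0.215, 0.265),
    "anemia": (0.138, 0.265),
    "vomiting": (0.215, 0.088),
    "decreased appetite": (0.185, 0.088),
    "diarrhea": (0.169, 0.088),
    "pyrexia": (0.138, 0.147),
    "asthenia": (0.108, 0.147),
    "constipation": (0.138, 0.088),
    "leukopenia": (0.108, 0.147),
    "stomatitis": (0.154, 0.029),
    "alopecia": (0.092, 0.118),
    "oedema peripheral": (0.108, 0.059),
}

_GRADE_P_DEFAULT = (0.45, 0.35, 0.15, 0.05, 0.0)
_GRADE_P_CYTOPENIA = (0.30, 0.30, 0.30, 0.10, 0.0)
_CYTOPENIAS = {"thrombocytopenia", "neutropenia", "anemia", "leukopenia"}


def simulate_ae_and_ecg_frames(
        patients: pd.DataFrame,
        incidence_table: Mapping[str, tuple[float, float]] | None = None,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        frac_qtc_30_60: float = 0.05,
        frac_qtc_gt60: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bernoulli AE draws per patient/term plus baseline/day-2/day-16 ECGs.

    ``incidence_table`` maps preferred term -> (P(experimental), P(control));
    QT/RR pairs are drawn so the configured fractions of patients land in the
    (30, 60] and >60 ms maximum-change-from-baseline QTcF categories.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    table = DEFAULT_AE_INCIDENCE if incidence_table is None else incidence_table
    for term, (pe, pc) in table.items():
        if not (0.0 <= pe <= 1.0 and 0.0 <= pc <= 1.0):
            raise ValueError(f"incidence for {term!r} outside [0, 1]")
    if not (0.0 <= frac_qtc_30_60 <= 1.0 and 0.0 <= frac_qtc_gt60 <= 1.0
            and frac_qtc_30_60 + frac_qtc_gt60 <= 1.0):
        raise ValueError("QTcF category fractions must form a sub-probability")

    is_exp = (patients["arm"] == ARM_E).to_numpy()
    ids = patients["patient_id"].to_numpy()
    arms = patients["arm"].to_numpy()
    n = len(ids)

    ae_rows = []
    for term, (pe, pc) in table.items():
        p = np.where(is_exp, pe, pc)
        hit = rng.random(n) < p
        gp = _GRADE_P_CYTOPENIA if term in _CYTOPENIAS else _GRADE_P_DEFAULT
        grades = rng.choice([1, 2, 3, 4, 5], size=int(hit.sum()), p=gp)
        for pid, arm, g in zip(ids[hit], arms[hit], grades):
            ae_rows.append((pid, arm, term, int(g), True, True))
    ae = pd.DataFrame(ae_rows, columns=[
        "patient_id", "arm", "preferred_term", "grade",
        "drug_related", "treatment_emergent"])

    # ECG: draw each patient's max post-baseline QTcF change by category
    cat = rng.choice([0, 1, 2], size=n,
                     p=[1.0 - frac_qtc_30_60 - frac_qtc_gt60,
                        frac_qtc_30_60, frac_qtc_gt60])
    dmax = np.empty(n)
    m0, m1, m2 = cat == 0, cat == 1, cat == 2
    dmax[m0] = np.minimum(rng.normal(8.0, 8.0, int(m0.sum())), 28.0)
    dmax[m1] = rng.uniform(31.0, 59.0, int(m1.sum()))
    dmax[m2] = rng.uniform(61.0, 80.0, int(m2.sum()))
    qtcf_base = rng.normal(400.0, 15.0, n)
    d_other = dmax - rng.uniform(0.0, 15.0, n)

    ecg_rows = []
    for i, pid in enumerate(ids):
        for label, qtcf in (("baseline", qtcf_base[i]),
                            ("day2", qtcf_base[i] + dmax[i]),
                            ("day16", qtcf_base[i] + d_other[i])):
            rr = float(np.clip(rng.normal(0.9, 0.12), 0.55, 1.4))
            qt = qtcf * rr ** (1.0 / 3.0)
            ecg_rows.append((pid, label, round(float(qt), 1), round(rr, 3)))
    ecg = pd.DataFrame(ecg_rows, columns=["patient_id", "timepoint",
                                          "qt_ms", "rr_s"])
    return ae, ecg


def simulate_ae_and_ecg(dataset: TrialDataset, incidence_table=None,
                        seed: int | None = None, **kwargs
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper operating on a :class:`TrialDataset`."""
    return simulate_ae_and_ecg_frames(dataset.patients, incidence_table,
                                      seed=seed, **kwargs)
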