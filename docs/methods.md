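# Methods

This note records the models, defaults and numerical conventions behind
`actrial`, and what the synthetic-data checks do and do not establish.

## Bayesian augmented-control analysis

**Likelihood and prior.** Overall survival in each arm is modeled as
exponential with hazard λ (month⁻¹); right-censored data enter through the
sufficient statistics (d events, T patient-months). The prior is a vague
Gamma(0.001, 0.001) per arm. The exponential/conjugate-gamma formulation is
the simplest model consistent with a median-based design (median = ln 2/λ);
the posterior types isolate it so a commensurate-prior or Weibull variant
could be added without touching the decision layer.

**Historical borrowing.** The control posterior uses a power prior: the
historical control likelihood raised to a₀ ∈ [0, 1], giving
Gamma(a + a₀·d_h + d_c, b + a₀·T_h + T_c). The bundled historical fixture is
a *synthetic reconstruction* (so labelled in code): 300 events at median
7 months (T_h = 300·7/ln 2), with default a₀ = 0.2, i.e. ≈60 effective
borrowed control events. With n = 99 at 2:1 and full follow-up this
configuration yields simulated type I error ≈ 0.15–0.17 and power ≈ 0.79 at
the strict-0.8 threshold; a₀ is a plain config argument, never hard-coded
into the analysis.

**Decision rule.** Superiority requires P(λ_e < λ_c) *strictly* greater
than 0.8. The probability is computed by the exact Beta identity
P(Beta(a_e, a_c) < b_e/(b_e+b_c)) (scipy's regularized incomplete beta);
a Monte-Carlo path (≥10⁵ gamma draws) exists as an independent cross-check
and agrees within 0.002. Superiority is defined on hazards; under the
exponential model this induces the same ordering as medians or survival at
any landmark.

**Operating characteristics.** Each replicate simulates a fresh trial from
the generator and runs the full posterior pipeline. Replicate `rep` of
master seed `s` uses `numpy.random.default_rng([s, rep])` — a documented
counter scheme that makes every replicate independently reproducible. The
default is full follow-up (every patient an event), matching the
event-count arithmetic of the design; censored variants are available
through the trial config. Default problem sizes — 10,000 replicates for the
log-rank power and 5,000 per Bayesian scenario — keep the full recomputation
in the tens of seconds while leaving Monte-Carlo standard errors below 0.01.

## Frequentist survival toolkit

Kaplan–Meier estimation delegates to `lifelines`; the median is the
smallest time with S(t) ≤ 0.5 (undefined if never reached), and ranges
render a censored maximum with a trailing `+` as in trial reports. The
log-rank statistic is computed in-package (the one-sided direction needs
the signed Z = (O_e − E_e)/√V, with hypergeometric variance and the
simultaneous-death tie convention, no continuity correction); `lifelines`'
chi-square form serves as the independent oracle in tests. The direction is
fixed to "experimental hazard lower". Design power uses the Schoenfeld
approximation Φ(√(d·p₁p₂)·|log HR| − z₁₋α), with all randomized patients
contributing events unless an event count is supplied.

## Secondary endpoints

Confidence intervals are exact Clopper–Pearson from Beta quantiles —
recomputation reproduces every published interval bound of the reference
design at one-decimal precision, so the method is inferred rather than
guessed. Clinical benefit is CR+PR+SD with no minimum SD duration (the
published count arithmetic matches exactly). Percentages round half-up to
one decimal, the convention of clinical tables. The tumor-size comparison
is a two-sided Wilcoxon rank-sum (exact enumeration for combined n ≤ 20
without ties, tie-corrected normal approximation otherwise); the identity
of the original trial's test is unknown, and its printed p-value is not
reproducible without patient data. CA19-9 response requires an elevated
baseline (> ULN) and a nadir strictly below half of baseline. Duration of
response runs from response onset to progression/death; since onset is not
part of the minimal patient record, the generator emits a
`response_onset_month` column (~8 weeks, the first assessment).

## Noncompartmental PK

Time origin is the start of infusion; the protocol's "pre-dose, end of
infusion, +1, +3, +24 h" schedule maps to 0, 1, 2, 4, 25 h. AUC uses
linear-up/log-down trapezoids (log rule only on strictly decreasing
positive segments), with method-consistent interpolation at interior
boundaries, so AUC(0,a)+AUC(a,b)=AUC(0,b) holds to 1e-10. AUC(0–24) is
measured from infusion start. λz comes from a log-linear fit over the
latest ≥3 positive post-peak points chosen by best adjusted R² (tmax
excluded); a rising or short profile is "not estimable", and then AUC0-∞,
%extrap, t½, CL, MRT and Vss are reported absent while Cmax/tmax/AUC0-24
survive — mirroring the varying per-parameter n of sparse-sampling studies.
Vss = CL·MRT with infusion correction MRT = AUMC/AUC − T_inf/2; AUMC uses
the matching trapezoid flavor. Cohort summaries are geometric means with
log-scale CV% = 100·√(exp(s²)−1); tmax is median (range); the intracycle
accumulation ratio is day-16/day-2 AUC0-∞ per patient.

A known property of the 25-h schedule, reproduced here deliberately: with
only one sample well past the distribution phase, λz is biased high (the
2- and 4-h points still carry the fast phase), so t½ is underestimated and
AUC0-∞ slightly underestimated relative to the true terminal kinetics. The
λz-recovery test therefore uses sampling extended to 48 h; the
protocol-schedule bias is left visible in cohort summaries.

## Synthetic-trial generator

The generator's defaults are the design conditions: 99 patients, strict
permuted blocks of 3 at 2:1 (the realized split of the reference trial was
65/34, implying its randomization was not strictly block-balanced at the
analysis-set level; the generator keeps strict blocks and so yields 66/33),
exponential OS with medians 9 (experimental) vs 7 (control) months,
PFS medians 3.5/5.6 months, accrual 18 months + follow-up 6 months,
dropout hazard 0.01/month.

PFS is linked to OS by a latent competing-risks construction: OS ~
Exp(λ_os), progression ~ Exp(λ_pfs − λ_os) independent, PFS = min. This
gives *exact* configured exponential marginals for both endpoints and
PFS ≤ OS always. (A shared gamma frailty was considered and rejected: it
makes the OS marginal a gamma mixture, destroying the exponentiality that
both the analysis model and the generator's own distributional checks
assume.) A Weibull shape parameter (default 1) generalizes both marginals
via the same construction.

Best response is multinomial with per-arm default frequencies taken from
the reference response distribution (the PD/NE split of the non-responding
remainder is a generator convention). Responders' week-8 target-lesion
sums always shrink; CA19-9 series decline to a nadir near cycle 3 for ~65%
of patients.

PK profiles come from a two-compartment constant-rate-infusion closed form
(verified in tests against direct ODE integration) with log-normal IIV
(CV 50% on CL and Vc, 30% on Vp and Q) and inter-occasion variability
(CV 25% on CL and Vc) that differentiates day 2 from day 16 and gives the
accumulation ratio a realistic ~35% spread. Typical values CL = 7.79 L/h
and Vss = 104 L are split Vc = 50 L / Vp = 54 L with Q = 15 L/h — the
Vc/Q split is the one calibrated quantity, chosen so cohort geometric-mean
Cmax (~3.5 µg/mL) and NCA t½ (~9.5 h) fall in the observed ranges.
Adverse events are Bernoulli per patient/term from a per-arm incidence
table; ECG QT/RR pairs are constructed so configured fractions of patients
land in the ≤30, (30, 60] and >60 ms maximum-ΔQTcF categories (the
boundary maps "between 30 and 60" to the half-open (30, 60] so the three
categories partition the line).

**What the generator does not emulate:** real trials have non-exponential
hazards, informative censoring, arm-dependent assessment schedules,
correlated AE profiles, measurable-lesion selection effects and
assay-level noise in CA19-9 and PK. Passing tests show the *analysis
machinery* is correct under the design's own assumptions, not that those
assumptions hold in any real dataset — which is precisely the sense in
which design operating characteristics are ever computed.

## Numerical conventions and edge cases

Months are 365.25/12 days; PK times are hours; every table column carries
its unit in the schema. Rounding in rendered tables is half-up (Decimal),
not banker's. Degenerate inputs are contracts, not accidents: all-censored
KM samples have undefined medians; a pooled sample with no events makes
the log-rank p undefined (raised explicitly); zero responders make
duration of response "not estimable"; identical constant samples give
rank-sum p = 1. Posterior parameters must be finite and positive;
borrowing weights outside [0, 1] are rejected.

## Known limitations

The historical-control fixture is a calibrated reconstruction, not the
actual historical datasets of the original design, whose borrowing
mechanism and hyperparameters were never published; absolute agreement of
simulated operating characteristics with the published 0.76/0.15 is
therefore expected only to within the design's own Monte-Carlo and
specification uncertainty. The observed-trial quantities (medians 7.8/8.3,
posterior probability 0.33, the printed PK cohort table) depend on
patient-level data that were never deposited and are deliberately not
asserted anywhere; the package instead pins the machinery with exact
identities, hand-computable oracles and bracketing checks.
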