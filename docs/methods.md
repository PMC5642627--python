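# Methods

## Model structure

A three-state cohort model — progression-free (PF), progressed (PD),
dead — tracks a cohort of RAS wild-type metastatic colorectal cancer
patients over a 10-year horizon in 14-day cycles (260 cycles). State
occupancy is obtained by the partitioned-survival ("area under the curve")
construction: at each grid point t,

    PF(t)   = S_PFS(t)
    dead(t) = 1 − S_OS(t)
    PD(t)   = max(0, S_OS(t) − S_PFS(t))

where S_PFS and S_OS are the arm-specific Weibull survival curves. No
transition-rate decomposition is assumed because the inputs are
independently fitted endpoint curves; when a fitted PFS curve crosses above
its OS curve (an artefact of independent fitting), the surplus is clamped
and counted. Costs and effects are discounted at 5% per year with the
continuous-in-time convention (1 + r)^(−t).

Each survival law is S(u) = exp(−λ·u^γ) with u in the curve's *native*
time unit, which travels with the curve (see Calibration). The Weibull
median is (ln 2/λ)^(1/γ) native units; one-way sensitivity analysis
perturbs curves through their median with γ held fixed.

## Costs (payer perspective, 2016 USD)

* FOLFIRI $2,050.5 per 14-day cycle while progression-free.
* Cetuximab while progression-free. Dosing machinery supports
  400 mg/m² loading + 250 mg/m² weekly maintenance at BSA 1.72 m² with
  whole-vial (100 mg, $637.4) wastage; the calibrated configuration charges
  one listed price unit per cycle instead (see Calibration).
* Patient assistance program (PAP): the payer covers treatment months 1–2,
  months 3–4 are donated, thereafter each paid month is followed by three
  donated months. The monthly calendar maps to cycles at 2 cycles/month.
* RAS screening $176.9 per test, loaded as 176.9/(1 − 0.41) = $299.8 per
  treated (wild-type) patient, once at entry of the cetuximab strategy.
* Salvage chemotherapy $2,411.8 per cycle on progressed occupancy, capped
  at 3 cycles per progressing patient (calibrated; the cap is implemented
  via the mass of recent PF exits, an upper bound on recent progressors).
* Terminal care $1,980.1 once at death entry.
* Expected severe-adverse-event management, once at entry, as
  Σ probability × unit cost per arm.
* All payer costs are scaled by an insurance coverage fraction of 0.6
  (calibrated; the catastrophic-insurance scenario).

## Outcomes

Utilities: 0.85 progression-free, 0.24 progressed on follow-on
chemotherapy/supportive care, 0.68 progressed on follow-on targeted
therapy. The progressed state of the cetuximab arm applies a blended
utility with targeted-therapy fraction 0.3714, solved in closed form during
calibration from the published intervention QALY total (neither pure
utility reproduces it). QALYs integrate utility-weighted, discounted
occupancy over the trace; ICERs are reported per QALY and per life-year
with dominance handling; net monetary benefit is threshold × QALY − cost at
$22,200/QALY (3× 2015 Chinese per-capita GDP).

## Calibration: why and how

The printed parameter book cannot reproduce the published base case under
any single literal reading:

1. The four survival-parameter rows carry duplicated labels and no time
   unit. No single unit choice reproduces both the underlying trials'
   median survival times and the published life-year totals.
2. The printed cetuximab cost increments are ~6× smaller than BSA-based
   whole-vial dosing arithmetic implies at the listed per-100 mg price.
   They are, however, consistent with charging approximately one listed
   price unit per cycle.
3. The published with-PAP/without-PAP cost gap and the salvage/terminal
   components constrain coverage, caps and calendar mappings that the text
   leaves unspecified.

Rather than silently picking conventions, `rascea.calibrate` runs a
deterministic, two-stage lexicographic grid search over a *declared*
convention space (survival-row reading; per-curve native time unit;
half-cycle correction; discounted vs undiscounted life-year reporting;
coverage fraction; salvage cap; terminal-care mode; PAP months→cycles
mapping; cetuximab pricing convention) — effects first, then costs with the
traces frozen. Each stage minimises the worst cell error in units of that
cell's reproduction tolerance (0.1 absolute for life-year/QALY cells, 10%
relative for cost cells). The result is frozen into
`rascea/data/calibrated_params.yaml`; the chosen conventions are:

| convention | chosen value |
|---|---|
| survival-row reading | as printed |
| native time units | PFS control: 14-day cycles; PFS cetuximab: weeks; OS control: months; OS cetuximab: 14-day cycles |
| half-cycle correction | off |
| life-years reported | discounted |
| PD targeted-therapy fraction (cetuximab arm) | 0.3714 |
| insurance coverage fraction | 0.6 |
| salvage cap | 3 cycles |
| terminal care | once, at death entry |
| PAP calendar mapping | 2 cycles per month |
| cetuximab pricing | one listed price unit per cycle |

Worst tolerance-scaled residual: 0.82 (effects stage), 0.39 (costs stage).
Per-cell residuals of the frozen configuration:

| cell | model | published |
|---|---|---|
| cost, control | 30,072 | 30,668 |
| cost, cetuximab + PAP | 41,062 | 39,511 |
| cost, cetuximab no PAP | 47,555 | 47,754 |
| PF life-years, control | 0.737 | 0.795 |
| PF life-years, cetuximab | 0.967 | 0.944 |
| life-years, control | 2.051 | 2.066 |
| life-years, cetuximab | 2.878 | 2.796 |
| QALYs, control | 0.942 | 0.963 |
| QALYs, cetuximab | 1.593 | 1.593 |

### Known irreducible discrepancies

Three reproduction checks fail at their stated tolerances and are retained
as failing tests rather than papered over:

* **With-PAP incremental cost** (model $10,990 vs published $8,843) and
  the corresponding **ICER per QALY** (model $16,876 vs published
  $14,049). The driver is the incremental progression-free time: every
  curve reading in the declared space that keeps the four per-arm totals
  within tolerance yields ΔPF ≈ 0.23 years, whereas the published per-arm
  cells imply ΔPF = 0.149. Larger ΔPF means more incremental FOLFIRI (and
  PAP-discounted cetuximab) time, inflating the with-PAP increment, where
  the fixed drug components dominate. The published per-arm cost totals
  and the no-PAP increment are reproduced within 10%; the published
  increments are mutually inconsistent with their own per-arm cells at the
  achievable ΔPF.
* **PSA probability, control cost-effective without PAP** (model 64.1% at
  the default seed vs published ≈75%, band ±10 points). The documented
  distributional assumptions sample the cetuximab price triangular with
  mode = base at the range top, so its mean sits below the deterministic
  base, pulling the sampled incremental cost down and the cetuximab
  strategy's acceptability up. The with-PAP counterpart (88.5% vs ≈90%)
  passes.

## Probabilistic sensitivity analysis

Costs are sampled from triangular(min, mode = base, max) distributions;
utilities and proportions from beta distributions matched by moments, with
utility standard errors at 25% of the mean and proportion standard errors
at range/(2×1.96); infeasible moment pairs fall back to the range-based
standard deviation (logged once). Each parameter owns an independent RNG
substream keyed by a hash of its name, so adding or removing a parameter
never perturbs the others' draws, and a fixed seed reproduces results
bit-identically. Because no distribution is attached to the survival
curves, the cohort traces are fixed across draws and the per-draw model
evaluation reduces to exact linear accounting over the sampled unit costs
and utilities — a 1,000-draw PSA runs in well under a second. Acceptability
curves count ties toward the intervention.

## Synthetic Kaplan–Meier generator and curve refits

The survival inputs were originally fitted to published Kaplan–Meier data
that are not available, so the package emulates the pipeline: Weibull event
times by inverse transform, independent exponential censoring plus an
optional administrative cut, the product-limit estimator, and the primary
refit by least squares on the linearisation ln(−ln S) = ln λ + γ ln t over
KM step points with 0 < S < 1 (equal weights; this is the formulation
whose goodness of fit is an adjusted R²). A maximum-likelihood fit on the
individual data serves as a cross-check.

Recovery accuracy for λ is **parameterisation-dependent**: λ = e^intercept
is evaluated at t = 1 native unit, so when the native unit is far from the
data's time scale (e.g. a ~19-cycle median expressed in 14-day cycles) the
intercept is a long extrapolation and its sampling error is large (median
relative error ≈20% at n = 500 — for the maximum-likelihood fit too, so
this is intrinsic, not an estimator defect). Expressed in years, where the
median is order one, the same fits recover λ with ≈3% median error. The
recovery property tests therefore state the truth on a yearly axis, and
the simulate-km CLI defaults to years.

## Limitations

* The model is a reconstruction of an under-specified published analysis;
  the calibrated conventions are the best fit within a declared space, not
  a statement of what the original authors computed.
* Survival extrapolation rests on two-parameter Weibull fits carried to 10
  years; no external validation of the extrapolated tails is possible from
  the inputs.
* The salvage cap is implemented through an upper bound on recent
  progressors (recent PF exits), which slightly overstates salvage
  eligibility when deaths occur quickly after progression.
* PSA uncertainty excludes the survival curves themselves (no distribution
  is given for them), so decision uncertainty is understated.
* The PAP calendar is mapped onto the cycle grid at exactly 2 cycles per
  month; the exact contractual calendar is monthly.
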