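# Methods

## Model structure and assumptions

Serum creatinine in an ELBW neonate is described by a one-compartment mass
balance in concentration units (mg/dl):

    dC/dt = R_in / (10 · Vd) − (CL_adj(t) / Vd) · C

* **Volume.** Vd = 0.7 L/kg × birth weight. Weight is held at its birth
  value for the whole 6-week horizon; no growth model is included, and
  body-surface-area values are carried as inert metadata. The factor 10
  converts Vd from litres to decilitres so the state stays in mg/dl.
* **Production.** R_in (mg/day) is a constant, neonate-specific endogenous
  creatinine input. The early postnatal rise of creatinine is in reality a
  mixture of limited clearance, tubular back-leak and residual maternal
  transfer; none of these is separately identifiable from end-of-window
  concentration tables, so they are absorbed into R_in and the initial
  condition C(0). C(0) is gestational-age specific (maternal transfer
  scales with gestation) and is consumed as an exact initial condition,
  never fitted.
* **Clearance maturation.** CL(t) = CL_BL,eff + E_max·t^H/(t50^H + t^H).
  The baseline CL_BL,eff = 0.075 × (1 + 2.55) = 0.26625 L/day is a fixed
  population constant (the bracketed covariate factor is applied to the
  raw baseline; this reading is the only one consistent with the absolute
  reduction being ~5 % of baseline at birth — the alternative, 5 % of
  0.075 L/day, is off by ~3.5-fold).
* **Ibuprofen effect.** While a course is active, a constant absolute
  0.0094 ml/min = 0.013536 L/day is subtracted from CL(t), independent of
  gestational and postnatal age; exposure is binary and the dose amounts
  (10/5/5 mg/kg at 24 h intervals) are recorded but never enter the
  dynamics. The textual "5 % decrease" is the week-1 proportional
  consequence of this absolute reduction, not a second mechanism. A floor
  of 1e-6 L/day preserves positivity (never binding for calibrated
  parameters).
* **Exposure window.** Calendar day d spans postnatal time (d−1, d], so a
  3-day course starting on day 1 is active on t ∈ [0, 3]; "Before" is the
  concentration at the window start and "After" at the window end. This
  convention makes the period-1 "Before" equal the birth value, matching
  the published tables. Each treatment period is an independent scenario
  carrying only its own course (supported by the arm-invariant "Before"
  columns); the figure overlay additionally shows one neonate receiving
  all three (non-overlapping) courses.
* **Delivery mode** is carried in the profile as an inert covariate slot;
  its published effect size is not available, so it has no numeric role.

## Parameters

| symbol | field | units | default / bounds |
|---|---|---|---|
| CL_BL,raw | `cl_bl_raw` | L/day | 0.075 (fixed) |
| 1 + 2.55 | `baseline_covariate_factor` | – | 3.55 (fixed) |
| Vd/kg | `vd_per_kg` | L/kg | 0.7 (fixed) |
| ΔCL | `ibuprofen_reduction` | L/day | 0.013536 (fixed) |
| E_max | `emax` | L/day | calibrated, [0.01, 5] |
| t50 | `t50` | days | calibrated, [0.5, 30] |
| H | `hill` | – | calibrated, [0.3, 8] |
| R_in | `production_rate` | mg/day | calibrated, [0.1, 10] |

All four calibrated parameters are per gestational-age group. Fitted
values for the reference groups land at E_max ≈ 0.95→0.58 L/day and t50 ≈
22→8 days from GA 24 to GA 32 — the monotone t50 decrease independently
expresses the expected faster clearance maturation at higher gestational
age, which was not imposed.

## Calibration design

The 20 non-initial no-ibuprofen anchor concentrations (5 times × 4 GA
groups, printed to 0.001 mg/dl) are fitted by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) independently
per GA group, from a deterministic 18-point multi-start grid
(t50 ∈ {3, 8, 16} × H ∈ {1, 2, 4} × E_max ∈ {0.2, 0.8}; the R_in start is
derived from the latest anchor by a quasi-steady-state argument). The best
start wins; a solution on a bound flags non-convergence. No random starts
are used, so calibration is bit-reproducible.

**Identifiability ridge and the clearance anchor.** Sparse end-of-window
concentrations leave a nearly flat objective valley trading clearance
scale against production (CL(30) anywhere between ~0.7 and ~1.4 L/day fits
the concentration anchors almost equally well, because a proportional
increase of CL and R_in leaves the quasi-steady state unchanged and the
transient is only weakly sampled). The published week-5 proportional-
reduction figure is one more printed model output that resolves the
valley: a −2 % proportional effect of the fixed absolute reduction implies
CL(30 d) ≈ 0.6768 L/day. Each group's residual vector therefore carries
one additional term, weight × (CL(30) − 0.6768), with weight 0.02 — the
precision ratio of the two data types (concentration anchors reproducible
to ~0.002 mg/dl; a one-significant-figure "−2 %" admits ~0.15 L/day).
Replication results are insensitive to this weight over at least
[0.02, 0.1]. The ibuprofen-arm concentrations and the between-arm
differences are *never* fitted; they are genuine out-of-sample
predictions. When the same estimator is applied to synthetic datasets
(which carry no such published statement) the clearance anchor is
disabled.

**Earlier structural variant.** A more parsimonious variant with shared
t50 and H across GA groups was evaluated first and rejected: its best
attainable fit leaves 0.014–0.018 mg/dl errors at specific anchors (the
four groups genuinely differ in maturation shape, not only in amplitude),
which propagates into the held-out ibuprofen-arm predictions.

## Numerical choices

* Integrator: classical fixed-step 4th-order Runge–Kutta, default step
  0.005 day (8401-point grid over 42 days); the clearance function is
  evaluated at the stage times. Exposure windows are grid-aligned and the
  exposure state is constant within a step (judged at the step midpoint),
  so the clearance discontinuity never falls inside a stage evaluation.
  Steps above 0.05 day are rejected as an accuracy guard. Against an
  independent forward-Euler oracle at step 1e-4 day the integrator agrees
  to <1e-5 mg/dl on the calibrated reference scenarios; halving the step
  changes trajectories by <1e-9 mg/dl.
* Calibration uses step 0.02 day inside the objective (anchor times are
  exact grid multiples); downstream simulation uses 0.005 day. The
  cross-step inconsistency is far below the printed precision.
* Table emission rounds to 3 decimals, round-half-to-even; unrounded
  values are kept in parallel columns.
* Degenerate inputs: E_max = 0 (no maturation), R_in = 0 (pure washout)
  and zero-width parameter bounds (pinning) are all legal and covered by
  tests; non-positive weights, concentrations, t50 or Hill are rejected.

## Synthetic cohorts

`generate_cohort` emulates the *structure* of the source dataset: 217
neonates, ~4,000 creatinine samples in the first 6 weeks, GA median 27
(IQR 26–28) weeks, weight median 830 (IQR 720–910) g.

* GA is discrete on {24,…,32} weeks with packaged probabilities shaped to
  the printed median/IQR.
* Weight | GA is lognormal; its median follows the reference neonates'
  weight-vs-GA shape but is anchored to the printed cohort median of 830 g
  at GA 27 (the GA-27 reference neonate's 779 g is a typical-profile
  value, not the cohort median), with log-scale σ = 0.16 tuned so the
  marginal IQR reproduces 720–910 g.
* Per-neonate E_max, R_in and a baseline-clearance multiplier are drawn
  lognormally around the calibrated typical values interpolated to the
  neonate's GA (default CV 20 %/20 %/10 % — invented, as no variance
  components are published); t50, H and C(0) stay at their typical values.
* Sampling: one mandatory birth sample plus Poisson(17.6) samples on
  uniform random days (the `"clinical"` schedule), or a fixed 18-time
  design (`"grid"`) used by recovery experiments. Observations get
  proportional (5 %) plus additive (0.01 mg/dl) noise — synthetic-only
  defaults — truncated by resampling so values stay positive.
* 30 % of neonates receive a day-1 course (typical of patent-ductus
  treatment rates in ELBW cohorts; the published exposure fraction is not
  available).
* Determinism: every neonate's random stream is keyed by (seed, index), so
  datasets are byte-identical across runs and per-neonate records do not
  depend on cohort size or order.

What passing recovery tests do **not** show about real data: real sampling
is clinically driven (denser in week 1, correlated with illness), real
residual error is not iid Gaussian, real neonates grow, and real
between-subject variability is larger and correlated across parameters.
The cohort module tests the estimation machinery, not the epidemiology.

`recovery_experiment` (simulation–estimation): generate a grid-schedule
cohort, average the unexposed observations per (GA group, time) into mean
curves, refit per group (pure concentration objective, reduced 4-point
start grid), and compare with the generating typical values. Noise-free
recovery is exact to machine precision; with 0.01 mg/dl additive noise at
n = 217 the median absolute relative error per parameter is ~2 %.

## Known limitations

* The week-1 GA gradient of the predicted effect (0.031 → 0.026 mg/dl
  across GA 24 → 32) is flatter than the published 0.030 → 0.023, because
  CL_BL,eff is GA-independent in the printed formula; the source
  mixed-effects model likely carried gestational age (and delivery mode)
  on the baseline with unpublished magnitudes. The GA 32 period-1
  difference is therefore over-predicted by ~0.003 mg/dl.
* Calibrated E_max/t50/H are reconstructions constrained by the printed
  tables plus the week-5 clearance statement; they need not equal the
  source model's estimates.
* Constant production cannot represent a decaying maternal-transfer input;
  it is adequate for the printed 6-week trajectories but should not be
  extrapolated backwards into fetal life or used for maternal-transfer
  inference.
* No ibuprofen pharmacokinetics: exposure is binary, so dose-dependent or
  concentration-dependent nephrotoxicity is out of scope, as are
  acute-kidney-injury staging and variance-component estimation.
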