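# Packaged defaults for the ELBW serum-creatinine simulation pipeline.
# Every numeric constant used by the stages lives here so that the model's
# structural choices (e.g. the covariate-scaled baseline clearance) are
# visible and overridable from a user configuration file.

model:
  # Baseline creatinine clearance before covariate scaling, L/day.
  cl_bl_raw_l_day: 0.075
  # Dimensionless covariate factor on the baseline: effective baseline
  # clearance = cl_bl_raw_l_day * baseline_covariate_factor = 0.26625 L/day.
  baseline_covariate_factor: 3.55
  # Apparent distribution volume of creatinine per kg body weight, L/kg.
  vd_per_kg_l: 0.7
  # Absolute creatinine-clearance reduction while ibuprofen is on board,
  # ml/min (converted internally to L/day: x * 1.44).
  ibuprofen_reduction_ml_min: 0.0094
  # Simulation horizon (days since birth) and integrator step (days).
  horizon_days: 42.0
  step_days: 0.005

# Four typical reference ELBW neonates (gestational age in completed weeks,
# birth weight in grams, serum creatinine at birth in mg/dl; body surface
# area on days 1 and 31 carried as metadata only).
profiles:
  - id: ga24
    gestational_age: 24
    birth_weight_g: 621.0
    initial_creatinine_mg_dl: 0.383
    bsa_day1_m2: 0.07
    bsa_day31_m2: 0.09
  - id: ga27
    gestational_age: 27
    birth_weight_g: 779.0
    initial_creatinine_mg_dl: 0.462
    bsa_day1_m2: 0.08
    bsa_day31_m2: 0.11
  - id: ga29
    gestational_age: 29
    birth_weight_g: 840.0
    initial_creatinine_mg_dl: 0.518
    bsa_day1_m2: 0.09
    bsa_day31_m2: 0.11
  - id: ga32
    gestational_age: 32
    birth_weight_g: 889.0
    initial_creatinine_mg_dl: 0.607
    bsa_day1_m2: 0.09
    bsa_day31_m2: 0.12

# Three-day ibuprofen courses (label dosing 10/5/5 mg/kg at 24 h intervals;
# doses are recorded metadata only -- exposure enters the model as a binary
# on/off on clearance).
periods:
  - start_day: 1
    duration_days: 3
    doses_mg_per_kg: [10.0, 5.0, 5.0]
  - start_day: 15
    duration_days: 3
    doses_mg_per_kg: [10.0, 5.0, 5.0]
  - start_day: 29
    duration_days: 3
    doses_mg_per_kg: [10.0, 5.0, 5.0]

# Published serum-creatinine anchor points (mg/dl) at the treatment-window
# boundaries, per gestational-age group and arm.  The no-ibuprofen rows are
# the calibration data; the ibuprofen rows and the end-of-course differences
# are held out for out-of-sample validation.
anchors:
  times_day: [0, 3, 14, 17, 28, 31]
  no_ibuprofen:
    24: [0.383, 0.876, 0.500, 0.462, 0.375, 0.365]
    27: [0.462, 0.830, 0.439, 0.411, 0.345, 0.339]
    29: [0.518, 0.807, 0.408, 0.384, 0.334, 0.328]
    32: [0.607, 0.772, 0.374, 0.355, 0.321, 0.318]
  ibuprofen:
    24: [0.383, 0.906, 0.500, 0.472, 0.375, 0.371]
    27: [0.462, 0.857, 0.439, 0.419, 0.345, 0.344]
    29: [0.518, 0.832, 0.408, 0.391, 0.334, 0.333]
    32: [0.607, 0.795, 0.374, 0.360, 0.321, 0.322]
  # End-of-course ibuprofen-minus-control differences (mg/dl) per period.
  differences:
    24: [0.030, 0.010, 0.006]
    27: [0.026, 0.008, 0.005]
    29: [0.025, 0.007, 0.005]
    32: [0.023, 0.006, 0.004]

calibration:
  # Integrator step used inside the least-squares objective (days).  The
  # anchor times must be integer multiples of this step.
  step_days: 0.02
  # Deterministic multi-start grid: 3 x 3 x 2 = 18 starts.
  t50_starts: [3.0, 8.0, 16.0]
  hill_starts: [1.0, 2.0, 4.0]
  emax_starts: [0.2, 0.8]
  # Soft clearance anchor resolving the clearance/production ridge: the
  # fixed absolute reduction is "approximately -2%" of clearance at week 5,
  # implying CL(30 d) ~= 0.6768 L/day.  The weight is the precision ratio of
  # concentration anchors (~0.002 mg/dl) to the one-significant-figure
  # clearance statement (~0.15 L/day).
  clearance_anchor:
    time_day: 30.0
    proportional_reduction_pct: -2.0
    weight: 0.02
  # Free-parameter bounds (generous physiological envelopes).
  bounds:
    emax: [0.01, 5.0]          # L/day
    production_rate: [0.1, 10.0]  # mg/day
    t50: [0.5, 30.0]           # days
    hill: [0.3, 8.0]           # dimensionless

cohort:
  n_neonates: 217
  # Discrete gestational-age distribution (weeks) shaped to a median of 27
  # with interquartile range 26-28.
  ga_probabilities:
    24: 0.04
    25: 0.07
    26: 0.18
    27: 0.32
    28: 0.20
    29: 0.09
    30: 0.05
    31: 0.03
    32: 0.02
  # Birth weight given GA: lognormal whose median follows the reference
  # neonates' weight-vs-GA shape, anchored to a cohort median of 830 g at
  # GA 27; sigma on the log scale tuned to the cohort IQR 720-910 g.
  weight_median_anchor_g: 830.0
  weight_sigma_log: 0.16
  # Number of creatinine samples per neonate: 1 mandatory birth sample plus
  # Poisson(17.6) further samples on random days 0-42 (mean 18.6 total).
  samples_poisson_mean: 17.6
  # Between-subject variability, lognormal coefficient of variation.
  bsv_cv:
    emax: 0.2
    production_rate: 0.2
    cl_bl: 0.1
  # Residual (assay + model misspecification) error on observations.
  residual_proportional: 0.05
  residual_additive_mg_dl: 0.01
  # Fraction of neonates receiving a 3-day ibuprofen course, and its start.
  exposure_fraction: 0.3
  exposure_start_day: 1
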