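# neocrea

Dynamic serum-creatinine modelling for extremely-low-birth-weight (ELBW,
≤1000 g) neonates: postnatal maturation of creatinine clearance, a
one-compartment concentration balance, and the nephrotoxic signal of a
3-day ibuprofen course (the standard pharmacological treatment of a patent
ductus arteriosus), modelled as a constant *absolute* reduction of
creatinine clearance while the drug is on board.

The package is aimed at pharmacometricians and neonatal clinical
pharmacologists who want to (i) reproduce the reference simulation study of
ibuprofen-related creatinine trends in typical ELBW neonates, (ii) reuse
the calibrated dynamic model for their own scenarios, or (iii) generate
virtual ELBW cohorts with known ground truth for simulation–estimation
work.

## Model

Serum creatinine C(t) (mg/dl) in a single well-stirred compartment of
volume Vd = 0.7 L/kg × birth weight, with constant endogenous production
R_in (mg/day) and first-order elimination:

    dC/dt = R_in / (10 · Vd) − k_et(t) · C,          C(0) = C_0

    k_et(t) = CL(t) / Vd                              (1/day)

    CL(t) = CL_BL,eff + E_max · t^H / (t50^H + t^H)   (L/day)

where t is postnatal age in days, CL_BL,eff = 0.075 L/day × (1 + 2.55) =
0.26625 L/day is the covariate-scaled baseline clearance, and the sigmoid
E_max (Hill) term describes postnatal maturation of glomerular filtration
(E_max: maximal additional clearance; t50: age at half-maximum; H:
steepness). During an ibuprofen course, CL(t) is reduced by a constant
absolute 0.0094 ml/min = 0.013536 L/day at every age — which is ~−5 % of
baseline clearance at birth but only ~−2 % of the matured clearance by
week 5, the mechanism behind the fading adverse-drug-reaction signal.

The free parameters (E_max, R_in, t50, H per gestational-age group) are
calibrated by deterministic multi-start bounded least squares against the
published no-ibuprofen concentration anchors; the ibuprofen arm is held out
entirely and serves as out-of-sample validation of the effect model.

## Worked example

```bash
neocrea calibrate --output-dir out/calib
neocrea replicate-study --params out/calib/parameters.csv --output-dir out/study
```

or equivalently in Python:

```python
from neocrea import (packaged_anchors, fit_parameters,
                     build_reference_grid, run_study)

result = fit_parameters(packaged_anchors())   # ~20 s, bit-reproducible
print(result.rms_residual)                    # 0.00166 mg/dl over 20 anchors
tables = run_study(build_reference_grid(), result.fitted)
print(tables.table1.to_string(index=False))
```

```
 ga_weeks  period  difference_mg_dl  difference_rounded
       24       1          0.031068               0.031
       24       2          0.009719               0.010
       24       3          0.006058               0.006
       27       1          0.026932               0.027
       27       2          0.007648               0.008
       27       3          0.005262               0.005
       29       1          0.026080               0.026
       29       2          0.006994               0.007
       29       3          0.005189               0.005
       32       1          0.025769               0.026
       32       2          0.006631               0.007
       32       3          0.005384               0.005
```

Each row is the predicted *end-of-course* creatinine difference
(ibuprofen-exposed minus unexposed, mg/dl) for one reference neonate
(gestational ages 24/27/29/32 weeks; birth weights 621/779/840/889 g) and
one 3-day treatment window (postnatal days 1–3, 15–17 or 29–31).  The
week-1 effect (~0.026–0.031 mg/dl) is several-fold larger than the week-3
and week-5 effects (~0.005–0.010 mg/dl): as clearance matures, the same
absolute clearance reduction produces an ever smaller concentration signal.
`table2.csv` holds the Before/After concentrations per arm, and the
`traj_ga*.csv` files the full concentration and clearance trajectories
behind the figures.

Other stages: `neocrea simulate` (reference trajectories),
`neocrea generate-cohort` (virtual ELBW cohort with ground truth) and
`neocrea recovery` (simulation–estimation parameter recovery).  Every stage
writes a JSON manifest (resolved configuration, version, seed, input
checksums) beside its outputs and refuses to overwrite existing files
unless `--force` is given.

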