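"""Dynamic serum-creatinine model for extremely-low-birth-weight neonates.

The model describes serum creatinine C(t) (mg/dl) in a single well-stirred
compartment of volume ``Vd = 0.7 L/kg x birth weight``.  Creatinine is
produced at a constant neonate-specific rate (mg/day) and eliminated with a
first-order rate constant ``ket(t) = CL(t) / Vd`` whose clearance matures
postnatally following a sigmoid Emax (Hill) function of postnatal age t in
days::

    CL(t) = CL_BL,eff + emax * t**hill / (t50**hill + t**hill)

``CL_BL,eff`` is the covariate-scaled baseline clearance (0.075 L/day x 3.55
for the reference population).  Ibuprofen exposure subtracts a constant
absolute amount (0.0094 ml/min = 0.013536 L/day) from CL(t) while a course
is running; exposure is binary -- dose amounts are recorded but never enter
the dynamics.

The concentration balance, with the volume expressed in decilitres so the
state stays in mg/dl, is::

    dC/dt = production_rate / (10 * Vd)  -  ket(t) * C

and is integrated with a classical fixed-step 4th-order Runge-Kutta scheme
whose step divides the treatment-window boundaries, so the clearance
discontinuity at an exposure switch is always aligned with a grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .units import ml_per_min_to_l_per_day

__all__ = [
    "DELIVERY_MODES",
    "GA_RANGE",
    "NeonateProfile",
    "ModelParameters",
    "TreatmentCourse",
    "CreatinineTrajectory",
    "maturation_clearance",
    "distribution_volume",
    "apply_ibuprofen_effect",
    "elimination_rate",
    "simulate_concentration",
    "CLEARANCE_FLOOR",
    "MAX_STEP",
]

DELIVERY_MODES = ("vaginal", "c_section", "unspecified")

#: Gestational-age range (completed weeks) covered by the model.
GA_RANGE = (22, 34)

#: Positivity floor (L/day) applied to clearance after the ibuprofen
#: subtraction; never binding for calibrated parameter sets.
CLEARANCE_FLOOR = 1e-6

#: Largest integrator step (days) accepted by :func:`simulate_concentration`.
MAX_STEP = 0.05


@dataclass(frozen=True)
class NeonateProfile:
    """One reference or virtual neonate.

    Parameters
    ----------
    id
        Short label, e.g. ``"ga24"``.
    gestational_age
        Completed weeks of gestation at birth (22-34).
    birth_weight
        Birth weight in grams; held constant over the simulation horizon.
    initial_creatinine
        Serum creatinine at birth (t = 0), mg/dl.  Gestational-age dependent
        (maternal creatinine transfer until birth).
    delivery_mode
        Inert covariate slot; carried but without numeric effect.
    bsa_day1, bsa_day31
        Optional body-surface-area metadata (m^2), unused by the dynamics.
    """

    id: str
    gestational_age: int
    birth_weight: float
    initial_creatinine: float
    delivery_mode: str = "unspecified"
    bsa_day1: float | None = None
    bsa_day31: float | None = None

    def __post_init__(self) -> None:
        if self.birth_weight <= 0:
            raise ValidationError(f"birth_weight must be positive, got {self.birth_weight}")
        if self.initial_creatinine <= 0:
            raise ValidationError(
                f"initial_creatinine must be positive, got {self.initial_creatinine}"
            )
        if not (GA_RANGE[0] <= self.gestational_age <= GA_RANGE[1]):
            raise ValidationError(
                f"gestational_age {self.gestational_age} outside {GA_RANGE}"
            )
        if self.delivery_mode not in DELIVERY_MODES:
            raise ValidationError(f"delivery_mode must be one of {DELIVERY_MODES}")


@dataclass(frozen=True)
class ModelParameters:
    """Coefficients of the clearance-maturation and concentration dynamics.

    All clearances in L/day, volumes per kg in L/kg, production in mg/day.
    ``emax`` and ``production_rate`` are neonate-specific (they carry the
    gestational-age dependence); the remaining fields are population
    constants.
    """

    emax: float                    # L/day, maximum additional matured clearance
    t50: float                     # days, postnatal age at half of emax
    hill: float                    # dimensionless steepness
    production_rate: float         # mg/day, endogenous creatinine input
    cl_bl_raw: float = 0.075       # L/day, baseline clearance before scaling
    baseline_covariate_factor: float = 3.55   # dimensionless (1 + 2.55)
    vd_per_kg: float = 0.7         # L/kg
    ibuprofen_reduction: float = ml_per_min_to_l_per_day(0.0094)  # L/day

    def __post_init__(self) -> None:
        for name in ("t50", "hill", "cl_bl_raw", "baseline_covariate_factor",
                     "vd_per_kg"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name} must be strictly positive, got {v}")
        for name in ("emax", "production_rate", "ibuprofen_reduction"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):  # zero = degenerate but legal
                raise ValidationError(f"{name} must be non-negative, got {v}")

    @property
    def cl_bl_eff(self) -> float:
        """Effective baseline clearance CL_BL,eff (L/day) entering CL(t)."""
        return self.cl_bl_raw * self.baseline_covariate_factor

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class TreatmentCourse:
    """An ibuprofen exposure window.

    ``start_day`` is the 1-based calendar day of the first dose; calendar
    day d spans postnatal time (d-1, d], so a course starting on day 1 and
    lasting 3 days is active on t in [0, 3] days since birth.
    """

    start_day: int
    duration_days: int = 3
    doses_mg_per_kg: tuple[float, ...] = (10.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        if self.start_day < 1:
            raise ValidationError(f"start_day must be >= 1, got {self.start_day}")
        if self.duration_days < 1:
            raise ValidationError(f"duration_days must be >= 1, got {self.duration_days}")
        if len(self.doses_mg_per_kg) != self.duration_days:
            raise ValidationError(
                f"dose list length {len(self.doses_mg_per_kg)} != duration "
                f"{self.duration_days}"
            )

    @property
    def window(self) -> tuple[float, float]:
        """Exposure window (start, end) in days since birth."""
        start = float(self.start_day - 1)
        return (start, start + self.duration_days)


@dataclass
class CreatinineTrajectory:
    """Paired time grids of concentration and clearance for one scenario.

    ``clearance`` is the post-ibuprofen-adjustment CL(t) in L/day;
    ``exposure_flag`` is True exactly inside a treatment window (closed
    interval, so both window boundaries are flagged).
    """

    times: np.ndarray          # days since birth, uniform grid
    concentration: np.ndarray  # mg/dl
    clearance: np.ndarray      # L/day
    exposure_flag: np.ndarray  # bool

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.concentration) == len(self.clearance) == len(self.exposure_flag) == n):
            raise ValidationError("trajectory channel lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if np.any(self.concentration <= 0):
            raise ValidationError("concentration must stay positive")
        if np.any(self.clearance <= 0):
            raise ValidationError("clearance must stay positive")

    def at(self, t: float) -> float:
        """Concentration at grid time ``t`` (must lie on the grid)."""
        step = self.times[1] - self.times[0]
        i = round(float(t) / step)
        if not (0 <= i < len(self.times)) or abs(self.times[i] - t) > 1e-9:
            raise ValidationError(f"time {t} is not on the trajectory grid")
        return float(self.concentration[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.times,
                "concentration_mg_dl": self.concentration,
                "clearance_l_day": self.clearance,
                "exposed": self.exposure_flag.astype(int),
            }
        )


def maturation_clearance(t, params: ModelParameters):
    """Creatinine clearance CL(t) (L/day) at postnatal age ``t`` days.

    Sigmoid Emax maturation on top of the covariate-scaled baseline:
    ``CL_BL,eff + emax * t**hill / (t50**hill + t**hill)``.  Accepts scalars
    or arrays; monotone non-decreasing in t and bounded by
    ``CL_BL,eff + emax``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("postnatal age t must be non-negative")
    th = np.power(t_arr, params.hill)
    cl = params.cl_bl_eff + params.emax * th / (params.t50**params.hill + th)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(cl)
    return cl


def distribution_volume(weight: float, params: ModelParameters) -> float:
    """Apparent distribution volume (L) for a birth weight in grams."""
    if weight <= 0:
        raise ValidationError(f"weight must be positive, got {weight}")
    return params.vd_per_kg * weight / 1000.0


def apply_ibuprofen_effect(cl, exposed, params: ModelParameters):
    """Subtract the absolute ibuprofen clearance reduction while exposed.

    The reduction is the same absolute amount (default 0.013536 L/day) at
    every postnatal age and every gestational age; the result is floored at
    ``CLEARANCE_FLOOR`` to preserve positivity.  Unexposed clearance passes
    through unchanged.  Accepts scalars or arrays.
    """
    cl_arr = np.asarray(cl, dtype=float)
    if np.any(cl_arr <= 0):
        raise ValidationError("clearance must be positive")
    reduced = np.maximum(cl_arr - params.ibuprofen_reduction, CLEARANCE_FLOOR)
    out = np.where(exposed, reduced, cl_arr)
    if out.ndim == 0:
        return float(out)
    return out


def elimination_rate(
    t: float, profile: NeonateProfile, params: ModelParameters, exposed: bool = False
) -> float:
    """First-order elimination rate constant ket(t) = CL_adj(t)/Vd (1/day)."""
    cl = apply_ibuprofen_effect(maturation_clearance(t, params), exposed, params)
    return cl / distribution_volume(profile.birth_weight, params)


def _validated_windows(
    courses: Iterable[TreatmentCourse], step: float
) -> list[tuple[float, float]]:
    windows = sorted(c.window for c in courses)
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if s1 < e0:
            raise ValidationError(
                f"treatment courses overlap: [{s0}, {e0}] and starting {s1}"
            )
    for s, e in windows:
        for b in (s, e):
            if abs(b / step - round(b / step)) > 1e-9:
                raise ValidationError(
                    f"window boundary {b} is not a multiple of step {step}"
                )
    return windows


def simulate_concentration(
    profile: NeonateProfile,
    params: ModelParameters,
    courses: Sequence[TreatmentCourse] = (),
    t_end: float = 42.0,
    step: float = 0.005,
) -> CreatinineTrajectory:
    """Integrate the creatinine balance over ``[0, t_end]`` days.

    Classical fixed-step RK4 on the uniform grid {0, step, ..., t_end}; the
    clearance function is evaluated at the stage times, and the exposure
    state is constant within each step (windows are grid-aligned, judged at
    the step midpoint), so the switch discontinuity never falls inside a
    stage evaluation.

    Raises
    ------
    ValidationError
        If ``step > MAX_STEP`` (accuracy guard), ``t_end`` is not a grid
        multiple, or courses overlap.
    """
    if t_end <= 0:
        raise ValidationError(f"t_end must be positive, got {t_end}")
    if not (0 < step <= MAX_STEP):
        raise ValidationError(f"step must be in (0, {MAX_STEP}] day, got {step}")
    n = round(t_end / step)
    if abs(n * step - t_end) > 1e-9:
        raise ValidationError(f"t_end {t_end} must be a multiple of step {step}")

    windows = _validated_windows(courses, step)
    vd = distribution_volume(profile.birth_weight, params)
    inflow = params.production_rate / (10.0 * vd)  # mg/dl per day

    times = np.arange(n + 1) * step
    cl_grid = maturation_clearance(times, params)
    cl_mid = maturation_clearance(times[:-1] + step / 2.0, params)

    mids = times[:-1] + step / 2.0
    exposed_mid = np.zeros(n, dtype=bool)
    exposed_grid = np.zeros(n + 1, dtype=bool)
    for s, e in windows:
        exposed_mid |= (mids > s) & (mids < e)
        exposed_grid |= (times >= s - 1e-12) & (times <= e + 1e-12)

    red = params.ibuprofen_reduction
    floor = CLEARANCE_FLOOR
    cg = cl_grid.tolist()
    cm = cl_mid.tolist()
    em = exposed_mid.tolist()

    conc = np.empty(n + 1)
    c = float(profile.initial_creatinine)
    conc[0] = c
    h = step
    inv_vd = 1.0 / vd
    for i in range(n):
        if em[i]:
            ka = max(cg[i] - red, floor) * inv_vd
            km = max(cm[i] - red, floor) * inv_vd
            kb = max(cg[i + 1] - red, floor) * inv_vd
        else:
            ka = cg[i] * inv_vd
            km = cm[i] * inv_vd
            kb = cg[i + 1] * inv_vd
        k1 = inflow - ka * c
        c2 = c + 0.5 * h * k1
        k2 = inflow - km * c2
        c3 = c + 0.5 * h * k2
        k3 = inflow - km * c3
        c4 = c + h * k3
        k4 = inflow - kb * c4
        c = c + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        conc[i + 1] = c

    clearance = np.where(
        exposed_grid, np.maximum(cl_grid - red, floor), cl_grid
    )
    return CreatinineTrajectory(
        times=times,
        concentration=conc,
        clearance=clearance,
        exposure_flag=exposed_grid,
    )
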