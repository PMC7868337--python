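"""Reference constants materialised from the configuration.

Builders that turn the (default or user-supplied) configuration mapping into
the domain objects used by the pipeline: the four typical reference ELBW
neonates, the three ibuprofen treatment periods, the published concentration
anchor points, and the fixed model constants.
"""

from __future__ import annotations

from typing import Any, Mapping

from .config import default_config
from .model import ModelParameters, NeonateProfile, TreatmentCourse
from .units import ml_per_min_to_l_per_day

__all__ = [
    "reference_profiles",
    "reference_periods",
    "model_constants",
    "base_parameters",
]


def reference_profiles(cfg: Mapping[str, Any] | None = None) -> dict[int, NeonateProfile]:
    """The reference neonates keyed by gestational age (weeks)."""
    cfg = cfg or default_config()
    out: dict[int, NeonateProfile] = {}
    for p in cfg["profiles"]:
        prof = NeonateProfile(
            id=str(p["id"]),
            gestational_age=int(p["gestational_age"]),
            birth_weight=float(p["birth_weight_g"]),
            initial_creatinine=float(p["initial_creatinine_mg_dl"]),
            bsa_day1=p.get("bsa_day1_m2"),
            bsa_day31=p.get("bsa_day31_m2"),
        )
        out[prof.gestational_age] = prof
    return out


def reference_periods(cfg: Mapping[str, Any] | None = None) -> list[TreatmentCourse]:
    """The ibuprofen treatment periods in start-day order."""
    cfg = cfg or default_config()
    return [
        TreatmentCourse(
            start_day=int(p["start_day"]),
            duration_days=int(p["duration_days"]),
            doses_mg_per_kg=tuple(float(d) for d in p["doses_mg_per_kg"]),
        )
        for p in cfg["periods"]
    ]


def model_constants(cfg: Mapping[str, Any] | None = None) -> dict[str, float]:
    """Fixed (non-calibrated) model constants in internal units."""
    cfg = cfg or default_config()
    m = cfg["model"]
    return {
        "cl_bl_raw": float(m["cl_bl_raw_l_day"]),
        "baseline_covariate_factor": float(m["baseline_covariate_factor"]),
        "vd_per_kg": float(m["vd_per_kg_l"]),
        "ibuprofen_reduction": ml_per_min_to_l_per_day(
            float(m["ibuprofen_reduction_ml_min"])
        ),
    }


def base_parameters(
    emax: float,
    t50: float,
    hill: float,
    production_rate: float,
    cfg: Mapping[str, Any] | None = None,
) -> ModelParameters:
    """A ModelParameters with the configured constants and given free values."""
    return ModelParameters(
        emax=emax, t50=t50, hill=hill, production_rate=production_rate,
        **model_constants(cfg),
    )
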