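"""Unit conversions used across the package.

The clearance literature for neonates mixes ml/min and L/day; concentrations
are reported in mg/dl while volumes of distribution are in litres.  All
conversions are exact rational factors so round trips are lossless.
"""

from __future__ import annotations

#: 1 ml/min = 1440 min/day / 1000 ml/L = 1.44 L/day
ML_PER_MIN_IN_L_PER_DAY = 1440.0 / 1000.0


def ml_per_min_to_l_per_day(x: float) -> float:
    """Convert a clearance from ml/min to L/day (factor 1.44)."""
    return x * ML_PER_MIN_IN_L_PER_DAY


def l_per_day_to_ml_per_min(x: float) -> float:
    """Convert a clearance from L/day to ml/min (exact inverse)."""
    return x / ML_PER_MIN_IN_L_PER_DAY


def mg_dl_to_mg_l(x: float) -> float:
    """Convert a concentration from mg/dl to mg/L (1 dl = 0.1 L)."""
    return x * 10.0


def mg_l_to_mg_dl(x: float) -> float:
    """Convert a concentration from mg/L to mg/dl (exact inverse)."""
    return x / 10.0


def l_to_dl(x: float) -> float:
    """Convert a volume from litres to decilitres."""
    return x * 10.0
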