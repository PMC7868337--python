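"""CSV serialisation of trajectories, anchors, parameters and datasets."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import pandas as pd

from .calibration import AnchorPoint, ARMS, CalibrationResult
from .errors import ValidationError
from .model import CreatinineTrajectory, ModelParameters

TRAJECTORY_HEADER = ["time_day", "concentration_mg_dl", "clearance_l_day", "exposed"]
ANCHOR_HEADER = ["ga_weeks", "time_day", "arm", "concentration_mg_dl"]

_PARAM_COLUMNS = [
    "ga_weeks", "emax_l_day", "production_rate_mg_day", "t50_day", "hill",
    "cl_bl_raw_l_day", "baseline_covariate_factor", "vd_per_kg_l",
    "ibuprofen_reduction_l_day", "initial_creatinine_mg_dl",
]


def write_trajectory(traj: CreatinineTrajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_HEADER if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing trajectory column(s) {missing}")
    return df


def write_anchors(anchors: list[AnchorPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANCHOR_HEADER)
        for a in anchors:
            w.writerow([a.gestational_age, a.time, a.arm, a.concentration])


def read_anchors(path: str | Path) -> list[AnchorPoint]:
    """Read an anchor CSV, reporting the line number of any malformed row."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ANCHOR_HEADER:
            raise ValidationError(
                f"{path}:1: expected header {','.join(ANCHOR_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                ga = int(row[0])
                t = float(row[1])
                arm = row[2].strip()
                conc = float(row[3])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if arm not in ARMS:
                raise ValidationError(f"{path}:{lineno}: unknown arm {arm!r}")
            out.append(AnchorPoint(ga, t, conc, arm))
    if not out:
        raise ValidationError(f"{path}: no anchor rows")
    return out


def write_parameters(result: CalibrationResult, path: str | Path) -> None:
    """Write the fitted parameter set, one row per GA group."""
    rows = []
    for ga in sorted(result.fitted):
        p = result.fitted[ga]
        rows.append(
            {
                "ga_weeks": ga,
                "emax_l_day": p.emax,
                "production_rate_mg_day": p.production_rate,
                "t50_day": p.t50,
                "hill": p.hill,
                "cl_bl_raw_l_day": p.cl_bl_raw,
                "baseline_covariate_factor": p.baseline_covariate_factor,
                "vd_per_kg_l": p.vd_per_kg,
                "ibuprofen_reduction_l_day": p.ibuprofen_reduction,
                "initial_creatinine_mg_dl": result.initial_conditions[ga],
            }
        )
    # default (shortest-repr) float formatting round-trips exactly
    pd.DataFrame(rows, columns=_PARAM_COLUMNS).to_csv(path, index=False)


def read_parameters(path: str | Path) -> tuple[dict[int, ModelParameters], dict[int, float]]:
    """Read a fitted parameter CSV back into per-GA parameters and initial
    conditions."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing parameter column(s) {missing}")
    params: dict[int, ModelParameters] = {}
    c0: dict[int, float] = {}
    for _, row in df.iterrows():
        ga = int(row["ga_weeks"])
        params[ga] = ModelParameters(
            emax=row["emax_l_day"],
            production_rate=row["production_rate_mg_day"],
            t50=row["t50_day"],
            hill=row["hill"],
            cl_bl_raw=row["cl_bl_raw_l_day"],
            baseline_covariate_factor=row["baseline_covariate_factor"],
            vd_per_kg=row["vd_per_kg_l"],
            ibuprofen_reduction=row["ibuprofen_reduction_l_day"],
        )
        c0[ga] = float(row["initial_creatinine_mg_dl"])
    return params, c0
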