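"""CSV readers/writers, result serialization and run manifests.

Timecourse CSV schema: ``time_days, y1_plasma, y2_body`` (header required,
decimal point, UTF-8); y2 may be blank on plasma-only sampling days.
Cohort CSV schema: ``subject_id, x1e_umol, fcr_per_day``, or with
``conc_umol_per_l`` / ``conc_g_per_l`` in place of the quantity column for
concentration-mode input (converted via the plasma volume v1 and, for g/l,
a molar mass).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FcrCohort
from .tracer import TracerTimecourse

__all__ = [
    "TimecourseFormatError",
    "RunManifest",
    "read_timecourse",
    "write_timecourse",
    "read_fcr_cohort",
    "write_fcr_cohort",
    "write_results",
    "IGG_MOLAR_MASS",
]

log = logging.getLogger("fcrnkinetics")

#: Default molar mass of IgG used for g/l → μmol conversion (g/mol).
IGG_MOLAR_MASS = 150_000.0


class TimecourseFormatError(ValueError):
    """Malformed timecourse file; the message carries the offending row."""


def read_timecourse(path, dose: float = 1.0) -> TracerTimecourse:
    """Read and validate a tracer timecourse CSV.

    Rows are sorted by time (with a warning if they arrived unsorted);
    duplicate times are rejected.  Retention fractions outside [0, 1.5]
    draw a warning (noise tolerance); outside [−0.1, 2] they are errors.
    A y1 > y2 row is accepted with a warning: observational noise can
    invert plasma and whole-body retention.
    """
    df = pd.read_csv(path)
    expected = ["time_days", "y1_plasma", "y2_body"]
    if list(df.columns[:3]) != expected:
        raise TimecourseFormatError(
            f"{path}: header must be {expected}, got {list(df.columns)}"
        )
    for col in expected:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise TimecourseFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 2}"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["time_days"].isna().any():
        raise TimecourseFormatError(f"{path}: missing time value")
    if not df["time_days"].is_monotonic_increasing:
        warnings.warn(f"{path}: rows were not sorted by time; sorting", stacklevel=2)
        df = df.sort_values("time_days", kind="stable").reset_index(drop=True)
    if df["time_days"].duplicated().any():
        t = df["time_days"][df["time_days"].duplicated()].iloc[0]
        raise TimecourseFormatError(f"{path}: duplicate time {t}")
    for col in ("y1_plasma", "y2_body"):
        vals = df[col].dropna()
        if ((vals < -0.1) | (vals > 2.0)).any():
            raise TimecourseFormatError(f"{path}: {col} outside the admissible range [-0.1, 2]")
        if ((vals < 0.0) | (vals > 1.5)).any():
            warnings.warn(f"{path}: {col} outside [0, 1.5]; accepted as noise", stacklevel=2)
    inverted = (df["y1_plasma"] > df["y2_body"]).fillna(False)
    if inverted.any():
        warnings.warn(
            f"{path}: y1 > y2 at {int(inverted.sum())} row(s); accepted as observational noise",
            stacklevel=2,
        )
    return TracerTimecourse(
        times=df["time_days"].to_numpy(),
        y1=df["y1_plasma"].to_numpy(),
        y2=df["y2_body"].to_numpy(),
        dose=dose,
    )


def write_timecourse(tc: TracerTimecourse, path) -> None:
    pd.DataFrame(
        {"time_days": tc.times, "y1_plasma": tc.y1, "y2_body": tc.y2}
    ).to_csv(path, index=False)


def read_fcr_cohort(
    path,
    units: str = "quantity",
    v1: float = 2.9,
    molar_mass: float = IGG_MOLAR_MASS,
) -> FcrCohort:
    """Read a per-subject FCR cohort CSV.

    ``units="quantity"`` expects ``x1e_umol``; ``units="concentration"``
    expects ``conc_umol_per_l`` (× v1 → μmol) or ``conc_g_per_l``
    (÷ molar mass in g/μmol, × v1).  Rows with nonpositive quantity or FCR
    are dropped with a log entry.
    """
    df = pd.read_csv(path)
    if units == "quantity":
        if "x1e_umol" not in df.columns:
            raise ValueError(f"{path}: quantity mode requires an x1e_umol column")
        x = df["x1e_umol"].astype(float)
    elif units == "concentration":
        if "conc_umol_per_l" in df.columns:
            x = df["conc_umol_per_l"].astype(float) * v1
        elif "conc_g_per_l" in df.columns:
            x = df["conc_g_per_l"].astype(float) / (molar_mass * 1e-6) * v1
        else:
            raise ValueError(
                f"{path}: concentration mode requires conc_umol_per_l or conc_g_per_l"
            )
    else:
        raise ValueError(f"unknown units {units!r}")
    fcr = df["fcr_per_day"].astype(float)
    keep = (x > 0) & (fcr > 0) & np.isfinite(x) & np.isfinite(fcr)
    if (~keep).any():
        log.info("dropped %d cohort row(s) with nonpositive x1E or FCR", int((~keep).sum()))
    ids = tuple(df.loc[keep, "subject_id"]) if "subject_id" in df.columns else None
    return FcrCohort(x1e=x[keep].to_numpy(), fcr=fcr[keep].to_numpy(), subject_ids=ids)


def write_fcr_cohort(cohort: FcrCohort, path) -> None:
    ids = cohort.subject_ids if cohort.subject_ids is not None else range(1, len(cohort) + 1)
    pd.DataFrame(
        {"subject_id": list(ids), "x1e_umol": cohort.x1e, "fcr_per_day": cohort.fcr}
    ).to_csv(path, index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_results(result, path, fmt: str = "json") -> None:
    """Serialize a result object losslessly (full float precision)."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonify(result), fh, indent=2, default=str)
    elif fmt == "csv":
        if isinstance(result, pd.DataFrame):
            result.to_csv(path)
        else:
            pd.DataFrame(_jsonify(result)).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _package_version() -> str:
    try:
        return version("fcrnkinetics")
    except PackageNotFoundError:
        return "unknown"


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to re-execute a CLI run bit-for-bit."""

    command: str
    configuration: dict
    master_seed: int | None
    stage_seeds: dict = field(default_factory=dict)
    package_version: str = field(default_factory=_package_version)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path) -> None:
        write_results(self, path, fmt="json")
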