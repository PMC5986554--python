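"""Readers and writers for the package's tabular formats.

CSV is the single tabular interchange format: time courses carry columns
``time_h`` (or ``time_s``), ``intensity`` and optional ``condition`` /
``replicate``; particle tables carry ``length_nm``, ``height_nm`` and
optional ``condition``.  Hours are accepted at the boundary and converted
to seconds exactly once.  Parsing is strict by default: malformed rows,
missing columns and duplicate time points raise named errors rather than
being dropped — silent data loss is never acceptable in a pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitOptions, ThTTimeCourse
from .kinetics import ValidationError
from .morphology import MorphologyRule, Particle, default_rules
from .synthetic import NoiseSpec

__all__ = [
    "RunConfig",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_particle_csv",
    "write_particle_csv",
    "read_constants_csv",
]

logger = logging.getLogger("amykin")

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults reproduce the experimental conditions
    (80 uM peptide, hours at the I/O boundary, seconds internally)."""

    a: float = 80e-6
    time_unit: str = "h"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fit_options: FitOptions = field(default_factory=FitOptions)
    rules: list[MorphologyRule] = field(default_factory=default_rules)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("concentration a must be > 0")
        if self.time_unit not in ("h", "s"):
            raise ValidationError("time_unit must be 'h' or 's'")


def _require_columns(df: pd.DataFrame, path, required: set[str]) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")


def _numeric(df: pd.DataFrame, path, cols, lenient: bool = False) -> pd.DataFrame:
    bad_rows = pd.Series(False, index=df.index)
    for col in cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            if not lenient:
                row = int(df.index[parsed.isna()][0]) + 2  # 1-based + header line
                raise ValidationError(
                    f"{path}: non-numeric or empty value in column {col!r} at line {row}"
                )
            bad_rows |= parsed.isna()
        df[col] = parsed
    if bad_rows.any():
        logger.warning(f"{path}: dropping {int(bad_rows.sum())} malformed row(s) (lenient mode)")
        df = df[~bad_rows].reset_index(drop=True)
    return df


def read_timecourse_csv(path, lenient: bool = False) -> list[ThTTimeCourse]:
    """Parse a ThT time-course CSV into one series per (condition, replicate).

    Requires a ``time_h`` or ``time_s`` column plus ``intensity``.  Times are
    converted to seconds (``time_s`` passes through untouched) and sorted
    within each series; duplicate times within a series are an error.
    Unknown extra columns are ignored with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if "time_h" in df.columns and "time_s" in df.columns:
        raise ValidationError(f"{path}: provide either time_h or time_s, not both")
    if "time_s" in df.columns:
        time_col, factor = "time_s", 1.0
    elif "time_h" in df.columns:
        time_col, factor = "time_h", SECONDS_PER_HOUR
    else:
        raise ValidationError(f"{path}: missing required column(s): time_h or time_s")
    _require_columns(df, path, {"intensity"})
    known = {time_col, "intensity", "condition", "replicate"}
    extra = set(df.columns) - known
    if extra:
        # documented laxity rule: extra columns never fail, only warn
        logger.warning(f"{path}: ignoring unknown column(s): {', '.join(sorted(extra))}")
    df = _numeric(df, path, [time_col, "intensity"], lenient=lenient)
    if "condition" not in df.columns:
        df["condition"] = ""
    if "replicate" not in df.columns:
        df["replicate"] = "mean"
    df["condition"] = df["condition"].fillna("")
    df["replicate"] = df["replicate"].fillna("mean")

    series = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values(time_col)
        times = grp[time_col].to_numpy(dtype=float) * factor
        if np.any(np.diff(times) == 0):
            t_dup = times[np.flatnonzero(np.diff(times) == 0)[0]]
            raise ValidationError(
                f"{path}: duplicate time {t_dup / factor:g} for condition={cond!r} replicate={rep!r}"
            )
        series.append(
            ThTTimeCourse(
                times=times,
                intensities=grp["intensity"].to_numpy(dtype=float),
                condition=str(cond),
                replicate=str(rep),
            )
        )
    return series


def write_timecourse_csv(path, series: list[ThTTimeCourse], time_unit: str = "h") -> None:
    """Write time courses with times in hours (default) or seconds."""
    if time_unit not in ("h", "s"):
        raise ValidationError("time_unit must be 'h' or 's'")
    factor = SECONDS_PER_HOUR if time_unit == "h" else 1.0
    frames = [
        pd.DataFrame(
            {
                f"time_{time_unit}": tc.times / factor,
                "intensity": tc.intensities,
                "condition": tc.condition,
                "replicate": tc.replicate,
            }
        )
        for tc in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_particle_csv(path) -> list[Particle]:
    """Parse an AFM particle table; row order is preserved.

    Non-positive or non-numeric measurements raise an error naming the line;
    unknown extra columns are ignored with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    _require_columns(df, path, {"length_nm", "height_nm"})
    extra = set(df.columns) - {"length_nm", "height_nm", "condition"}
    if extra:
        logger.warning(f"{path}: ignoring unknown column(s): {', '.join(sorted(extra))}")
    df = _numeric(df, path, ["length_nm", "height_nm"])
    if "condition" not in df.columns:
        df["condition"] = ""
    df["condition"] = df["condition"].fillna("")
    particles = []
    for i, row in enumerate(df.itertuples(), start=2):
        if row.length_nm <= 0 or row.height_nm <= 0:
            raise ValidationError(f"{path}: non-positive measurement at line {i}")
        particles.append(
            Particle(length=float(row.length_nm), height=float(row.height_nm), condition=str(row.condition))
        )
    return particles


def write_particle_csv(path, particles: list[Particle]) -> None:
    pd.DataFrame(
        {
            "length_nm": [p.length for p in particles],
            "height_nm": [p.height for p in particles],
            "condition": [p.condition for p in particles],
        }
    ).to_csv(path, index=False)


def read_constants_csv(path):
    """Parse a rate-constants CSV (condition, kn_per_s, ke_per_mol_s)."""
    from .comparison import ConditionConstants

    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, path, {"condition", "kn_per_s", "ke_per_mol_s"})
    df = _numeric(df, path, ["kn_per_s", "ke_per_mol_s"])
    out = []
    seen = set()
    for row in df.itertuples():
        if row.condition in seen:
            raise ValidationError(f"{path}: duplicate condition label {row.condition!r}")
        seen.add(row.condition)
        out.append(ConditionConstants(condition=str(row.condition), kn=row.kn_per_s, ke=row.ke_per_mol_s))
    return out
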