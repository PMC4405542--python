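"""Plain-text readers and writers.

Every file is delimited text with a block of ``#``-prefixed header
lines that record the producing invocation's parameterization and seed,
so any output can be regenerated from its own header.

Trajectory files come in two layouts:

* positions — columns ``animal_id, t, x, y``; step angles, lengths and
  target bearings are derived on read (a target position is required);
* angles — columns ``animal_id, t, y_angle, psi1[, psi2]`` holding
  precomputed step angles and target bearings.

Angles are radians internally; files may declare ``units: degrees`` and
are converted at the boundary.  Landscape rasters are integer grids
with a three-line header (rows, cols, pixel size).
"""

from __future__ import annotations

import io as _io
import math
from typing import Optional

import numpy as np
import pandas as pd

from .estimators import FitResult, StepSeries
from .simulate import Landscape

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_landscape",
    "write_landscape",
    "write_fit_result",
    "TrajectoryFormatError",
]

DEG2RAD = math.pi / 180.0


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def _read_delimited(path):
    meta = {}
    lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
            else:
                lines.append((lineno, line))
    if not lines:
        raise TrajectoryFormatError(f"{path}: no data rows")
    text = "".join(l for _, l in lines)
    df = pd.read_csv(_io.StringIO(text))
    first_line = lines[0][0]
    return meta, df, first_line


def read_trajectory(path, target: Optional[tuple[float, float]] = None) -> StepSeries:
    """Read a trajectory file into a :class:`StepSeries`.

    Positions layouts need ``target`` (planar x, y) to compute the
    bearing to the attractor at each step's origin; angles layouts carry
    the bearings themselves.  The first record of each animal is marked
    unusable by the StepSeries constructor.
    """
    meta, df, first_line = _read_delimited(path)
    units = meta.get("units", "radians")
    if units not in ("radians", "degrees"):
        raise TrajectoryFormatError(f"{path}: unknown units {units!r}")
    cols = set(df.columns)
    if {"animal_id", "t", "x", "y"} <= cols:
        return _series_from_positions(df, target, path)
    if {"animal_id", "t", "y_angle", "psi1"} <= cols:
        return _series_from_angles(df, units, path, first_line)
    raise TrajectoryFormatError(
        f"{path}: columns {sorted(cols)} match neither the positions layout "
        "(animal_id,t,x,y) nor the angles layout (animal_id,t,y_angle,psi1)"
    )


def _check_monotone(df, path):
    for lab, grp in df.groupby("animal_id", sort=False):
        t = grp["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
            raise TrajectoryFormatError(
                f"{path}: t not strictly increasing for animal {lab!r} near t={t[bad + 1]}"
            )


def _series_from_positions(df, target, path) -> StepSeries:
    if target is None:
        raise TrajectoryFormatError(
            f"{path}: positions layout requires a target position to derive bearings"
        )
    _check_monotone(df, path)
    parts = []
    tx, ty = float(target[0]), float(target[1])
    for lab, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("t")
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        if x.size < 2:
            continue
        dx, dy = np.diff(x), np.diff(y)
        ang = np.arctan2(dy, dx)
        psi = np.arctan2(ty - y[:-1], tx - x[:-1])
        parts.append(
            StepSeries(
                animal=np.repeat(lab, ang.size),
                t=np.arange(ang.size),
                y=ang,
                psi1=psi,
                d=np.hypot(dx, dy),
            )
        )
    if not parts:
        raise TrajectoryFormatError(f"{path}: no animal has two or more positions")
    return StepSeries.concat(parts)


def _series_from_angles(df, units, path, first_line) -> StepSeries:
    _check_monotone(df, path)
    limit = 180.0 if units == "degrees" else math.pi
    for col in ("y_angle", "psi1") + (("psi2",) if "psi2" in df.columns else ()):
        vals = df[col].to_numpy(float)
        bad = np.flatnonzero((vals < -limit) | (vals >= limit))
        if bad.size:
            raise TrajectoryFormatError(
                f"{path}: {col} out of [-{limit:g}, {limit:g}) near data line "
                f"{first_line + 1 + int(bad[0])}"
            )
    factor = DEG2RAD if units == "degrees" else 1.0
    return StepSeries(
        animal=df["animal_id"].to_numpy(),
        t=df["t"].to_numpy(int),
        y=df["y_angle"].to_numpy(float) * factor,
        psi1=df["psi1"].to_numpy(float) * factor,
        psi2=df["psi2"].to_numpy(float) * factor if "psi2" in df.columns else None,
        d=df["d"].to_numpy(float) if "d" in df.columns else None,
    )


def write_trajectory(series: StepSeries, path, units: str = "radians", meta: Optional[dict] = None):
    """Write a StepSeries in the angles layout with a reproducibility header."""
    if units not in ("radians", "degrees"):
        raise ValueError("units must be 'radians' or 'degrees'")
    df = series.to_frame()
    if units == "degrees":
        for col in ("y_angle", "psi1", "psi2"):
            if col in df.columns:
                df[col] = df[col] / DEG2RAD
    with open(path, "w") as fh:
        fh.write("# movebias trajectory\n")
        fh.write("# format: angles\n")
        fh.write(f"# units: {units}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        # 12 significant digits: unit conversion round-trips reproduce the
        # printed values exactly while staying far below data precision
        df.to_csv(fh, index=False, float_format="%.12g")


def write_landscape(landscape: Landscape, path, meta: Optional[dict] = None):
    """Integer habitat grid with a three-line rows/cols/pixel-size header."""
    with open(path, "w") as fh:
        fh.write(f"# rows: {landscape.rows}\n")
        fh.write(f"# cols: {landscape.cols}\n")
        fh.write(f"# pixel_size: {landscape.pixel_size:.17g}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        np.savetxt(fh, landscape.grid, fmt="%d")


def read_landscape(path) -> Landscape:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        grid = np.loadtxt(fh, dtype=int)
    grid = np.atleast_2d(grid)
    rows = int(meta.get("rows", grid.shape[0]))
    cols = int(meta.get("cols", grid.shape[1]))
    if grid.shape != (rows, cols):
        raise ValueError(f"{path}: grid shape {grid.shape} does not match header ({rows}, {cols})")
    return Landscape(grid=grid, pixel_size=float(meta.get("pixel_size", 1.0)))


def write_fit_result(fit: FitResult, path, meta: Optional[dict] = None):
    """Parameter table (estimate, model SE, robust SE) plus bias strengths."""
    with open(path, "w") as fh:
        fh.write(f"# movebias fit: {fit.method}\n")
        fh.write(f"# loglik: {fit.loglik:.10g}\n")
        fh.write(f"# n_obs: {fit.n_obs}\n")
        fh.write(f"# converged: {fit.converged}\n")
        fh.write(f"# at_bound: {fit.at_bound}\n")
        for name in fit.beta:
            fh.write(f"# {name}: {fit.beta[name]:.10g} (se {fit.beta_se[name]:.6g})\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fit.summary_frame().to_csv(fh, index=False, float_format="%.10g")
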