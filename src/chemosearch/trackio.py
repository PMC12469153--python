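"""Trajectory container and delimited-text track I/O.

Tracks are uniformly sampled positional time series as produced by video
tracking software (the recordings this package analyses were digitised at
5 Hz, coordinates in millimetres).  The on-disk dialect is plain delimited
text with a header row::

    time_s,x_mm,y_mm[,theta_rad][,mode]

Readers for other export dialects (different delimiters, column names, or
preamble rows) are supported through the ``read_track`` options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError, ValidationError

__all__ = ["Trajectory", "read_track", "write_track", "finite_difference_speed"]

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Uniformly sampled planar track.

    times : sample times, s, strictly increasing (nominally uniform)
    xs, ys : coordinates, mm
    heading : optional heading channel, rad
    mode : optional per-sample behavioural mode ("rest" or "run")
    sample_rate_hz : nominal sampling rate (5 Hz for the recordings)
    meta : free-form provenance metadata (seed, generator parameters, ...)
    """

    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    heading: Optional[np.ndarray] = None
    mode: Optional[np.ndarray] = None
    sample_rate_hz: float = 5.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if self.heading is not None:
            self.heading = np.asarray(self.heading, dtype=float)
        if self.mode is not None:
            self.mode = np.asarray(self.mode, dtype=object)
        n = len(self.times)
        for name in ("xs", "ys", "heading", "mode"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValidationError(
                    f"channel {name!r} has length {len(ch)}, expected {n}")
        if self.sample_rate_hz <= 0:
            raise ValidationError(
                f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            idx = int(np.argmax(dts <= 0))
            raise ValidationError(
                f"times must be strictly increasing; first violation at index {idx + 1}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def positions(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.xs, self.ys])

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_s": self.times, "x_mm": self.xs, "y_mm": self.ys}
        if self.heading is not None:
            data["theta_rad"] = self.heading
        if self.mode is not None:
            data["mode"] = self.mode
        return pd.DataFrame(data)


def read_track(path, *, delimiter: str = ",", time_col="time_s", x_col="x_mm",
               y_col="y_mm", theta_col="theta_rad", mode_col="mode",
               skip_rows: int = 0, time_unit: float = 1.0,
               sample_rate_hz: Optional[float] = None) -> Trajectory:
    """Read a delimited-text track file into a :class:`Trajectory`.

    Columns are resolved by name (or by integer index for headerless files);
    ``skip_rows`` discards preamble lines above the header, as found in some
    tracking-software exports.  ``time_unit`` converts the time column to
    seconds (e.g. 1/1000 for milliseconds).  Rows with a missing coordinate
    are dropped and counted in a log message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, skiprows=skip_rows,
                     header=None if isinstance(time_col, int) else 0)
    cols = {}
    for key, spec in (("time", time_col), ("x", x_col), ("y", y_col)):
        if isinstance(spec, int):
            if spec >= df.shape[1]:
                raise FormatError(f"{path}: no column index {spec} for {key!r}")
            cols[key] = df.columns[spec]
        else:
            if spec not in df.columns:
                raise FormatError(f"{path}: missing column {spec!r} for {key!r}")
            cols[key] = spec

    sub = df[[cols["time"], cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce")
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with missing coordinates",
                       path, n_dropped)
    sub = sub[keep]

    times = sub[cols["time"]].to_numpy(dtype=float) * time_unit
    if len(times) > 1:
        dts = np.diff(times)
        if np.any(dts <= 0):
            idx = int(np.argmax(dts <= 0)) + 1
            raise ValidationError(
                f"{path}: times not strictly increasing at row index {idx}")

    heading = None
    if not isinstance(theta_col, int) and theta_col in df.columns:
        heading = pd.to_numeric(df[theta_col], errors="coerce")[keep].to_numpy(float)
    mode = None
    if not isinstance(mode_col, int) and mode_col in df.columns:
        mode = df[mode_col][keep].to_numpy(object)

    if sample_rate_hz is None:
        if len(times) > 1:
            sample_rate_hz = 1.0 / float(np.median(np.diff(times)))
        else:
            sample_rate_hz = 5.0
    return Trajectory(times=times, xs=sub[cols["x"]].to_numpy(float),
                      ys=sub[cols["y"]].to_numpy(float), heading=heading,
                      mode=mode, sample_rate_hz=sample_rate_hz,
                      meta={"source": str(path), "rows_dropped": n_dropped})


def write_track(traj: Trajectory, path, *, delimiter: str = ",") -> None:
    """Write a track as delimited text (9 significant digits)."""
    df = traj.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False, float_format="%.9g")


def finite_difference_speed(traj: Trajectory) -> np.ndarray:
    """Per-sample speed (mm/s) by finite differences of the positions.

    Central differences at interior samples, one-sided at the two ends; exact
    for uniform straight-line motion.  Returns one value per sample.
    """
    n = len(traj)
    if n < 2:
        raise InsufficientDataError(
            f"need at least 2 samples to differentiate, got {n}")
    t, x, y = traj.times, traj.xs, traj.ys
    vx = np.empty(n)
    vy = np.empty(n)
    vx[1:-1] = (x[2:] - x[:-2]) / (t[2:] - t[:-2])
    vy[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    vx[0] = (x[1] - x[0]) / (t[1] - t[0])
    vy[0] = (y[1] - y[0]) / (t[1] - t[0])
    vx[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
    vy[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    return np.hypot(vx, vy)
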