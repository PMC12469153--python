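"""Empirical trajectory statistics for intermittent searchers.

Operations mirroring how the recorded isopod and coral-larva tracks are
analysed: rest/run bout segmentation by a speed threshold, maximum-likelihood
Gamma fits to resting times, histogram expectations under the fitted Gamma,
osculating-circle turning radii, and source-approach metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .trackio import Trajectory, finite_difference_speed

__all__ = [
    "BoutStats",
    "GammaFit",
    "TurningPoints",
    "ApproachMetrics",
    "segment_bouts",
    "fit_gamma_rests",
    "fit_gamma_moments",
    "expected_bin_counts",
    "turning_radii",
    "approach_metrics",
]

#: speed below which a tracked animal is considered at rest (mm/s)
REST_SPEED_THRESHOLD = 0.05


@dataclass
class BoutStats:
    """Rest/run bout durations (s) and per-run mean speeds (mm/s).

    ``boundary_partial`` flags whether the first/last bout touch the record
    boundary (their true duration is censored by the recording window).
    """

    rest_durations: np.ndarray
    run_durations: np.ndarray
    run_speeds: np.ndarray
    speed_threshold: float
    boundary_partial: tuple[bool, bool] = (True, True)

    @property
    def mean_rest(self) -> float:
        return float(np.mean(self.rest_durations)) if len(self.rest_durations) else math.nan

    @property
    def mean_run(self) -> float:
        return float(np.mean(self.run_durations)) if len(self.run_durations) else math.nan

    @property
    def mean_run_speed(self) -> float:
        return float(np.mean(self.run_speeds)) if len(self.run_speeds) else math.nan


@dataclass
class GammaFit:
    """Maximum-likelihood Gamma fit (no location shift) to bout durations."""

    shape_hat: float
    scale_hat: float
    log_likelihood: float
    n: int

    @property
    def mean(self) -> float:
        return self.shape_hat * self.scale_hat


@dataclass
class TurningPoints:
    """Turning points of a track and their osculating radii (mm).

    ``indices``/``radii`` are the detected turning points (local curvature
    maxima above the percentile threshold); ``sample_radii`` holds the
    osculating radius at every interior sample with finite curvature.
    """

    indices: np.ndarray
    radii: np.ndarray
    curvatures: np.ndarray
    sample_radii: np.ndarray

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii)) if len(self.radii) else math.nan


@dataclass
class ApproachMetrics:
    """Distances (mm) of a track to a fixed source point."""

    initial_distance: float
    final_distance: float
    min_distance: float
    time_within: float
    approached: bool


def segment_bouts(traj: Trajectory, speed_threshold: float = REST_SPEED_THRESHOLD,
                  drop_partial: bool = False) -> BoutStats:
    """Split a track into rest and run bouts by a speed threshold.

    A sample is *resting* when its finite-difference speed is strictly below
    ``speed_threshold`` (speeds exactly at the threshold count as running);
    maximal runs of same-state samples form bouts.  A bout of ``n`` samples
    is assigned duration ``n`` sampling intervals (a single-sample bout lasts
    one interval).  The first and last bout are censored by the recording
    window; ``drop_partial=True`` removes them.
    """
    if len(traj) < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to segment, got {len(traj)}")
    if speed_threshold <= 0:
        raise ValidationError(
            f"speed_threshold must be > 0, got {speed_threshold}")
    speeds = finite_difference_speed(traj)
    resting = speeds < speed_threshold
    interval = 1.0 / traj.sample_rate_hz

    # maximal constant-state segments
    change = np.flatnonzero(np.diff(resting.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(resting)]])

    rests, runs, run_speeds = [], [], []
    for k, (s, e) in enumerate(zip(starts, ends)):
        if drop_partial and (k == 0 or k == len(starts) - 1):
            continue
        duration = (e - s) * interval
        if resting[s]:
            rests.append(duration)
        else:
            runs.append(duration)
            run_speeds.append(float(np.mean(speeds[s:e])))
    return BoutStats(rest_durations=np.asarray(rests),
                     run_durations=np.asarray(runs),
                     run_speeds=np.asarray(run_speeds),
                     speed_threshold=speed_threshold,
                     boundary_partial=(not drop_partial, not drop_partial))


def fit_gamma_rests(rest_durations) -> GammaFit:
    """Maximum-likelihood Gamma fit to resting times (location fixed at 0)."""
    x = np.asarray(rest_durations, dtype=float)
    if len(x) < 10:
        raise InsufficientDataError(
            f"need at least 10 durations for a Gamma fit, got {len(x)}")
    if np.any(x <= 0):
        raise ValidationError("rest durations must be positive")
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    return GammaFit(shape_hat=float(shape), scale_hat=float(scale),
                    log_likelihood=ll, n=len(x))


def fit_gamma_moments(rest_durations) -> GammaFit:
    """Method-of-moments Gamma fit (closed form; cross-check for the MLE).

    shape = mean²/var, scale = var/mean.
    """
    x = np.asarray(rest_durations, dtype=float)
    if len(x) < 10:
        raise InsufficientDataError(
            f"need at least 10 durations for a Gamma fit, got {len(x)}")
    if np.any(x <= 0):
        raise ValidationError("rest durations must be positive")
    mean = float(np.mean(x))
    var = float(np.var(x))
    shape = mean * mean / var
    scale = var / mean
    ll = float(np.sum(stats.gamma.logpdf(x, shape, scale=scale)))
    return GammaFit(shape_hat=shape, scale_hat=scale, log_likelihood=ll, n=len(x))


def expected_bin_counts(fit: GammaFit, bin_edges, n: int) -> np.ndarray:
    """Expected histogram counts n·(CDF(right) − CDF(left)) per bin."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin_edges must be a 1-d increasing sequence")
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    cdf = stats.gamma.cdf(edges, fit.shape_hat, scale=fit.scale_hat)
    return n * np.diff(cdf)


def _menger_curvature(p0, p1, p2) -> float:
    """Curvature of the circle through three points: 4·Area/(abc).

    Collinear triples give curvature 0 (infinite radius).
    """
    a = math.dist(p0, p1)
    b = math.dist(p1, p2)
    c = math.dist(p0, p2)
    if a == 0.0 or b == 0.0 or c == 0.0:
        return 0.0
    cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
    return 2.0 * abs(cross) / (a * b * c)


def turning_radii(traj: Trajectory, curvature_percentile: float = 90.0) -> TurningPoints:
    """Osculating-circle radii at the turning points of a track.

    Per-sample curvature is the circumscribed-circle curvature of each
    triple of consecutive positions.  Turning points are local curvature
    maxima (plateaus included) at or above the given percentile of the
    positive curvatures; the radius at each is 1/κ.  Collinear triples
    (infinite radius) are never turning-point candidates.
    """
    n = len(traj)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")
    if not 0.0 <= curvature_percentile <= 100.0:
        raise ValidationError("curvature_percentile must be in [0, 100]")
    pts = traj.positions()
    kappa = np.array([
        _menger_curvature(pts[i - 1], pts[i], pts[i + 1]) for i in range(1, n - 1)
    ])
    positive = kappa > 0.0
    if not np.any(positive):
        empty = np.array([])
        return TurningPoints(indices=np.array([], dtype=int), radii=empty,
                             curvatures=kappa, sample_radii=empty)
    threshold = np.percentile(kappa[positive], curvature_percentile)
    # local maxima with plateau tolerance, restricted to positive curvature
    is_max = np.ones(len(kappa), dtype=bool)
    is_max[1:] &= kappa[1:] >= kappa[:-1]
    is_max[:-1] &= kappa[:-1] >= kappa[1:]
    selected = positive & is_max & (kappa >= threshold)
    idx = np.flatnonzero(selected) + 1  # back to trajectory sample indices
    return TurningPoints(indices=idx, radii=1.0 / kappa[idx - 1],
                         curvatures=kappa, sample_radii=1.0 / kappa[positive])


def approach_metrics(traj: Trajectory, source, radius: float = 3.0) -> ApproachMetrics:
    """Distance statistics of a track relative to a fixed source point.

    ``time_within`` is the recorded time spent inside the given capture
    radius (sample count × sampling interval); ``approached`` reports
    whether the track ends closer to the source than it started.
    """
    if len(traj) == 0:
        raise InsufficientDataError("empty trajectory")
    sx, sy = float(source[0]), float(source[1])
    d = np.hypot(traj.xs - sx, traj.ys - sy)
    interval = 1.0 / traj.sample_rate_hz
    return ApproachMetrics(
        initial_distance=float(d[0]),
        final_distance=float(d[-1]),
        min_distance=float(d.min()),
        time_within=float(np.count_nonzero(d <= radius) * interval),
        approached=bool(d[-1] < d[0]),
    )
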