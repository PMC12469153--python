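"""Kinematic fixture tracks with exact ground truth.

These generators build tracks *kinematically* — positions are written down
directly from the generating parameters, without running any of the vehicle
dynamics — so the analysis operations in :mod:`chemosearch.trajstats` can be
tested against ground truth that cannot share a bug with the simulators.

``make_rest_run_track`` emulates the statistical structure of an intermittent
searcher: Gamma-distributed rests alternating with straight runs at constant
speed, with Normal heading perturbations at each rest.  Run durations mirror
the energy mechanism (run = recharge/(m·v0²) makes each run proportional to
the preceding rest), via ``run_ratio`` = mean run / mean rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .behavior import MEAN_REST_S, MEAN_RUN_S, RUN_SPEED_MM_S, _ensure_rng
from .exceptions import InvalidParameterError
from .trackio import Trajectory

__all__ = [
    "Bout",
    "FixtureSpec",
    "make_rest_run_track",
    "make_geometric_track",
    "make_fixture",
]


@dataclass(frozen=True)
class Bout:
    """Ground-truth bout: kind ("rest"|"run"), start/end time (s)."""

    kind: str
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture description (kind + generating parameters)."""

    kind: str  # rest_run | line | circle | arc | noisy_circle
    params: dict = dc_field(default_factory=dict)
    sample_rate_hz: float = 5.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.sample_rate_hz <= 0:
            raise InvalidParameterError(
                f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")


def make_rest_run_track(k: float = 0.127, theta_scale: float = 16.257,
                        v0: float = RUN_SPEED_MM_S, orient_std: float = 1.0,
                        sample_rate_hz: float = 5.0, duration: float = 600.0,
                        seed=0, *, run_ratio: float = MEAN_RUN_S / MEAN_REST_S,
                        start: tuple[float, float] = (0.0, 0.0),
                        ) -> tuple[Trajectory, list[Bout]]:
    """Kinematic rest–run track with exact bout boundaries.

    Alternates runs (straight lines at speed ``v0``) with rests (stationary)
    starting with a run.  Rest durations are Gamma(k, θ); each following run
    lasts ``run_ratio`` times the *preceding* rest, mirroring the energy
    reservoir (recharge ∝ rest, depletion ∝ time at fixed speed).  The first
    run's duration is drawn like the others from an unobserved leading rest.
    Headings change by Normal(0, orient_std) at each rest.  Returns the
    uniformly sampled track and the chronological ground-truth bout list.
    """
    if k <= 0 or theta_scale <= 0:
        raise InvalidParameterError("Gamma parameters must be positive")
    if v0 < 0:
        raise InvalidParameterError(f"v0 must be >= 0, got {v0}")
    rng = _ensure_rng(seed)

    bouts: list[Bout] = []
    segments = []  # (t0, t1, x0, y0, vx, vy)
    t = 0.0
    x, y = float(start[0]), float(start[1])
    heading = float(rng.uniform(0.0, 2.0 * math.pi))
    pending_run = run_ratio * max(float(rng.gamma(k, theta_scale)), 5e-324)
    while t < duration:
        if v0 > 0.0:
            t_run = pending_run
            t1 = min(t + t_run, duration)
            vx = v0 * math.cos(heading)
            vy = v0 * math.sin(heading)
            segments.append((t, t1, x, y, vx, vy))
            bouts.append(Bout("run", t, t + t_run))
            x += vx * (t1 - t)
            y += vy * (t1 - t)
            t += t_run
            if t >= duration:
                break
        rest = max(float(rng.gamma(k, theta_scale)), 5e-324)
        segments.append((t, min(t + rest, duration), x, y, 0.0, 0.0))
        bouts.append(Bout("rest", t, t + rest))
        t += rest
        pending_run = run_ratio * rest
        heading = heading + float(rng.normal(0.0, orient_std))
        if v0 == 0.0 and t >= duration:
            break
    if v0 == 0.0 and not segments:
        segments.append((0.0, duration, x, y, 0.0, 0.0))
        bouts.append(Bout("rest", 0.0, duration))

    interval = 1.0 / sample_rate_hz
    n = int(math.floor(duration / interval)) + 1
    times = np.arange(n) * interval
    xs = np.empty(n)
    ys = np.empty(n)
    modes = np.empty(n, dtype=object)
    seg_idx = 0
    for i, ti in enumerate(times):
        while seg_idx < len(segments) - 1 and ti >= segments[seg_idx][1]:
            seg_idx += 1
        t0, _, sx, sy, vx, vy = segments[seg_idx]
        xs[i] = sx + vx * (ti - t0)
        ys[i] = sy + vy * (ti - t0)
        modes[i] = "run" if (vx or vy) else "rest"

    traj = Trajectory(times=times, xs=xs, ys=ys, mode=modes,
                      sample_rate_hz=sample_rate_hz,
                      meta={"kind": "rest_run", "seed": seed, "k": k,
                            "theta_scale": theta_scale, "v0": v0,
                            "orient_std": orient_std, "run_ratio": run_ratio})
    return traj, bouts


def make_geometric_track(kind: str, params: Optional[dict] = None,
                         noise_sd: float = 0.0, sample_rate_hz: float = 5.0,
                         duration: float = 60.0, seed=0) -> Trajectory:
    """Exactly parameterised line / circle / arc track, plus optional noise.

    kinds and parameters:

    * ``line``: ``start`` (mm), ``heading`` (rad), ``speed`` (mm/s)
    * ``circle`` / ``arc``: ``center`` (mm), ``radius`` (mm), ``omega``
      (rad/s), ``phase`` (rad); an arc is simply a circle observed for less
      than a full revolution

    ``noise_sd`` adds isotropic Gaussian positional noise (mm).
    """
    params = dict(params or {})
    rng = _ensure_rng(seed)
    if duration <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("duration and sample_rate_hz must be > 0")
    interval = 1.0 / sample_rate_hz
    n = int(math.floor(duration / interval)) + 1
    times = np.arange(n) * interval

    if kind == "line":
        x0, y0 = params.get("start", (0.0, 0.0))
        heading = params.get("heading", 0.0)
        speed = params.get("speed", RUN_SPEED_MM_S)
        xs = x0 + speed * math.cos(heading) * times
        ys = y0 + speed * math.sin(heading) * times
    elif kind in ("circle", "arc", "noisy_circle"):
        cx, cy = params.get("center", (0.0, 0.0))
        radius = params.get("radius", 1.8)
        omega = params.get("omega", 1.0)
        phase = params.get("phase", 0.0)
        if radius <= 0:
            raise InvalidParameterError(f"radius must be > 0, got {radius}")
        ang = phase + omega * times
        xs = cx + radius * np.cos(ang)
        ys = cy + radius * np.sin(ang)
    else:
        raise InvalidParameterError(
            f"unknown geometric kind {kind!r}; use line|circle|arc")

    if noise_sd > 0.0:
        xs = xs + rng.normal(0.0, noise_sd, size=n)
        ys = ys + rng.normal(0.0, noise_sd, size=n)

    return Trajectory(times=times, xs=xs, ys=ys, sample_rate_hz=sample_rate_hz,
                      meta={"kind": kind, "seed": seed, "noise_sd": noise_sd,
                            **{k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in params.items()}})


def make_fixture(spec: FixtureSpec) -> tuple[Trajectory, dict]:
    """Build the track for a :class:`FixtureSpec` plus a ground-truth record.

    The ground-truth mapping is JSON-serialisable and round-trips the full
    generating parameter set (and, for rest-run fixtures, the exact bout
    boundaries).
    """
    if spec.kind == "rest_run":
        traj, bouts = make_rest_run_track(
            sample_rate_hz=spec.sample_rate_hz, duration=spec.duration,
            seed=spec.seed, **spec.params)
        truth = {
            "kind": spec.kind,
            "seed": spec.seed,
            "params": dict(spec.params),
            "bouts": [
                {"kind": b.kind, "t_start": b.t_start, "t_end": b.t_end}
                for b in bouts
            ],
        }
    else:
        traj = make_geometric_track(
            spec.kind, spec.params.get("params"),
            noise_sd=spec.params.get("noise_sd", 0.0),
            sample_rate_hz=spec.sample_rate_hz, duration=spec.duration,
            seed=spec.seed)
        truth = {"kind": spec.kind, "seed": spec.seed, "params": dict(spec.params)}
    json.dumps(truth)  # invariant: ground truth is JSON-serialisable
    return traj, truth
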