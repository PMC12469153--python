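"""Stochastic behavioural layer: rest–run switching, vigilance SDE, pursuit.

Three scenario runners sit on top of the deterministic vehicle dynamics:

``simulate_rest_run``
    An energy-gated intermittent searcher (gnathiid-like).  The agent moves
    as the deterministic gradient-search vehicle while an energy reservoir
    ``E`` is depleted at rate ``m·speed²``.  When ``E`` falls below
    ``E_min`` the agent halts, draws a resting time ``T_R`` from a Gamma
    distribution, recharges to ``E = T_R`` (recharge rate 1), and resumes in
    a new heading drawn from a Normal centred on the previous one.

``simulate_vigilance``
    A continuously moving searcher (coral-larva-like) integrated with the
    Euler–Maruyama scheme.  Position and heading carry Wiener noise
    (``σ1, σ2, σ3``); the heading's gradient coupling is scaled by a
    vigilance variable ``r ∈ [0, 1]`` that decays as ``dr = −α·r·dt`` and is
    renewed to 1 at the epochs of a rate-``β`` Poisson process.  An optional
    second signal adds a vigilance-independent steering term.

``simulate_pursuit``
    Either agent released against a source translating at constant speed
    ``v1``; the chase succeeds when the agent enters the capture circle
    around the moving source.

All randomness flows from one seeded ``numpy`` generator per simulation,
split into per-component substreams (rest times, reorientations, Wiener
increments, renewal epochs) so that toggling one stochastic component leaves
the draw sequence of the others unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import (GRAD_EPS, ResponseParams, SteeringParams, VehicleState,
                       response_F_prime, response_G, wrap_angle)
from .exceptions import InvalidParameterError
from .landscapes import SignalField, translate_field
from .trackio import Trajectory

__all__ = [
    "RestModel",
    "EnergyParams",
    "NoiseParams",
    "PursuitConfig",
    "RestRunResult",
    "VigilanceResult",
    "PursuitResult",
    "calibrate_depletion",
    "energy_derivative",
    "draw_rest_time",
    "apply_rest",
    "simulate_rest_run",
    "em_step",
    "simulate_vigilance",
    "simulate_pursuit",
]

#: observed mean resting / running bout durations (s) and running speed (mm/s)
#: of the isopod recordings that anchor the default parameter values
MEAN_REST_S = 2.06
MEAN_RUN_S = 3.81
RUN_SPEED_MM_S = 3.04

TWO_PI = 2.0 * math.pi


def _ensure_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class RestModel:
    """Resting-time model: Gamma-distributed rests, Normal reorientation.

    gamma_shape : shape k of the resting-time Gamma distribution
    gamma_scale : scale θ (s); mean rest = k·θ
    orient_std : s.d. (rad) of the new heading around the pre-rest heading
    recharge_rate : energy gained per second of rest (1 in model units, so a
        rest of duration T_R recharges the reservoir to exactly T_R)
    """

    gamma_shape: float = 0.127
    gamma_scale: float = 16.257
    orient_std: float = 1.0
    recharge_rate: float = 1.0

    def __post_init__(self):
        for name in ("gamma_shape", "gamma_scale", "orient_std", "recharge_rate"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def mean_rest(self) -> float:
        return self.gamma_shape * self.gamma_scale


def calibrate_depletion(mean_rest: float = MEAN_REST_S,
                        mean_run: float = MEAN_RUN_S,
                        v0: float = RUN_SPEED_MM_S) -> float:
    """Depletion constant m making flat-field run bouts last ``mean_run``.

    In a flat landscape the agent runs at speed v0, so a reservoir recharged
    to E = T_R empties after T_R/(m·v0²) seconds; matching the mean run to
    ``mean_run`` given E[T_R] = ``mean_rest`` yields
    m = mean_rest/(mean_run·v0²).
    """
    if min(mean_rest, mean_run, v0) <= 0:
        raise InvalidParameterError("bout means and v0 must be positive")
    return mean_rest / (mean_run * v0 * v0)


@dataclass(frozen=True)
class EnergyParams:
    """Energy-reservoir constants.

    m : depletion constant (energy·s/mm²); dE/dt = −m·speed² while moving.
        Default calibrated from the observed bout means and running speed.
    E_min : threshold below which the agent stops to rest.
    E_init : initial reservoir; None draws one Gamma resting time, so the
        agent starts statistically as if it had just rested.
    """

    m: float = calibrate_depletion()
    E_min: float = 0.0
    E_init: Optional[float] = None

    def __post_init__(self):
        if self.m <= 0:
            raise InvalidParameterError(f"m must be > 0, got {self.m}")
        if self.E_min < 0:
            raise InvalidParameterError(f"E_min must be >= 0, got {self.E_min}")
        if self.E_init is not None and self.E_init < 0:
            raise InvalidParameterError(f"E_init must be >= 0, got {self.E_init}")


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic-term constants of the vigilance SDE.

    sigma1, sigma2 : position noise intensities (mm/√s)
    sigma3 : heading noise intensity (rad/√s)
    alpha : vigilance decay rate (1/s)
    beta : renewal rate (1/s) of the vigilance-resetting Poisson process
    """

    sigma1: float = 0.0
    sigma2: float = 0.0
    sigma3: float = 0.0
    alpha: float = 0.5
    beta: float = 1.0

    def __post_init__(self):
        for name in ("sigma1", "sigma2", "sigma3", "alpha"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)}")
        if self.beta <= 0:
            raise InvalidParameterError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class PursuitConfig:
    """Moving-source chase scenario.

    v1 : source speed along +x (mm/s)
    x0 : initial x of the source centre (mm)
    source_line_y : the horizontal line the source travels on (mm)
    start : initial agent position (mm); the agent starts below the line
    capture_radius : distance at which the chase ends successfully (mm)
    t_max : time budget of the chase (s)
    agent : "rest_run" (energy-gated searcher) or "vigilance" (SDE searcher)
    """

    v1: float
    x0: float = -40.0
    source_line_y: float = 20.0
    start: tuple[float, float] = (0.0, 0.0)
    capture_radius: float = 3.0
    t_max: float = 300.0
    agent: str = "vigilance"

    def __post_init__(self):
        if self.capture_radius <= 0:
            raise InvalidParameterError(
                f"capture_radius must be > 0, got {self.capture_radius}")
        if self.t_max <= 0:
            raise InvalidParameterError(f"t_max must be > 0, got {self.t_max}")
        if self.agent not in ("rest_run", "vigilance"):
            raise InvalidParameterError(
                f"agent must be rest_run|vigilance, got {self.agent!r}")

    def source_position(self, t: float) -> tuple[float, float]:
        return self.x0 + self.v1 * t, self.source_line_y


@dataclass
class RestRunResult:
    """Outcome of a rest–run simulation: the recorded track plus the exact
    bout log (rest and completed-run durations in chronological order)."""

    trajectory: Trajectory
    rest_durations: np.ndarray
    run_durations: np.ndarray
    final_state: VehicleState

    @property
    def n_cycles(self) -> int:
        return len(self.run_durations)


@dataclass
class VigilanceResult:
    """Outcome of a vigilance-SDE simulation."""

    trajectory: Trajectory
    vigilance: np.ndarray
    renewal_times: np.ndarray
    final_state: VehicleState


@dataclass
class PursuitResult:
    """Outcome of a moving-source chase."""

    success: bool
    capture_time: Optional[float]
    min_distance: float
    trajectory: Trajectory


# -- elementary operations ---------------------------------------------------

def energy_derivative(speed: float, ep: EnergyParams) -> float:
    """dE/dt = −m·speed² while moving (zero when stationary)."""
    if speed < 0:
        raise InvalidParameterError(f"speed must be >= 0, got {speed}")
    return -ep.m * speed * speed


def draw_rest_time(rm: RestModel, rng) -> float:
    """One Gamma(shape k, scale θ) resting time (s); always positive."""
    rng = _ensure_rng(rng)
    t = float(rng.gamma(rm.gamma_shape, rm.gamma_scale))
    # guard against underflow to exactly 0 for very small shape parameters
    return t if t > 0.0 else 5e-324


def apply_rest(state: VehicleState, t: float, rm: RestModel,
               rng) -> tuple[VehicleState, float]:
    """Advance through one resting bout.

    Draws T_R, jumps the clock to ``t + T_R``, recharges ``E`` to
    ``recharge_rate·T_R``, and redraws the heading from
    Normal(previous θ, orient_std), wrapped to [0, 2π).  The position is
    unchanged.  Returns the new state and new time.
    """
    rng = _ensure_rng(rng)
    t_rest = draw_rest_time(rm, rng)
    new = state.copy()
    new.E = rm.recharge_rate * t_rest
    new.theta = wrap_angle(float(rng.normal(state.theta, rm.orient_std)))
    return new, t + t_rest


# -- rest-run simulation -----------------------------------------------------

def _reflect(x, y, theta, arena):
    """Reflect position and heading off the walls of a rectangular arena."""
    xmin, xmax, ymin, ymax = arena
    if x < xmin:
        x = 2.0 * xmin - x
        theta = math.pi - theta
    elif x > xmax:
        x = 2.0 * xmax - x
        theta = math.pi - theta
    if y < ymin:
        y = 2.0 * ymin - y
        theta = -theta
    elif y > ymax:
        y = 2.0 * ymax - y
        theta = -theta
    return x, y, wrap_angle(theta)


def _rest_capture(x, y, t0, t1, source: PursuitConfig):
    """Earliest time in [t0, t1] at which the moving source comes within the
    capture radius of a resting agent at (x, y), or None.

    The squared distance is quadratic in time, so the first crossing is found
    in closed form.
    """
    sy = source.source_line_y
    v1 = source.v1
    R = source.capture_radius
    dy2 = (y - sy) ** 2
    rel0 = x - source.x0 - v1 * t0
    if v1 == 0.0:
        d2 = rel0 * rel0 + dy2
        return (t0 if d2 <= R * R else None), math.sqrt(d2)
    # minimum of the quadratic over [t0, t1]
    t_star = t0 + rel0 / v1
    t_star = min(max(t_star, t0), t1)
    rel_star = x - source.x0 - v1 * t_star
    d2_min = rel_star * rel_star + dy2
    min_dist = math.sqrt(d2_min)
    if d2_min > R * R:
        return None, min_dist
    q = R * R - dy2  # >= 0 here
    root = math.sqrt(q)
    # |x - x0 - v1 t| = root at t = (x - x0 ∓ root)/v1; earliest admissible
    candidates = sorted(((x - source.x0 - root) / v1,
                         (x - source.x0 + root) / v1))
    for tc in candidates:
        if t0 - 1e-12 <= tc <= t1 + 1e-12:
            return max(tc, t0), min_dist
    return t0, min_dist  # already inside the circle at t0


def simulate_rest_run(field_: SignalField, rp: ResponseParams,
                      sp: SteeringParams, ep: EnergyParams, rm: RestModel,
                      t_max: Optional[float], dt: float = 0.01, rng=None, *,
                      record_hz: float = 5.0, state0: Optional[VehicleState] = None,
                      max_cycles: Optional[int] = None,
                      arena: Optional[tuple] = None,
                      _capture: Optional[PursuitConfig] = None) -> RestRunResult:
    """Simulate the energy-gated rest–run searcher.

    Run phases integrate the gradient-search vehicle with fixed-step RK4 at
    step ``dt`` while the reservoir drains by ``m·speed²·dt`` per step; once
    ``E < E_min`` the agent rests (Gamma time, instantaneous clock jump,
    recharge, Normal reorientation).  The track is recorded at ``record_hz``
    (rest phases emit stationary samples at the same cadence, emulating a
    video recording).  Stops at ``t_max``, after ``max_cycles`` completed run
    bouts, or on capture when a pursuit config is attached.

    Bit-reproducible for a fixed integer seed.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if t_max is None:
        if max_cycles is None:
            raise InvalidParameterError("need t_max or max_cycles")
        t_max = math.inf
    elif t_max <= dt:
        raise InvalidParameterError("need dt < t_max")
    if record_hz <= 0:
        raise InvalidParameterError(f"record_hz must be > 0, got {record_hz}")

    rng = _ensure_rng(rng)
    rest_rng, orient_rng = rng.spawn(2)

    st0 = state0 if state0 is not None else VehicleState()
    x, y, theta = st0.x, st0.y, st0.theta
    E = ep.E_init if ep.E_init is not None else \
        rm.recharge_rate * draw_rest_time(rm, rest_rng)
    E_min = ep.E_min
    m = ep.m
    v0 = sp.v0

    rec_dt = 1.0 / record_hz
    times = [0.0]
    xs = [x]
    ys = [y]
    headings = [theta]
    modes = ["run"]
    next_rec = rec_dt

    rest_durations: list[float] = []
    run_durations: list[float] = []

    t = 0.0
    success = False
    capture_time = None
    min_dist = math.inf
    if _capture is not None:
        sx, sy_ = _capture.source_position(0.0)
        min_dist = math.hypot(x - sx, y - sy_)
        if min_dist <= _capture.capture_radius:
            success, capture_time = True, 0.0

    vg = field_.value_and_gradient
    cos, sin = math.cos, math.sin

    def _rhs(px, py, pth, pt):
        S, gx, gy = vg(px, py, pt)
        speed = v0 + response_G(gx * gx + gy * gy, rp)
        if gx * gx + gy * gy < GRAD_EPS * GRAD_EPS:
            dth = 0.0
        else:
            fp = response_F_prime(S, rp)
            if sp.coupling == "parallel":
                dth = -sp.d * (fp * gx * cos(pth) + fp * gy * sin(pth))
            else:
                sign = -1.0 if sp.connection == "ipsilateral" else 1.0
                dth = sign * sp.d * (-fp * gx * sin(pth) + fp * gy * cos(pth))
        return speed * cos(pth), speed * sin(pth), dth, speed

    while t < t_max and not success:
        if max_cycles is not None and len(run_durations) >= max_cycles:
            break
        # ---- run phase ----
        run_steps = 0
        while E >= E_min and t < t_max:
            k1 = _rhs(x, y, theta, t)
            h2 = 0.5 * dt
            k2 = _rhs(x + h2 * k1[0], y + h2 * k1[1], theta + h2 * k1[2], t + h2)
            k3 = _rhs(x + h2 * k2[0], y + h2 * k2[1], theta + h2 * k2[2], t + h2)
            k4 = _rhs(x + dt * k3[0], y + dt * k3[1], theta + dt * k3[2], t + dt)
            x += dt / 6.0 * (k1[0] + 2.0 * (k2[0] + k3[0]) + k4[0])
            y += dt / 6.0 * (k1[1] + 2.0 * (k2[1] + k3[1]) + k4[1])
            theta = wrap_angle(theta + dt / 6.0 * (k1[2] + 2.0 * (k2[2] + k3[2]) + k4[2]))
            if arena is not None:
                x, y, theta = _reflect(x, y, theta, arena)
            E += dt * (-m * k1[3] * k1[3])  # explicit Euler on the reservoir
            t += dt
            run_steps += 1
            if _capture is not None:
                sx, sy_ = _capture.source_position(t)
                dist = math.hypot(x - sx, y - sy_)
                if dist < min_dist:
                    min_dist = dist
                if dist <= _capture.capture_radius:
                    success, capture_time = True, t
                    break
            if t >= next_rec - 1e-12:
                times.append(t)
                xs.append(x)
                ys.append(y)
                headings.append(theta)
                modes.append("run")
                while next_rec <= t + 1e-12:
                    next_rec += rec_dt
        if run_steps and E < E_min:
            # a completed run bout (ended by energy exhaustion, not by t_max)
            run_durations.append(run_steps * dt)
        if success or t >= t_max:
            break
        # ---- rest phase ----
        t_rest = draw_rest_time(rm, rest_rng)
        t_end = t + t_rest
        truncated = t_end > t_max
        if truncated:
            t_end = t_max
        if _capture is not None:
            tc, dmin = _rest_capture(x, y, t, t_end, _capture)
            if dmin < min_dist:
                min_dist = dmin
            if tc is not None:
                success, capture_time = True, tc
                t_end = tc
        while next_rec <= t_end + 1e-12:
            times.append(next_rec)
            xs.append(x)
            ys.append(y)
            headings.append(theta)
            modes.append("rest")
            next_rec += rec_dt
        t = t_end
        if not truncated and not success:
            rest_durations.append(t_rest)
            E = rm.recharge_rate * t_rest
            theta = wrap_angle(float(orient_rng.normal(theta, rm.orient_std)))

    if times[-1] < t - 1e-12:
        times.append(t)
        xs.append(x)
        ys.append(y)
        headings.append(theta)
        modes.append("rest" if E < E_min else "run")

    traj = Trajectory(times=times, xs=xs, ys=ys, heading=headings, mode=modes,
                      sample_rate_hz=record_hz,
                      meta={"model": "rest_run", "dt": dt})
    final = VehicleState(x=x, y=y, theta=theta, E=max(E, 0.0))
    result = RestRunResult(trajectory=traj,
                           rest_durations=np.asarray(rest_durations),
                           run_durations=np.asarray(run_durations),
                           final_state=final)
    if _capture is not None:
        result._pursuit = PursuitResult(success=success, capture_time=capture_time,
                                        min_distance=min_dist, trajectory=traj)
    return result


# -- Euler-Maruyama vigilance model ------------------------------------------

def _em_drift(x: float, y: float, theta: float, r: float,
              fieldS: SignalField, fieldR: Optional[SignalField],
              rp: ResponseParams, sp: SteeringParams,
              t: float) -> tuple[float, float, float]:
    """Deterministic drift (dx/dt, dy/dt, dθ/dt) of the vigilance SDE."""
    S, gx, gy = fieldS.value_and_gradient(x, y, t)
    speed = sp.v0 + response_G(gx * gx + gy * gy, rp)
    vx = vy = 0.0
    if gx * gx + gy * gy >= GRAD_EPS * GRAD_EPS:
        fp = response_F_prime(S, rp)
        vx = r * fp * gx
        vy = r * fp * gy
    if fieldR is not None:
        R, hx, hy = fieldR.value_and_gradient(x, y, t)
        if hx * hx + hy * hy >= GRAD_EPS * GRAD_EPS:
            fpR = response_F_prime(R, rp)
            vx += fpR * hx
            vy += fpR * hy
    ct = math.cos(theta)
    st = math.sin(theta)
    if vx == 0.0 and vy == 0.0:
        dth = 0.0
    elif sp.coupling == "parallel":
        dth = -sp.d * (vx * ct + vy * st)
    else:
        sign = -1.0 if sp.connection == "ipsilateral" else 1.0
        dth = sign * sp.d * (-vx * st + vy * ct)
    return speed * ct, speed * st, dth


def em_step(state: VehicleState, fieldS: SignalField, rp: ResponseParams,
            sp: SteeringParams, noise: NoiseParams, dt: float, rng, *,
            fieldR: Optional[SignalField] = None, t: float = 0.0,
            dW: Optional[tuple[float, float, float]] = None) -> VehicleState:
    """One Euler–Maruyama step of the vigilance SDE.

    Drift is evaluated at the pre-step state; each Wiener increment is
    Normal(0, dt) (drawn from ``rng`` unless ``dW`` is supplied).  With all
    σ = 0 this is exactly one explicit-Euler step of the deterministic
    system.  Vigilance decays as r ← r − α·r·dt; renewals are handled by the
    scenario runner, not here.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if dW is None:
        rng = _ensure_rng(rng)
        sqdt = math.sqrt(dt)
        dW = (float(rng.normal(0.0, sqdt)), float(rng.normal(0.0, sqdt)),
              float(rng.normal(0.0, sqdt)))
    fx, fy, fth = _em_drift(state.x, state.y, state.theta, state.r,
                            fieldS, fieldR, rp, sp, t)
    new = state.copy()
    new.x = state.x + fx * dt + noise.sigma1 * dW[0]
    new.y = state.y + fy * dt + noise.sigma2 * dW[1]
    new.theta = wrap_angle(state.theta + fth * dt + noise.sigma3 * dW[2])
    new.r = state.r - noise.alpha * state.r * dt
    return new


def _renewal_epochs(beta: float, t_max: float, rng: np.random.Generator) -> np.ndarray:
    """Epochs of a rate-beta Poisson process on (0, t_max]."""
    epochs = []
    t = 0.0
    while True:
        t += float(rng.exponential(1.0 / beta))
        if t > t_max:
            break
        epochs.append(t)
    return np.asarray(epochs)


def simulate_vigilance(fieldS: SignalField, rp: ResponseParams,
                       sp: SteeringParams, noise: NoiseParams, t_max: float,
                       dt: float = 0.01, rng=None, *,
                       fieldR: Optional[SignalField] = None,
                       state0: Optional[VehicleState] = None,
                       record_every: int = 1,
                       arena: Optional[tuple] = None,
                       _capture: Optional[PursuitConfig] = None):
    """Euler–Maruyama integration of the vigilance searcher.

    Vigilance is renewed to 1 at rate-``β`` Poisson epochs (a renewal falling
    inside a step is applied at the end of that step).  Returns a
    :class:`VigilanceResult`; the vigilance series is recorded alongside the
    track.  Bit-reproducible for a fixed integer seed.
    """
    if t_max <= 0 or dt <= 0 or dt >= t_max:
        raise InvalidParameterError("need 0 < dt < t_max")
    rng = _ensure_rng(rng)
    wiener_rng, renewal_rng = rng.spawn(2)

    st0 = state0 if state0 is not None else VehicleState()
    x, y, theta, r = st0.x, st0.y, st0.theta, st0.r

    n_steps = int(round(t_max / dt))
    sqdt = math.sqrt(dt)
    epochs = _renewal_epochs(noise.beta, t_max, renewal_rng)
    next_epoch = 0  # index into epochs

    times = [0.0]
    xs = [x]
    ys = [y]
    headings = [theta]
    rs = [r]

    success = False
    capture_time = None
    min_dist = math.inf
    if _capture is not None:
        sx, sy_ = _capture.source_position(0.0)
        min_dist = math.hypot(x - sx, y - sy_)
        if min_dist <= _capture.capture_radius:
            success, capture_time = True, 0.0

    s1, s2, s3, alpha = noise.sigma1, noise.sigma2, noise.sigma3, noise.alpha
    chunk = 65536
    i = 0
    while i < n_steps and not success:
        n = min(chunk, n_steps - i)
        dW = wiener_rng.normal(0.0, sqdt, size=(n, 3))
        for j in range(n):
            t = (i + j) * dt
            fx, fy, fth = _em_drift(x, y, theta, r, fieldS, fieldR, rp, sp, t)
            w = dW[j]
            x += fx * dt + s1 * w[0]
            y += fy * dt + s2 * w[1]
            theta = wrap_angle(theta + fth * dt + s3 * w[2])
            r -= alpha * r * dt
            t += dt
            while next_epoch < len(epochs) and epochs[next_epoch] <= t:
                r = 1.0
                next_epoch += 1
            if arena is not None:
                x, y, theta = _reflect(x, y, theta, arena)
            if _capture is not None:
                sx, sy_ = _capture.source_position(t)
                dist = math.hypot(x - sx, y - sy_)
                if dist < min_dist:
                    min_dist = dist
                if dist <= _capture.capture_radius:
                    success, capture_time = True, t
            step = i + j + 1
            if step % record_every == 0 or step == n_steps or success:
                times.append(t)
                xs.append(x)
                ys.append(y)
                headings.append(theta)
                rs.append(r)
            if success:
                break
        i += n

    traj = Trajectory(times=times, xs=xs, ys=ys, heading=headings,
                      sample_rate_hz=1.0 / (dt * record_every),
                      meta={"model": "vigilance", "dt": dt})
    final = VehicleState(x=x, y=y, theta=theta, r=max(min(r, 1.0), 0.0))
    result = VigilanceResult(trajectory=traj, vigilance=np.asarray(rs),
                             renewal_times=epochs, final_state=final)
    if _capture is not None:
        result._pursuit = PursuitResult(success=success, capture_time=capture_time,
                                        min_distance=min_dist, trajectory=traj)
    return result


# -- pursuit -----------------------------------------------------------------

def simulate_pursuit(base_field: SignalField, pc: PursuitConfig,
                     rp: ResponseParams, sp: SteeringParams,
                     ep: Optional[EnergyParams] = None,
                     rm: Optional[RestModel] = None,
                     noise: Optional[NoiseParams] = None,
                     dt: float = 0.01, rng=None, *,
                     record_hz: float = 5.0,
                     theta0: Optional[float] = None) -> PursuitResult:
    """Chase a source translating along the line ``y = source_line_y``.

    The static ``base_field`` (centred at the origin) is translated so its
    centre travels from ``(x0, source_line_y)`` rightward at ``v1``.  The
    agent starts at ``pc.start`` with a uniformly random initial heading
    (unless ``theta0`` is given) and runs either the rest–run or the
    vigilance model against the moving landscape.  Success means entering
    the capture circle before ``t_max``.
    """
    rng = _ensure_rng(rng)
    moving = translate_field(base_field, pc.v1, x0=pc.x0, y0=pc.source_line_y)
    if theta0 is None:
        theta0 = float(rng.uniform(0.0, TWO_PI))
    state0 = VehicleState(x=pc.start[0], y=pc.start[1], theta=theta0)

    if pc.agent == "rest_run":
        ep = ep if ep is not None else EnergyParams()
        rm = rm if rm is not None else RestModel()
        res = simulate_rest_run(moving, rp, sp, ep, rm, pc.t_max, dt, rng,
                                record_hz=record_hz, state0=state0, _capture=pc)
    else:
        noise = noise if noise is not None else NoiseParams()
        res = simulate_vigilance(moving, rp, sp, noise, pc.t_max, dt, rng,
                                 state0=state0,
                                 record_every=max(1, int(round(1.0 / (record_hz * dt)))),
                                 _capture=pc)
    return res._pursuit
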