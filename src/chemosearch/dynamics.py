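"""Deterministic Braitenberg-vehicle dynamics.

Two closely related planar models of a chemosensing agent with position
``(x, y)`` (mm) and heading ``θ`` (rad, measured against the positive x-axis):

* the *classic* vehicle, whose forward speed is a decreasing response
  ``F(S) = a1·arctan((b − S)/c1)`` of the local signal level (a type-3a
  vehicle: it halts on the level set ``S = b``), and
* the *gradient-search* vehicle, whose speed ``v0 + G(‖∇S‖²)`` with
  ``G(s) = a2·arctan(s/c2)`` rises with the squared gradient magnitude, so the
  agent accelerates where the signal changes and coasts at the background
  speed ``v0`` in featureless regions.

In both cases the heading relaxes toward the uphill direction at a rate set by
the turn gain ``d`` through the perpendicular projection of ``∇F(S)``,
expanded by the chain rule as ``F'(S)·∇S``.  A heading-parallel coupling
variant is selectable (``SteeringParams(coupling="parallel")``); it steers the
agent along level sets rather than up the gradient and is kept for model
comparison.  A dual-signal steering term adds a second, vigilance-independent
signal ``R`` (e.g. a short-range visual or hydromechanical cue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import InvalidParameterError
from .landscapes import SignalField

__all__ = [
    "ResponseParams",
    "SteeringParams",
    "VehicleState",
    "response_F",
    "response_F_prime",
    "response_G",
    "rano_rhs",
    "gradient_rhs",
    "dual_signal_heading",
    "simulate_deterministic",
    "wrap_angle",
]

TWO_PI = 2.0 * math.pi

#: below this gradient norm the signal is treated as exactly flat, so sensor
#: noise at the resolution limit cannot be amplified into spurious turning
GRAD_EPS = 1e-12


def wrap_angle(theta: float) -> float:
    """Wrap an angle into [0, 2π)."""
    theta = math.fmod(theta, TWO_PI)
    if theta < 0.0:
        theta += TWO_PI
    # a tiny negative angle can round up to exactly 2*pi
    return 0.0 if theta >= TWO_PI else theta


@dataclass(frozen=True)
class ResponseParams:
    """Constants of the speed response functions F and G.

    a1 : speed scale of F (mm/s); sets the speed far below the target level.
    b : target signal level; F crosses zero exactly at S = b.
    c1 : width of the velocity transition region of F (signal units).
    a2 : speed scale of G (mm/s).
    c2 : transition width of G ((signal units/mm)²).
    """

    a1: float = 1.0
    b: float = 1.0
    c1: float = 2.0
    a2: float = 1.0
    c2: float = 2.0

    def __post_init__(self):
        for name in ("a1", "c1", "a2", "c2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class SteeringParams:
    """Heading-dynamics constants.

    d : turn-rate gain; how fast the heading responds to the signal gradient.
    connection : "ipsilateral" (sensors drive same-side wheels; attractive for
        a decreasing F) or "contralateral" (opposite sign).
    v0 : background speed (mm/s) of the gradient-search vehicle.
    coupling : "perpendicular" projects ∇F on the left-normal of the heading
        (the classic-vehicle steering; turns the agent uphill); "parallel"
        projects on the heading itself.
    """

    d: float = 5.0
    connection: str = "ipsilateral"
    v0: float = 0.0
    coupling: str = "perpendicular"

    def __post_init__(self):
        if self.d < 0:
            raise InvalidParameterError(f"d must be >= 0, got {self.d}")
        if self.v0 < 0:
            raise InvalidParameterError(f"v0 must be >= 0, got {self.v0}")
        if self.connection not in ("ipsilateral", "contralateral"):
            raise InvalidParameterError(
                f"connection must be ipsilateral|contralateral, got {self.connection!r}")
        if self.coupling not in ("perpendicular", "parallel"):
            raise InvalidParameterError(
                f"coupling must be perpendicular|parallel, got {self.coupling!r}")


@dataclass
class VehicleState:
    """Agent state: position (mm), heading (rad in [0, 2π)), energy, vigilance."""

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    E: float = 0.0
    r: float = 1.0

    def __post_init__(self):
        self.theta = wrap_angle(self.theta)
        if not 0.0 <= self.r <= 1.0:
            raise InvalidParameterError(f"vigilance r must be in [0,1], got {self.r}")
        if self.E < 0.0:
            raise InvalidParameterError(f"energy E must be >= 0, got {self.E}")

    def copy(self) -> "VehicleState":
        return replace(self)


# -- response functions ------------------------------------------------------

def response_F(S: float, p: ResponseParams) -> float:
    """Speed response of the classic (type-3a) vehicle: a1·arctan((b−S)/c1).

    Strictly decreasing in S, zero exactly at the target level S = b, negative
    above it (the vehicle backs away from over-strong signal).
    """
    return p.a1 * math.atan((p.b - S) / p.c1)


def response_F_prime(S: float, p: ResponseParams) -> float:
    """dF/dS = −a1 / (c1·(1 + ((b−S)/c1)²)); always negative."""
    u = (p.b - S) / p.c1
    return -p.a1 / (p.c1 * (1.0 + u * u))


def response_G(grad_norm_sq: float, p: ResponseParams) -> float:
    """Gradient speed response a2·arctan(s/c2), s = ‖∇S‖²; G(0) = 0."""
    if grad_norm_sq < 0:
        raise InvalidParameterError(
            f"grad_norm_sq must be >= 0, got {grad_norm_sq}")
    return p.a2 * math.atan(grad_norm_sq / p.c2)


# -- steering kernels --------------------------------------------------------

def _steer(gx: float, gy: float, S: float, theta: float,
           rp: ResponseParams, sp: SteeringParams) -> float:
    """dθ/dt from a signal gradient, via ∇F(S) = F'(S)·∇S.

    Perpendicular coupling: dθ/dt = ∓d·(−∂F/∂x·sinθ + ∂F/∂y·cosθ)
    ("−" for ipsilateral).  Parallel coupling: dθ/dt = −d·(∇F·[cosθ, sinθ]).
    """
    if gx * gx + gy * gy < GRAD_EPS * GRAD_EPS:
        return 0.0
    fp = response_F_prime(S, rp)
    fx = fp * gx
    fy = fp * gy
    if sp.coupling == "parallel":
        proj = fx * math.cos(theta) + fy * math.sin(theta)
        return -sp.d * proj
    proj = -fx * math.sin(theta) + fy * math.cos(theta)
    sign = -1.0 if sp.connection == "ipsilateral" else 1.0
    return sign * sp.d * proj


def rano_rhs(state: VehicleState, field_: SignalField, rp: ResponseParams,
             sp: SteeringParams, t: float = 0.0) -> tuple[float, float, float]:
    """Right-hand side of the classic vehicle ODE.

    Speed F(S) along the heading; heading steered by the perpendicular
    projection of ∇F, with the connection-type sign.
    """
    S, gx, gy = field_.value_and_gradient(state.x, state.y, t)
    speed = response_F(S, rp)
    dtheta = _steer(gx, gy, S, state.theta, rp, sp)
    return speed * math.cos(state.theta), speed * math.sin(state.theta), dtheta


def gradient_rhs(state: VehicleState, field_: SignalField, rp: ResponseParams,
                 sp: SteeringParams, t: float = 0.0) -> tuple[float, float, float]:
    """Right-hand side of the gradient-search vehicle ODE.

    Speed v0 + G(‖∇S‖²) along the heading; same steering as the classic
    vehicle (under the default perpendicular coupling).
    """
    S, gx, gy = field_.value_and_gradient(state.x, state.y, t)
    speed = sp.v0 + response_G(gx * gx + gy * gy, rp)
    dtheta = _steer(gx, gy, S, state.theta, rp, sp)
    return speed * math.cos(state.theta), speed * math.sin(state.theta), dtheta


def dual_signal_heading(state: VehicleState, fieldS: SignalField,
                        fieldR: SignalField, rp: ResponseParams,
                        sp: SteeringParams, r: float, t: float = 0.0) -> float:
    """Heading drift under two signals: −d·((r·∇F(S) + ∇F(R))·u).

    The primary-signal term is scaled by the vigilance ``r``; the secondary
    signal R (a close-range cue) is *not* — the agent keeps responding to it
    at full strength even when vigilance has decayed.  ``u`` is the coupling
    direction (left-normal of the heading by default).
    """
    if not 0.0 <= r <= 1.0:
        raise InvalidParameterError(f"vigilance r must be in [0,1], got {r}")
    S, sgx, sgy = fieldS.value_and_gradient(state.x, state.y, t)
    R, rgx, rgy = fieldR.value_and_gradient(state.x, state.y, t)
    vx = vy = 0.0
    if sgx * sgx + sgy * sgy >= GRAD_EPS * GRAD_EPS:
        fpS = response_F_prime(S, rp)
        vx += r * fpS * sgx
        vy += r * fpS * sgy
    if rgx * rgx + rgy * rgy >= GRAD_EPS * GRAD_EPS:
        fpR = response_F_prime(R, rp)
        vx += fpR * rgx
        vy += fpR * rgy
    if vx == 0.0 and vy == 0.0:
        return 0.0
    ct = math.cos(state.theta)
    st = math.sin(state.theta)
    if sp.coupling == "parallel":
        return -sp.d * (vx * ct + vy * st)
    sign = -1.0 if sp.connection == "ipsilateral" else 1.0
    return sign * sp.d * (-vx * st + vy * ct)


# -- deterministic integration ----------------------------------------------

_RHS = {"rano": rano_rhs, "gradient": gradient_rhs}


def simulate_deterministic(field_: SignalField, rp: ResponseParams,
                           sp: SteeringParams, state0: VehicleState,
                           t_max: float, dt: float = 0.01,
                           model: str = "rano", record_every: int = 1):
    """Integrate the classic or gradient-search vehicle with fixed-step RK4.

    Returns a :class:`chemosearch.trackio.Trajectory` with a heading channel,
    recorded every ``record_every`` steps (the initial state and the final
    state are always included).
    """
    from .trackio import Trajectory  # deferred: trackio imports numpy/pandas

    if model not in _RHS:
        raise InvalidParameterError(f"model must be one of {sorted(_RHS)}")
    if t_max <= 0 or dt <= 0 or dt >= t_max:
        raise InvalidParameterError("need 0 < dt < t_max")
    rhs = _RHS[model]

    n_steps = int(round(t_max / dt))
    x, y, theta = state0.x, state0.y, state0.theta
    st = state0.copy()
    times = [0.0]
    xs = [x]
    ys = [y]
    headings = [theta]
    for i in range(1, n_steps + 1):
        t = (i - 1) * dt
        st.x, st.y, st.theta = x, y, theta
        k1 = rhs(st, field_, rp, sp, t)
        st.x, st.y, st.theta = x + 0.5 * dt * k1[0], y + 0.5 * dt * k1[1], theta + 0.5 * dt * k1[2]
        k2 = rhs(st, field_, rp, sp, t + 0.5 * dt)
        st.x, st.y, st.theta = x + 0.5 * dt * k2[0], y + 0.5 * dt * k2[1], theta + 0.5 * dt * k2[2]
        k3 = rhs(st, field_, rp, sp, t + 0.5 * dt)
        st.x, st.y, st.theta = x + dt * k3[0], y + dt * k3[1], theta + dt * k3[2]
        k4 = rhs(st, field_, rp, sp, t + dt)
        x += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        y += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        theta = wrap_angle(theta + dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]))
        if i % record_every == 0 or i == n_steps:
            times.append(i * dt)
            xs.append(x)
            ys.append(y)
            headings.append(theta)
    return Trajectory(times=times, xs=xs, ys=ys, heading=headings,
                      sample_rate_hz=1.0 / (dt * record_every))
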