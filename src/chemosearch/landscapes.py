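"""Scalar chemical signal landscapes and their spatial gradients.

A landscape is a non-negative scalar field ``S(x, y, t)`` (arbitrary signal
units) defined on the plane, with coordinates in millimetres and time in
seconds.  The vehicles in :mod:`chemosearch.dynamics` steer on the spatial
gradient of the field, so every field exposes both point evaluation and an
analytic (or finite-difference) gradient.  Static fields ignore ``t``;
uniformly translating fields model a source drifting at constant speed.
"""

from __future__ import annotations

import math
from typing import Sequence

import yaml

from .exceptions import InvalidParameterError

__all__ = [
    "SignalField",
    "GaussianField",
    "LinearField",
    "MultiPeakField",
    "TranslatingField",
    "gaussian_field",
    "linear_field",
    "multi_peak_field",
    "translate_field",
    "field_from_dict",
    "field_to_dict",
    "load_field",
]

_FD_STEP = 1e-4  # mm; central-difference step for fields without analytic gradients


class SignalField:
    """Base class for signal landscapes.

    Subclasses must implement :meth:`evaluate`; :meth:`gradient` falls back to
    central finite differences (step ``1e-4`` mm) unless overridden with an
    analytic form.  ``drift_speed`` is 0 for static fields.
    """

    drift_speed: float = 0.0

    def evaluate(self, x: float, y: float, t: float = 0.0) -> float:
        raise NotImplementedError

    def gradient(self, x: float, y: float, t: float = 0.0) -> tuple[float, float]:
        h = _FD_STEP
        gx = (self.evaluate(x + h, y, t) - self.evaluate(x - h, y, t)) / (2.0 * h)
        gy = (self.evaluate(x, y + h, t) - self.evaluate(x, y - h, t)) / (2.0 * h)
        return gx, gy

    def value_and_gradient(
        self, x: float, y: float, t: float = 0.0
    ) -> tuple[float, float, float]:
        """Return ``(S, dS/dx, dS/dy)`` in one call (hot path of integrators)."""
        gx, gy = self.gradient(x, y, t)
        return self.evaluate(x, y, t), gx, gy

    @property
    def is_static(self) -> bool:
        return self.drift_speed == 0.0

    def to_dict(self) -> dict:
        raise NotImplementedError(f"{type(self).__name__} is not serialisable")


class GaussianField(SignalField):
    """Radially symmetric Gaussian hill ``A·exp(−((x−cx)² + (y−cy)²)/(2ℓ²))``."""

    def __init__(self, amplitude: float, length_scale: float = 1.0,
                 center: tuple[float, float] = (0.0, 0.0)):
        if amplitude <= 0:
            raise InvalidParameterError(f"amplitude must be > 0, got {amplitude}")
        if length_scale <= 0:
            raise InvalidParameterError(f"length_scale must be > 0, got {length_scale}")
        self.amplitude = float(amplitude)
        self.length_scale = float(length_scale)
        self.center = (float(center[0]), float(center[1]))

    def evaluate(self, x: float, y: float, t: float = 0.0) -> float:
        dx = x - self.center[0]
        dy = y - self.center[1]
        ell2 = self.length_scale * self.length_scale
        return self.amplitude * math.exp(-(dx * dx + dy * dy) / (2.0 * ell2))

    def gradient(self, x: float, y: float, t: float = 0.0) -> tuple[float, float]:
        dx = x - self.center[0]
        dy = y - self.center[1]
        ell2 = self.length_scale * self.length_scale
        s = self.amplitude * math.exp(-(dx * dx + dy * dy) / (2.0 * ell2))
        return -s * dx / ell2, -s * dy / ell2

    def value_and_gradient(self, x, y, t=0.0):
        dx = x - self.center[0]
        dy = y - self.center[1]
        ell2 = self.length_scale * self.length_scale
        s = self.amplitude * math.exp(-(dx * dx + dy * dy) / (2.0 * ell2))
        return s, -s * dx / ell2, -s * dy / ell2

    def to_dict(self) -> dict:
        return {
            "type": "gaussian",
            "amplitude": self.amplitude,
            "length_scale": self.length_scale,
            "center": list(self.center),
        }


class LinearField(SignalField):
    """Planar ramp ``rate · (direction · (x, y))`` clipped at zero.

    ``rate == 0`` yields the flat (signal-free) environment; the clip keeps the
    field non-negative on the half-plane behind the ramp.
    """

    def __init__(self, direction: tuple[float, float] = (1.0, 0.0), rate: float = 1.0):
        if rate < 0:
            raise InvalidParameterError(f"rate must be >= 0, got {rate}")
        norm = math.hypot(direction[0], direction[1])
        if norm == 0.0:
            raise InvalidParameterError("direction must be a non-zero vector")
        self.direction = (direction[0] / norm, direction[1] / norm)
        self.rate = float(rate)

    def evaluate(self, x: float, y: float, t: float = 0.0) -> float:
        raw = self.rate * (self.direction[0] * x + self.direction[1] * y)
        return raw if raw > 0.0 else 0.0

    def gradient(self, x: float, y: float, t: float = 0.0) -> tuple[float, float]:
        raw = self.rate * (self.direction[0] * x + self.direction[1] * y)
        if raw > 0.0:
            return self.rate * self.direction[0], self.rate * self.direction[1]
        return 0.0, 0.0

    def value_and_gradient(self, x, y, t=0.0):
        raw = self.rate * (self.direction[0] * x + self.direction[1] * y)
        if raw > 0.0:
            return raw, self.rate * self.direction[0], self.rate * self.direction[1]
        return 0.0, 0.0, 0.0

    def to_dict(self) -> dict:
        return {"type": "linear", "direction": list(self.direction), "rate": self.rate}


class MultiPeakField(SignalField):
    """Superposition of Gaussian hills (a landscape with several sources)."""

    def __init__(self, peaks: Sequence[tuple[tuple[float, float], float, float]]):
        if not peaks:
            raise InvalidParameterError("multi-peak field needs at least one peak")
        self.components = [
            GaussianField(amplitude=a, length_scale=s, center=c) for c, a, s in peaks
        ]

    def evaluate(self, x: float, y: float, t: float = 0.0) -> float:
        return sum(c.evaluate(x, y, t) for c in self.components)

    def gradient(self, x: float, y: float, t: float = 0.0) -> tuple[float, float]:
        gx = gy = 0.0
        for c in self.components:
            cgx, cgy = c.gradient(x, y, t)
            gx += cgx
            gy += cgy
        return gx, gy

    def value_and_gradient(self, x, y, t=0.0):
        s = gx = gy = 0.0
        for c in self.components:
            cs, cgx, cgy = c.value_and_gradient(x, y, t)
            s += cs
            gx += cgx
            gy += cgy
        return s, gx, gy

    def to_dict(self) -> dict:
        return {
            "type": "multi_peak",
            "peaks": [
                [list(c.center), c.amplitude, c.length_scale] for c in self.components
            ],
        }


class TranslatingField(SignalField):
    """A static base field rigidly translating along x at speed ``v1``.

    By default the base field's features sit shifted by ``(x0 + v1·t, y0)``, so
    a base peak at the origin is at ``x = x0 + v1·t`` (``x0`` is the initial
    location of the centre).  ``literal=True`` selects the alternative
    convention ``x → x − (v1·t − x0)``, which places the centre at
    ``v1·t − x0`` instead.
    """

    def __init__(self, base: SignalField, v1: float, x0: float = 0.0,
                 y0: float = 0.0, literal: bool = False):
        if not base.is_static:
            raise InvalidParameterError("base field of a translation must be static")
        self.base = base
        self.drift_speed = float(v1)
        self.x0 = float(x0)
        self.y0 = float(y0)
        self.literal = bool(literal)

    def _shift(self, t: float) -> float:
        if self.literal:
            return self.drift_speed * t - self.x0
        return self.x0 + self.drift_speed * t

    def offset(self, t: float) -> tuple[float, float]:
        """Rigid offset applied to the base field at time ``t``."""
        return self._shift(t), self.y0

    def evaluate(self, x: float, y: float, t: float = 0.0) -> float:
        return self.base.evaluate(x - self._shift(t), y - self.y0, 0.0)

    def gradient(self, x: float, y: float, t: float = 0.0) -> tuple[float, float]:
        return self.base.gradient(x - self._shift(t), y - self.y0, 0.0)

    def value_and_gradient(self, x, y, t=0.0):
        return self.base.value_and_gradient(x - self._shift(t), y - self.y0, 0.0)

    @property
    def is_static(self) -> bool:
        return self.drift_speed == 0.0 and self.x0 == 0.0 and self.y0 == 0.0

    def to_dict(self) -> dict:
        return {
            "type": "translating",
            "base": self.base.to_dict(),
            "v1": self.drift_speed,
            "x0": self.x0,
            "y0": self.y0,
            "literal": self.literal,
        }


# -- constructor functions ---------------------------------------------------

def gaussian_field(amplitude: float, length_scale: float = 1.0,
                   center: tuple[float, float] = (0.0, 0.0)) -> GaussianField:
    """Gaussian hill with peak value ``amplitude`` at ``center``."""
    return GaussianField(amplitude, length_scale, center)


def linear_field(direction: tuple[float, float] = (1.0, 0.0),
                 rate: float = 1.0) -> LinearField:
    """Linear ramp along ``direction`` at ``rate`` units/mm (0 = flat field)."""
    return LinearField(direction, rate)


def multi_peak_field(
    peaks: Sequence[tuple[tuple[float, float], float, float]]
) -> MultiPeakField:
    """Sum of Gaussian peaks given as ``(center, amplitude, length_scale)``."""
    return MultiPeakField(peaks)


def translate_field(base: SignalField, v1: float, x0: float = 0.0,
                    y0: float = 0.0, literal: bool = False) -> TranslatingField:
    """Translate a static field along x at speed ``v1``, starting at ``x0``."""
    return TranslatingField(base, v1, x0=x0, y0=y0, literal=literal)


# -- serialisation -----------------------------------------------------------

_BUILDERS = {
    "gaussian": lambda d: GaussianField(d["amplitude"], d.get("length_scale", 1.0),
                                        tuple(d.get("center", (0.0, 0.0)))),
    "linear": lambda d: LinearField(tuple(d.get("direction", (1.0, 0.0))),
                                    d.get("rate", 1.0)),
    "flat": lambda d: LinearField((1.0, 0.0), 0.0),
    "multi_peak": lambda d: MultiPeakField(
        [(tuple(c), a, s) for c, a, s in d["peaks"]]),
    "translating": lambda d: TranslatingField(
        field_from_dict(d["base"]), d["v1"], d.get("x0", 0.0),
        d.get("y0", 0.0), d.get("literal", False)),
}


def field_from_dict(spec: dict) -> SignalField:
    """Build a field from a type-tagged mapping (the config-file dialect)."""
    try:
        kind = spec["type"]
    except (KeyError, TypeError):
        raise InvalidParameterError("field spec must be a mapping with a 'type' tag")
    try:
        builder = _BUILDERS[kind]
    except KeyError:
        raise InvalidParameterError(
            f"unknown field type {kind!r}; known: {sorted(_BUILDERS)}")
    return builder(spec)


def field_to_dict(field: SignalField) -> dict:
    return field.to_dict()


def load_field(source) -> SignalField:
    """Load a field from a mapping, a YAML/JSON string, or a file path."""
    if isinstance(source, SignalField):
        return source
    if isinstance(source, dict):
        return field_from_dict(source)
    text = source
    try:
        import os
        if os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
    except (TypeError, ValueError):
        pass
    return field_from_dict(yaml.safe_load(text))
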