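"""Configuration documents: one YAML/JSON mapping describing a simulation.

The schema mirrors the parameter dataclasses field-for-field::

    model: rano | gradient | rest_run | vigilance | dual
    landscape:  {type: ..., ...}           # see chemosearch.landscapes
    landscape2: {type: ..., ...}           # second signal (dual model only)
    response:   {a1, b, c1, a2, c2}
    steering:   {d, v0, connection, coupling}
    energy:     {m, E_min, E_init}
    rest:       {gamma_shape, gamma_scale, orient_std, recharge_rate}
    noise:      {sigma1, sigma2, sigma3, alpha, beta}
    pursuit:    {v1, x0, source_line_y, start, capture_radius, t_max, agent}
    initial:    {x, y, theta, E, r}
    t_max: s
    dt: s
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .behavior import EnergyParams, NoiseParams, PursuitConfig, RestModel
from .dynamics import ResponseParams, SteeringParams, VehicleState
from .exceptions import InvalidParameterError
from .landscapes import SignalField, field_from_dict

__all__ = ["SimulationConfig", "load_config", "config_from_dict"]

MODELS = ("rano", "gradient", "rest_run", "vigilance", "dual")


@dataclass
class SimulationConfig:
    """Fully resolved simulation setup."""

    model: str
    landscape: SignalField
    response: ResponseParams
    steering: SteeringParams
    energy: Optional[EnergyParams] = None
    rest: Optional[RestModel] = None
    noise: Optional[NoiseParams] = None
    pursuit: Optional[PursuitConfig] = None
    landscape2: Optional[SignalField] = None
    initial: Optional[VehicleState] = None
    t_max: float = 200.0
    dt: float = 0.01
    raw: Optional[dict] = None


def _build(cls, mapping, what):
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise InvalidParameterError(f"invalid {what} section: {exc}") from None


def config_from_dict(doc: dict) -> SimulationConfig:
    if not isinstance(doc, dict):
        raise InvalidParameterError("config must be a mapping")
    model = doc.get("model", "gradient")
    if model not in MODELS:
        raise InvalidParameterError(
            f"model must be one of {MODELS}, got {model!r}")
    if "landscape" not in doc:
        raise InvalidParameterError("config is missing the 'landscape' section")
    landscape = field_from_dict(doc["landscape"])
    landscape2 = field_from_dict(doc["landscape2"]) if "landscape2" in doc else None
    if model == "dual" and landscape2 is None:
        raise InvalidParameterError("the dual model needs a 'landscape2' section")

    response = _build(ResponseParams, doc.get("response", {}), "response")
    steering = _build(SteeringParams, doc.get("steering", {}), "steering")
    energy = _build(EnergyParams, doc["energy"], "energy") if "energy" in doc else None
    rest = _build(RestModel, doc["rest"], "rest") if "rest" in doc else None
    noise = _build(NoiseParams, doc["noise"], "noise") if "noise" in doc else None
    pursuit = None
    if "pursuit" in doc:
        p = dict(doc["pursuit"])
        if "start" in p:
            p["start"] = tuple(p["start"])
        pursuit = _build(PursuitConfig, p, "pursuit")
    initial = _build(VehicleState, doc["initial"], "initial") if "initial" in doc else None

    if model == "rest_run":
        energy = energy or EnergyParams()
        rest = rest or RestModel()
    if model in ("vigilance", "dual"):
        noise = noise or NoiseParams()

    return SimulationConfig(
        model=model, landscape=landscape, landscape2=landscape2,
        response=response, steering=steering, energy=energy, rest=rest,
        noise=noise, pursuit=pursuit, initial=initial,
        t_max=float(doc.get("t_max", 200.0)), dt=float(doc.get("dt", 0.01)),
        raw=doc,
    )


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML/JSON simulation config file."""
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)
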