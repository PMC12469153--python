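"""Named scenario presets.

Each preset bundles a landscape, response/steering parameters, and (where
relevant) the stochastic-layer parameters for one of the canonical
simulation scenarios studied with these models:

* ``levelset`` — the classic type-3a vehicle halting on the S = 1 level set
  of a Gaussian hill (a1 = b = 1, c1 = 2, d = 5; background speed 0).
* ``restrun`` — the energy-gated isopod-like searcher in a flat landscape
  (v0 = 3.04 mm/s; Gamma(0.127, 16.257) rests).
* ``multipeak`` — the same searcher wandering a landscape of several peaks
  (turn gain d = 0.5).
* ``larva`` — the coral-larva-like vigilance searcher on a Gaussian hill
  (a1 = a2 = 100, b = 1, c1 = c2 = 2, d = 2, σ1 = σ2 = 5, σ3 = 1,
  v0 = 0.15, α = 0.5, β = 1).
* ``dual_signal`` — the vigilance searcher plus a narrow second signal that
  is immune to vigilance decay.
* ``pursuit`` — the continuous vigilance searcher chasing a source translating along
  y = 20 mm, capture radius 3 mm.

The landscape amplitudes/scales of ``multipeak``, ``larva``, ``dual_signal``
and ``pursuit`` are not pinned by the recorded data; the values here are the
package's documented defaults (see docs/methods.md).
"""

from __future__ import annotations

import copy

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, dict] = {
    "levelset": {
        "model": "rano",
        "landscape": {"type": "gaussian", "amplitude": 1.2, "length_scale": 1.0},
        "response": {"a1": 1.0, "b": 1.0, "c1": 2.0, "a2": 1.0, "c2": 2.0},
        "steering": {"d": 5.0, "v0": 0.0},
        "initial": {"x": 1.7, "y": 0.0, "theta": 2.356194490192345},
        "t_max": 200.0,
        "dt": 0.01,
    },
    "restrun": {
        "model": "rest_run",
        "landscape": {"type": "flat"},
        "response": {"a1": 1.0, "b": 1.0, "c1": 2.0, "a2": 1.0, "c2": 2.0},
        "steering": {"d": 5.0, "v0": 3.04},
        "energy": {"E_min": 0.0},
        "rest": {"gamma_shape": 0.127, "gamma_scale": 16.257, "orient_std": 1.0},
        "initial": {"x": 0.0, "y": 0.0, "theta": 0.0},
        "t_max": 300.0,
        "dt": 0.01,
    },
    "multipeak": {
        "model": "rest_run",
        "landscape": {
            "type": "multi_peak",
            "peaks": [
                [[15.0, 25.0], 1.2, 6.0],
                [[-20.0, 5.0], 1.0, 5.0],
                [[10.0, -18.0], 0.8, 4.0],
                [[-8.0, -25.0], 1.1, 5.0],
            ],
        },
        "response": {"a1": 1.0, "b": 1.0, "c1": 2.0, "a2": 1.0, "c2": 2.0},
        "steering": {"d": 0.5, "v0": 3.04},
        "energy": {"E_min": 0.0},
        "rest": {"gamma_shape": 0.127, "gamma_scale": 16.257, "orient_std": 1.0},
        "initial": {"x": 0.0, "y": 0.0, "theta": 0.0},
        "t_max": 300.0,
        "dt": 0.01,
    },
    "larva": {
        "model": "vigilance",
        "landscape": {"type": "gaussian", "amplitude": 8.0, "length_scale": 20.0,
                      "center": [0.0, 0.0]},
        "response": {"a1": 100.0, "b": 1.0, "c1": 2.0, "a2": 100.0, "c2": 2.0},
        "steering": {"d": 2.0, "v0": 0.15},
        "noise": {"sigma1": 5.0, "sigma2": 5.0, "sigma3": 1.0,
                  "alpha": 0.5, "beta": 1.0},
        "initial": {"x": 60.0, "y": 0.0, "theta": 2.356194490192345, "r": 1.0},
        "t_max": 180.0,
        "dt": 0.01,
    },
    "dual_signal": {
        "model": "dual",
        "landscape": {"type": "gaussian", "amplitude": 8.0, "length_scale": 50.0,
                      "center": [0.0, 0.0]},
        "landscape2": {"type": "gaussian", "amplitude": 16.0, "length_scale": 15.0,
                       "center": [0.0, 0.0]},
        "response": {"a1": 100.0, "b": 1.0, "c1": 2.0, "a2": 100.0, "c2": 2.0},
        "steering": {"d": 2.0, "v0": 0.15},
        "noise": {"sigma1": 5.0, "sigma2": 5.0, "sigma3": 1.0,
                  "alpha": 0.5, "beta": 1.0},
        "initial": {"x": 100.0, "y": 0.0, "theta": 2.356194490192345, "r": 1.0},
        "t_max": 300.0,
        "dt": 0.01,
    },
    "pursuit": {
        "model": "vigilance",
        "landscape": {"type": "gaussian", "amplitude": 3.0, "length_scale": 20.0},
        "response": {"a1": 1.0, "b": 1.0, "c1": 2.0, "a2": 1.0, "c2": 2.0},
        "steering": {"d": 20.0, "v0": 3.04},
        "noise": {"sigma1": 0.2, "sigma2": 0.2, "sigma3": 0.2,
                  "alpha": 0.5, "beta": 1.0},
        "pursuit": {"v1": 2.736, "x0": -40.0, "source_line_y": 20.0,
                    "start": [0.0, 0.0], "capture_radius": 3.0, "t_max": 300.0,
                    "agent": "vigilance"},
        "dt": 0.01,
    },
}


def get_preset(name: str) -> dict:
    """Deep copy of a named preset configuration."""
    try:
        return copy.deepcopy(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
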