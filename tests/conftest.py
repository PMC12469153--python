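import math

import numpy as np
import pytest

import chemosearch as cs


@pytest.fixture
def unit_gaussian():
    """The reference Gaussian hill: amplitude 1.2, length scale 1, at origin."""
    return cs.gaussian_field(1.2, 1.0)


@pytest.fixture
def flat_field():
    return cs.linear_field((1.0, 0.0), 0.0)


@pytest.fixture
def classic_params():
    """Response/steering constants of the level-set demonstration."""
    return (cs.ResponseParams(a1=1.0, b=1.0, c1=2.0, a2=1.0, c2=2.0),
            cs.SteeringParams(d=5.0, v0=0.0))


@pytest.fixture
def larva_params():
    """Response/steering/noise constants of the vigilance searcher."""
    return (cs.ResponseParams(a1=100.0, b=1.0, c1=2.0, a2=100.0, c2=2.0),
            cs.SteeringParams(d=2.0, v0=0.15),
            cs.NoiseParams(sigma1=5.0, sigma2=5.0, sigma3=1.0, alpha=0.5, beta=1.0))


@pytest.fixture
def levelset_ics():
    """Initial conditions of the level-set scenario (headings tilted against +x)."""
    return [(x0, th0) for x0 in (1.3, 1.7, 2.1)
            for th0 in (math.pi - math.pi / 4, math.pi - math.pi / 8)]


def straight_rest_track(segments, speed=3.04, sample_rate_hz=5.0):
    """Kinematic track from explicit (kind, t0, t1) segments along +x."""
    t_end = segments[-1][2]
    times = np.arange(0.0, t_end + 1e-9, 1.0 / sample_rate_hz)
    xs = []
    for ti in times:
        p = 0.0
        for kind, a, b in segments:
            if kind == "run":
                p += speed * min(max(ti - a, 0.0), b - a)
        xs.append(p)
    return cs.Trajectory(times=times, xs=xs, ys=np.zeros_like(times),
                         sample_rate_hz=sample_rate_hz)
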