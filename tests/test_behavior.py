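import math

import numpy as np
import pytest

import chemosearch as cs
from chemosearch.behavior import _rest_capture
from chemosearch.dynamics import response_F_prime, wrap_angle
from chemosearch.exceptions import InvalidParameterError

RP = cs.ResponseParams(a1=1.0, b=1.0, c1=2.0, a2=1.0, c2=2.0)
SP_RUN = cs.SteeringParams(d=5.0, v0=3.04)


class TestEnergyModel:
    def test_no_motion_no_depletion(self):
        assert cs.energy_derivative(0.0, cs.EnergyParams(m=1.0)) == 0.0

    def test_quadratic_depletion(self):
        assert cs.energy_derivative(2.0, cs.EnergyParams(m=1.0)) == -4.0

    def test_calibrated_flat_field_run_duration(self):
        # closed form: a reservoir of E = 2.06 at speed 3.04 empties in
        # E/(m v0^2) seconds, which the calibration pins to the observed 3.81
        m = cs.calibrate_depletion()
        assert m == pytest.approx(2.06 / (3.81 * 3.04**2), rel=1e-12)
        assert 2.06 / (m * 3.04**2) == pytest.approx(3.81, rel=1e-12)

    def test_negative_speed_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.energy_derivative(-1.0, cs.EnergyParams())


class TestRestModel:
    def test_draw_statistics_match_gamma(self):
        rm = cs.RestModel()
        rng = np.random.default_rng(12)
        draws = np.array([cs.draw_rest_time(rm, rng) for _ in range(1_000_000)])
        assert np.all(draws > 0.0)
        assert draws.mean() == pytest.approx(2.06, abs=0.02)
        assert draws.var() == pytest.approx(0.127 * 16.257**2, abs=1.0)

    def test_apply_rest_contract(self):
        rm = cs.RestModel()
        rng = np.random.default_rng(9)
        expected_rest = np.random.default_rng(9).gamma(0.127, 16.257)
        st = cs.VehicleState(x=3.0, y=-2.0, theta=1.0, E=0.0)
        new, t1 = cs.apply_rest(st, t=10.0, rm=rm, rng=rng)
        assert (new.x, new.y) == (3.0, -2.0)
        assert t1 == pytest.approx(10.0 + expected_rest, rel=1e-12)
        assert new.E == pytest.approx(expected_rest, rel=1e-12)

    def test_apply_rest_recharge_equals_rest_time(self):
        rm = cs.RestModel()
        st = cs.VehicleState(E=0.0)
        new, t1 = cs.apply_rest(st, t=0.0, rm=rm, rng=3)
        assert new.E == pytest.approx(t1, rel=1e-12)

    def test_tiny_orientation_noise_keeps_heading(self):
        rm = cs.RestModel(orient_std=1e-12)
        st = cs.VehicleState(theta=2.5)
        new, _ = cs.apply_rest(st, 0.0, rm, np.random.default_rng(0))
        assert new.theta == pytest.approx(2.5, abs=1e-9)


@pytest.fixture(scope="module")
def flat_run():
    return cs.simulate_rest_run(
        cs.linear_field(rate=0.0), RP, SP_RUN, cs.EnergyParams(),
        cs.RestModel(), t_max=None, dt=0.01, rng=2, max_cycles=2000,
        record_hz=5.0)


class TestRestRunSimulation:
    def test_run_phase_speed_is_background(self, flat_run):
        # a few sample pairs straddle a rest shorter than the recording
        # interval; all others move at exactly the background speed
        tr = flat_run.trajectory
        run = np.asarray(tr.mode) == "run"
        dt_pairs = np.diff(tr.times)
        step = np.hypot(np.diff(tr.xs), np.diff(tr.ys)) / dt_pairs
        both_run = run[:-1] & run[1:] & (np.abs(dt_pairs - 0.2) < 1e-9)
        assert both_run.sum() > 100
        at_v0 = np.abs(step[both_run] - 3.04) < 1e-6 * 3.04
        assert at_v0.mean() > 0.99
        assert np.median(step[both_run]) == pytest.approx(3.04, rel=1e-9)

    def test_run_segments_are_straight(self, flat_run):
        tr = flat_run.trajectory
        run = np.asarray(tr.mode) == "run"
        vx, vy = np.diff(tr.xs), np.diff(tr.ys)
        inner = run[:-2] & run[1:-1] & run[2:]
        cross = vx[:-1][inner] * vy[1:][inner] - vy[:-1][inner] * vx[1:][inner]
        # heading only changes at rests; sub-interval rests leave a few kinks
        assert (np.abs(cross) < 1e-9).mean() > 0.98

    def test_bout_means_match_rest_model(self, flat_run):
        # 2000 cycles: mean rest within Monte-Carlo error of k*theta = 2.065
        assert flat_run.rest_durations.mean() == pytest.approx(2.06, abs=0.4)
        assert flat_run.run_durations.mean() == pytest.approx(3.81, abs=0.7)

    def test_energy_gating_links_rest_to_next_run(self, flat_run):
        # flat field: the run fed by a rest of T_R lasts ceil(T_R/(m v0^2 dt)) dt
        m_v0sq = cs.EnergyParams().m * 3.04**2
        rests = flat_run.rest_durations
        runs = flat_run.run_durations[1:len(rests) + 1]
        expected = np.ceil(rests / m_v0sq / 0.01 - 1e-9) * 0.01
        np.testing.assert_allclose(runs, expected[:len(runs)], atol=0.011)

    def test_deterministic_under_fixed_seed(self):
        kw = dict(t_max=None, dt=0.01, max_cycles=60, record_hz=5.0)
        a = cs.simulate_rest_run(cs.linear_field(rate=0.0), RP, SP_RUN,
                                 cs.EnergyParams(), cs.RestModel(), rng=7, **kw)
        b = cs.simulate_rest_run(cs.linear_field(rate=0.0), RP, SP_RUN,
                                 cs.EnergyParams(), cs.RestModel(), rng=7, **kw)
        assert np.array_equal(a.trajectory.xs, b.trajectory.xs)
        assert np.array_equal(a.trajectory.times, b.trajectory.times)
        assert np.array_equal(a.rest_durations, b.rest_durations)

    def test_invalid_configuration(self):
        with pytest.raises(InvalidParameterError):
            cs.simulate_rest_run(cs.linear_field(rate=0.0), RP, SP_RUN,
                                 cs.EnergyParams(), cs.RestModel(),
                                 t_max=0.005, dt=0.01, rng=0)


class TestEulerMaruyama:
    def test_zero_noise_reduces_to_explicit_euler(self, unit_gaussian):
        """One EM step with sigma = 0 equals the hand-written Euler step bitwise."""
        sp = cs.SteeringParams(d=2.0, v0=0.15)
        noise = cs.NoiseParams(sigma1=0.0, sigma2=0.0, sigma3=0.0, alpha=0.5)
        state = cs.VehicleState(x=1.1, y=-0.4, theta=0.8, r=0.9)
        dt = 0.01
        for _ in range(100):
            S, gx, gy = unit_gaussian.value_and_gradient(state.x, state.y, 0.0)
            speed = sp.v0 + cs.response_G(gx * gx + gy * gy, RP)
            fp = response_F_prime(S, RP)
            vx, vy = state.r * fp * gx, state.r * fp * gy
            dth = -sp.d * (-vx * math.sin(state.theta) + vy * math.cos(state.theta))
            euler = (state.x + speed * math.cos(state.theta) * dt,
                     state.y + speed * math.sin(state.theta) * dt,
                     wrap_angle(state.theta + dth * dt),
                     state.r - noise.alpha * state.r * dt)
            state = cs.em_step(state, unit_gaussian, RP, sp, noise, dt,
                               rng=np.random.default_rng(0))
            assert (state.x, state.y, state.theta, state.r) == euler

    def test_vigilance_euler_update(self):
        noise = cs.NoiseParams(alpha=0.5)
        st = cs.VehicleState(r=1.0)
        new = cs.em_step(st, cs.linear_field(rate=0.0), RP,
                         cs.SteeringParams(d=1.0), noise, dt=0.01, rng=0)
        assert new.r == 0.995

    def test_mean_increment_matches_drift(self, unit_gaussian):
        sp = cs.SteeringParams(d=2.0, v0=0.5)
        noise = cs.NoiseParams(sigma1=1.0, sigma2=1.0, sigma3=0.5, alpha=0.5)
        state = cs.VehicleState(x=1.0, y=0.5, theta=0.7, r=1.0)
        dt = 0.01
        rng = np.random.default_rng(21)
        n = 4000
        dx = np.empty(n)
        dy = np.empty(n)
        for i in range(n):
            new = cs.em_step(state, unit_gaussian, RP, sp, noise, dt, rng)
            dx[i], dy[i] = new.x - state.x, new.y - state.y
        S, gx, gy = unit_gaussian.value_and_gradient(1.0, 0.5, 0.0)
        speed = sp.v0 + cs.response_G(gx * gx + gy * gy, RP)
        sem = noise.sigma1 * math.sqrt(dt) / math.sqrt(n)
        assert dx.mean() == pytest.approx(speed * math.cos(0.7) * dt, abs=4 * sem)
        assert dy.mean() == pytest.approx(speed * math.sin(0.7) * dt, abs=4 * sem)


class TestVigilanceSimulation:
    def test_decay_matches_closed_form_between_renewals(self, flat_field):
        noise = cs.NoiseParams(alpha=0.5, beta=1e-6)
        res = cs.simulate_vigilance(flat_field, RP, cs.SteeringParams(d=1.0, v0=1.0),
                                    noise, t_max=2.0, dt=0.01, rng=5)
        assert len(res.renewal_times) == 0
        assert res.vigilance[-1] == pytest.approx(math.exp(-0.5 * 2.0), abs=5e-3)

    def test_frequent_renewal_pins_vigilance_high(self, flat_field):
        noise = cs.NoiseParams(alpha=0.5, beta=500.0)
        res = cs.simulate_vigilance(flat_field, RP, cs.SteeringParams(d=1.0, v0=1.0),
                                    noise, t_max=5.0, dt=0.01, rng=5)
        assert res.vigilance.min() > 0.9

    def test_vigilance_bounded(self, unit_gaussian, larva_params):
        rp, sp, noise = larva_params
        res = cs.simulate_vigilance(unit_gaussian, rp, sp, noise, t_max=30.0,
                                    dt=0.01, rng=3, record_every=5)
        assert np.all(res.vigilance >= 0.0)
        assert np.all(res.vigilance <= 1.0)

    def test_deterministic_under_fixed_seed(self, unit_gaussian, larva_params):
        rp, sp, noise = larva_params
        a = cs.simulate_vigilance(unit_gaussian, rp, sp, noise, 10.0, 0.01, rng=17)
        b = cs.simulate_vigilance(unit_gaussian, rp, sp, noise, 10.0, 0.01, rng=17)
        assert np.array_equal(a.trajectory.xs, b.trajectory.xs)
        assert np.array_equal(a.vigilance, b.vigilance)
        assert np.array_equal(a.renewal_times, b.renewal_times)

    def test_attraction_to_gaussian_peak(self, larva_params):
        """Noisy vigilance searchers drift toward the signal peak."""
        rp, sp, noise = larva_params
        field = cs.gaussian_field(8.0, 20.0)
        init, fin = [], []
        for seed in range(50):
            st = cs.VehicleState(x=60.0, y=0.0, theta=3 * math.pi / 4)
            res = cs.simulate_vigilance(field, rp, sp, noise, t_max=180.0,
                                        dt=0.01, rng=seed, state0=st,
                                        record_every=100)
            tr = res.trajectory
            init.append(math.hypot(tr.xs[0], tr.ys[0]))
            fin.append(math.hypot(tr.xs[-1], tr.ys[-1]))
        assert np.median(fin) < np.median(init)


class TestDualSignalContainment:
    def test_second_signal_retains_agent_near_peak(self):
        """After first entering the region where R >= S, the dual-signal agent
        stays there a larger fraction of the remaining time (paired seeds)."""
        rp = cs.ResponseParams(a1=100.0, b=1.0, c1=2.0, a2=100.0, c2=2.0)
        sp = cs.SteeringParams(d=2.0, v0=0.15)
        noise = cs.NoiseParams(sigma1=5.0, sigma2=5.0, sigma3=1.0,
                               alpha=0.5, beta=1.0)
        S = cs.gaussian_field(8.0, 50.0)
        R = cs.gaussian_field(16.0, 15.0)

        def frac_inside(res):
            tr = res.trajectory
            r2 = tr.xs**2 + tr.ys**2
            inside = 16.0 * np.exp(-r2 / 450.0) >= 8.0 * np.exp(-r2 / 5000.0)
            if not inside.any():
                return None
            return float(inside[np.argmax(inside):].mean())

        pairs = []
        for seed in range(30):
            st = cs.VehicleState(x=100.0, y=0.0, theta=3 * math.pi / 4)
            single = cs.simulate_vigilance(S, rp, sp, noise, 300.0, 0.01,
                                           rng=seed, state0=st, record_every=20)
            dual = cs.simulate_vigilance(S, rp, sp, noise, 300.0, 0.01,
                                         rng=seed, state0=st, record_every=20,
                                         fieldR=R)
            pairs.append((frac_inside(single), frac_inside(dual)))
        both = [(a, b) for a, b in pairs if a is not None and b is not None]
        assert len(both) >= 5
        a = np.array([p[0] for p in both])
        b = np.array([p[1] for p in both])
        assert b.mean() > a.mean()


@pytest.fixture(scope="module")
def pursuit_setup():
    from chemosearch.config import config_from_dict
    from chemosearch.presets import get_preset
    return config_from_dict(get_preset("pursuit"))


class TestPursuit:
    def test_degenerate_capture_radius(self, pursuit_setup):
        cfg = pursuit_setup
        pc = cs.PursuitConfig(v1=2.736, x0=-40.0, capture_radius=1e6, t_max=10.0)
        res = cs.simulate_pursuit(cfg.landscape, pc, cfg.response, cfg.steering,
                                  noise=cfg.noise, rng=0)
        assert res.success and res.capture_time == 0.0

    def test_static_source_found_on_all_seeds(self, pursuit_setup):
        cfg = pursuit_setup
        pc = cs.PursuitConfig(v1=0.0, x0=-20.0, t_max=300.0)
        results = [cs.simulate_pursuit(cfg.landscape, pc, cfg.response,
                                       cfg.steering, noise=cfg.noise,
                                       rng=np.random.default_rng([3, s]))
                   for s in range(15)]
        assert sum(r.success for r in results) >= 14

    def test_rest_run_agent_supported(self, pursuit_setup):
        cfg = pursuit_setup
        pc = cs.PursuitConfig(v1=0.0, x0=-10.0, t_max=60.0, agent="rest_run")
        res = cs.simulate_pursuit(cfg.landscape, pc, cfg.response,
                                  cs.SteeringParams(d=20.0, v0=3.04),
                                  ep=cs.EnergyParams(), rm=cs.RestModel(), rng=1)
        assert res.min_distance < math.hypot(10.0, 20.0)
        assert len(res.trajectory) > 2

    def test_resting_capture_closed_form(self):
        # brute-force time grid vs the quadratic closed form
        pc = cs.PursuitConfig(v1=2.0, x0=-10.0, source_line_y=2.0,
                              capture_radius=3.0, t_max=100.0)
        tc, dmin = _rest_capture(0.0, 0.0, 0.0, 20.0, pc)
        grid = np.linspace(0.0, 20.0, 2_000_001)
        dist = np.hypot(0.0 - (-10.0 + 2.0 * grid), 2.0)
        assert dmin == pytest.approx(dist.min(), abs=1e-9)
        first = grid[np.argmax(dist <= 3.0)]
        assert tc == pytest.approx(first, abs=1e-4)

    def test_resting_capture_static_source(self):
        pc = cs.PursuitConfig(v1=0.0, x0=1.0, source_line_y=0.0,
                              capture_radius=3.0, t_max=10.0)
        tc, dmin = _rest_capture(0.0, 0.0, 5.0, 8.0, pc)
        assert tc == 5.0 and dmin == pytest.approx(1.0)
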