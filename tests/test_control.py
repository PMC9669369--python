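import numpy as np
import pytest

from myodyn import control as C
from myodyn.synth import SynthConfig, generate_trajectory


def const_target(value=1.0):
    v = np.full(3, value)
    return lambda t: np.tile(v, (len(np.atleast_1d(t)), 1))


def zero_target():
    return lambda t: np.zeros((len(np.atleast_1d(t)), 3))


def ramp_target(v):
    def fn(t):
        t = np.atleast_1d(t)
        return v * t[:, None] * np.ones((1, 3))
    return fn


class TestLaws:
    def test_znn_is_feedforward_at_zero_error(self):
        u = C.znn_law([1, 2, 3], [4, 5, 6], [1, 2, 3], gamma=100)
        np.testing.assert_allclose(u, [4, 5, 6])

    def test_znn_error_arithmetic_and_linearity(self):
        u = C.znn_law([0.01] * 3, [0] * 3, [0] * 3, gamma=100)
        np.testing.assert_allclose(u, 1.0)
        u2 = C.znn_law([0.02] * 3, [0] * 3, [0] * 3, gamma=100)
        np.testing.assert_allclose(u2, 2 * u)

    def test_nsznn_reduces_to_znn(self):
        args = ([1.0, 0.5, 0.2], [0.1, 0.1, 0.1], [0.9, 0.4, 0.3])
        np.testing.assert_allclose(
            C.nsznn_law(*args, np.zeros(3), 100, 200), C.znn_law(*args, 100))
        np.testing.assert_allclose(
            C.nsznn_law(*args, np.ones(3), 100, 0.0), C.znn_law(*args, 100))

    def test_nsznn_integral_arithmetic(self):
        u = C.nsznn_law([0] * 3, [0] * 3, [0] * 3, [0.005] * 3, 100, 200)
        np.testing.assert_allclose(u, 1.0)

    def test_gnn_zero_error_and_offset_from_znn(self):
        np.testing.assert_allclose(C.gnn_law([1, 2, 3], [1, 2, 3], 100), 0.0)
        d = C.znn_law([1, 2, 3], [7, 8, 9], [0, 0, 0], 50) - C.gnn_law([1, 2, 3], [0, 0, 0], 50)
        np.testing.assert_allclose(d, [7, 8, 9])

    def test_pid_arithmetic_and_proportional_identity(self):
        np.testing.assert_allclose(C.pid_law([0] * 3, [0] * 3, [0] * 3, 10, 0.5, 0.2), 0.0)
        dt = 1e-3
        u = C.pid_law([1] * 3, [dt] * 3, [1 / dt] * 3, 10, 0.5, 0.2)
        np.testing.assert_allclose(u, 10 + 0.5 * dt + 0.2 / dt)
        np.testing.assert_allclose(
            C.pid_law([0.3] * 3, [9] * 3, [9] * 3, 70, 0, 0), C.gnn_law([0.3] * 3, [0] * 3, 70))


class TestNoise:
    def test_constant_and_linear_values(self):
        assert np.all(C.noise_value(C.NoiseSpec(kind="constant", c=1.0), 5.0) == 1.0)
        assert np.all(C.noise_value(C.NoiseSpec(kind="linear", a=0.5), 10.0) == 5.0)
        assert np.all(C.noise_value(C.NoiseSpec(kind="none"), 3.0) == 0.0)

    def test_random_seed_reproducible(self):
        s = C.NoiseSpec(kind="random", r=2.0, seed=9)
        a = [C.noise_value(s, 0.0, rng) for rng in [np.random.default_rng(9)] for _ in range(3)]
        rng = np.random.default_rng(9)
        b = [C.noise_value(s, 0.0, rng) for _ in range(3)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_random_bounds(self):
        rng = np.random.default_rng(0)
        s = C.NoiseSpec(kind="random", r=1.5)
        vals = np.array([C.noise_value(s, 0.0, rng) for _ in range(200)])
        assert vals.min() >= 0.0 and vals.max() <= 1.5

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            C.NoiseSpec(kind="pink")


class TestClosedForms:
    def test_znn_closed_form_values(self):
        assert C.znn_error_closed_form(1.0, 100.0, 0.05) == pytest.approx(np.exp(-5))
        assert C.znn_error_closed_form(0.7, 100.0, 0.0) == 0.7
        e = C.znn_error_closed_form(1.0, 50.0, np.linspace(0, 1, 11))
        assert np.all(np.diff(e) < 0)

    def test_nsznn_steady_state_laws(self):
        assert C.nsznn_steady_state(C.NoiseSpec(kind="constant", c=7.0), 100, 200) == 0.0
        assert C.nsznn_steady_state(C.NoiseSpec(kind="linear", a=2.0), 100, 200) == pytest.approx(0.01)
        assert C.nsznn_steady_state(C.NoiseSpec(kind="none"), 100, 200) == 0.0
        assert C.nsznn_steady_state(C.NoiseSpec(kind="random", r=1.0), 100, 200) == 0.0
        with pytest.raises(ValueError):
            C.nsznn_steady_state(C.NoiseSpec(kind="constant"), -1, 200)


class TestSimulator:
    def test_znn_matches_exponential_decay_and_improves_with_dt(self):
        errs = {}
        for dt in (1e-3, 1e-4):
            prob = C.TrackingProblem(const_target(), zero_target(), duration=0.1, dt=dt)
            res = C.simulate(prob, C.ControllerSpec(type="znn"))
            exact = C.znn_error_closed_form(1.0, 100.0, res.t)
            errs[dt] = np.max(np.abs(res.error[:, 0] - exact) / exact)
        assert errs[1e-4] < errs[1e-3] < 1e-2

    def test_znn_constant_noise_settles_at_c_over_gamma(self):
        prob = C.TrackingProblem(const_target(), zero_target(), duration=0.5, dt=1e-3,
                                 theta0=np.ones(3))
        res = C.simulate(prob, C.ControllerSpec(type="znn"), C.NoiseSpec(kind="constant", c=1.0))
        assert np.abs(res.error[-1]) == pytest.approx(np.full(3, 0.01), rel=0.02)

    def test_gnn_ramp_lag_is_v_over_gamma_while_znn_vanishes(self):
        v = 2.0
        prob = C.TrackingProblem(ramp_target(v), const_target(v), duration=1.0, dt=1e-3)
        gnn = C.simulate(prob, C.ControllerSpec(type="gnn"))
        znn = C.simulate(prob, C.ControllerSpec(type="znn"))
        assert gnn.error[-1, 0] == pytest.approx(v / 100.0, rel=0.02)
        assert abs(znn.error[-1, 0]) < 1e-6

    def test_linear_noise_znn_unbounded_nsznn_bounded(self):
        a = 1.0
        prob = C.TrackingProblem(const_target(), zero_target(), duration=8.0, dt=1e-3,
                                 theta0=np.ones(3))
        spec = C.NoiseSpec(kind="linear", a=a)
        znn = C.simulate(prob, C.ControllerSpec(type="znn"), spec)
        nsznn = C.simulate(prob, C.ControllerSpec(type="nsznn"), spec)
        e = np.abs(znn.error[:, 0])
        t = znn.t
        # ZNN error keeps growing with asymptotic slope a / gamma
        slope = (e[-1] - e[4000]) / (t[-1] - t[4000])
        assert slope == pytest.approx(a / 100.0, rel=0.05)
        # NSZNN error stays within 2 a / lambda after the transient
        assert np.max(np.abs(nsznn.error[2000:, 0])) <= 2 * a / 200.0

    def test_simulated_nsznn_matches_steady_state_prediction(self):
        prob = C.TrackingProblem(const_target(), zero_target(), duration=6.0, dt=1e-3)
        spec = C.NoiseSpec(kind="linear", a=2.0)
        res = C.simulate(prob, C.ControllerSpec(type="nsznn"), spec)
        pred = C.nsznn_steady_state(spec, 100.0, 200.0)
        assert np.abs(res.error[-1, 0]) == pytest.approx(pred, rel=0.05)

    def test_random_noise_run_is_seed_deterministic(self):
        prob = C.TrackingProblem(const_target(), zero_target(), duration=0.2, dt=1e-3)
        spec = C.NoiseSpec(kind="random", r=1.0, seed=77)
        a = C.simulate(prob, C.ControllerSpec(type="nsznn"), spec)
        b = C.simulate(prob, C.ControllerSpec(type="nsznn"), spec)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.rmse, b.rmse)

    def test_euler_method_available_and_first_order(self):
        prob = C.TrackingProblem(const_target(), zero_target(), duration=0.05, dt=1e-4)
        res = C.simulate(prob, C.ControllerSpec(type="znn"), method="euler")
        exact = C.znn_error_closed_form(1.0, 100.0, res.t)
        rel = np.max(np.abs(res.error[:, 0] - exact) / exact)
        assert 1e-4 < rel < 0.1  # converges, but visibly first-order

    def test_pid_tracks_constant_target(self):
        prob = C.TrackingProblem(const_target(5.0), zero_target(), duration=3.0, dt=1e-3)
        res = C.simulate(prob, C.ControllerSpec(type="pid"))
        assert np.max(np.abs(res.error[-1])) < 0.05

    def test_result_contract(self, small_trajectory):
        prob = C.TrackingProblem.from_trajectory(small_trajectory, dt=1e-3, theta0="start")
        res = C.simulate(prob, C.ControllerSpec(type="znn"))
        np.testing.assert_array_equal(res.error, res.theta_d - res.theta)
        from myodyn.evaluation import rmse
        for j in range(3):
            assert res.rmse[j] == pytest.approx(rmse(res.theta_d[:, j], res.theta[:, j]))

    def test_compare_runs_all_four_controllers(self, small_trajectory):
        prob = C.TrackingProblem.from_trajectory(small_trajectory, dt=1e-2, theta0="start")
        out = C.compare_controllers(prob, C.NoiseSpec(kind="none"))
        assert set(out) == set(C.CONTROLLERS)
        for res in out.values():
            assert res.rmse.shape == (3,)
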