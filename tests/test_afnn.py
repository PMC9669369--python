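import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myodyn import afnn
from myodyn.afnn import (
    AFNNModel,
    TrainConfig,
    centers,
    denormalize,
    forward,
    gradients,
    init_model,
    loss,
    membership,
    normalize,
    predict,
    train,
)


def random_model(rng, n_in=2, n_out=2, L=3):
    return AFNNModel(
        f=rng.normal(0.5, 0.3, (L, n_out)),
        b=rng.normal(0, 0.5, (n_in, L)),
        c=rng.normal(0, 0.5, (n_in, L)),
        sigma=rng.uniform(0.3, 0.8, (n_in, L)),
    )


class TestNormalization:
    def test_minmax_maps_to_unit_interval(self):
        out, stats = normalize(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(out.ravel(), [0, 0.5, 1])

    def test_constant_column_guarded_to_half(self):
        out, _ = normalize(np.array([[3.0], [3.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 30), k=st.integers(1, 5))
    def test_denormalize_inverts(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 100, (n, k))
        xn, stats = normalize(x)
        np.testing.assert_allclose(denormalize(xn, stats), x, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.empty((0, 3)))


class TestCentersAndMembership:
    def test_zero_parameters_give_half(self, rng):
        m = random_model(rng)
        m.b[:], m.c[:] = 0.0, 0.0
        np.testing.assert_allclose(centers(m, np.array([0.3, 0.9])), 0.5)

    def test_extreme_argument_saturates_to_zero(self, rng):
        m = random_model(rng)
        m.b[:], m.c[:] = 1.0, 1e4
        mu = centers(m, np.array([0.0, 0.0]))
        assert np.all(mu < 1e-10) and np.all(mu >= 0)

    def test_quarter_point_by_inverted_logistic(self, rng):
        # b=1, x=0, c = 2 sigma ln 3  =>  argument ln 3, logistic(-ln 3) = 1/4
        m = random_model(rng, n_in=1, L=1)
        m.b[:] = 1.0
        m.sigma[:] = 0.4
        m.c[:] = 2.0 * 0.4 * np.log(3.0)
        assert centers(m, np.array([0.0]))[0, 0] == pytest.approx(0.25)

    def test_membership_peak_unit_deviation_and_monotone_decay(self, rng):
        # b = c = 0 pins the center at 0.5 independent of x
        m = random_model(rng, n_in=1, L=1)
        m.b[:], m.c[:] = 0.0, 0.0
        sig = m.sigma[0, 0]
        assert membership(m, np.array([0.5]))[0, 0] == pytest.approx(1.0)
        assert membership(m, np.array([0.5 + sig]))[0, 0] == pytest.approx(np.exp(-1))
        assert membership(m, np.array([0.5 - sig]))[0, 0] == pytest.approx(np.exp(-1))
        devs = [0.1, 0.3, 0.6, 1.2]
        phis = [membership(m, np.array([0.5 + d]))[0, 0] for d in devs]
        assert all(a > b for a, b in zip(phis, phis[1:]))


class TestForward:
    def test_single_rule_returns_its_consequent(self, rng):
        m = random_model(rng, L=1)
        for _ in range(5):
            x = rng.uniform(0, 1, 2)
            np.testing.assert_allclose(forward(m, x), m.f[0])

    def test_equal_consequents_collapse_to_that_vector(self, rng):
        m = random_model(rng, L=4)
        m.f[:] = np.array([0.2, 0.7])
        np.testing.assert_allclose(forward(m, rng.uniform(0, 1, 2)), [0.2, 0.7])

    def test_symmetric_two_rule_average(self):
        # identical membership parameters for both rules => equal weights
        m = AFNNModel(
            f=np.array([[0.0, 1.0], [1.0, 0.0]]),
            b=np.zeros((2, 2)),
            c=np.zeros((2, 2)),
            sigma=np.full((2, 2), 0.5),
        )
        np.testing.assert_allclose(forward(m, np.array([0.3, 0.8])), [0.5, 0.5])

    def test_output_in_convex_hull_of_consequents(self, rng):
        m = random_model(rng, L=6)
        X = rng.uniform(-2, 2, (50, 2))
        Y = forward(m, X)
        assert np.all(Y >= m.f.min(axis=0) - 1e-12)
        assert np.all(Y <= m.f.max(axis=0) + 1e-12)

    def test_far_outlier_input_still_finite(self, rng):
        # rule activations underflow in linear space; log-space keeps them valid
        m = random_model(rng, L=3)
        y = forward(m, np.array([1e3, -1e3]))
        assert np.all(np.isfinite(y))


class TestLossAndGradients:
    def test_perfect_prediction_zero_loss(self, rng):
        m = random_model(rng)
        X = rng.uniform(0, 1, (10, 2))
        assert loss(m, X, forward(m, X)) == 0.0

    def test_constant_offset_gives_squared_offset(self, rng):
        m = random_model(rng)
        X = rng.uniform(0, 1, (10, 2))
        assert loss(m, X, forward(m, X) + 0.3) == pytest.approx(0.09)

    def test_agrees_with_direct_recomputation(self, rng):
        m = random_model(rng)
        X = rng.uniform(0, 1, (7, 2))
        Y = rng.uniform(0, 1, (7, 2))
        direct = np.mean((forward(m, X) - Y) ** 2)
        assert loss(m, X, Y) == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_analytic_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, n_in=2, n_out=2, L=3)
        X = rng.uniform(0, 1, (20, 2))
        Y = rng.uniform(0, 1, (20, 2))
        gf, gb, gc = gradients(m, X, Y)
        h = 1e-6
        for arr, g in ((m.f, gf), (m.b, gb), (m.c, gc)):
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                ep = loss(m, X, Y)
                arr[idx] = orig - h
                em = loss(m, X, Y)
                arr[idx] = orig
                num[idx] = (ep - em) / (2 * h)
            scale = np.maximum(np.abs(num), 1e-4)
            assert np.max(np.abs(g - num) / scale) <= 1e-5

    def test_dimension_mismatch_rejected(self, rng):
        m = random_model(rng)
        with pytest.raises(ValueError):
            loss(m, np.ones((5, 2)), np.ones((4, 2)))


class TestTraining:
    def test_descent_is_monotone_at_small_learning_rate(self, rng):
        m = random_model(rng, L=4)
        X = rng.uniform(0, 1, (40, 2))
        Y = rng.uniform(0, 1, (40, 2))
        _, hist = train(m, X, Y, TrainConfig(maxstep=200, learning_rate=0.5))
        assert all(a >= b - 1e-15 for a, b in zip(hist, hist[1:]))

    def test_seed_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (30, 2))
        Y = rng.uniform(0, 1, (30, 2))
        runs = []
        for _ in range(2):
            m = init_model(2, 2, 3, Y=Y, seed=11)
            mt, hist = train(m, X, Y, TrainConfig(maxstep=50, learning_rate=1.0, seed=11))
            runs.append((mt.f.copy(), mt.b.copy(), mt.c.copy(), tuple(hist)))
        for a, b in zip(runs[0], runs[1]):
            np.testing.assert_array_equal(a, b)

    def test_self_generated_targets_recover_consequents(self, rng):
        """Data from a known rule base: perturbed f returns to truth (linear-in-f)."""
        truth = random_model(rng, n_in=2, n_out=2, L=3)
        X = rng.uniform(0, 1, (60, 2))
        Y = forward(truth, X)
        start = AFNNModel(
            f=truth.f + rng.normal(0, 1e-2, truth.f.shape),
            b=truth.b.copy(), c=truth.c.copy(), sigma=truth.sigma.copy(),
        )
        fitted, hist = train(start, X, Y, TrainConfig(maxstep=4000, learning_rate=2.0))
        assert hist[-1] <= 1e-9
        assert np.max(np.abs(fitted.f - truth.f)) <= 1e-3

    def test_nearby_initialization_reaches_tiny_loss(self, rng):
        truth = random_model(rng, n_in=2, n_out=1, L=2)
        X = rng.uniform(0, 1, (50, 2))
        Y = forward(truth, X)
        start = AFNNModel(
            f=truth.f + 1e-3, b=truth.b + 1e-3, c=truth.c - 1e-3, sigma=truth.sigma.copy()
        )
        _, hist = train(start, X, Y, TrainConfig(maxstep=5000, learning_rate=1.0, tol=1e-13))
        assert hist[-1] <= 1e-6

    def test_divergence_raises_with_iteration_index(self, rng):
        m = random_model(rng)
        X = rng.uniform(0, 1, (30, 2))
        Y = rng.uniform(0, 1, (30, 2))
        with np.errstate(over="ignore"), pytest.raises(afnn.TrainingDivergedError):
            train(m, X, Y, TrainConfig(maxstep=3000, learning_rate=1e6))


class TestPrediction:
    def test_constant_envelope_gives_constant_angles(self, small_envelope):
        import pandas as pd
        from myodyn.dataio import TimeSeriesTable
        from myodyn.preprocess import MUSCLES, EnvelopeFeatures
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 0.9, (50, 6))
        Y = rng.uniform(-30, 60, (50, 3))
        model, _ = afnn.fit(X, Y, L=3, cfg=TrainConfig(maxstep=5))
        const = EnvelopeFeatures(table=TimeSeriesTable(
            rate=100.0, data=pd.DataFrame({m: np.full(10, 0.4) for m in MUSCLES})))
        traj = afnn.predict_trajectory(model, const)
        assert np.ptp(traj.angles(), axis=0).max() == 0.0

    def test_prediction_consistent_with_training_row(self, rng):
        X = rng.uniform(0.1, 0.9, (40, 6))
        Y = rng.uniform(-30, 60, (40, 3))
        model, _ = afnn.fit(X, Y, L=4, cfg=TrainConfig(maxstep=20))
        # predicting a training input must reproduce the fitted value exactly
        np.testing.assert_allclose(predict(model, X[:5]), predict(model, X)[:5], atol=1e-12)

    def test_untrained_model_rejected(self, small_envelope):
        m = init_model(6, 3, 4)
        with pytest.raises(ValueError):
            afnn.predict_trajectory(m, small_envelope)

    def test_serialization_round_trip(self, tmp_path, rng):
        X = rng.uniform(0, 1, (30, 6))
        Y = rng.uniform(-10, 10, (30, 3))
        model, _ = afnn.fit(X, Y, L=3, cfg=TrainConfig(maxstep=10))
        back = afnn.load_model(afnn.save_model(model, tmp_path / "m.json"))
        np.testing.assert_array_equal(back.f, model.f)
        np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)
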