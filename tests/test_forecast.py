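import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from cowordcast.errors import ConfigurationError, NoHistoryError, UndefinedR2Error
from cowordcast.forecast import (
    WindowSpec,
    build_training_set,
    evaluate_r2,
    extract_window,
    fit,
    predict_bin,
    predict_matrix,
    recurrent_forecast,
    window_size_sweep,
)
from cowordcast.synthetic import Dynamics, TrendScenario, generate_tensor

FIG1_BLOCK = np.array([[5.0, 3.0, 5.0], [3.0, 4.0, 4.0], [7.0, 5.0, 4.0]])


class TestExtractWindow:
    def test_w1_is_cell_value(self):
        m = np.arange(12.0).reshape(3, 4)
        for i in range(3):
            for j in range(4):
                assert extract_window(m, i, j, WindowSpec(1)) == pytest.approx([m[i, j]])

    def test_worked_example_center_and_neighbors(self):
        # 3x3 block with centre 4 and neighbours 5,3,5,3,4,7,5,4 (row-major)
        vec = extract_window(FIG1_BLOCK, 1, 1, WindowSpec(3))
        assert vec[4] == 4.0  # centre at position (w^2 - 1) / 2
        neighbors = np.delete(vec, 4)
        assert list(neighbors) == [5, 3, 5, 3, 4, 7, 5, 4]
        assert neighbors.sum() == 36.0

    def test_corner_padding_matches_bounds_oracle(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        spec = WindowSpec(3)
        vec = extract_window(m, 0, 0, spec)
        # explicit index-bounds oracle
        expected = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = 0 + di, 0 + dj
                expected.append(m[i, j] if 0 <= i < 2 and 0 <= j < 2 else 0.0)
        assert list(vec) == expected
        assert sum(v == 0.0 for v in vec) == 5

    def test_custom_padding(self):
        m = np.array([[1.0]])
        vec = extract_window(m, 0, 0, WindowSpec(3, padding=-7.0))
        assert list(vec) == [-7.0] * 4 + [1.0] + [-7.0] * 4

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            extract_window(np.zeros((2, 2)), 2, 0, WindowSpec(3))

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            WindowSpec(4)


class TestBuildTrainingSet:
    def test_two_bins_3x3(self):
        arr = np.random.default_rng(0).poisson(3, (2, 3, 3)).astype(float)
        ts = build_training_set(arr, upto=1, spec=WindowSpec(3))
        assert ts.X.shape == (9, 9)
        assert ts.y.shape == (9,)
        assert all(t == 1 for t, _, _ in ts.index)

    def test_five_bins_2x2(self):
        arr = np.zeros((5, 2, 2))
        ts = build_training_set(arr, upto=4, spec=WindowSpec(1))
        assert ts.X.shape == (16, 1)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(4, (4, 5, 6)).astype(float)
        spec = WindowSpec(3)
        ts = build_training_set(arr, upto=3, spec=spec)
        rows = {}
        for k, (t, i, j) in enumerate(ts.index):
            rows[(t, i, j)] = (ts.X[k], ts.y[k])
        for t in range(1, 4):
            for i in range(5):
                for j in range(6):
                    x, y = rows[(t, i, j)]
                    assert np.array_equal(x, extract_window(arr[t - 1], i, j, spec))
                    assert y == arr[t, i, j]
        assert len(rows) == 3 * 5 * 6

    def test_no_history_error(self):
        with pytest.raises(NoHistoryError):
            build_training_set(np.zeros((3, 2, 2)), upto=0, spec=WindowSpec(1))


class TestFit:
    def make_train(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, (n, 9))
        return X

    @pytest.mark.parametrize("backend", ["ridge", "lasso", "elastic_net", "omp", "passive_aggressive"])
    def test_constant_targets(self, backend):
        from cowordcast.forecast import TrainingSet

        X = self.make_train()
        y = np.full(X.shape[0], 7.0)
        model = fit(backend, TrainingSet(X=X, y=y, index=[(1, 0, k) for k in range(len(y))]), seed=0)
        pred = model.predict(X)
        if backend == "passive_aggressive":
            # online epsilon-insensitive updates only approach the constant
            assert np.mean(pred) == pytest.approx(7.0, abs=1.0)
        else:
            assert np.allclose(pred, 7.0, atol=0.3)

    def test_ridge_recovers_exact_linear_function(self):
        from cowordcast.forecast import TrainingSet

        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, (200, 9))
        beta = rng.uniform(-1, 1, 9)
        y = X @ beta + 2.0
        model = fit("ridge", TrainingSet(X=X, y=y, index=[(1, 0, k) for k in range(200)]), seed=0)
        assert evaluate_r2(model.predict(X), y) > 0.999

    def test_unknown_backend(self):
        from cowordcast.forecast import TrainingSet

        X = self.make_train()
        with pytest.raises(ConfigurationError, match="xgboost"):
            fit("xgboost", TrainingSet(X=X, y=np.zeros(len(X)), index=[(1, 0, k) for k in range(len(X))]))

    def test_lasso_matches_coordinate_descent_oracle(self):
        """Independent cyclic coordinate-descent lasso with the same
        standardization must reproduce the pipeline's coefficients."""
        from cowordcast.forecast import TrainingSet

        rng = np.random.default_rng(7)
        n, p = 200, 9
        X = rng.uniform(0, 20, (n, p))
        beta = np.array([2.0, 0.0, 0.0, -1.5, 0.0, 0.5, 0.0, 0.0, 1.0])
        y = X @ beta + 5.0 + 0.1 * rng.standard_normal(n)

        model = fit("lasso", TrainingSet(X=X, y=y, index=[(1, 0, k) for k in range(n)]), seed=0)
        got = model.named_steps["reg"].coef_

        # oracle: standardize (biased std), then cyclic coordinate descent on
        # (1/2n)||y - Xw - b||^2 + alpha ||w||_1 with alpha = 1.0
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        yc = y - y.mean()
        alpha = 1.0
        w = np.zeros(p)
        for _ in range(2000):
            w_old = w.copy()
            for j in range(p):
                r = yc - Xs @ w + Xs[:, j] * w[j]
                rho = Xs[:, j] @ r / n
                z = Xs[:, j] @ Xs[:, j] / n
                w[j] = np.sign(rho) * max(abs(rho) - alpha, 0.0) / z
            if np.max(np.abs(w - w_old)) < 1e-12:
                break
        assert np.allclose(got, w, atol=1e-6)

    def test_empty_training_set(self):
        from cowordcast.forecast import TrainingSet

        with pytest.raises(ConfigurationError):
            fit("ridge", TrainingSet(X=np.empty((0, 9)), y=np.empty(0), index=[]))


class _InterceptOnly:
    def __init__(self, b):
        self.b = b

    def predict(self, X):
        return np.full(X.shape[0], self.b)


class TestPredict:
    def test_constant_tensor_predicts_constant(self):
        arr = np.full((6, 4, 4), 9.0)
        ts = build_training_set(arr, upto=5, spec=WindowSpec(3))
        model = fit("ridge", ts, seed=0)
        pred = predict_bin(model, arr, 5, WindowSpec(3))
        assert np.allclose(pred, 9.0, atol=0.5)

    def test_intercept_only_model(self):
        pred = predict_matrix(_InterceptOnly(3.5), np.zeros((3, 3)), WindowSpec(3))
        assert np.all(pred == 3.5)

    def test_negative_predictions_clamped(self):
        pred = predict_matrix(_InterceptOnly(-2.0), np.zeros((3, 3)), WindowSpec(3))
        assert np.all(pred == 0.0)

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.poisson(6, (3, 3, 3)).astype(float)
        spec = WindowSpec(3)
        ts = build_training_set(arr, upto=2, spec=spec)
        model = fit("ridge", ts, seed=0)
        pred = predict_bin(model, arr, 2, spec)
        for i in range(3):
            for j in range(3):
                x = extract_window(arr[1], i, j, spec)
                expected = max(0.0, float(model.predict(x[None, :])[0]))
                assert pred[i, j] == pytest.approx(expected)

    def test_missing_prior_bin(self):
        with pytest.raises(NoHistoryError):
            predict_bin(_InterceptOnly(0.0), np.zeros((3, 2, 2)), 0, WindowSpec(1))


class TestEvaluateR2:
    def test_perfect_prediction(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert evaluate_r2(a, a) == pytest.approx(1.0)

    def test_mean_baseline_is_zero(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert evaluate_r2(np.full_like(a, a.mean()), a) == pytest.approx(0.0)

    def test_hand_computed_six_values(self):
        actual = np.array([[3.0, 5.0, 2.0], [8.0, 4.0, 2.0]])
        pred = np.array([[2.0, 5.0, 4.0], [7.0, 5.0, 1.0]])
        # by hand: mean = 4, SS_tot = 1+1+4+16+0+4 = 26, SS_res = 1+0+4+1+1+1 = 8
        assert evaluate_r2(pred, actual) == pytest.approx(1.0 - 8.0 / 26.0)

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedR2Error):
            evaluate_r2(np.zeros((2, 2)), np.full((2, 2), 3.0))

    def test_shape_mismatch(self):
        with pytest.raises(ConfigurationError):
            evaluate_r2(np.zeros((2, 2)), np.zeros((2, 3)))


class TestRecurrentForecast:
    def test_horizon_one_equals_single_step_bitwise(self, random_tensor):
        spec = WindowSpec(3)
        run = recurrent_forecast(random_tensor, start_bin=2, horizon=1, backend="ridge", spec=spec, seed=0)
        ts = build_training_set(random_tensor, upto=1, spec=spec)
        model = fit("ridge", ts, seed=0)
        single = predict_bin(model, random_tensor, 2, spec)
        assert np.array_equal(run.predictions[2], single)

    def test_geometric_growth_matches_closed_form(self):
        # cell dynamics M_t = a * M_{t-1}: learnable exactly from the centre
        # feature, so the recurrent forecast must track a^h extrapolation
        a = 1.1
        rng = np.random.default_rng(0)
        arr = np.empty((10, 5, 5))
        arr[0] = rng.uniform(20, 50, (5, 5))
        for t in range(1, 10):
            arr[t] = a * arr[t - 1]
        run = recurrent_forecast(arr, start_bin=6, horizon=4, backend="ridge", spec=WindowSpec(3), seed=0)
        for h in range(4):
            expected = arr[5] * a ** (h + 1)
            rel = np.abs(run.predictions[6 + h] - expected) / expected
            assert rel.max() < 0.05

    def test_trace_only_where_actuals_exist(self, random_tensor):
        n = random_tensor.n_bins
        run = recurrent_forecast(random_tensor, start_bin=n - 1, horizon=3, backend="ridge", spec=WindowSpec(1), seed=0)
        assert sorted(run.predictions) == [n - 1, n, n + 1]
        assert sorted(run.r2_trace) == [n - 1]

    def test_start_bin_without_history(self, random_tensor):
        with pytest.raises(NoHistoryError):
            recurrent_forecast(random_tensor, start_bin=1, horizon=2)

    def test_r2_declines_with_horizon_on_noisy_fixture(self):
        traces = []
        for seed in range(10):
            s = TrendScenario(
                k_ai=20, k_bio=20, bins=16, base_rate=8.0, spatial_corr=0.4, pair_jitter=1.0,
                dynamics=Dynamics("linear", slope=0.15), seed=seed,
            )
            tens, _ = generate_tensor(s)
            run = recurrent_forecast(tens, start_bin=10, horizon=6, backend="ridge", spec=WindowSpec(3), seed=0)
            traces.append([run.r2_trace[10 + h] for h in range(6)])
        med = np.median(np.array(traces), axis=0)
        assert np.all(np.diff(med) <= 0)


class TestWindowSizeSweep:
    def test_single_evaluable_bin_mean_is_that_r2(self):
        rng = np.random.default_rng(8)
        arr = rng.poisson(5, (3, 4, 4)).astype(float)
        spec = WindowSpec(1)
        tab = window_size_sweep(arr, sizes=(1,), backends=("ridge",), seed=0)
        ts = build_training_set(arr, upto=1, spec=spec)
        model = fit("ridge", ts, seed=0)
        expected = evaluate_r2(predict_bin(model, arr, 2, spec), arr[2])
        assert tab.loc["ridge", 1] == pytest.approx(expected)

    def test_spatially_dependent_tensor_prefers_w3(self):
        # each bin is (nearly) an exact function of the previous bin's 3x3
        # neighbourhood, so w=3 must beat the keyword-only baseline
        rng = np.random.default_rng(4)
        arr = np.empty((12, 10, 10))
        arr[0] = rng.uniform(10, 60, (10, 10))
        for t in range(1, 12):
            arr[t] = 1.05 * uniform_filter(arr[t - 1], size=3, mode="constant") + 0.2 * rng.standard_normal((10, 10))
        tab = window_size_sweep(arr, sizes=(1, 3), backends=("ridge",), seed=0)
        assert tab.loc["ridge", 3] > tab.loc["ridge", 1]

    def test_deterministic_across_reruns(self, random_tensor):
        t1 = window_size_sweep(random_tensor, sizes=(1, 3), backends=("ridge", "elastic_net"), seed=0)
        t2 = window_size_sweep(random_tensor, sizes=(1, 3), backends=("ridge", "elastic_net"), seed=0)
        assert t1.equals(t2)

    def test_even_size_rejected(self, random_tensor):
        with pytest.raises(ConfigurationError):
            window_size_sweep(random_tensor, sizes=(2,), backends=("ridge",))


class TestInvariants:
    def test_w1_baseline_equivalence(self):
        rng = np.random.default_rng(9)
        m = rng.poisson(7, (6, 7)).astype(float)
        spec = WindowSpec(1)
        for i in range(6):
            for j in range(7):
                assert extract_window(m, i, j, spec)[0] == m[i, j]

    def test_parameter_recovery_linear_backends(self):
        # y_t(i,j) = a * mean(window_{t-1}(i,j)) + eps  =>  sum of feature
        # partials equals a; measured by finite differences on the fitted model
        a = 1.02
        spec = WindowSpec(3)
        for backend in ("ridge", "elastic_net"):
            for seed in (0, 1):
                rng = np.random.default_rng(seed)
                arr = np.empty((10, 12, 12))
                arr[0] = rng.uniform(50, 150, (12, 12))
                for t in range(1, 10):
                    arr[t] = a * uniform_filter(arr[t - 1], size=3, mode="constant") + 0.5 * rng.standard_normal((12, 12))
                ts = build_training_set(arr, upto=9, spec=spec)
                assert ts.X.shape[0] >= 500
                model = fit(backend, ts, seed=0)
                X0 = ts.X[:64]
                a_hat = float(np.mean(model.predict(X0 + 1.0) - model.predict(X0)))
                assert abs(a_hat - a) / a < 0.10
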