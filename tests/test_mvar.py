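"""Static/dynamic MVAR estimation, causality measures, forgetting selection."""

import numpy as np
import pytest

from dgcnet import (
    DGCTensor,
    DynamicCoeffs,
    InvalidArgumentError,
    MVARModel,
    TimeSeriesMatrix,
    burn_in_trim,
    dgc,
    fit_dynamic_mvar,
    fit_static_mvar,
    group_initialize,
    optimize_forgetting,
    select_order_bic,
    simulate_scenario,
    static_gc,
    true_dgc_series,
)
from dgcnet.mvar import forgetting_objective


def _coupled_pair(t_total=5000, k=0.9, seed=0):
    """Two stable series with a known lag-1 influence x -> y of strength k."""
    rng = np.random.default_rng(seed)
    x = np.zeros(t_total)
    y = np.zeros(t_total)
    ex, ey = rng.standard_normal((2, t_total)) * 0.3
    for t in range(1, t_total):
        x[t] = 0.3 * x[t - 1] + ex[t]
        y[t] = k * x[t - 1] + 0.1 * y[t - 1] + ey[t]
    return TimeSeriesMatrix(np.column_stack([x, y]))


class TestStaticFit:
    def test_recovers_known_coupling(self):
        series = _coupled_pair()
        model = fit_static_mvar(series, 1)
        assert model.lag_coeffs[0, 1, 0] == pytest.approx(0.9, abs=0.05)

    def test_white_noise_coefficients_within_three_se(self, rng):
        t_total = 2000
        series = TimeSeriesMatrix(rng.standard_normal((t_total, 4)))
        model = fit_static_mvar(series, 1)
        x = series.values[:-1] - series.values[:-1].mean(axis=0)
        gram_inv = np.linalg.inv(x.T @ x)
        for j in range(4):
            se = np.sqrt(np.diag(gram_inv) * model.residual_cov[j, j])
            off = [i for i in range(4) if i != j]
            assert np.all(np.abs(model.lag_coeffs[off, j, 0]) < 3.5 * se[off])

    def test_matches_normal_equations_oracle(self, small_series):
        ts, _ = small_series
        model = fit_static_mvar(ts, 2)
        centered = ts.values - ts.values.mean(axis=0)
        x = np.hstack([centered[1:-1], centered[:-2]])
        y = centered[2:]
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        r = ts.n_regions
        np.testing.assert_allclose(model.lag_coeffs[:, :, 0], beta[:r], atol=1e-8)
        np.testing.assert_allclose(model.lag_coeffs[:, :, 1], beta[r:], atol=1e-8)

    def test_rank_deficient_raises(self):
        values = np.random.default_rng(0).standard_normal((100, 2))
        values = np.column_stack([values, values[:, 0]])  # duplicated column
        with pytest.raises(np.linalg.LinAlgError):
            fit_static_mvar(TimeSeriesMatrix(values), 1)


class TestStaticGC:
    def test_single_coefficient(self):
        coeffs = np.zeros((3, 3, 1))
        coeffs[0, 1, 0] = 0.5
        model = MVARModel(1, coeffs, np.zeros(3), np.eye(3))
        g = static_gc(model)
        assert g[0, 1] == pytest.approx(0.25)
        off = ~np.eye(3, dtype=bool)
        off[0, 1] = False
        assert np.all(g[off] == 0)

    def test_sums_over_lags(self):
        coeffs = np.zeros((2, 2, 2))
        coeffs[0, 1, 0] = 0.3
        coeffs[0, 1, 1] = 0.4
        model = MVARModel(2, coeffs, np.zeros(2), np.eye(2))
        assert static_gc(model)[0, 1] == pytest.approx(0.25)

    def test_zero_model(self):
        model = MVARModel(1, np.zeros((2, 2, 1)), np.zeros(2), np.eye(2))
        assert np.all(static_gc(model) == 0)


class TestOrderSelection:
    def test_lag1_data_selects_one(self):
        ts, _ = simulate_scenario("constant", 2000, 6, seed=2, block_size=3)
        assert select_order_bic(ts, 5) == 1

    def test_lag2_data_selects_two(self, rng):
        t_total = 3000
        z = np.zeros((t_total, 2))
        noise = rng.standard_normal((t_total, 2))
        for t in range(2, t_total):
            z[t] = 0.2 * z[t - 1] - 0.6 * z[t - 2] + noise[t]
        assert select_order_bic(TimeSeriesMatrix(z), 4) == 2

    def test_single_candidate(self, small_series):
        assert select_order_bic(small_series[0], 1) == 1


class TestDynamicFit:
    def test_time_average_tracks_constant_truth(self, constant_sim):
        ts, truth = constant_sim
        coeffs = fit_dynamic_mvar(ts, 1, 0.01)
        avg = coeffs.values[:, :, 0, 50:].mean(axis=2)
        assert np.max(np.abs(avg - truth.coeff_series[0])) < 0.1

    def test_no_forgetting_limit_equals_growing_window_ols(self, small_series):
        ts, _ = small_series
        coeffs = fit_dynamic_mvar(ts, 1, 0.0)
        model = fit_static_mvar(ts, 1)
        final = coeffs.values[:, :, 0, -1]
        assert np.max(np.abs(final - model.lag_coeffs[:, :, 0])) < 1e-4

    def test_truth_initialization_converges_faster(self, small_series):
        ts, truth = small_series
        init = truth.coeff_series[0][:, :, None]
        warm = fit_dynamic_mvar(ts, 1, 0.05, init_coeffs=init)
        cold = fit_dynamic_mvar(ts, 1, 0.05)
        k_true = truth.coeff_series[0]
        err_warm = np.abs(warm.values[:, :, 0, 1:51] - k_true[:, :, None]).mean()
        err_cold = np.abs(cold.values[:, :, 0, 1:51] - k_true[:, :, None]).mean()
        assert err_warm < err_cold

    def test_bad_forgetting_raises(self, small_series):
        with pytest.raises(InvalidArgumentError):
            fit_dynamic_mvar(small_series[0], 1, 1.0)

    def test_bad_init_shape_raises(self, small_series):
        with pytest.raises(InvalidArgumentError):
            fit_dynamic_mvar(small_series[0], 1, 0.05, init_coeffs=np.zeros((2, 2, 1)))


class TestDGC:
    def test_squares_and_sums_coefficients(self):
        values = np.zeros((2, 2, 1, 5))
        values[0, 1, 0, 3] = -0.4
        tensor = dgc(DynamicCoeffs(values=values, forgetting=0.05))
        assert tensor.values[0, 1, 3] == pytest.approx(0.16)
        assert tensor.values.sum() == pytest.approx(0.16)

    def test_zero_coefficients_zero_tensor(self):
        tensor = dgc(DynamicCoeffs(values=np.zeros((3, 3, 2, 4)), forgetting=0.1))
        assert np.all(tensor.values == 0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_sinusoidal_tracking_correlation(self, seed):
        """Estimated DGC follows the oscillating ground-truth k(t)^2 on average
        over within-block connections (weak connections individually have low
        signal-to-noise, so the mean over pairs is the tested statistic)."""
        ts, truth = simulate_scenario("sinusoidal", 1000, 12, seed=seed)
        tensor = burn_in_trim(dgc(fit_dynamic_mvar(ts, 1, 0.02)), 50)
        target = true_dgc_series(truth)[:, :, 50:]
        base = truth.coeff_series[0]
        cors = [
            np.corrcoef(tensor.values[i, j], target[i, j])[0, 1]
            for i in range(12)
            for j in range(12)
            if i != j and base[i, j] != 0
        ]
        assert np.mean(cors) > 0.55

    def test_permutation_equivariance(self, small_series, rng):
        ts, _ = small_series
        perm = rng.permutation(ts.n_regions)
        permuted = TimeSeriesMatrix(ts.values[:, perm])
        t1 = dgc(fit_dynamic_mvar(ts, 1, 0.05))
        t2 = dgc(fit_dynamic_mvar(permuted, 1, 0.05))
        np.testing.assert_allclose(
            t2.values, t1.values[np.ix_(perm, perm)], atol=1e-10
        )


class TestForgettingSelection:
    def test_single_element_grid(self, small_series):
        assert optimize_forgetting(small_series[0], 1, grid=(0.07,)) == 0.07

    def test_constant_data_prefers_longest_memory(self):
        grid = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20)
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            ts, _ = simulate_scenario("constant", 600, 6, seed=seed, block_size=3)
            if optimize_forgetting(ts, 1, grid=grid) == grid[0]:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_objective_matches_independent_recomputation(self, small_series):
        ts, _ = small_series
        f = 0.05
        obj = forgetting_objective(ts, 1, f, burn_in=50)
        # recompute a priori residuals from the coefficient track itself
        coeffs = fit_dynamic_mvar(ts, 1, f)
        centered = ts.values - ts.values.mean(axis=0)
        energy = []
        for t in range(1, ts.n_time):
            w_prev = coeffs.values[:, :, 0, t - 1]
            err = centered[t] - w_prev.T @ centered[t - 1]
            energy.append(np.sum(err**2))
        expected = np.var(np.asarray(energy)[49:])
        assert obj == pytest.approx(expected, abs=1e-10)


class TestGroupInitialize:
    def test_single_run_equals_final_state(self, small_series):
        ts, _ = small_series
        init = group_initialize([ts], 1, 0.05)
        coeffs = fit_dynamic_mvar(ts, 1, 0.05)
        np.testing.assert_allclose(init[:, :, 0], coeffs.values[:, :, 0, -1], atol=1e-10)

    def test_identical_models_yield_truth(self):
        from dgcnet import sample_stable_block_coeffs

        k_true = sample_stable_block_coeffs(6, 3, seed=21)
        rng = np.random.default_rng(99)
        runs = []
        for _ in range(3):  # same model, independent noise realizations
            z = np.zeros((600, 6))
            noise = rng.standard_normal((600, 6))
            for t in range(1, 600):
                z[t] = k_true.T @ z[t - 1] + noise[t]
            runs.append(TimeSeriesMatrix(z))
        # no-forgetting pass: the natural setting for a time-invariant group state
        init = group_initialize(runs, 1, 0.0)
        assert np.max(np.abs(init[:, :, 0] - k_true)) < 0.1

    def test_run_order_matters_for_heterogeneous_runs(self):
        a, _ = simulate_scenario("constant", 400, 6, seed=1, block_size=3)
        b, _ = simulate_scenario("constant", 400, 6, seed=2, block_size=3)
        init_ab = group_initialize([a, b], 1, 0.05)
        init_ba = group_initialize([b, a], 1, 0.05)
        assert np.max(np.abs(init_ab - init_ba)) > 1e-6

    def test_mismatched_regions_raise(self):
        a, _ = simulate_scenario("constant", 200, 6, seed=1, block_size=3)
        b, _ = simulate_scenario("constant", 200, 12, seed=1)
        with pytest.raises(InvalidArgumentError):
            group_initialize([a, b], 1, 0.05)


class TestBurnInTrim:
    def test_lengths(self):
        tensor = DGCTensor(values=np.random.default_rng(0).random((3, 3, 1000)))
        trimmed = burn_in_trim(tensor, 50)
        assert trimmed.n_time == 950
        assert trimmed.burn_in_removed
        assert trimmed.burn_in_length == 50

    def test_zero_discard_is_identity(self):
        tensor = DGCTensor(values=np.random.default_rng(0).random((3, 3, 100)))
        same = burn_in_trim(tensor, 0)
        np.testing.assert_array_equal(same.values, tensor.values)
        assert same.burn_in_removed == tensor.burn_in_removed

    def test_composition(self):
        tensor = DGCTensor(values=np.random.default_rng(0).random((3, 3, 100)))
        once = burn_in_trim(tensor, 50)
        twice = burn_in_trim(burn_in_trim(tensor, 50), 0)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.burn_in_length == twice.burn_in_length

    def test_too_large_discard_raises(self):
        tensor = DGCTensor(values=np.zeros((2, 2, 10)))
        with pytest.raises(InvalidArgumentError):
            burn_in_trim(tensor, 10)


def test_stationary_forgetting_limit_matches_static_gc():
    """Time-averaged DGC at F=0 converges to the static Granger causality."""
    ts, _ = simulate_scenario("constant", 5000, 6, seed=6, block_size=3)
    tensor = burn_in_trim(dgc(fit_dynamic_mvar(ts, 1, 0.0)), 500)
    static = static_gc(fit_static_mvar(ts, 1))
    assert np.max(np.abs(tensor.values.mean(axis=2) - static)) < 0.05


def test_cross_block_dgc_near_zero_in_constant_scenario(constant_sim):
    """Regions in different blocks show almost no estimated causality."""
    ts, truth = constant_sim
    tensor = burn_in_trim(dgc(fit_dynamic_mvar(ts, 1, 0.01)), 50)
    cross = truth.coeff_series[0] == 0
    np.fill_diagonal(cross, False)
    assert np.max(tensor.values.mean(axis=2)[cross]) < 0.02
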