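"""Strong-order estimation, pullback stability, coalescence, ensembles."""

import numpy as np
import pytest
from scipy.linalg import expm

from diabsde import (
    LinearCoefficients,
    Mesh,
    ModelParams,
    NoiseSpec,
    StateVec,
    ensemble_summary,
    fit_order,
    ode_reference,
    pullback_experiment,
    strong_error_study,
    trajectory_coalescence,
)


class TestFitOrder:
    @pytest.mark.parametrize("p_true", [0.5, 1.0])
    def test_recovers_synthetic_power_law(self, p_true):
        dts = np.array([0.1, 0.05, 0.025, 0.0125])
        assert fit_order(dts, 3.0 * dts ** p_true) == pytest.approx(p_true)

    def test_two_point_slope(self):
        # log(0.1/0.05)/log(0.1/0.025) = log 2 / log 4 = 0.5
        assert fit_order([0.1, 0.025], [0.1, 0.05]) == pytest.approx(0.5)

    def test_degenerate_levels_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            slope = fit_order([0.1, 0.05, 0.025], [0.1, 0.05, 0.0])
        assert slope == pytest.approx(1.0)

    def test_all_degenerate_raises(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            fit_order([0.1, 0.05], [0.0, 0.0])


class TestStrongErrorStudy:
    def test_noise_free_order_one_against_exact_reference(self, noise_free):
        res = strong_error_study(noise_free, T=5.0, finest_dt=2.0 ** -10,
                                 n_levels=3, n_paths=1, seed=1,
                                 reference="exact")
        assert 0.9 < res.fitted_order < 1.1

    def test_default_model_order_at_least_half(self, canonical):
        # scaled-down study (50 paths, finest 2^-10); the full-size run is
        # the acceptance test
        res = strong_error_study(canonical, T=5.0, finest_dt=2.0 ** -10,
                                 n_levels=3, n_paths=50, seed=3)
        assert res.fitted_order >= 0.5
        assert np.all(np.diff(res.dts) > 0) or np.all(np.diff(res.dts) < 0)
        assert np.all(res.rms_errors > 0)

    def test_frozen_drift_and_noise_errors_are_zero(self):
        """Zero drift AND zero noise: every level is exact, fit degenerate."""
        p = ModelParams(coeffs=LinearCoefficients(0, 0, 0, 0, 0),
                        noise=NoiseSpec(0.0))
        res = strong_error_study(p, T=5.0, finest_dt=2.0 ** -8, n_levels=3,
                                 n_paths=2, seed=0)
        assert res.degenerate_levels == (0, 1, 2)
        assert np.isnan(res.fitted_order)

    def test_exact_reference_requires_noise_free(self, canonical):
        with pytest.raises(ValueError):
            strong_error_study(canonical, reference="exact", n_paths=1)

    def test_errors_shrink_with_dt(self, canonical):
        res = strong_error_study(canonical, T=5.0, finest_dt=2.0 ** -10,
                                 n_levels=3, n_paths=20, seed=9)
        # dts increase with level; errors must increase alongside
        assert np.all(np.diff(res.rms_errors) > 0)


class TestPullback:
    def test_identical_starts_give_zero(self, canonical):
        res = pullback_experiment(canonical, StateVec(0.7, 0.1),
                                  StateVec(0.7, 0.1), 40.0, [10.0, 20.0],
                                  seed=1)
        assert np.all(res.diffs == 0.0)

    def test_monotone_decay_in_tau(self, canonical):
        res = pullback_experiment(canonical, StateVec(0.70, 0.10),
                                  StateVec(0.65, 0.11), 40.0,
                                  [10.0, 20.0, 40.0], seed=2)
        assert np.all(np.diff(res.diffs) < 0)

    def test_matches_matrix_exponential_oracle(self, canonical, constant_M):
        dt = 0.01
        res = pullback_experiment(canonical, StateVec(0.70, 0.10),
                                  StateVec(0.65, 0.11), 40.0,
                                  [10.0, 20.0, 40.0], seed=2, dt=dt)
        dx0 = np.array([0.05, -0.01])
        for tau, diff in zip(res.taus, res.diffs):
            s = 40.0 - tau
            oracle = np.linalg.norm(
                expm(constant_M * (40.0 ** 2 - s ** 2) / 2.0) @ dx0)
            assert abs(diff - oracle) < 10 * dt

    def test_diffs_independent_of_noise_realization(self, canonical):
        """Additive noise cancels in the difference (up to float residue)."""
        runs = [
            pullback_experiment(canonical, StateVec(0.70, 0.10),
                                StateVec(0.65, 0.11), 40.0, [10.0, 30.0],
                                seed=s).diffs
            for s in (1, 2, 3)
        ]
        assert np.allclose(runs[0], runs[1], atol=1e-12)
        assert np.allclose(runs[0], runs[2], atol=1e-12)

    def test_negative_start_times_use_reflected_path(self, canonical,
                                                     constant_M):
        """tau > t_fixed starts before time zero on the reflected path.

        There the linear-in-time coefficients change sign (A(t) = t*M with
        t < 0 is anti-stable), so the difference need not decay -- but it
        must still track the matrix-exponential oracle exactly, noise-free.
        """
        dt = 0.01
        res = pullback_experiment(canonical, StateVec(0.70, 0.10),
                                  StateVec(0.65, 0.11), 5.0,
                                  [10.0, 20.0], seed=4, dt=dt)
        dx0 = np.array([0.05, -0.01])
        for tau, diff in zip(res.taus, res.diffs):
            s = 5.0 - tau
            oracle = np.linalg.norm(
                expm(constant_M * (5.0 ** 2 - s ** 2) / 2.0) @ dx0)
            assert diff == pytest.approx(oracle, rel=0.05, abs=10 * dt)

    def test_bad_taus_rejected(self, canonical):
        with pytest.raises(ValueError):
            pullback_experiment(canonical, StateVec(0.7, 0.1),
                                StateVec(0.6, 0.1), 40.0, [20.0, 10.0])


class TestCoalescence:
    def test_identical_starts_zero_series(self, canonical):
        out = trajectory_coalescence(
            canonical, [StateVec(0.7, 0.1), StateVec(0.7, 0.1)],
            Mesh(0.0, 5.0, 0.01), seed=1)
        assert np.all(out[(0, 1)] == 0.0)

    def test_terminal_over_initial_ratio(self, canonical):
        out = trajectory_coalescence(
            canonical, [StateVec(0.70, 0.10), StateVec(0.65, 0.11)],
            Mesh(0.0, 40.0, 0.01), seed=1)
        series = out[(0, 1)]
        ratio = series[-1] / series[0]
        # exact matrix-exponential decay gives 1.111e-3 at t=40
        assert ratio == pytest.approx(1.11e-3, rel=0.05)

    def test_series_independent_of_seed(self, canonical):
        a = trajectory_coalescence(
            canonical, [StateVec(0.70, 0.10), StateVec(0.65, 0.11)],
            Mesh(0.0, 20.0, 0.01), seed=1)[(0, 1)]
        b = trajectory_coalescence(
            canonical, [StateVec(0.70, 0.10), StateVec(0.65, 0.11)],
            Mesh(0.0, 20.0, 0.01), seed=987)[(0, 1)]
        assert np.allclose(a, b, atol=1e-12)

    def test_three_starts_give_three_pairs(self, canonical):
        out = trajectory_coalescence(
            canonical,
            [StateVec(0.70, 0.10), StateVec(0.65, 0.11), StateVec(0.79, 0.09)],
            Mesh(0.0, 5.0, 0.01), seed=1)
        assert set(out) == {(0, 1), (0, 2), (1, 2)}


class TestEnsembleSummary:
    def test_noise_free_variance_zero(self, noise_free):
        out = ensemble_summary(noise_free, Mesh(0.0, 2.0, 0.01), n_paths=5,
                               seed=1)
        assert np.max(out["var"]) == pytest.approx(0.0, abs=1e-25)

    def test_single_path_mean_is_the_trajectory(self, canonical):
        from diabsde import integrate, sample_path
        from diabsde.schemes import _em_ensemble
        mesh = Mesh(0.0, 2.0, 0.01)
        out = ensemble_summary(canonical, mesh, n_paths=1, seed=6)
        # the mean of one path is that path; variance is reported as zero
        assert out["mean"].shape == (mesh.n_steps + 1, 2)
        assert np.all(out["var"] == 0.0)

    def test_mean_matches_closed_form_within_mc_error(self, canonical):
        mesh = Mesh(0.0, 5.0, 0.01)
        n = 500
        out = ensemble_summary(canonical, mesh, n_paths=n, seed=11)
        exact = ode_reference(5.0, canonical).as_array()
        se = np.sqrt(out["var"][-1] / n)
        assert np.all(np.abs(out["mean"][-1] - exact) < 3 * se + 10 * mesh.dt)
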