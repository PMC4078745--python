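"""Exact Gaussian-VAR analytics against closed forms and simulation oracles."""

import numpy as np
import pytest

from dyncausal.exceptions import (
    InvalidArgumentError,
    NumericalError,
    StationarityError,
)
from dyncausal.var_gaussian import (
    CovarianceSequence,
    GrangerResult,
    ObservationMap,
    VARModel,
    gaussian_cmi,
    instantaneous_causality,
    is_stationary,
    joint_lag_cov,
    nats_to_bits,
    observed_cov,
    simulate,
    stationary_cov,
    transfer_entropy,
)

from conftest import random_stable_var


def plugin_te(series: np.ndarray, src: int, dst: int, L: int) -> float:
    """Regression-residual transfer-entropy estimate: ½·ln(RSS_r / RSS_f).

    Independent of the analytic covariance path: ordinary least squares of
    dst_{t+1} on the truncated pasts, with and without the source past.
    """
    T = series.shape[0]
    t = np.arange(L - 1, T - 1)
    target = series[t + 1, dst]
    own = np.column_stack([series[t - l, dst] for l in range(L)])
    other = np.column_stack([series[t - l, src] for l in range(L)])
    ones = np.ones((len(t), 1))
    Xr = np.hstack([ones, own])
    Xf = np.hstack([ones, own, other])
    rss_r = np.sum((target - Xr @ np.linalg.lstsq(Xr, target, rcond=None)[0]) ** 2)
    rss_f = np.sum((target - Xf @ np.linalg.lstsq(Xf, target, rcond=None)[0]) ** 2)
    return 0.5 * np.log(rss_r / rss_f)


class TestStationarity:
    def test_zero_matrix_is_stationary(self):
        assert is_stationary(VARModel(np.zeros((2, 2))))

    def test_unit_root_is_not(self):
        assert not is_stationary(VARModel(np.array([[1.0]])))

    def test_agrees_with_trajectory_blowup(self, rng):
        for _ in range(10):
            C = rng.normal(0, 0.6, (2, 2))
            m = VARModel(C)
            rho = m.spectral_radius
            if abs(rho - 1.0) < 0.05:
                continue  # too close to the boundary to diagnose from a finite run
            v = np.ones(2)
            blew_up = False
            for _ in range(2000):
                v = C @ v
                if np.linalg.norm(v) > 1e12:
                    blew_up = True
                    break
            assert is_stationary(m) == (not blew_up)

    def test_stationary_cov_rejects_unstable(self):
        with pytest.raises(StationarityError):
            stationary_cov(VARModel(np.array([[1.1]])), 2)


class TestStationaryCov:
    def test_white_noise(self):
        cs = stationary_cov(VARModel(np.zeros((2, 2))), 3)
        assert np.allclose(cs.gamma(0), np.eye(2))
        assert np.allclose(cs.gamma(1), 0)

    def test_ar1_closed_form(self):
        c = 0.8
        cs = stationary_cov(VARModel(np.array([[c]])), 4)
        g0 = 1.0 / (1.0 - c**2)
        for k in range(5):
            assert cs.gamma(k)[0, 0] == pytest.approx(c**k * g0, rel=1e-12)

    def test_negative_lag_is_transpose(self, rng):
        cs = stationary_cov(random_stable_var(rng, 3), 2)
        assert np.allclose(cs.gamma(-2), cs.gamma(2).T)

    def test_matches_million_step_simulation(self, rng):
        m = random_stable_var(rng, 2, radius=0.7)
        lat, _ = simulate(m, None, 1_000_000, seed=7)
        x = lat.to_numpy()
        cs = stationary_cov(m, 1)
        n_batches = 100
        for lag in (0, 1):
            prods = x[lag:, :, None] * x[: len(x) - lag, None, :]
            batches = np.array_split(prods, n_batches)
            means = np.array([b.mean(axis=0) for b in batches])
            se = means.std(axis=0, ddof=1) / np.sqrt(n_batches)
            assert np.all(np.abs(means.mean(axis=0) - cs.gamma(lag)) < 3.5 * se + 1e-3)


class TestObservedCov:
    def test_identity_map_is_identity(self, rng):
        m = random_stable_var(rng, 3)
        cs = stationary_cov(m, 4)
        oc = observed_cov(cs, ObservationMap.identity(m.names), 4)
        assert np.allclose(oc.gammas, cs.gammas)

    def test_sum_of_independent_ar1(self):
        C = np.diag([0.5, 0.8])
        cs = stationary_cov(VARModel(C), 2)
        o = ObservationMap(np.array([[1.0, 1.0]]), signal_names=("S",))
        oc = observed_cov(cs, o, 2)
        expect = 1 / (1 - 0.25) + 1 / (1 - 0.64)
        assert oc.gamma(0)[0, 0] == pytest.approx(expect, rel=1e-12)

    def test_subsampled_ar1_lag1(self):
        c = 0.8
        cs = stationary_cov(VARModel(np.array([[c]])), 4)
        o = ObservationMap(np.array([[1.0]]), signal_names=("X",), subsample=2)
        oc = observed_cov(cs, o, 2)
        assert oc.gamma(1)[0, 0] == pytest.approx(c**2 * cs.gamma(0)[0, 0], rel=1e-12)

    def test_noise_only_at_lag_zero(self):
        cs = stationary_cov(VARModel(np.array([[0.5]])), 2)
        o = ObservationMap(
            np.array([[1.0]]), signal_names=("X",), noise_variances=[2.0]
        )
        oc = observed_cov(cs, o, 2)
        assert oc.gamma(0)[0, 0] == pytest.approx(cs.gamma(0)[0, 0] + 2.0)
        assert oc.gamma(1)[0, 0] == pytest.approx(cs.gamma(1)[0, 0])

    def test_insufficient_lags_raise(self, rng):
        cs = stationary_cov(random_stable_var(rng, 2), 3)
        o = ObservationMap(np.eye(2), subsample=2)
        with pytest.raises(InvalidArgumentError):
            observed_cov(cs, o, 2)


class TestGaussianCMI:
    def test_identity_covariance_gives_zero(self):
        assert gaussian_cmi(np.eye(4), [0], [1], [2, 3]) == 0.0

    def test_bivariate_closed_form(self):
        rho = 0.5
        J = np.array([[1.0, rho], [rho, 1.0]])
        assert gaussian_cmi(J, [0], [1]) == pytest.approx(
            -0.5 * np.log(1 - rho**2), rel=1e-12
        )
        assert gaussian_cmi(J, [0], [1]) == pytest.approx(0.14384, abs=1e-5)

    def test_matches_monte_carlo_plugin(self, rng):
        A = rng.normal(size=(4, 4))
        J = A @ A.T + 0.5 * np.eye(4)
        exact = gaussian_cmi(J, [0], [1], [2, 3])
        x = rng.multivariate_normal(np.zeros(4), J, size=400_000)
        Jh = np.cov(x.T)
        estimate = gaussian_cmi(Jh, [0], [1], [2, 3])
        assert estimate == pytest.approx(exact, abs=0.01)

    def test_overlapping_sets_raise(self):
        with pytest.raises(InvalidArgumentError):
            gaussian_cmi(np.eye(3), [0], [0])

    def test_singular_matrix_raises(self):
        J = np.ones((2, 2))
        with pytest.raises(NumericalError):
            gaussian_cmi(J, [0], [1])


class TestTransferEntropy:
    def test_decoupled_model_is_zero_both_ways(self):
        m = VARModel(np.diag([0.5, 0.7]), names=("X", "Y"))
        assert transfer_entropy(m, None, "X", "Y").is_zero()
        assert transfer_entropy(m, None, "Y", "X").is_zero()

    def test_unidirectional_coupling_signature(self):
        m = VARModel(np.array([[0.8, 0.5], [0.0, 0.8]]), names=("X", "Y"))
        assert transfer_entropy(m, None, "X", "Y").value <= 1e-9
        assert transfer_entropy(m, None, "Y", "X").value > 1e-3

    def test_observation_invariance_under_identity_map(self, rng):
        m = random_stable_var(rng, 3, names=("A", "B", "C"))
        o = ObservationMap.identity(m.names)
        direct = transfer_entropy(m, None, "A", "B", ("C",))
        through = transfer_entropy(m, o, "A", "B", ("C",))
        assert direct.value == through.value

    def test_converges_in_lag_depth(self, rng):
        for _ in range(5):
            m = random_stable_var(rng, 2, names=("X", "Y"))
            res = transfer_entropy(m, None, "X", "Y", L=20)
            assert res.converged

    def test_matches_regression_residual_plugin(self, rng):
        for _ in range(3):
            m = random_stable_var(rng, 2, names=("X", "Y"), radius=0.75)
            lat, _ = simulate(m, None, 400_000, seed=int(rng.integers(2**31)))
            x = lat.to_numpy()
            for src, dst in (("X", "Y"), ("Y", "X")):
                exact = transfer_entropy(m, None, src, dst, L=10).value
                est = plugin_te(x, m.index(src), m.index(dst), L=10)
                assert est == pytest.approx(exact, abs=0.005)

    def test_invalid_arguments(self):
        m = VARModel(np.diag([0.5, 0.5]), names=("X", "Y"))
        with pytest.raises(InvalidArgumentError):
            transfer_entropy(m, None, "X", "X")
        with pytest.raises(InvalidArgumentError):
            transfer_entropy(m, None, "X", "Y", ("X",))


class TestInstantaneousCausality:
    def test_fully_observed_diagonal_innovations_is_zero(self, rng):
        m = random_stable_var(rng, 3, names=("A", "B", "C"))
        assert instantaneous_causality(m, None, "A", "B", ("C",)).value <= 1e-12

    def test_latent_mediator_gives_zero(self, rng):
        for _ in range(10):
            c = rng.uniform(0.3, 0.7, size=5)
            C = np.array([[c[0], 0, 0], [c[3], c[1], 0], [0, c[4], c[2]]])
            m = VARModel(C, names=("X", "a", "Y"))
            o = ObservationMap.selecting(m, ("X", "Y"))
            assert instantaneous_causality(m, o, "X", "Y").value <= 1e-9
            assert transfer_entropy(m, o, "X", "Y").value > 1e-6

    def test_latent_common_driver_gives_positive(self, rng):
        for _ in range(10):
            c = rng.uniform(0.3, 0.7, size=5)
            C = np.array([[c[0], c[3], 0], [0, c[1], 0], [0, c[4], c[2]]])
            m = VARModel(C, names=("X", "a", "Y"))
            o = ObservationMap.selecting(m, ("X", "Y"))
            assert instantaneous_causality(m, o, "X", "Y").value > 1e-6
            assert transfer_entropy(m, o, "X", "Y").value > 1e-6


class TestSimulate:
    def test_deterministic_for_fixed_seed(self, rng):
        m = random_stable_var(rng, 2)
        a = simulate(m, None, 500, seed=3)[0]
        b = simulate(m, None, 500, seed=3)[0]
        assert a.equals(b)

    def test_white_noise_sample_covariance(self):
        m = VARModel(np.zeros((2, 2)))
        lat, _ = simulate(m, None, 100_000, seed=5)
        assert np.allclose(np.cov(lat.to_numpy().T), np.eye(2), atol=0.03)

    def test_ar1_sample_autocorrelation(self):
        m = VARModel(np.array([[0.8]]))
        lat, _ = simulate(m, None, 200_000, seed=11)
        x = lat.to_numpy()[:, 0]
        r1 = np.corrcoef(x[1:], x[:-1])[0, 1]
        se = np.sqrt((1 - 0.8**2) / len(x)) * 3
        assert abs(r1 - 0.8) < 3 * max(se, 1e-3)

    def test_nonstationary_raises(self):
        with pytest.raises(StationarityError):
            simulate(VARModel(np.array([[1.2]])), None, 100, seed=0)


class TestResultType:
    def test_negative_roundoff_clipped_to_zero(self):
        assert GrangerResult(value=-1e-13, lag_depth=20, converged=True).value == 0.0

    def test_bits_conversion(self):
        assert nats_to_bits(np.log(2.0)) == pytest.approx(1.0)
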