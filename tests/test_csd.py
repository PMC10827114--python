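"""Synaptic kernels, spatial inference, penalized cost, and the CSD fit."""

import numpy as np
import pytest

from lpa.csd import (
    CSDModel,
    KernelParams,
    csd_cost,
    deviation_from_zero,
    exponential_kernel,
    infer_spatial,
    lambda_sweep,
    postsynaptic_profiles,
)
from lpa.containers import LaminarSignal
from lpa.metrics import pearson_corr, relative_mse


def _csd_signal(values, spacing=40.0, dt=1e-3):
    values = np.asarray(values, dtype=float)
    return LaminarSignal(values=values,
                         depths_um=np.arange(values.shape[0]) * spacing,
                         t=np.arange(values.shape[1]) * dt, dt=dt, kind="CSD")


class TestExponentialKernel:
    dt = 1e-3
    t = np.arange(0, 0.3, 1e-3)

    def test_causal_before_delay(self):
        h = exponential_kernel(0.02, 0.01, self.t, self.dt)
        assert np.all(h[self.t + self.dt <= 0.01] == 0)

    def test_closed_form_values_at_delay_and_tau(self):
        tau, delta = 0.05, 0.01  # tau >> dt so bin averages ~ pointwise
        h = exponential_kernel(tau, delta, self.t, self.dt)
        i0 = int(round(delta / self.dt))
        assert h[i0] == pytest.approx(1.0 / tau, rel=0.02)
        i1 = int(round((delta + tau) / self.dt))
        assert h[i1] == pytest.approx(np.exp(-1.0) / tau, rel=0.02)

    def test_mass_matches_analytic_integral(self):
        """Sum h dt over a 10-tau window equals 1 - e^-10 (the kernel is
        bin-averaged, so mass is exact for any tau)."""
        tau, delta = 0.02, 0.005
        t = np.arange(0, delta + 10 * tau, self.dt)
        h = exponential_kernel(tau, delta, t, self.dt)
        expected = 1.0 - np.exp(-(t[-1] + self.dt - delta) / tau)
        assert np.sum(h) * self.dt == pytest.approx(expected, rel=1e-10)
        assert np.sum(h) * self.dt == pytest.approx(1 - np.exp(-10), rel=1e-2)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            exponential_kernel(-0.01, 0.0, self.t, self.dt)
        with pytest.raises(ValueError):
            KernelParams(tau_s=0.01, delta_s=-0.001)


class TestPostsynapticProfiles:
    dt = 1e-3

    def test_dirac_rate_returns_kernel(self):
        B = 200
        rate = np.zeros((1, B))
        rate[0, 0] = 1.0 / self.dt
        k = KernelParams(tau_s=0.02, delta_s=0.005)
        R = postsynaptic_profiles(rate, [k], self.dt)
        t = np.arange(B) * self.dt
        np.testing.assert_allclose(R[0], exponential_kernel(0.02, 0.005, t, self.dt))

    def test_tiny_tau_approximates_pure_delay(self):
        rng = np.random.default_rng(0)
        B = 150
        rate = rng.random((1, B))
        delay_bins = 7
        k = KernelParams(tau_s=1e-4, delta_s=delay_bins * self.dt)
        R = postsynaptic_profiles(rate, [k], self.dt)
        np.testing.assert_allclose(R[0, delay_bins + 1 :],
                                   rate[0, 1 : B - delay_bins], rtol=0.05,
                                   atol=0.05 * rate.max())

    def test_step_response_closed_form(self):
        c, tau, delta = 4.0, 0.02, 0.01
        B = 400
        rate = np.full((1, B), c)
        R = postsynaptic_profiles(rate, [KernelParams(tau, delta)], self.dt)
        t = np.arange(B) * self.dt
        for tj in (0.05, 0.1, 0.2):
            j = int(round(tj / self.dt))
            expected = c * (1.0 - np.exp(-(t[j] + self.dt - delta) / tau))
            assert R[0, j] == pytest.approx(expected, rel=1e-9)
            # and agrees with the continuous-time expression to O(dt/tau)
            assert R[0, j] == pytest.approx(
                c * (1 - np.exp(-(tj - delta) / tau)), rel=0.06)

    def test_linear_in_rates(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((2, 100)), rng.random((2, 100))
        ks = [KernelParams(0.01, 0.002), KernelParams(0.03, 0.004)]
        lhs = postsynaptic_profiles(2 * a + b, ks, self.dt)
        rhs = 2 * postsynaptic_profiles(a, ks, self.dt) + \
            postsynaptic_profiles(b, ks, self.dt)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_kernel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            postsynaptic_profiles(np.ones((2, 50)), [KernelParams(0.01, 0.0)],
                                  self.dt)


class TestInferSpatial:
    def test_exact_recovery_from_independent_rows(self):
        rng = np.random.default_rng(2)
        L_true = rng.standard_normal((10, 3))
        R = rng.standard_normal((3, 60))
        L, full = infer_spatial(L_true @ R, R)
        np.testing.assert_allclose(L, L_true, atol=1e-10)
        assert full

    def test_duplicated_row_splits_profile_minimum_norm(self):
        """Perfect synchrony: the pseudoinverse splits the joint profile
        between the duplicated populations, but their sum equals the
        single-population truth."""
        rng = np.random.default_rng(3)
        l_true = rng.standard_normal(8)
        r = rng.standard_normal(50)
        C = np.outer(l_true, r)
        R = np.vstack([r, r])
        L, full = infer_spatial(C, R)
        assert not full
        np.testing.assert_allclose(L[:, 0] + L[:, 1], l_true, atol=1e-8)
        np.testing.assert_allclose(L[:, 0], L[:, 1], atol=1e-8)

    def test_zero_csd_gives_zero_profiles(self):
        L, _ = infer_spatial(np.zeros((5, 30)), np.ones((2, 30)))
        np.testing.assert_array_equal(L, 0.0)


class TestDeviationAndCost:
    def test_pure_dipoles_have_zero_deviation(self):
        C = np.array([[1.0, 2.0], [-1.0, -2.0]])
        assert deviation_from_zero(C) == 0.0

    def test_hand_arithmetic_all_ones(self):
        C = np.ones((4, 10))
        assert deviation_from_zero(C) == pytest.approx(4.0)
        assert deviation_from_zero(C, normalized=True) == pytest.approx(4.0)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(4)
        C = rng.standard_normal((6, 9))
        assert deviation_from_zero(-C) == pytest.approx(deviation_from_zero(C))

    def test_all_zero_normalized_deviation_is_zero(self):
        assert deviation_from_zero(np.zeros((3, 4)), normalized=True) == 0.0

    def test_cost_zero_for_perfect_zero_sum_reconstruction(self):
        C = np.array([[1.0, -2.0], [-1.0, 2.0]])
        for lam in (0.0, 3.0):
            assert csd_cost(C, C, lam) == 0.0

    def test_lambda_zero_reduces_to_relative_mse(self):
        rng = np.random.default_rng(5)
        C, C_est = rng.random((4, 7)), rng.random((4, 7))
        assert csd_cost(C, C_est, 0.0) == pytest.approx(relative_mse(C, C_est))

    def test_hand_arithmetic_penalized_cost(self):
        B = 5
        C = np.tile([[1.0], [-1.0]], (1, B))
        C_est = np.tile([[1.0], [0.0]], (1, B))
        for lam in (0.0, 2.0):
            assert csd_cost(C, C_est, lam) == pytest.approx(0.5 + lam * 1.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            csd_cost(np.ones((2, 2)), np.ones((2, 2)), -1.0)


class TestCSDModel:
    def test_contributions_sum_to_reconstruction_exactly(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        res = CSDModel(ds.csd, ds.rates).fit(seed=0, maxiter=15, popsize=8)
        np.testing.assert_array_equal(res.contributions.sum(axis=0), res.C_est)
        np.testing.assert_allclose(res.C_est, res.L @ res.R, rtol=1e-10)

    def test_fixed_kernels_pipeline_reproducible(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        model = CSDModel(ds.csd, ds.rates)
        out1 = model._eval(ds.kernels_true)
        out2 = model._eval(ds.kernels_true)
        np.testing.assert_array_equal(out1[2], out2[2])
        assert out1[3] == out2[3]

    def test_true_kernels_give_near_zero_cost_on_noiseless_data(
            self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        model = CSDModel(ds.csd, ds.rates)
        cost = model._eval(ds.kernels_true)[3]
        assert cost < 1e-10

    def test_relative_mse_non_increasing_in_population_count(
            self, noiseless_csd_dataset):
        """At lambda = 0, adding a temporal regressor cannot worsen the
        least-squares fit (nested population sets)."""
        ds = noiseless_csd_dataset
        kernels = ds.kernels_true
        errs = []
        for n in (2, 3, 4):
            model = CSDModel(ds.csd, ds.rates[:n])
            _, _, C_est, _, _ = model._eval(kernels[:n])
            errs.append(relative_mse(model._C, C_est))
        assert errs[0] >= errs[1] >= errs[2]

    def test_mismatched_time_grid_rejected(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        with pytest.raises(ValueError):
            CSDModel(ds.csd, ds.rates[:, :-5])

    def test_infeasible_bounds_rejected(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        with pytest.raises(ValueError):
            CSDModel(ds.csd, ds.rates, tau_bounds_s=(0.1, 0.01))


class TestLambdaSweep:
    def test_single_lambda_grid_returns_that_fit(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        table, results, best = lambda_sweep(ds.csd, ds.rates, [0.5], seed=0,
                                            maxiter=10, popsize=8)
        assert len(results) == 1 and best == 0
        assert table["lambda"].tolist() == [0.5]

    def test_unsorted_grid_rejected(self, noiseless_csd_dataset):
        ds = noiseless_csd_dataset
        with pytest.raises(ValueError):
            lambda_sweep(ds.csd, ds.rates, [1.0, 0.0], seed=0)
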