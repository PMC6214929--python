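"""Blahut–Arimoto, mutual information, channel discretization, product
channels, and the small-noise capacity approximation."""

import math

import numpy as np
import pytest

from sigcap.core import ConfigurationError, make_grid
from sigcap.fixtures import bsc, bsc_capacity, gaussian_location_channel
from sigcap.reference import (
    BAConfig,
    DiscretizedChannel,
    blahut_arimoto,
    discretize_channel,
    mutual_information,
    product_channel,
    small_noise_capacity,
)
from sigcap.sensor import SensorParams, sensor_channel

SQRT_2PIE = math.sqrt(2.0 * math.pi * math.e)


class TestDiscretize:
    def test_discrete_alphabet_passthrough(self):
        p = SensorParams(L=4, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        chan = sensor_channel(p)
        grid = np.geomspace(0.1, 10, 7)
        dc = discretize_channel(chan, grid)
        assert dc.n == 5 and dc.m == 7
        np.testing.assert_allclose(dc.Q.sum(axis=1), 1.0, atol=1e-12)

    def test_stochastic_matrix_is_identity_operation(self):
        Q = np.array([[0.2, 0.8], [0.7, 0.3]])
        dc = DiscretizedChannel(np.array([[0.0], [1.0]]), np.array([0, 1]), Q)
        np.testing.assert_array_equal(dc.Q, Q)

    def test_gaussian_binning_captures_mass(self):
        """Binning a unit Gaussian on [-6 sigma, 6 sigma] leaves < 1e-4 of
        probability outside (Gaussian tail bound)."""
        chan = gaussian_location_channel(sigma=1.0, bounds=(0.0, 1.0), n_nodes=3)
        edges = np.linspace(-6.0, 7.0, 101)
        dc = discretize_channel(chan, chan.input_space, y_spec=edges)
        assert dc.meta["row_mass"].min() >= 0.9999
        assert not dc.meta["warnings"]

    def test_truncated_support_warns(self):
        chan = gaussian_location_channel(sigma=1.0, bounds=(0.0, 1.0), n_nodes=3)
        dc = discretize_channel(chan, chan.input_space,
                                y_spec=np.linspace(-0.5, 1.5, 11))
        assert dc.meta["warnings"]


class TestBlahutArimoto:
    def test_noiseless_binary_channel(self):
        res = blahut_arimoto(bsc(0.0))
        assert res.value_bits == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.optimal_input.weights, [0.5, 0.5], atol=1e-6)

    def test_useless_channel(self):
        res = blahut_arimoto(bsc(0.5))
        assert res.value_bits == pytest.approx(0.0, abs=1e-9)

    def test_bsc_closed_form(self):
        """C = 1 - H2(p), computed independently from the entropy formula."""
        res = blahut_arimoto(bsc(0.11), BAConfig(tol_bits=1e-8))
        assert res.value_bits == pytest.approx(bsc_capacity(0.11), abs=1e-8)
        assert res.diagnostics["bound_gap_bits"] < 1e-8
        assert res.diagnostics["converged"]

    def test_lower_bound_trace_nondecreasing(self):
        p = SensorParams(L=8, H=1.0, lam=10.0, m_F=0.5, sigma_XF=0.5)
        chan = sensor_channel(p, make_grid([(0.05, 20.0)], 41, "log"))
        dc = discretize_channel(chan, chan.input_space)
        res = blahut_arimoto(dc, BAConfig(tol_bits=1e-7))
        trace = res.diagnostics["lower_bound_trace_bits"]
        assert len(trace) >= 2
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_non_convergence_is_flagged(self):
        # asymmetric channel: the uniform start is not optimal, so a 2-step
        # budget cannot certify a 1e-12 gap
        Q = np.array([[0.9, 0.1], [0.3, 0.7]])
        dc = DiscretizedChannel(np.array([[0.0], [1.0]]), np.array([0, 1]), Q)
        res = blahut_arimoto(dc, BAConfig(tol_bits=1e-12, max_iter=2))
        assert not res.diagnostics["converged"]
        assert "warning" in res.diagnostics

    def test_overrelaxed_matches_plain(self):
        p = SensorParams(L=16, H=1.0, lam=1.0, m_F=0.5, sigma_XF=1.0)
        chan = sensor_channel(p, make_grid([(0.05, 20.0)], 31, "log"))
        dc = discretize_channel(chan, chan.input_space)
        plain = blahut_arimoto(dc, BAConfig(tol_bits=1e-7))
        fast = blahut_arimoto(dc, BAConfig(tol_bits=1e-7, overrelax=2.0))
        assert fast.value_bits == pytest.approx(plain.value_bits, abs=2e-7)


class TestMutualInformation:
    def test_deterministic_bijection(self):
        m = 4
        dc = DiscretizedChannel(np.arange(m, dtype=float)[:, None],
                                np.arange(m), np.eye(m))
        assert mutual_information(np.full(m, 0.25), dc) == pytest.approx(2.0)

    def test_input_independent_channel(self):
        Q = np.tile([0.3, 0.7], (3, 1))
        dc = DiscretizedChannel(np.arange(3.0)[:, None], np.arange(2), Q)
        assert mutual_information(np.array([0.2, 0.5, 0.3]), dc) == pytest.approx(0.0)

    def test_dominated_by_capacity(self):
        dc = bsc(0.2)
        cap = blahut_arimoto(dc).value_bits
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = rng.dirichlet([1.0, 1.0])
            assert mutual_information(p, dc) <= cap + 1e-6

    def test_support_mismatch_rejected(self):
        dc = bsc(0.2)
        with pytest.raises(ConfigurationError):
            mutual_information(np.array([1.0]), dc)


class TestProductChannel:
    def test_identity_for_single_copy(self):
        dc = bsc(0.3)
        np.testing.assert_array_equal(product_channel(dc, 1).Q, dc.Q)

    def test_two_copies_outer_product_rows(self):
        dc = bsc(0.3)
        pc = product_channel(dc, 2)
        np.testing.assert_allclose(pc.Q[0], np.kron(dc.Q[0], dc.Q[0]))
        assert pc.n == 4

    def test_capacity_nondecreasing_in_copies(self):
        p = SensorParams(L=2, H=1.0, lam=10.0, m_F=0.5, sigma_XF=1.0)
        chan = sensor_channel(p, make_grid([(0.1, 10.0)], 5, "log"))
        dc = discretize_channel(chan, chan.input_space)
        caps = [blahut_arimoto(product_channel(dc, N)).value_bits for N in (1, 2, 4)]
        assert caps[0] <= caps[1] + 1e-9 <= caps[2] + 2e-9

    def test_tractability_guard(self):
        dc = bsc(0.3)
        with pytest.raises(ConfigurationError):
            product_channel(dc, 30)


class TestSmallNoise:
    def test_gaussian_cancellation(self):
        space = make_grid([(0.0, SQRT_2PIE)], 101, "lin")
        res = small_noise_capacity(lambda x: x, lambda x: 1.0, space)
        assert res.value_bits == pytest.approx(0.0, abs=1e-9)

    def test_constant_mean_has_no_capacity(self):
        space = make_grid([(0.0, 1.0)], 11)
        res = small_noise_capacity(lambda x: 3.0, lambda x: 1.0, space)
        assert res.value_bits == -math.inf
        assert res.diagnostics["failure"] == "zero_sensitivity"

    def test_binomial_small_noise_equals_asymptotic(self):
        """For a binomial output the Gaussian small-noise information
        (dmu/dx)^2 / sigma^2 equals the exact Fisher information, so C_SN
        and C_A agree (within FD/quadrature error)."""
        from sigcap.capacity import asymptotic_capacity
        from sigcap.core import FIMField
        from sigcap.sensor import sensor_fim_grid

        p = SensorParams(L=100, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        space = make_grid([(0.05, 20.0)], 101, "log")
        chan = sensor_channel(p, space)

        def mean_fn(x):
            return chan.moments(x)[0][0]

        def sd_fn(x):
            return math.sqrt(chan.moments(x)[1][0, 0])

        c_sn = small_noise_capacity(mean_fn, sd_fn, space).value_bits
        field = FIMField(space, sensor_fim_grid(p, space.grids[0])[:, None, None])
        c_a = asymptotic_capacity(field).value_bits
        assert abs(c_sn - c_a) < 0.02

    def test_vanishing_sigma_rejected(self):
        space = make_grid([(0.0, 1.0)], 5)
        with pytest.raises(ConfigurationError):
            small_noise_capacity(lambda x: x, lambda x: 0.0, space)

    def test_scalar_input_only(self):
        space = make_grid([(0.0, 1.0), (0.0, 1.0)], 3)
        with pytest.raises(ConfigurationError):
            small_noise_capacity(lambda x: x, lambda x: 1.0, space)
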