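"""Asymptotic capacity, Jeffreys prior, N-cell scaling, estimator
covariance, discrimination error, and isolines."""

import math

import numpy as np
import pytest

from sigcap.capacity import (
    DiscriminationQuery,
    Quadrature,
    asymptotic_capacity,
    clamp_for_single_cell,
    discrimination_error,
    estimator_covariance,
    fim_isolines,
    jeffreys_prior,
    population_capacity,
    resolvable_inputs,
    trapezoid_weights,
)
from sigcap.core import CapacityResult, ConfigurationError, FIMField, make_grid
from sigcap.sensor import SensorParams, sensor_fim_grid

SQRT_2PIE = math.sqrt(2.0 * math.pi * math.e)


def constant_field(bounds, n, value=1.0, k=1):
    if k == 1:
        space = make_grid([bounds], n, "lin")
        mats = np.full((n, 1, 1), value)
    else:
        space = make_grid([bounds] * k, n, "lin")
        mats = np.tile(np.eye(k) * value, (n**k, 1, 1))
    return FIMField(space, mats)


class TestAsymptoticCapacity:
    def test_gaussian_location_zero_and_one_bit(self):
        """Y ~ N(x, 1) on [0, sqrt(2 pi e)]: the Jeffreys integral exactly
        cancels the (2 pi e)^(-1/2) prefactor -> 0 bits; doubling the range
        adds exactly one bit (closed form log2(range / (sigma sqrt(2 pi e))))."""
        res = asymptotic_capacity(constant_field((0.0, SQRT_2PIE), 101))
        assert res.value_bits == pytest.approx(0.0, abs=1e-9)
        res2 = asymptotic_capacity(constant_field((0.0, 2 * SQRT_2PIE), 101))
        assert res2.value_bits == pytest.approx(1.0, abs=1e-9)
        assert res.diagnostics["quadrature_error_estimate"] < 1e-9

    def test_independent_pair_adds_capacities(self):
        """For independent coordinates |FIM| factorizes, so a pair of 0-bit
        scalar channels has 0 bits jointly."""
        res = asymptotic_capacity(constant_field((0.0, SQRT_2PIE), 41, k=2))
        assert res.k == 2
        assert res.value_bits == pytest.approx(0.0, abs=1e-9)

    def test_all_singular_field_is_flagged(self):
        res = asymptotic_capacity(constant_field((0.0, 1.0), 11, value=0.0))
        assert res.value_bits == -math.inf
        assert res.diagnostics["failure"] == "all_singular_field"

    def test_monte_carlo_quadrature_agrees(self):
        field = constant_field((0.0, SQRT_2PIE), 51)
        mc = asymptotic_capacity(field, Quadrature("monte_carlo", 20_000, seed=4))
        assert mc.value_bits == pytest.approx(0.0, abs=0.02)

    def test_reparameterization_invariance_log_map(self):
        """C_A is invariant under x = exp(u) when the FIM transforms
        covariantly (FIM_u = FIM_x e^{2u}); binomial sensor fixture."""
        p = SensorParams(L=100, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        space_x = make_grid([(0.1, 10.0)], 201, "log")
        xs = space_x.grids[0]
        field_x = FIMField(space_x, sensor_fim_grid(p, xs)[:, None, None])
        c_x = asymptotic_capacity(field_x).value_bits

        us = np.log(xs)
        space_u = make_grid([(us[0], us[-1])], 201, "lin")
        fim_u = sensor_fim_grid(p, np.exp(space_u.grids[0])) * np.exp(
            2 * space_u.grids[0]
        )
        c_u = asymptotic_capacity(FIMField(space_u, fim_u[:, None, None])).value_bits
        assert abs(c_x - c_u) < 0.02


class TestJeffreysPrior:
    def test_constant_field_gives_uniform_interior(self):
        field = constant_field((0.0, 1.0), 5)
        jp = jeffreys_prior(field)
        w = jp.weights
        # uniform density: weights equal the trapezoid cell sizes
        np.testing.assert_allclose(w, trapezoid_weights(field.input_space))

    def test_binomial_fixture_closed_form_weights(self):
        p = SensorParams(L=100, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        space = make_grid([(0.1, 10.0)], 21, "log")
        xs = space.grids[0]
        fim = p.L * p.H / (xs * (xs + p.H) ** 2)
        field = FIMField(space, fim[:, None, None])
        jp = jeffreys_prior(field)
        expected = np.sqrt(fim) * trapezoid_weights(space)
        np.testing.assert_allclose(jp.weights, expected / expected.sum(), rtol=1e-12)

    def test_singular_node_gets_zero_weight(self):
        space = make_grid([(0.0, 1.0)], 3)
        field = FIMField(space, np.array([[[1.0]], [[0.0]], [[1.0]]]))
        jp = jeffreys_prior(field)
        assert jp.weights[1] == 0.0

    def test_all_singular_errors(self):
        with pytest.raises(ConfigurationError):
            jeffreys_prior(constant_field((0.0, 1.0), 3, value=0.0))


class TestScalingLaws:
    def test_population_capacity_arithmetic(self):
        c = CapacityResult(value_bits=1.0, method="asymptotic", k=2)
        assert population_capacity(c, 4).value_bits == pytest.approx(3.0)
        assert population_capacity(c, 1).value_bits == pytest.approx(1.0)

    def test_two_bit_gap_preserved_at_any_population_size(self):
        """Systems at C_A = -1 and +1 bits differ by exactly 2 bits in C_N."""
        lo = CapacityResult(value_bits=-1.0, method="asymptotic", k=1)
        hi = CapacityResult(value_bits=1.0, method="asymptotic", k=1)
        for N in (1, 64, 4096):
            gap = population_capacity(hi, N).value_bits - population_capacity(
                lo, N
            ).value_bits
            assert gap == pytest.approx(2.0)

    def test_population_requires_positive_n(self):
        c = CapacityResult(value_bits=0.0, method="asymptotic", k=1)
        with pytest.raises(ConfigurationError):
            population_capacity(c, 0)

    @pytest.mark.parametrize(
        "bits,k,N,expected",
        [(2.0, 1, 1, 4.0), (0.0, 2, 16, 16.0), (-1.0, 2, 2, 1.0)],
    )
    def test_resolvable_inputs(self, bits, k, N, expected):
        assert resolvable_inputs(bits, k, N) == pytest.approx(expected)


class TestEstimatorCovariance:
    def test_scalar_inverse_scaling(self):
        cov = estimator_covariance(np.array([[25.0]]), N=4)
        assert cov[0, 0] == pytest.approx(0.01)

    def test_identity(self):
        np.testing.assert_allclose(estimator_covariance(np.eye(2), 1), np.eye(2))

    def test_singular_fim_names_null_direction(self):
        with pytest.raises(np.linalg.LinAlgError) as err:
            estimator_covariance(np.array([[1.0, 1.0], [1.0, 1.0]]), 1)
        msg = str(err.value)
        # null direction is (1, -1)/sqrt(2) up to sign
        assert "0.707107" in msg or "-0.707107" in msg

    def test_precision_frequency_link(self):
        """The Jeffreys weights are proportional to the inverse estimator
        uncertainty: frequent signals are recognized with high precision."""
        p = SensorParams(L=100, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        space = make_grid([(0.2, 5.0)], 31, "log")
        xs = space.grids[0]
        fim = sensor_fim_grid(p, xs)
        field = FIMField(space, fim[:, None, None])
        jp = jeffreys_prior(field)
        inv_sd = np.array(
            [1.0 / math.sqrt(estimator_covariance(np.array([[f]]), 1)[0, 0])
             for f in fim]
        )
        expected = inv_sd * trapezoid_weights(space)
        np.testing.assert_allclose(jp.weights, expected / expected.sum(), rtol=1e-9)


class TestDiscriminationError:
    def test_no_change_no_detection(self):
        q = DiscriminationQuery(x0=[1.0], x1=[1.0], N=10)
        assert discrimination_error(q, np.array([[5.0]])) == 1.0

    def test_scalar_exponential_form(self):
        q = DiscriminationQuery(x0=[0.0], x1=[1.0], N=1)
        assert discrimination_error(q, np.array([[1.0]])) == pytest.approx(
            math.exp(-1.0)
        )

    def test_null_direction_never_discriminated(self):
        """Parallel isolines: along a null eigenvector the error stays 1 for
        any population size."""
        fim = np.array([[1.0, 0.0], [0.0, 0.0]])
        for N in (1, 100, 10_000):
            q = DiscriminationQuery(x0=[0.0, 0.0], x1=[0.0, 5.0], N=N)
            assert discrimination_error(q, fim) == 1.0

    def test_query_validation(self):
        with pytest.raises(ConfigurationError):
            DiscriminationQuery(x0=[0.0], x1=[1.0], N=0)
        space = make_grid([(0.0, 1.0)], 3)
        with pytest.raises(ConfigurationError):
            DiscriminationQuery(x0=[0.0], x1=[2.0], N=1, input_space=space)

    def test_matches_monte_carlo_likelihood_ratio_to_leading_order(self):
        """On the binomial sensor, the exponential-order of the missed-change
        probability from a simulated likelihood-ratio test agrees with the
        quadratic form N (x1-x0)^2 FIM within a factor of 2."""
        from sigcap.sensor import sensor_channel

        p = SensorParams(L=100, H=1.0, lam=10.0, m_F=0.0, sigma_XF=0.0)
        chan = sensor_channel(p)
        x0, N = 1.0, 50
        fim = float(sensor_fim_grid(p, np.array([x0]))[0])
        dx = math.sqrt(1.5 / (N * fim))  # small shift, N * quad_form = 1.5
        x1 = x0 + dx
        quad_form = N * dx**2 * fim
        rng_trials = 4000
        misses = 0
        y = np.stack([
            chan.sample(np.array([x1]), N, seed=1000 + t) for t in range(rng_trials)
        ])  # draws under the changed input
        ll1 = chan.log_density(y, np.array([x1])).reshape(rng_trials, N).sum(axis=1)
        ll0 = chan.log_density(y, np.array([x0])).reshape(rng_trials, N).sum(axis=1)
        misses = float(np.mean(ll0 >= ll1))
        ratio = -math.log(misses) / quad_form
        assert 0.5 <= ratio <= 2.0


class TestClamping:
    def test_negative_clamped_and_flagged(self):
        c = CapacityResult(value_bits=-0.3, method="asymptotic", k=1)
        out = clamp_for_single_cell(c)
        assert out.value_bits == 0.0
        assert out.diagnostics["clamped"] is True

    def test_positive_untouched(self):
        c = CapacityResult(value_bits=1.7, method="small_noise", k=1)
        out = clamp_for_single_cell(c)
        assert out.value_bits == 1.7 and out.diagnostics["clamped"] is False

    def test_exact_zero_unflagged(self):
        c = CapacityResult(value_bits=0.0, method="asymptotic", k=1)
        assert clamp_for_single_cell(c).diagnostics["clamped"] is False

    def test_ba_results_not_clampable(self):
        c = CapacityResult(value_bits=1.0, method="blahut_arimoto", k=1)
        with pytest.raises(ConfigurationError):
            clamp_for_single_cell(c)


class TestIsolines:
    def test_identity_fim_unit_circle(self):
        (iso,) = fim_isolines(np.eye(2), [0.0, 0.0], [1.0])
        assert iso.kind == "ellipse"
        assert iso.semi_axes == pytest.approx((1.0, 1.0))

    def test_anisotropic_semi_axes(self):
        (iso,) = fim_isolines(np.diag([4.0, 1.0]), [0.0, 0.0], [1.0])
        assert sorted(iso.semi_axes) == pytest.approx([0.5, 1.0])

    def test_singular_fim_gives_parallel_lines(self):
        (iso,) = fim_isolines(np.array([[1.0, 0.0], [0.0, 0.0]]), [0, 0], [1.0])
        assert iso.kind == "parallel_lines"
        np.testing.assert_allclose(np.abs(iso.normal), [1.0, 0.0], atol=1e-12)
        assert iso.offset == pytest.approx(1.0)

    def test_only_two_dimensional(self):
        with pytest.raises(ConfigurationError):
            fim_isolines(np.eye(3), [0, 0, 0], [1.0])
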