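"""LNA engine: macroscopic trajectories, covariance propagation, cross-time
blocks, extrinsic mixing, and the network-to-channel wrapper."""

import numpy as np
import pytest

from sigcap.core import ConfigurationError, make_grid
from sigcap.fixtures import birth_death_network
from sigcap.lna import (
    ExtrinsicSpec,
    ReactionNetwork,
    channel_from_network,
    extrinsic_mixture_moments,
    lna_covariance,
    mixture_moments,
    moments_batch,
    mre_trajectory,
)
from tests.conftest import gillespie_samples


def linear_cascade(b=4.0, k1=0.4, k2=0.6, k3=0.3):
    """0 -> A -> (catalyzes) B; both degrade: a 2-species linear network."""

    def prop(phi, t, params, x):
        A, B = phi[..., 0], phi[..., 1]
        return np.stack(
            [np.full_like(A, b), k1 * A, k2 * A, k3 * B], axis=-1
        )

    stoich = np.array([
        [1.0, -1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0, -1.0],
    ])
    return ReactionNetwork(("A", "B"), np.array([0.0, 0.0]), stoich, prop,
                           name="cascade")


class TestMreTrajectory:
    def test_zero_reaction_network_is_constant(self):
        net = ReactionNetwork(("A",), np.array([7.0]), np.zeros((1, 0)),
                              lambda phi, t, p, x: np.zeros(phi.shape[:-1] + (0,)))
        out = mre_trajectory(net, [0.0], [0.0, 1.0, 5.0])
        np.testing.assert_array_equal(out[:, 0], [7.0, 7.0, 7.0])

    def test_exponential_decay_closed_form(self):
        k = 0.7

        def prop(phi, t, p, x):
            return (k * phi[..., 0])[..., None]

        net = ReactionNetwork(("A",), np.array([100.0]), np.array([[-1.0]]), prop)
        times = np.array([0.5, 1.0, 3.0])
        out = mre_trajectory(net, [0.0], times)
        np.testing.assert_allclose(out[:, 0], 100.0 * np.exp(-k * times), rtol=1e-7)

    def test_birth_death_reaches_stationary_mean(self):
        fx = birth_death_network()
        out = mre_trajectory(fx.obj, [0.0], [40.0])
        assert out[-1, 0] == pytest.approx(fx.oracle["stationary_mean"], rel=1e-6)


class TestLnaCovariance:
    def test_birth_death_closed_form_moments(self):
        """Linear birth-death: the LNA is exact.  Mean/variance follow the
        moment ODEs; the stationary law is Poisson (var = mean = b/k) and the
        autocovariance decays as exp(-k tau) (Ornstein-Uhlenbeck form)."""
        fx = birth_death_network()
        b, k = fx.oracle["birth"], fx.oracle["death"]
        times = np.array([8.0, 12.0, 30.0])
        tm = lna_covariance(fx.obj, [0.0], times, dt=0.01)
        mean_30 = tm.mean[2]
        var_30 = tm.cov[2, 2]
        assert mean_30 == pytest.approx(b / k, rel=1e-5)
        assert var_30 == pytest.approx(b / k, rel=1e-5)
        # transient autocovariance: Cov(t1, t2) = Var(t1) exp(-k (t2 - t1))
        assert tm.cov[0, 1] == pytest.approx(
            tm.cov[0, 0] * np.exp(-k * 4.0), rel=1e-5
        )

    def test_deterministic_start_has_zero_initial_covariance(self):
        fx = birth_death_network()
        tm = lna_covariance(fx.obj, [0.0], [1e-3], dt=1e-4)
        assert tm.cov[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_step_halving_converges(self):
        fx = birth_death_network()
        t = [3.0, 9.0]
        coarse = lna_covariance(fx.obj, [0.0], t, dt=0.2)
        fine = lna_covariance(fx.obj, [0.0], t, dt=0.1)
        assert np.abs(coarse.cov - fine.cov).max() < 1e-5

    def test_cross_time_switch_zeroes_off_diagonal(self):
        fx = birth_death_network()
        tm = lna_covariance(fx.obj, [0.0], [3.0, 9.0], dt=0.05, cross_time=False)
        assert tm.cov[0, 1] == 0.0 and tm.cov[1, 1] > 0

    def test_cascade_matches_gillespie(self):
        """2-species linear cascade: LNA mean/variance/cross-species moments
        agree with exact stochastic simulation within 3 standard errors."""
        net = linear_cascade()
        times = np.array([5.0, 10.0])
        tm = lna_covariance(net, [0.0], times, dt=0.01)

        def rate_fn(states):
            A, B = states[:, 0], states[:, 1]
            return np.stack([np.full_like(A, 4.0), 0.4 * A, 0.6 * A, 0.3 * B],
                            axis=-1)

        n_runs = 10_000
        samp = gillespie_samples(net.stoich, rate_fn, net.x0, times, n_runs,
                                 seed=77)
        # stacked order: (A(t1), B(t1), A(t2), B(t2))
        flat = samp.reshape(n_runs, -1)
        mean_hat = flat.mean(axis=0)
        se_mean = flat.std(axis=0, ddof=1) / np.sqrt(n_runs)
        assert (np.abs(tm.mean - mean_hat) < 3 * se_mean + 1e-9).all()
        centered = flat - mean_hat
        for i in range(4):
            for j in range(i, 4):
                prod = centered[:, i] * centered[:, j]
                se = prod.std(ddof=1) / np.sqrt(n_runs)
                assert abs(tm.cov[i, j] - prod.mean()) < 3 * se + 1e-9, (i, j)


class TestExtrinsicMixing:
    def test_zero_cv_short_circuits(self):
        fx = birth_death_network()
        ext = ExtrinsicSpec(varying=("A",), cv=0.0)
        a = extrinsic_mixture_moments(fx.obj, [0.0], [2.0, 5.0], ext, dt=0.05)
        b = lna_covariance(fx.obj, [0.0], [2.0, 5.0], dt=0.05)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.cov, b.cov)

    @pytest.mark.parametrize("quadrature", ["unscented", "gauss"])
    def test_static_species_variance_is_mixing_variance(self, quadrature):
        """A species with no dynamics keeps its initial value, so the output
        variance equals the variance of the mixing law, (cv * mu)^2."""
        net = ReactionNetwork(("A",), np.array([100.0]), np.zeros((1, 0)),
                              lambda phi, t, p, x: np.zeros(phi.shape[:-1] + (0,)))
        cv = 0.4
        ext = ExtrinsicSpec(varying=("A",), cv=cv, quadrature=quadrature)
        tm = extrinsic_mixture_moments(net, [0.0], [1.0], ext, dt=0.1)
        assert tm.mean[0] == pytest.approx(100.0, rel=1e-9)  # mean preserved
        assert tm.cov[0, 0] == pytest.approx((cv * 100.0) ** 2, rel=1e-8)

    def test_total_covariance_dominates_average_conditional(self):
        """Law of total variance: the extrinsic (between-cell) part is PSD."""
        fx = birth_death_network()
        ext = ExtrinsicSpec(varying=("A",), cv=0.8)
        nodes, w = ext.nodes(fx.obj)
        times = [2.0, 6.0]
        X = np.zeros((nodes.shape[0], 1))
        means, covs = moments_batch(fx.obj, X, nodes, times, dt=0.05)
        mu, total = mixture_moments(means, covs, w)
        avg_cond = np.einsum("q,qab->ab", w, covs)
        eig = np.linalg.eigvalsh(total - avg_cond)
        assert eig.min() > -1e-8 * np.trace(total)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            mixture_moments(np.zeros((2, 3)), np.zeros((2, 3, 3)),
                            np.array([0.6, 0.3]))


@pytest.fixture(scope="module")
def bd_channel():
    """Birth-death with the input modulating the birth rate."""

    def prop(phi, t, params, x):
        A = phi[..., 0]
        rate = x[..., 0] if x.ndim == phi.ndim else x[0]
        return np.stack([np.broadcast_to(rate, A.shape), 0.5 * A], axis=-1)

    net = ReactionNetwork(("A",), np.array([0.0]), np.array([[1.0, -1.0]]),
                          prop, name="bd_input")
    space = make_grid([(1.0, 10.0)], 5, "log")
    times = np.array([2.0, 4.0, 8.0])
    chan = channel_from_network(net, None, times, observed=(0,),
                                input_space=space, dt=0.02)
    return net, chan, times


class TestChannelFromNetwork:

    def test_channel_mean_matches_mre(self, bd_channel):
        net, chan, times = bd_channel
        mu, cov = chan.moments(np.array([4.0]))
        mre = mre_trajectory(net, [4.0], times)[:, 0]
        np.testing.assert_allclose(mu, mre, rtol=1e-4)

    def test_prefix_times_give_leading_subblocks(self, bd_channel):
        net, chan, times = bd_channel
        tm = lna_covariance(net, [4.0], times, dt=0.02)
        short = tm.prefix(4.0)
        assert short.times.tolist() == [2.0, 4.0]
        np.testing.assert_array_equal(short.mean, tm.mean[:2])
        np.testing.assert_array_equal(short.cov, tm.cov[:2, :2])

    def test_fim_nondecreasing_with_observation_horizon(self, bd_channel):
        """Extending the observed time series cannot reduce Fisher
        information (nested outputs: extra coordinates are extra data)."""
        from sigcap.fisher import fim_from_moment_stencil

        net, chan, times = bd_channel
        x0 = 4.0
        h = 1e-4 * x0
        tms = {}
        for x in (x0, x0 + h, x0 - h):
            tms[x] = lna_covariance(net, [x], times, dt=0.02)
        fims = []
        for n_keep in (1, 2, 3):
            m = n_keep
            mu0 = tms[x0].mean[:m]
            cov0 = tms[x0].cov[:m, :m]
            dmu = ((tms[x0 + h].mean[:m] - tms[x0 - h].mean[:m]) / (2 * h))[None, :]
            dcov = ((tms[x0 + h].cov[:m, :m] - tms[x0 - h].cov[:m, :m]) / (2 * h))[
                None, :, :
            ]
            fims.append(fim_from_moment_stencil(mu0, cov0, dmu, dcov)[0, 0])
        assert fims[0] <= fims[1] + 1e-8 * fims[1]
        assert fims[1] <= fims[2] + 1e-8 * fims[2]

    def test_sampler_reproducible_and_gaussian(self, bd_channel):
        net, chan, times = bd_channel
        a = chan.sample(np.array([4.0]), 30, seed=9)
        b = chan.sample(np.array([4.0]), 30, seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (30, 3)


def test_trajectory_moments_validation():
    from sigcap.lna import TrajectoryMoments

    with pytest.raises(ConfigurationError):
        TrajectoryMoments(times=[1.0], mean=[1.0, 2.0], cov=np.eye(2),
                          observed=(0,))
    with pytest.raises(ConfigurationError):
        TrajectoryMoments(times=[1.0, 2.0], mean=[1.0, 2.0],
                          cov=np.array([[1.0, 2.0], [0.0, 1.0]]), observed=(0,))
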