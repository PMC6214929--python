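"""Linear noise approximation (LNA) of stochastic reaction networks.

For a network with stoichiometry ``S`` (species x reactions) and macroscopic
propensities ``f(phi, t; x)``, the LNA describes the copy-number process as
a Gaussian around the macroscopic rate equation:

    mean:        d phi / dt   = S f(phi, t)
    covariance:  d Sigma / dt = A Sigma + Sigma A' + S diag(f) S',
                 A(t) = S (df/dphi)

Cross-time covariances follow from the fundamental matrix of the linearized
dynamics, ``d Phi/dt = A(t) Phi``:

    Cov(X(t_i), X(t_j)) = Sigma(t_i) Phi(t_j, t_i)',   t_j >= t_i,

so the observed time series ``Y = (Y(t_1), ..., Y(t_n))`` has an explicit
multivariate-Gaussian law — exactly what the Gaussian Fisher-information
route consumes.

Cell-to-cell (extrinsic) variability in initial copy numbers is layered on
top by Gaussian moment matching: the LNA moments are computed at quadrature
nodes of the copy-number distribution (lognormal marginals, parameterized by
a coefficient of variation) and combined by the law of total variance.  The
resulting mixture is treated downstream as a single Gaussian; its residual
non-Gaussianity is an acknowledged approximation.

Numerics: the moment equations are integrated with a fixed-step classical
Runge–Kutta scheme vectorized over a batch axis (many inputs / initial
conditions / finite-difference stencil points in one pass); steps are
aligned to observation times and stimulus boundaries, and the step length
is a parameter validated by step-halving in the test suite.  The
macroscopic-only path (:func:`mre_trajectory`) uses a stiff-safe adaptive
integrator (LSODA, rtol 1e-8 / atol 1e-10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import Channel, ConfigurationError, InputSpace

__all__ = [
    "ReactionNetwork",
    "TrajectoryMoments",
    "ExtrinsicSpec",
    "mre_trajectory",
    "lna_covariance",
    "moments_batch",
    "extrinsic_mixture_moments",
    "channel_from_network",
]


@dataclass
class ReactionNetwork:
    """Stochastic kinetic model: species, stoichiometry, and rate laws.

    ``propensity(phi, t, params, x)`` maps a state array of shape
    ``(..., d)`` (and input ``x`` of shape ``(..., k)``) to per-reaction
    rates of shape ``(..., R)``; it must be vectorized over the leading
    batch axis.  ``propensity_jac`` returns the state Jacobian
    ``(..., R, d)``; if omitted it is computed by central differences.
    Time dependence (e.g. a stimulus applied only during
    ``stimulus_window``) is the propensity function's responsibility.
    """

    species: tuple[str, ...]
    x0: np.ndarray  # initial copy numbers (d,)
    stoich: np.ndarray  # (d, R)
    propensity: Callable
    params: dict = field(default_factory=dict)
    propensity_jac: Callable | None = None
    stimulus_window: tuple[float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.x0 = np.asarray(self.x0, dtype=float)
        self.stoich = np.asarray(self.stoich, dtype=float)
        d = len(self.species)
        if self.x0.shape != (d,):
            raise ConfigurationError("x0 must have one entry per species")
        if self.stoich.ndim != 2 or self.stoich.shape[0] != d:
            raise ConfigurationError("stoich must be (n_species, n_reactions)")

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    def index(self, name: str) -> int:
        return self.species.index(name)

    def rates(self, phi, t, x) -> np.ndarray:
        f = np.asarray(self.propensity(np.asarray(phi, float), t, self.params,
                                       np.asarray(x, float)), dtype=float)
        return f

    def jac(self, phi, t, x) -> np.ndarray:
        """Per-reaction state Jacobian (..., R, d)."""
        phi = np.asarray(phi, dtype=float)
        if self.propensity_jac is not None:
            return np.asarray(
                self.propensity_jac(phi, t, self.params, np.asarray(x, float)),
                dtype=float,
            )
        # central-difference fallback
        d = self.d
        h = np.maximum(np.abs(phi), 1.0) * 1e-6
        out = np.empty(phi.shape[:-1] + (self.n_reactions, d))
        for a in range(d):
            pp, pm = phi.copy(), phi.copy()
            pp[..., a] += h[..., a]
            pm[..., a] -= h[..., a]
            out[..., :, a] = (self.rates(pp, t, x) - self.rates(pm, t, x)) / (
                2.0 * h[..., a][..., None]
            )
        return out


@dataclass
class TrajectoryMoments:
    """Gaussian law of the observed time series.

    ``mean`` stacks the observed species time-major:
    entry ``i * n_obs + a`` is species ``observed[a]`` at ``times[i]``.
    ``cov`` is the full ``(n n_obs) x (n n_obs)`` covariance including
    cross-time blocks (or block-diagonal if cross-time correlations were
    disabled).
    """

    times: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    observed: tuple[int, ...]
    species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.cov = np.asarray(self.cov, dtype=float)
        n_tot = self.times.size * len(self.observed)
        if self.mean.size != n_tot or self.cov.shape != (n_tot, n_tot):
            raise ConfigurationError("mean/cov shapes inconsistent with times/observed")
        if np.abs(self.cov - self.cov.T).max() > 1e-6 * max(
            np.abs(self.cov).max(), 1e-300
        ):
            raise ConfigurationError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        scale = max(float(np.abs(self.mean).max()), 1.0)
        if float(self.mean.min()) < -1e-6 * scale:
            raise ConfigurationError("copy-number means must be nonnegative")
        w = np.linalg.eigvalsh(self.cov)
        tr = max(np.trace(self.cov), 1e-300)
        if w[0] < -1e-8 * tr:
            raise ConfigurationError("covariance not PSD within tolerance")

    @property
    def n_obs(self) -> int:
        return len(self.observed)

    def mean_frame(self):
        """Long-format means: one row per (time, observed species)."""
        import pandas as pd

        names = [self.species[i] if self.species else str(i) for i in self.observed]
        rows = []
        for i, t in enumerate(self.times):
            for a, name in enumerate(names):
                rows.append({"time": t, "species": name,
                             "mean": self.mean[i * self.n_obs + a]})
        return pd.DataFrame(rows)

    def cov_frame(self):
        """Full stacked covariance as a labeled matrix table."""
        import pandas as pd

        names = [self.species[i] if self.species else str(i) for i in self.observed]
        labels = [f"{name}@t={t:g}" for t in self.times for name in names]
        return pd.DataFrame(self.cov, index=labels, columns=labels)

    def prefix(self, t_n: float) -> "TrajectoryMoments":
        """Restrict to observation times <= t_n (consistent sub-blocks)."""
        keep = self.times <= t_n + 1e-12
        n_keep = int(keep.sum())
        if n_keep == 0:
            raise ConfigurationError("no observation times <= t_n")
        m = n_keep * self.n_obs
        return TrajectoryMoments(
            times=self.times[:n_keep],
            mean=self.mean[:m],
            cov=self.cov[:m, :m],
            observed=self.observed,
            species=self.species,
        )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def _breakpoints(net: ReactionNetwork, times: np.ndarray) -> np.ndarray:
    """Observation times plus stimulus boundaries (propensities may jump there)."""
    pts = set(float(t) for t in times)
    if net.stimulus_window is not None:
        t_max = float(times[-1])
        for b in net.stimulus_window:
            if 0.0 < b < t_max:
                pts.add(float(b))
    pts.add(0.0)
    return np.array(sorted(pts))


def mre_trajectory(net: ReactionNetwork, x, times: Sequence[float]) -> np.ndarray:
    """Macroscopic rate-equation trajectory, shape ``(len(times), d)``.

    Integrates ``d phi/dt = S f(phi, t; x)`` with LSODA at rtol 1e-8 /
    atol 1e-10, restarting at stimulus boundaries so the discontinuity is
    not smoothed over.
    """
    from scipy.integrate import solve_ivp

    times = np.asarray(times, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    S = net.stoich
    if net.n_reactions == 0:
        return np.tile(net.x0, (times.size, 1))

    def rhs(t, phi):
        return S @ net.rates(phi, t, x)

    bps = _breakpoints(net, times)
    out = np.empty((times.size, net.d))
    phi = net.x0.copy()
    for a, b in zip(bps[:-1], bps[1:]):
        sol = solve_ivp(rhs, (a, b), phi, method="LSODA", rtol=1e-8, atol=1e-10,
                        dense_output=False, t_eval=[b])
        if not sol.success:
            raise RuntimeError(f"MRE integration failed near t = {sol.t[-1] if sol.t.size else a}: {sol.message}")
        phi = sol.y[:, -1]
        hit = np.isclose(times, b)
        if np.any(hit):
            out[hit] = phi
    if np.isclose(times[0], 0.0):
        out[np.isclose(times, 0.0)] = net.x0
    return out


def moments_batch(
    net: ReactionNetwork,
    X: np.ndarray,
    phi0: np.ndarray,
    times: Sequence[float],
    dt: float | None = None,
    observed: Sequence[int] | None = None,
    cross_time: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """LNA moments for a batch of (input, initial condition) pairs.

    Parameters
    ----------
    X
        Inputs, shape ``(B, k)``.
    phi0
        Initial copy numbers, shape ``(B, d)`` (deterministic per batch
        element; initial covariance is zero).
    times
        Observation times (strictly increasing, > 0).
    dt
        Target RK4 step; defaults to ``times[-1] / 2000``.  Steps are
        shortened to land exactly on observation times and stimulus
        boundaries.
    observed
        Species indices assembled into the output (default: all).

    Returns
    -------
    means : (B, n * n_obs) stacked observed means (time-major)
    covs : (B, n * n_obs, n * n_obs) stacked covariance with cross-time
        blocks (zero if ``cross_time`` is False).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    if times[0] <= 0:
        raise ConfigurationError("observation times must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phi0 = np.atleast_2d(np.asarray(phi0, dtype=float))
    B = X.shape[0]
    if phi0.shape[0] == 1 and B > 1:
        phi0 = np.broadcast_to(phi0, (B, net.d)).copy()
    if phi0.shape != (B, net.d):
        raise ConfigurationError("phi0 must be (B, d)")
    d = net.d
    S = net.stoich
    obs = tuple(range(d)) if observed is None else tuple(observed)
    o = len(obs)
    n = times.size
    if dt is None:
        dt = float(times[-1]) / 2000.0

    E = np.zeros((o, d))
    E[np.arange(o), obs] = 1.0

    phi = phi0.copy()
    # M holds the covariance and (once observations start, if cross-time
    # blocks are requested) the segment fundamental matrix side by side:
    # M[:, :, :d] = Sigma, M[:, :, d:] = Phi.  Fusing them lets the
    # linearized part of the moment equations be one batched matmul.
    M = np.zeros((B, d, d))

    mean_snaps = np.empty((B, n, o))
    sig_row_snaps = np.empty((B, n, o, d))  # Sigma(t_i)[obs, :]
    diag_snaps = np.empty((B, n, o, o))
    seg_phis: list[np.ndarray | None] = [None] * n  # seg_phis[i] = Phi(t_i, t_{i-1})

    St = np.ascontiguousarray(S.T)

    def rhs(t, phi, M):
        f = np.maximum(net.rates(phi, t, X), 0.0)  # (B, R)
        J = net.jac(phi, t, X)  # (B, R, d)
        A = np.matmul(S, J)  # (B, d, d)
        dphi = f @ St
        dM = np.matmul(A, M)  # A Sigma | A Phi
        # Sigma part also needs (A Sigma)^T + S diag(f) S^T
        AS_T = np.transpose(dM[:, :, :d], (0, 2, 1))
        dM[:, :, :d] += AS_T
        dM[:, :, :d] += np.matmul(S * f[:, None, :], St)
        return dphi, dM

    def rk4(t0, t1, phi, M):
        span = t1 - t0
        n_steps = max(1, int(math.ceil(span / dt - 1e-9)))
        h = span / n_steps
        t = t0
        for _ in range(n_steps):
            k1p, k1m = rhs(t, phi, M)
            k2p, k2m = rhs(t + h / 2, phi + (h / 2) * k1p, M + (h / 2) * k1m)
            k3p, k3m = rhs(t + h / 2, phi + (h / 2) * k2p, M + (h / 2) * k2m)
            k4p, k4m = rhs(t + h, phi + h * k3p, M + h * k3m)
            k1p += k4p
            k1p += 2.0 * (k2p + k3p)
            phi = phi + (h / 6) * k1p
            k1m += k4m
            k1m += 2.0 * (k2m + k3m)
            M = M + (h / 6) * k1m
            t += h
        return phi, M

    bps = _breakpoints(net, times)
    obs_set = {float(t): i for i, t in enumerate(times)}
    prev_obs_idx = -1
    for a, b in zip(bps[:-1], bps[1:]):
        phi, M = rk4(a, b, phi, M)
        if float(b) in obs_set:
            i = obs_set[float(b)]
            Sigma = M[:, :, :d]
            mean_snaps[:, i] = phi[:, obs]
            sig_row_snaps[:, i] = Sigma[:, obs, :]
            diag_snaps[:, i] = Sigma[:, obs, :][:, :, obs]
            if cross_time:
                if prev_obs_idx >= 0 and M.shape[2] == 2 * d:
                    seg_phis[i] = M[:, :, d:].copy()
                # fresh fundamental matrix for the next segment
                M2 = np.empty((B, d, 2 * d))
                M2[:, :, :d] = Sigma
                M2[:, :, d:] = np.eye(d)
                M = M2
            prev_obs_idx = i

    means = mean_snaps.reshape(B, n * o)
    covs = np.zeros((B, n * o, n * o))
    for i in range(n):
        covs[:, i * o:(i + 1) * o, i * o:(i + 1) * o] = diag_snaps[:, i]
    if cross_time:
        for j in range(1, n):
            V = np.broadcast_to(E, (B, o, d)).copy()  # Phi(t_j, t_i)[obs, :]
            for i in range(j - 1, -1, -1):
                V = V @ seg_phis[i + 1]
                block = sig_row_snaps[:, i] @ np.transpose(V, (0, 2, 1))
                covs[:, i * o:(i + 1) * o, j * o:(j + 1) * o] = block
                covs[:, j * o:(j + 1) * o, i * o:(i + 1) * o] = np.transpose(
                    block, (0, 2, 1)
                )
    return means, covs


def lna_covariance(
    net: ReactionNetwork,
    x,
    times: Sequence[float],
    observed: Sequence[int] | None = None,
    dt: float | None = None,
    cross_time: bool = True,
) -> TrajectoryMoments:
    """LNA mean and full (cross-time) covariance of the observed series."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    means, covs = moments_batch(
        net, x[None, :], net.x0[None, :], times, dt=dt,
        observed=observed, cross_time=cross_time,
    )
    obs = tuple(range(net.d)) if observed is None else tuple(observed)
    return TrajectoryMoments(
        times=np.asarray(times, dtype=float), mean=means[0], cov=covs[0],
        observed=obs, species=net.species,
    )


# ---------------------------------------------------------------------------
# Extrinsic (cell-to-cell) variability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtrinsicSpec:
    """Cell-to-cell variability of initial copy numbers.

    The listed species' initial counts vary across cells with lognormal
    marginals (positive support; the standard model for mammalian
    expression noise), independent across species, all with the same
    coefficient of variation ``cv = sigma/mu``.  ``quadrature`` selects the
    mixing rule: "unscented" (2 d_v + 1 sigma points in the latent Gaussian)
    or "gauss" (tensor Gauss–Hermite with ``n_gauss`` nodes per dimension).
    Node coordinates are rescaled per dimension so each marginal mean is
    preserved exactly.
    """

    varying: tuple[str, ...]
    cv: float
    family: str = "lognormal"
    quadrature: str = "unscented"
    n_gauss: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "varying", tuple(self.varying))
        if self.cv < 0:
            raise ConfigurationError("cv must be >= 0")
        if self.family != "lognormal":
            raise ConfigurationError("only lognormal extrinsic marginals are supported")
        if self.quadrature not in ("unscented", "gauss"):
            raise ConfigurationError("quadrature must be 'unscented' or 'gauss'")

    def nodes(self, net: ReactionNetwork) -> tuple[np.ndarray, np.ndarray]:
        """Initial-state quadrature: ``(nodes (E, d), weights (E,))``."""
        idx = [net.index(s) for s in self.varying]
        dv = len(idx)
        if self.cv == 0.0 or dv == 0:
            return net.x0[None, :].copy(), np.array([1.0])
        s2 = math.log1p(self.cv**2)
        s = math.sqrt(s2)
        if self.quadrature == "unscented":
            kappa = 1.0
            scale = math.sqrt(dv + kappa)
            xi = np.zeros((2 * dv + 1, dv))
            w = np.empty(2 * dv + 1)
            w[0] = kappa / (dv + kappa)
            for a in range(dv):
                xi[1 + 2 * a, a] = scale
                xi[2 + 2 * a, a] = -scale
                w[1 + 2 * a] = w[2 + 2 * a] = 0.5 / (dv + kappa)
        else:
            t, gw = np.polynomial.hermite.hermgauss(self.n_gauss)
            t = t * math.sqrt(2.0)
            gw = gw / math.sqrt(math.pi)
            grids = np.meshgrid(*([t] * dv), indexing="ij")
            xi = np.stack([g.ravel() for g in grids], axis=-1)
            wg = np.meshgrid(*([gw] * dv), indexing="ij")
            w = np.prod(np.stack([g.ravel() for g in wg], axis=-1), axis=-1)
        w = w / w.sum()
        # lognormal with mean mu: exp(ln mu - s^2/2 + s xi)
        factors = np.exp(-0.5 * s2 + s * xi)  # (E, dv)
        # moment-match each marginal exactly: first normalize the mean, then
        # rescale the spread so the weighted variance is (cv mu)^2 (the raw
        # sigma-point/Gauss images of the lognormal underestimate it)
        factors = factors / (w @ factors)[None, :]
        dev = factors - 1.0
        var = w @ dev**2  # (dv,)
        scale = np.sqrt(self.cv**2 / np.maximum(var, 1e-300))
        factors = 1.0 + dev * scale[None, :]
        if np.any(factors <= 0):
            raise ConfigurationError(
                "extrinsic quadrature produced nonpositive copy numbers; "
                "reduce cv or use the tensor Gauss rule"
            )
        nodes = np.tile(net.x0, (xi.shape[0], 1))
        for col, a in enumerate(idx):
            nodes[:, a] = net.x0[a] * factors[:, col]
        return nodes, w


def mixture_moments(
    means: np.ndarray, covs: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Law-of-total-variance combination of Gaussian mixture components.

    ``total mean = sum w_q mu_q``;
    ``total cov = sum w_q (Sigma_q + mu_q mu_q') - mu mu'``.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-10:
        raise ConfigurationError("mixture weights must sum to 1 within 1e-10")
    mu = weights @ means
    second = np.einsum("q,qab->ab", weights, covs)
    second += np.einsum("q,qa,qb->ab", weights, means, means)
    cov = second - np.outer(mu, mu)
    return mu, 0.5 * (cov + cov.T)


def extrinsic_mixture_moments(
    net: ReactionNetwork,
    x,
    times: Sequence[float],
    ext: ExtrinsicSpec,
    observed: Sequence[int] | None = None,
    dt: float | None = None,
    cross_time: bool = True,
) -> TrajectoryMoments:
    """Moments of the observed series under intrinsic + extrinsic noise.

    With ``cv = 0`` this reduces exactly to :func:`lna_covariance`.  The
    mixture over initial copy numbers is collapsed to a single Gaussian by
    moment matching (mean and covariance are exact; higher mixture cumulants
    are dropped).
    """
    if ext.cv == 0.0:
        return lna_covariance(net, x, times, observed=observed, dt=dt,
                              cross_time=cross_time)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    nodes, w = ext.nodes(net)
    E = nodes.shape[0]
    X = np.broadcast_to(x, (E, x.size)).copy()
    means, covs = moments_batch(net, X, nodes, times, dt=dt, observed=observed,
                                cross_time=cross_time)
    mu, cov = mixture_moments(means, covs, w)
    obs = tuple(range(net.d)) if observed is None else tuple(observed)
    return TrajectoryMoments(
        times=np.asarray(times, dtype=float), mean=mu, cov=cov,
        observed=obs, species=net.species,
    )


def channel_from_network(
    net: ReactionNetwork,
    ext: ExtrinsicSpec | None,
    times: Sequence[float],
    observed: Sequence[int],
    input_space: InputSpace,
    dt: float | None = None,
    cross_time: bool = True,
) -> Channel:
    """Wrap a reaction network as a Gaussian time-series channel.

    ``moments(x)`` returns the (extrinsic-mixed) LNA mean and covariance of
    the stacked observed series; the sampler draws Gaussian trajectories
    from those moments, and the log-density is the corresponding
    multivariate normal.  The Fisher-information route for this channel is
    the Gaussian moment formula (:func:`sigcap.fisher.fim_gaussian`).
    """
    times = np.asarray(times, dtype=float)
    obs = tuple(observed)

    def moments(x):
        if ext is None or ext.cv == 0.0:
            tm = lna_covariance(net, x, times, observed=obs, dt=dt,
                                cross_time=cross_time)
        else:
            tm = extrinsic_mixture_moments(net, x, times, ext, observed=obs,
                                           dt=dt, cross_time=cross_time)
        return tm.mean, tm.cov

    def _prepared(x):
        mu, cov = moments(x)
        tr = max(np.trace(cov), 1e-300)
        w = np.linalg.eigvalsh(cov)
        if w[0] < 1e-10 * tr:
            cov = cov + np.eye(cov.shape[0]) * (1e-8 * tr / cov.shape[0])
        return mu, cov

    def log_density(y, x):
        from scipy.stats import multivariate_normal

        mu, cov = _prepared(x)
        return multivariate_normal.logpdf(np.asarray(y, float), mean=mu, cov=cov,
                                          allow_singular=True)

    def sample(x, n, seed):
        rng = np.random.default_rng(seed)
        mu, cov = _prepared(x)
        return rng.multivariate_normal(mu, cov, size=n, method="eigh")

    return Channel(
        input_space=input_space,
        log_density=log_density,
        sample=sample,
        output_kind="continuous",
        moments=moments,
        name=net.name or "lna_channel",
    )
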