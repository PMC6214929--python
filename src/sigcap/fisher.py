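"""Fisher information matrices of signaling channels.

The Fisher information matrix

    FIM_ij(x) = E[ d/dx_i log P(Y|x) * d/dx_j log P(Y|x) ]

summarizes how sensitively the output distribution responds to each input
direction relative to its noise.  Four computation routes are provided:

* :func:`fim_discrete` — exact expectation over a discrete output alphabet,
  score by central finite differences;
* :func:`fim_monte_carlo` — sample-average of score outer products, with
  per-entry standard errors;
* :func:`fim_gaussian` — the closed multivariate-Gaussian form
  ``dmu' S^-1 dmu + 1/2 tr(S^-1 dS S^-1 dS)`` used for LNA outputs;
* closed forms supplied by built-in model families (tagged "analytic").

Finite differences use a relative step ``max(|x_i|, 1) * rel_step``:
signaling inputs are concentrations spanning decades, so absolute steps
fail at the extremes of a log grid.  Returned matrices are symmetrized and,
where a determinant is about to be taken, negative eigenvalues from FD
noise are clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Channel, ConfigurationError, FIMField, InputSpace

__all__ = [
    "FDScheme",
    "fim_discrete",
    "fim_monte_carlo",
    "fim_gaussian",
    "fim_from_moment_stencil",
    "fim_field_discrete",
    "symmetrize_clip",
]

_TINY = 1e-300


@dataclass(frozen=True)
class FDScheme:
    """Central finite-difference scheme for the score function."""

    relative_step: float = 1e-4

    def __post_init__(self) -> None:
        if not self.relative_step > 0:
            raise ConfigurationError("FD step must be positive")

    def steps(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(np.abs(x), 1.0) * self.relative_step


def symmetrize_clip(m: np.ndarray) -> np.ndarray:
    """Symmetrize and clip negative eigenvalues at zero (PSD projection)."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    if w[0] >= 0:
        return m
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def _as_point(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


def fim_discrete(channel: Channel, x, scheme: FDScheme = FDScheme()) -> np.ndarray:
    """FIM of a discrete channel by exact summation over the alphabet.

    Zero-probability outcomes are dropped from the score sum (the standard
    0*log 0 convention).  Raises if the density vanishes on the whole
    alphabet or is negative anywhere.
    """
    x = _as_point(x)
    k = x.size
    p0 = channel.density(x)
    if np.any(p0 < -1e-12):
        raise ConfigurationError("channel density is negative")
    if not np.any(p0 > 0):
        raise ConfigurationError("channel density vanishes on the whole alphabet")
    h = scheme.steps(x)
    support = p0 > _TINY
    scores = np.zeros((k, p0.size))
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        lp = channel.log_density(channel.y_alphabet, xp)
        lm = channel.log_density(channel.y_alphabet, xm)
        scores[i, support] = (lp[support] - lm[support]) / (2.0 * h[i])
    fim = (scores * p0) @ scores.T
    return symmetrize_clip(fim)


def fim_monte_carlo(
    channel: Channel,
    x,
    n_samples: int,
    seed: int,
    scheme: FDScheme = FDScheme(),
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo FIM: sample mean of score outer products over Y ~ P(.|x).

    Returns ``(fim, standard_errors)`` with matching shapes.  Reproducible
    for a given seed.
    """
    if n_samples < 100:
        raise ConfigurationError("need n_samples >= 100")
    x = _as_point(x)
    k = x.size
    ys = channel.sample(x, n_samples, seed)
    h = scheme.steps(x)
    scores = np.empty((k, n_samples))
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        scores[i] = (channel.log_density(ys, xp) - channel.log_density(ys, xm)) / (
            2.0 * h[i]
        )
    outer = scores[:, None, :] * scores[None, :, :]  # (k, k, n)
    fim = outer.mean(axis=-1)
    se = outer.std(axis=-1, ddof=1) / np.sqrt(n_samples)
    return 0.5 * (fim + fim.T), se


def fim_from_moment_stencil(
    mu0: np.ndarray,
    cov0: np.ndarray,
    dmu: np.ndarray,
    dcov: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian FIM from precomputed moment derivatives.

    Parameters
    ----------
    mu0, cov0
        Mean (d,) and covariance (d, d) at the evaluation point.
    dmu, dcov
        Derivatives along each input direction: shapes (k, d) and (k, d, d).
        With ``dcov=None`` only the mean-sensitivity term
        ``dmu' Sigma^-1 dmu`` is computed (the covariance-sensitivity trace
        term is dropped — appropriate when the output law is only
        moment-matched Gaussian and covariance shape carries no trustworthy
        information).

    The covariance receives a diagonal jitter ``1e-8 * mean(diag)`` if its
    smallest eigenvalue is below ``1e-10 * trace``; failure to be positive
    definite after jitter raises with the offending eigenvalues.
    """
    d = mu0.size
    cov0 = 0.5 * (cov0 + cov0.T)
    tr = np.trace(cov0)
    w = np.linalg.eigvalsh(cov0)
    if w[0] < 1e-10 * max(tr, _TINY):
        cov0 = cov0 + np.eye(d) * (1e-8 * max(tr / max(d, 1), _TINY))
        w = np.linalg.eigvalsh(cov0)
        if w[0] <= 0:
            raise np.linalg.LinAlgError(
                f"covariance not positive definite after jitter; eigenvalues {w}"
            )
    k = dmu.shape[0]
    # solve S^-1 dmu and S^-1 dS once per direction
    sol_mu = np.linalg.solve(cov0, dmu.T)  # (d, k)
    fim = dmu @ sol_mu  # mean part
    if dcov is not None:
        sol_cov = np.empty_like(dcov)
        for i in range(k):
            dci = 0.5 * (dcov[i] + dcov[i].T)
            sol_cov[i] = np.linalg.solve(cov0, dci)
        for i in range(k):
            for j in range(i, k):
                t = 0.5 * np.trace(sol_cov[i] @ sol_cov[j])
                fim[i, j] += t
                if j != i:
                    fim[j, i] += t
    return symmetrize_clip(fim)


def fim_gaussian(mean_fn, cov_fn, x, scheme: FDScheme = FDScheme()) -> np.ndarray:
    """FIM of a Gaussian output family ``Y ~ N(mu(x), Sigma(x))``.

    Derivatives of mean and covariance are taken by central differences;
    this is the formula paired with linear-noise-approximation outputs.
    Scalar ``mu``/``Sigma`` returns are promoted to 1x1 arrays.
    """
    x = _as_point(x)
    k = x.size
    mu0 = np.atleast_1d(np.asarray(mean_fn(x), dtype=float)).ravel()
    cov0 = np.atleast_2d(np.asarray(cov_fn(x), dtype=float))
    d = mu0.size
    h = scheme.steps(x)
    dmu = np.empty((k, d))
    dcov = np.empty((k, d, d))
    for i in range(k):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        mup = np.atleast_1d(np.asarray(mean_fn(xp), dtype=float)).ravel()
        mum = np.atleast_1d(np.asarray(mean_fn(xm), dtype=float)).ravel()
        cvp = np.atleast_2d(np.asarray(cov_fn(xp), dtype=float))
        cvm = np.atleast_2d(np.asarray(cov_fn(xm), dtype=float))
        dmu[i] = (mup - mum) / (2.0 * h[i])
        dcov[i] = (cvp - cvm) / (2.0 * h[i])
    return fim_from_moment_stencil(mu0, cov0, dmu, dcov)


def fim_field_discrete(
    channel: Channel,
    input_space: InputSpace | None = None,
    scheme: FDScheme = FDScheme(),
) -> FIMField:
    """Evaluate :func:`fim_discrete` on every node of an input space."""
    space = input_space if input_space is not None else channel.input_space
    nodes = space.nodes()
    mats = np.stack([fim_discrete(channel, x, scheme) for x in nodes])
    return FIMField(space, mats, method_tag="finite_difference")
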