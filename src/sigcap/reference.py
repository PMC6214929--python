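"""Exact and classical comparators: Blahut–Arimoto, mutual information,
and the small-noise capacity approximation.

These are the established routes against which the Fisher-information
asymptotic capacity is benchmarked:

* :func:`blahut_arimoto` — exact single-cell capacity of a discretized
  channel by alternating maximization, with a certified stopping rule (the
  run terminates when the standard upper/lower capacity bounds differ by
  less than ``tol_bits``);
* :func:`mutual_information` — I(X; Y) = H(Y) - H(Y|X) for a given input
  distribution over the discretized channel;
* :func:`small_noise_capacity` — the analytic approximation
  ``log2((2 pi e)^(-1/2) Integral |dmu/dx| / sigma(x) dx)`` valid when
  output fluctuations around the mean dose-response are small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CapacityResult,
    Channel,
    ConfigurationError,
    InputDistribution,
    InputSpace,
)
from .fisher import FDScheme

__all__ = [
    "DiscretizedChannel",
    "BAConfig",
    "discretize_channel",
    "blahut_arimoto",
    "mutual_information",
    "product_channel",
    "small_noise_capacity",
]

LN2 = math.log(2.0)


@dataclass
class DiscretizedChannel:
    """Row-stochastic transition matrix ``Q[i, j] = P(y_j | x_i)``."""

    x_nodes: np.ndarray  # (m, k) input nodes
    y_alphabet: np.ndarray  # (n,) output state labels
    Q: np.ndarray  # (m, n) row-stochastic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_nodes = np.atleast_2d(np.asarray(self.x_nodes, dtype=float))
        if self.x_nodes.shape[0] == 1 and self.x_nodes.shape[1] > 1:
            # a flat list of scalar nodes, not one multi-d node
            self.x_nodes = self.x_nodes.T
        self.Q = np.asarray(self.Q, dtype=float)
        self.y_alphabet = np.asarray(self.y_alphabet)
        if self.Q.shape != (self.x_nodes.shape[0], self.y_alphabet.size):
            raise ConfigurationError("Q must be (len(x_nodes), len(y_alphabet))")
        if np.any(self.Q < 0):
            raise ConfigurationError("transition probabilities must be >= 0")
        rows = self.Q.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-10):
            raise ConfigurationError("rows of Q must sum to 1 within 1e-10")

    @property
    def m(self) -> int:
        return self.x_nodes.shape[0]

    @property
    def n(self) -> int:
        return self.y_alphabet.size


@dataclass(frozen=True)
class BAConfig:
    """Blahut–Arimoto configuration: stop when the capacity bound gap
    (max_i D(Q_i || q) - I(p)) drops below ``tol_bits``.

    ``overrelax`` > 1 applies the multiplicative update with exponent
    gamma (p_i <- p_i exp(gamma c_i)); a monotonicity safeguard falls back
    to the plain step whenever the accelerated step would lower I(p).  The
    certified bounds are evaluated at the current p, so acceleration never
    affects correctness, only the iteration count.
    """

    tol_bits: float = 1e-6
    max_iter: int = 100_000
    overrelax: float = 1.0

    def __post_init__(self) -> None:
        if not self.tol_bits > 0:
            raise ConfigurationError("tolerance must be positive")
        if not 1.0 <= self.overrelax <= 3.0:
            raise ConfigurationError("overrelax must be in [1, 3]")


def discretize_channel(channel: Channel, x_grid, y_spec=None) -> DiscretizedChannel:
    """Tabulate a channel on input nodes (and, if continuous, output bins).

    Discrete channels pass their alphabet through unchanged.  Continuous
    outputs are binned on the edges ``y_spec``: per-bin mass from CDF
    differences when the channel provides a CDF, otherwise density at the
    bin midpoint times bin width.  Rows are renormalized; a row mass below
    0.999 before renormalization is recorded as a truncated-support warning.
    """
    if isinstance(x_grid, InputSpace):
        x_nodes = x_grid.nodes()
    else:
        x_nodes = np.atleast_2d(np.asarray(x_grid, dtype=float))
        if x_nodes.shape[0] == 1 and x_nodes.shape[1] > 1:
            x_nodes = x_nodes.T
    meta: dict = {"warnings": [], "row_mass": None}
    if channel.output_kind == "discrete":
        Q = np.stack([channel.density(x) for x in x_nodes])
        y = channel.y_alphabet
    else:
        if y_spec is None:
            raise ConfigurationError("continuous channels need output bin edges")
        edges = np.asarray(y_spec, dtype=float)
        mids = 0.5 * (edges[:-1] + edges[1:])
        widths = np.diff(edges)
        rows = []
        for x in x_nodes:
            if channel.cdf is not None:
                cdf = channel.cdf(edges, x)
                rows.append(np.diff(cdf))
            else:
                dens = np.exp(channel.log_density(mids, x))
                rows.append(dens * widths)
        Q = np.stack(rows)
        y = mids
    mass = Q.sum(axis=1)
    meta["row_mass"] = mass
    if np.any(mass < 0.999):
        meta["warnings"].append(
            f"truncated support: min row mass {mass.min():.6g} before renormalization"
        )
    Q = Q / mass[:, None]
    meta["renormalization"] = mass
    return DiscretizedChannel(x_nodes=x_nodes, y_alphabet=y, Q=Q, meta=meta)


def _row_relative_entropies(Q: np.ndarray, q: np.ndarray) -> np.ndarray:
    """D(Q_i || q) in nats for every row, with the 0 log 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(Q > 0, Q / q[None, :], 1.0)
        terms = np.where(Q > 0, Q * np.log(ratio), 0.0)
    return terms.sum(axis=1)


def blahut_arimoto(dc: DiscretizedChannel, cfg: BAConfig = BAConfig()) -> CapacityResult:
    """Exact capacity of a discretized channel by Blahut–Arimoto iteration.

    Starts from the uniform input distribution.  At each step the certified
    bounds ``I(p) <= C <= max_i D(Q_i || q)`` are evaluated; iteration stops
    when their gap is below ``cfg.tol_bits``.  A run that exhausts
    ``max_iter`` is returned flagged non-converged with the residual gap.
    """
    Q = dc.Q
    m = dc.m
    # D(Q_i || q) = sum_j Q_ij ln Q_ij - sum_j Q_ij ln q_j; the first term is
    # constant, so only n logs are needed per iteration.
    with np.errstate(divide="ignore", invalid="ignore"):
        row_neg_h = np.where(Q > 0, Q * np.log(np.where(Q > 0, Q, 1.0)), 0.0).sum(axis=1)
    # Active-set iteration: inputs whose weight has collapsed to ~0 are
    # dropped from the multiplicative update (they shrink monotonically under
    # BA).  Certification is unaffected: the upper bound max_i D(Q_i || q) is
    # periodically evaluated over ALL rows, and termination requires the full
    # certificate, so pruning can only delay, never corrupt, the result.
    active = np.arange(m)
    Qa, rowHa = Q, row_neg_h
    pa = np.full(m, 1.0 / m)
    gap_bits = math.inf
    lower_bits = 0.0
    prev_lower = -math.inf
    trace: list[float] = []
    it = 0
    gamma = cfg.overrelax
    prev_pa = pa
    certify_every = 50
    for it in range(1, cfg.max_iter + 1):
        q = np.maximum(pa @ Qa, 1e-300)
        logq = np.log(q)
        ca = rowHa - Qa @ logq
        lower = float(pa @ ca)
        if gamma > 1.0 and lower < prev_lower - 1e-13:
            # safeguard: redo the last step without acceleration
            pa = prev_pa
            q = np.maximum(pa @ Qa, 1e-300)
            logq = np.log(q)
            ca = rowHa - Qa @ logq
            lower = float(pa @ ca)
            logp = np.log(np.maximum(pa, 1e-300)) + ca
            logp -= logp.max()
            pa = np.exp(logp)
            pa /= pa.sum()
            prev_lower = lower
            continue
        lower_bits = lower / LN2
        gap_active = (float(ca.max()) - lower) / LN2
        if it % 100 == 1:
            trace.append(lower_bits)
        if gap_active < cfg.tol_bits or it % certify_every == 0:
            # full certificate over all inputs
            upper = float((row_neg_h - Q @ logq).max())
            gap_bits = (upper - lower) / LN2
            if gap_bits < cfg.tol_bits:
                break
        prev_lower = lower
        prev_pa = pa
        # multiplicative update p_i <- p_i exp(gamma c_i) / Z
        logp = np.log(np.maximum(pa, 1e-300)) + gamma * ca
        logp -= logp.max()
        pa = np.exp(logp)
        pa /= pa.sum()
        if active.size > 8 and it % 20 == 0:
            keep = pa > 1e-15
            if not keep.all() and keep.sum() >= 1:
                active = active[keep]
                Qa = Qa[keep]
                rowHa = rowHa[keep]
                pa = pa[keep]
                pa /= pa.sum()
                prev_pa = pa
                prev_lower = -math.inf
    p = np.zeros(m)
    p[active] = pa
    converged = gap_bits < cfg.tol_bits
    diagnostics = {
        "iterations": it,
        "bound_gap_bits": gap_bits,
        "converged": bool(converged),
        "lower_bound_trace_bits": trace,
    }
    if not converged:
        diagnostics["warning"] = "max_iter reached before certification"
    opt = None
    try:
        space = InputSpace(
            grids=(dc.x_nodes[:, 0],) if dc.x_nodes.shape[1] == 1 else tuple(
                np.unique(dc.x_nodes[:, j]) for j in range(dc.x_nodes.shape[1])
            ),
            spacing=("lin",) * dc.x_nodes.shape[1],
        )
        if space.n_nodes == m:
            opt = InputDistribution.from_unnormalized(space, p)
    except ConfigurationError:
        diagnostics["optimal_input_note"] = "nodes do not form a tensor grid"
    return CapacityResult(
        value_bits=max(lower_bits, 0.0),
        method="blahut_arimoto",
        k=dc.x_nodes.shape[1],
        N=1,
        optimal_input=opt,
        diagnostics=diagnostics,
    )


def mutual_information(p_x, dc: DiscretizedChannel) -> float:
    """I(X; Y) in bits for input weights ``p_x`` over ``dc.x_nodes``.

    Computed as H(Y) - H(Y|X), which equals the input-side form
    H(X) - H(X|Y) by symmetry of mutual information.
    """
    if isinstance(p_x, InputDistribution):
        nodes = p_x.input_space.nodes()
        if nodes.shape != dc.x_nodes.shape or not np.allclose(nodes, dc.x_nodes):
            raise ConfigurationError("input distribution support must match channel nodes")
        w = p_x.weights
    else:
        w = np.asarray(p_x, dtype=float).ravel()
        if w.size != dc.m:
            raise ConfigurationError("need one weight per channel input node")
    q = w @ dc.Q
    return float(w @ _row_relative_entropies(dc.Q, q)) / LN2


def product_channel(dc: DiscretizedChannel, N: int) -> DiscretizedChannel:
    """Channel of N independent observations: Q entries multiply across copies.

    The output alphabet is the N-fold product, indexed 0 .. n^N - 1; a guard
    ``N log2 n <= 24`` keeps the tabulation tractable (use small fixtures).
    """
    if N < 1:
        raise ConfigurationError("need N >= 1")
    if N * math.log2(dc.n) > 24 + 1e-9:
        raise ConfigurationError(
            "product alphabet too large (N log2|Y| > 24); use a smaller fixture"
        )
    if N == 1:
        return DiscretizedChannel(dc.x_nodes, dc.y_alphabet, dc.Q.copy())
    rows = []
    for i in range(dc.m):
        r = dc.Q[i]
        out = r
        for _ in range(N - 1):
            out = np.kron(out, r)
        rows.append(out)
    Q = np.stack(rows)
    Q = Q / Q.sum(axis=1, keepdims=True)
    return DiscretizedChannel(dc.x_nodes, np.arange(dc.n**N), Q)


def small_noise_capacity(
    mean_fn,
    sd_fn,
    input_space: InputSpace,
    scheme: FDScheme = FDScheme(),
) -> CapacityResult:
    """Small-noise capacity for a scalar input and scalar output summary.

    ``C*_SN = log2((2 pi e)^(-1/2) Integral |dmu/dx| / sigma(x) dx)`` with the
    mean slope by central differences on the grid nodes.  Valid when the
    output distribution is well summarized by its mean and standard
    deviation and fluctuations are small; for single-cell use the value is
    clamped at zero downstream (:func:`sigcap.capacity.clamp_for_single_cell`).
    """
    if input_space.k != 1:
        raise ConfigurationError("small-noise form implemented for scalar input only")
    from .capacity import LOG2_2PIE, trapezoid_weights

    g = input_space.grids[0]
    sd = np.array([float(sd_fn(x)) for x in g])
    if np.any(sd <= 0):
        raise ConfigurationError("sigma(x) must be positive on the grid")
    slopes = np.empty_like(g)
    for i, x in enumerate(g):
        h = scheme.steps(np.atleast_1d(x))[0]
        slopes[i] = (float(mean_fn(x + h)) - float(mean_fn(x - h))) / (2.0 * h)
    integrand = np.abs(slopes) / sd
    integral = float(integrand @ trapezoid_weights(input_space))
    diagnostics = {"integral": integral, "n_nodes": g.size}
    if integral <= 0:
        diagnostics["failure"] = "zero_sensitivity"
        return CapacityResult(
            value_bits=-math.inf, method="small_noise", k=1, diagnostics=diagnostics
        )
    value = math.log2(integral) - 0.5 * LOG2_2PIE
    return CapacityResult(value_bits=value, method="small_noise", k=1,
                          diagnostics=diagnostics)
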