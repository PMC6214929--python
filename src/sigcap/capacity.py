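"""Asymptotic information capacity and related Fisher-information quantities.

For a channel with k-dimensional input observed by N independent cells, the
joint capacity obeys the scaling law

    C*_N  ~  C*_A + (k/2) log2 N,        N -> infinity,

with the per-cell baseline (*asymptotic capacity*)

    C*_A = log2( (2 pi e)^(-k/2) * Integral_X sqrt|FIM(x)| dx ),

achieved asymptotically by the Jeffreys prior P*(x) ~ sqrt|FIM(x)|.
``C*_A`` may legitimately be negative: it is the rate at which the number of
resolvable inputs, 2^{C*_A} N^{k/2}, grows with the population size, not a
single-cell capacity.  When used as an approximation of the single-cell
capacity it should be clamped at zero (:func:`clamp_for_single_cell`).

The same Fisher field yields the asymptotic estimator covariance
``(N FIM)^-1`` and the discrimination error
``eps = exp(-N (x1-x0) FIM(x0) (x1-x0)^T)`` between nearby inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CapacityResult,
    ConfigurationError,
    FIMField,
    InputDistribution,
    InputSpace,
)

__all__ = [
    "Quadrature",
    "DiscriminationQuery",
    "trapezoid_weights",
    "asymptotic_capacity",
    "jeffreys_prior",
    "population_capacity",
    "resolvable_inputs",
    "estimator_covariance",
    "discrimination_error",
    "clamp_for_single_cell",
    "fim_isolines",
    "IsolineDescriptor",
]

LOG2_2PIE = math.log2(2.0 * math.pi * math.e)


@dataclass(frozen=True)
class Quadrature:
    """Integration rule for the Jeffreys integral over the input space.

    ``trapezoid`` integrates on the stored tensor grid (deterministic, with a
    Richardson half-grid error estimate).  ``monte_carlo`` draws uniform
    points in the bounds and linearly interpolates sqrt|FIM| from the grid —
    intended for k > 2 where tensor grids blow up.
    """

    rule: str = "trapezoid"
    n_mc: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("trapezoid", "monte_carlo"):
            raise ConfigurationError(f"unknown quadrature rule {self.rule!r}")
        if self.rule == "monte_carlo" and self.n_mc < 1000:
            raise ConfigurationError("monte_carlo quadrature needs n_mc >= 1e3")


@dataclass(frozen=True)
class DiscriminationQuery:
    """Hypothesis-testing query: detect the change x0 -> x1 from N cells."""

    x0: np.ndarray
    x1: np.ndarray
    N: int = 1
    input_space: InputSpace | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.atleast_1d(np.asarray(self.x0, float)))
        object.__setattr__(self, "x1", np.atleast_1d(np.asarray(self.x1, float)))
        if self.N < 1:
            raise ConfigurationError("need N >= 1 cells")
        if self.x0.shape != self.x1.shape:
            raise ConfigurationError("x0 and x1 must have the same dimension")
        if self.input_space is not None:
            for x in (self.x0, self.x1):
                for xi, (lo, hi) in zip(x, self.input_space.bounds):
                    if not (lo <= xi <= hi):
                        raise ConfigurationError("query point outside input space")


def trapezoid_weights(space: InputSpace) -> np.ndarray:
    """Tensor trapezoid weights on the (possibly non-uniform) grid, (n_nodes,)."""
    per_dim = []
    for g in space.grids:
        if g.size == 1:
            per_dim.append(np.ones(1))
            continue
        w = np.empty(g.size)
        w[0] = (g[1] - g[0]) / 2.0
        w[-1] = (g[-1] - g[-2]) / 2.0
        if g.size > 2:
            w[1:-1] = (g[2:] - g[:-2]) / 2.0
        per_dim.append(w)
    out = per_dim[0]
    for w in per_dim[1:]:
        out = np.multiply.outer(out, w)
    return out.ravel()


def _jeffreys_integral_trapezoid(fim_field: FIMField) -> tuple[float, float]:
    """Integral of sqrt|FIM| and a Richardson half-grid error estimate."""
    g = fim_field.sqrt_det()
    w = trapezoid_weights(fim_field.input_space)
    integral = float(g @ w)
    # half-grid (every other node, endpoints kept) for the error estimate
    space = fim_field.input_space
    idx_per_dim = []
    for grid in space.grids:
        idx = np.arange(0, grid.size, 2)
        if idx[-1] != grid.size - 1:
            idx = np.append(idx, grid.size - 1)
        idx_per_dim.append(idx)
    coarse_grids = tuple(grid[idx] for grid, idx in zip(space.grids, idx_per_dim))
    coarse_space = InputSpace(coarse_grids, space.spacing)
    shape = tuple(grid.size for grid in space.grids)
    g_nd = g.reshape(shape)
    sel = np.ix_(*idx_per_dim)
    g_coarse = g_nd[sel].ravel()
    coarse = float(g_coarse @ trapezoid_weights(coarse_space))
    err = abs(integral - coarse) / 3.0  # trapezoid is O(h^2)
    return integral, err


def _jeffreys_integral_mc(fim_field: FIMField, quad: Quadrature) -> tuple[float, float]:
    from scipy.interpolate import RegularGridInterpolator

    space = fim_field.input_space
    shape = tuple(g.size for g in space.grids)
    interp = RegularGridInterpolator(
        space.grids, fim_field.sqrt_det().reshape(shape), bounds_error=False,
        fill_value=None,
    )
    rng = np.random.default_rng(quad.seed)
    lows = np.array([b[0] for b in space.bounds])
    highs = np.array([b[1] for b in space.bounds])
    pts = rng.uniform(lows, highs, size=(quad.n_mc, space.k))
    vals = interp(pts)
    vol = float(np.prod(highs - lows))
    integral = vol * float(vals.mean())
    se = vol * float(vals.std(ddof=1)) / math.sqrt(quad.n_mc)
    return integral, se


def asymptotic_capacity(
    fim_field: FIMField, quad: Quadrature = Quadrature()
) -> CapacityResult:
    """Per-cell asymptotic capacity C*_A from a Fisher-information field.

    ``value_bits = log2((2 pi e)^(-k/2) * Integral sqrt|FIM(x)| dx)``; the
    value may be negative.  An all-singular field (zero integral) returns a
    flagged failure with ``value_bits = -inf`` rather than a number.
    """
    k = fim_field.input_space.k
    if quad.rule == "trapezoid":
        integral, err = _jeffreys_integral_trapezoid(fim_field)
    else:
        integral, err = _jeffreys_integral_mc(fim_field, quad)
    diagnostics = {
        "quadrature_rule": quad.rule,
        "jeffreys_integral": integral,
        "quadrature_error_estimate": err,
        "n_nodes": fim_field.input_space.n_nodes,
    }
    if integral <= 0:
        diagnostics["failure"] = "all_singular_field"
        return CapacityResult(
            value_bits=-math.inf, method="asymptotic", k=k, N=1,
            diagnostics=diagnostics,
        )
    value = math.log2(integral) - 0.5 * k * LOG2_2PIE
    return CapacityResult(
        value_bits=value, method="asymptotic", k=k, N=1, diagnostics=diagnostics
    )


def jeffreys_prior(fim_field: FIMField) -> InputDistribution:
    """Discretized Jeffreys prior: node weights ~ sqrt|FIM| * quadrature weight.

    Singular nodes (|FIM| = 0) receive weight zero; an all-singular field
    raises, since the prior is then undefined.
    """
    g = fim_field.sqrt_det()
    w = g * trapezoid_weights(fim_field.input_space)
    if not w.sum() > 0:
        raise ConfigurationError("Jeffreys prior undefined: sqrt|FIM| integrates to 0")
    return InputDistribution.from_unnormalized(fim_field.input_space, w)


def population_capacity(c_a: CapacityResult, N: int) -> CapacityResult:
    """Joint capacity of N cells: C*_N ~ C*_A + (k/2) log2 N."""
    if N < 1:
        raise ConfigurationError("need N >= 1")
    value = c_a.value_bits + 0.5 * c_a.k * math.log2(N)
    diag = dict(c_a.diagnostics)
    diag["scaled_from_N"] = c_a.N
    return CapacityResult(
        value_bits=value, method=c_a.method, k=c_a.k, N=N,
        optimal_input=c_a.optimal_input, diagnostics=diag,
    )


def resolvable_inputs(value_bits: float, k: int, N: int) -> float:
    """Number of input states resolvable by N cells: 2^{C*_A} * N^{k/2}."""
    return float(2.0**value_bits * N ** (k / 2.0))


def estimator_covariance(fim: np.ndarray, N: int) -> np.ndarray:
    """Asymptotic covariance of an efficient estimator of x: (N * FIM)^-1.

    A singular FIM (condition number >= 1e12) raises, naming the null
    eigenvector — the input combination that cannot be identified.
    """
    if N < 1:
        raise ConfigurationError("need N >= 1")
    fim = np.atleast_2d(np.asarray(fim, dtype=float))
    fim = 0.5 * (fim + fim.T)
    w, v = np.linalg.eigh(fim)
    if w[-1] <= 0 or w[0] <= 0 or w[-1] / w[0] >= 1e12:
        null = v[:, 0]
        raise np.linalg.LinAlgError(
            "FIM is singular; non-identifiable input direction "
            f"{np.array2string(null, precision=6)}"
        )
    inv = (v / w) @ v.T
    return 0.5 * (inv + inv.T) / N


def discrimination_error(q: DiscriminationQuery, fim_at_x0: np.ndarray) -> float:
    """Probability of missing the change x0 -> x1 given N cells.

    ``eps = exp(-N (x1-x0) FIM(x0) (x1-x0)^T)``, clipped to [0, 1].  Along a
    null direction of a singular FIM the error stays 1 for any N: parallel
    FIM isolines mean no discriminability.
    """
    d = q.x1 - q.x0
    fim = np.atleast_2d(np.asarray(fim_at_x0, dtype=float))
    quad_form = float(d @ fim @ d)
    return float(np.clip(math.exp(-q.N * max(quad_form, 0.0)), 0.0, 1.0))


def clamp_for_single_cell(c: CapacityResult) -> CapacityResult:
    """Clamp a capacity approximation at zero for single-cell use.

    The asymptotic and small-noise values approximate the single-cell
    capacity C*_1, which is nonnegative; negative approximations are set to
    zero and flagged.
    """
    if c.method not in ("asymptotic", "small_noise"):
        raise ConfigurationError("clamping applies to asymptotic/small_noise results")
    diag = dict(c.diagnostics)
    clamped = c.value_bits < 0
    if clamped:
        diag["clamped_from"] = c.value_bits
    diag["clamped"] = bool(clamped)
    return CapacityResult(
        value_bits=max(c.value_bits, 0.0), method=c.method, k=c.k, N=c.N,
        optimal_input=c.optimal_input, diagnostics=diag,
    )


@dataclass(frozen=True)
class IsolineDescriptor:
    """One isoline of the quadratic form (x-x0)^T FIM(x0) (x-x0) = level.

    ``kind`` is "ellipse" (semi-axes ``sqrt(level)/sqrt(lambda_i)`` along the
    eigenvectors) or "parallel_lines" when an eigenvalue is numerically zero:
    the form is degenerate and the isoline is the pair of lines normal to the
    remaining sensitive direction.
    """

    level: float
    kind: str
    semi_axes: tuple[float, ...] = ()
    axes: np.ndarray = field(default_factory=lambda: np.eye(2))
    angle: float = 0.0
    normal: np.ndarray | None = None
    offset: float | None = None


def fim_isolines(fim_at_x0: np.ndarray, x0, levels) -> list[IsolineDescriptor]:
    """Isoline descriptors of the discrimination quadratic form (k = 2 only)."""
    fim = np.atleast_2d(np.asarray(fim_at_x0, dtype=float))
    if fim.shape != (2, 2):
        raise ConfigurationError("isolines are supported for k = 2 only")
    fim = 0.5 * (fim + fim.T)
    w, v = np.linalg.eigh(fim)  # ascending
    tr = max(np.trace(fim), 1e-300)
    out = []
    for level in levels:
        level = float(level)
        if w[0] <= 1e-12 * tr:
            # degenerate: lines perpendicular to the dominant eigenvector
            normal = v[:, 1]
            offset = math.sqrt(level / w[1]) if w[1] > 0 else math.inf
            out.append(
                IsolineDescriptor(level=level, kind="parallel_lines",
                                  normal=normal, offset=offset)
            )
        else:
            semi = tuple(math.sqrt(level / wi) for wi in w)
            angle = math.atan2(v[1, 0], v[0, 0])
            out.append(
                IsolineDescriptor(level=level, kind="ellipse", semi_axes=semi,
                                  axes=v, angle=angle)
            )
    return out
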