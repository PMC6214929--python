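"""Shared domain types: input spaces, channels, input distributions, FIM fields.

The central abstraction is a *channel* ``P(Y | X = x)``: a conditional law
mapping a k-dimensional input ``x`` (typically ligand concentrations) to a
random output ``Y`` (typically effector activity, possibly a time series).
Everything downstream — Fisher information, asymptotic capacity, Jeffreys
priors, Blahut–Arimoto — consumes these types.

Conventions
-----------
* All capacities are in bits (log base 2); natural-log internals are
  converted once at the boundary.
* Input grids are node lists (not cell midpoints); quadrature rules own the
  integration weights.
* Discrete output alphabets are explicit integer sets ``{0, ..., L}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "InputSpace",
    "Channel",
    "InputDistribution",
    "FIMField",
    "CapacityResult",
    "make_grid",
]

LN2 = float(np.log(2.0))


class ConfigurationError(ValueError):
    """Raised when a model/grid configuration violates its preconditions."""


# ---------------------------------------------------------------------------
# Input spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputSpace:
    """Bounded k-dimensional signal domain with a tensor grid.

    Parameters
    ----------
    grids
        Per-dimension node arrays, strictly increasing, spanning the bounds
        inclusively.  Units are concentration units of the model at hand.
    spacing
        ``"lin"`` or ``"log"`` per dimension (metadata: how the nodes were
        generated; log spacing requires positive nodes).
    """

    grids: tuple[np.ndarray, ...]
    spacing: tuple[str, ...]

    def __post_init__(self) -> None:
        grids = tuple(np.asarray(g, dtype=float) for g in self.grids)
        object.__setattr__(self, "grids", grids)
        spacing = tuple(self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(grids) < 1:
            raise ConfigurationError("input space needs k >= 1 dimensions")
        if len(spacing) != len(grids):
            raise ConfigurationError("spacing flags must match dimensions")
        for g, s in zip(grids, spacing):
            if g.ndim != 1 or g.size < 1:
                raise ConfigurationError("each grid must be a 1-D node list")
            if g.size > 1 and not np.all(np.diff(g) > 0):
                raise ConfigurationError("grid nodes must be strictly increasing")
            if s not in ("lin", "log"):
                raise ConfigurationError(f"unknown spacing flag {s!r}")
            if s == "log" and g[0] <= 0:
                raise ConfigurationError("log spacing requires positive nodes")

    @property
    def k(self) -> int:
        return len(self.grids)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(g[0]), float(g[-1])) for g in self.grids)

    @property
    def n_nodes(self) -> int:
        n = 1
        for g in self.grids:
            n *= g.size
        return n

    def nodes(self) -> np.ndarray:
        """Tensor-product nodes as an ``(n_nodes, k)`` array (C order)."""
        mesh = np.meshgrid(*self.grids, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "spacing": list(self.spacing),
            "grids": [g.tolist() for g in self.grids],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputSpace":
        return cls(
            grids=tuple(np.asarray(g, dtype=float) for g in d["grids"]),
            spacing=tuple(d["spacing"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "InputSpace":
        return cls.from_dict(json.loads(s))


def make_grid(
    bounds: Sequence,
    n_nodes,
    spacing="lin",
) -> InputSpace:
    """Build a tensor-grid :class:`InputSpace` covering ``bounds`` inclusively.

    Parameters
    ----------
    bounds
        One ``(lo, hi)`` pair per dimension, or a single pair for k = 1.
    n_nodes
        Nodes per dimension (int, or one int per dimension); at least 2.
    spacing
        ``"lin"`` or ``"log"`` (str, or one per dimension).  Log spacing
        requires ``lo > 0``.
    """
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    k = bounds.shape[0]
    if np.isscalar(n_nodes):
        n_nodes = [int(n_nodes)] * k
    if isinstance(spacing, str):
        spacing = [spacing] * k
    if len(n_nodes) != k or len(spacing) != k:
        raise ConfigurationError("n_nodes/spacing must match the number of bounds")
    grids = []
    for (lo, hi), n, s in zip(bounds, n_nodes, spacing):
        if not lo < hi:
            raise ConfigurationError(f"need lo < hi, got [{lo}, {hi}]")
        if n < 2:
            raise ConfigurationError("need at least 2 nodes per dimension")
        if s == "lin":
            g = np.linspace(lo, hi, n)
        elif s == "log":
            if lo <= 0:
                raise ConfigurationError("log spacing requires a positive lower bound")
            g = np.geomspace(lo, hi, n)
        else:
            raise ConfigurationError(f"unknown spacing {s!r}")
        # pin endpoints exactly
        g[0], g[-1] = lo, hi
        grids.append(g)
    return InputSpace(grids=tuple(grids), spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# Channels
# ---------------------------------------------------------------------------


@dataclass
class Channel:
    """Conditional law ``P(Y | X = x)`` of a signaling system.

    ``log_density(y, x)`` evaluates the log conditional density/pmf;
    ``sample(x, n, seed)`` draws ``n`` outputs reproducibly.  For channels
    with tractable first two moments, ``moments(x)`` returns
    ``(mean vector, covariance matrix)`` — this is the route used for
    Gaussian/LNA outputs.
    """

    input_space: InputSpace
    log_density: Callable  # (y, x) -> log P(y|x)
    sample: Callable  # (x, n, seed) -> (n, ...) draws
    output_kind: str  # "discrete" | "continuous"
    y_alphabet: np.ndarray | None = None  # discrete channels: output states
    moments: Callable | None = None  # (x,) -> (mu, Sigma)
    cdf: Callable | None = None  # continuous channels: (y, x) -> CDF
    name: str = ""

    def __post_init__(self) -> None:
        if self.output_kind not in ("discrete", "continuous"):
            raise ConfigurationError("output_kind must be 'discrete' or 'continuous'")
        if self.output_kind == "discrete" and self.y_alphabet is None:
            raise ConfigurationError("discrete channels need an explicit y_alphabet")

    def density(self, x) -> np.ndarray:
        """Pmf over the whole alphabet at ``x`` (discrete channels only)."""
        if self.output_kind != "discrete":
            raise ConfigurationError("density() is defined for discrete channels")
        return np.exp(self.log_density(self.y_alphabet, np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Input distributions
# ---------------------------------------------------------------------------


@dataclass
class InputDistribution:
    """Discrete distribution over the tensor nodes of an :class:`InputSpace`."""

    input_space: InputSpace
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        self.weights = w
        if w.size != self.input_space.n_nodes:
            raise ConfigurationError("one weight per grid node required")
        if np.any(w < 0):
            raise ConfigurationError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ConfigurationError("weights must sum to 1 (within 1e-12)")

    @classmethod
    def from_unnormalized(cls, input_space: InputSpace, w) -> "InputDistribution":
        w = np.asarray(w, dtype=float).ravel()
        total = w.sum()
        if not total > 0:
            raise ConfigurationError("cannot normalize: total weight is zero")
        w = w / total
        w = w / w.sum()  # second pass kills residual rounding
        return cls(input_space, w)

    def to_dict(self) -> dict:
        return {
            "input_space": self.input_space.to_dict(),
            "weights": self.weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputDistribution":
        return cls(InputSpace.from_dict(d["input_space"]), np.asarray(d["weights"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "InputDistribution":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Fisher information fields
# ---------------------------------------------------------------------------


@dataclass
class FIMField:
    """Map ``x -> FIM(x)`` over the grid of an input space.

    ``matrices`` has shape ``(n_nodes, k, k)``, ordered like
    ``InputSpace.nodes()``.  Each matrix is symmetric and positive
    semidefinite up to floating-point noise (validated on construction).
    """

    input_space: InputSpace
    matrices: np.ndarray
    method_tag: str = "analytic"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        k = self.input_space.k
        m = m.reshape(self.input_space.n_nodes, k, k)
        self.matrices = m
        asym = np.abs(m - np.transpose(m, (0, 2, 1))).max(axis=(1, 2))
        scale = np.abs(m).max(axis=(1, 2))
        bad = asym > 1e-8 * np.maximum(scale, 1e-300)
        if np.any(bad & (scale > 0)):
            raise ConfigurationError("FIM matrices must be symmetric")
        sym = 0.5 * (m + np.transpose(m, (0, 2, 1)))
        eig = np.linalg.eigvalsh(sym)
        tr = np.trace(sym, axis1=1, axis2=2)
        # FD noise scales with the magnitude of the field, not of each node
        tol = 1e-8 * max(float(tr.max(initial=0.0)), 1e-300)
        if np.any(eig[:, 0] < -tol):
            raise ConfigurationError("FIM matrices must be PSD after symmetrization")
        self.matrices = sym

    def sqrt_det(self) -> np.ndarray:
        """sqrt |FIM(x)| per node, with negative FD-noise eigenvalues clipped at 0."""
        eig = np.linalg.eigvalsh(self.matrices)
        return np.sqrt(np.prod(np.clip(eig, 0.0, None), axis=-1))

    def to_frame(self):
        """Long-format table: x_1..x_k, fim_11..fim_kk, method_tag."""
        import pandas as pd

        k = self.input_space.k
        nodes = self.input_space.nodes()
        cols = {f"x_{i + 1}": nodes[:, i] for i in range(k)}
        for i in range(k):
            for j in range(k):
                cols[f"fim_{i + 1}{j + 1}"] = self.matrices[:, i, j]
        df = pd.DataFrame(cols)
        df["method_tag"] = self.method_tag
        return df


# ---------------------------------------------------------------------------
# Capacity results
# ---------------------------------------------------------------------------


@dataclass
class CapacityResult:
    """A capacity value in bits plus provenance.

    ``value_bits`` may be negative for the asymptotic method (a meaningful
    outcome: the per-cell contribution to an N-cell ensemble can be below
    zero); Blahut–Arimoto and clamped small-noise values are >= 0.
    """

    value_bits: float
    method: str  # "asymptotic" | "blahut_arimoto" | "small_noise"
    k: int = 1
    N: int = 1
    optimal_input: InputDistribution | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "value_bits": self.value_bits,
            "method": self.method,
            "k": self.k,
            "N": self.N,
            "diagnostics": {
                key: (val.tolist() if isinstance(val, np.ndarray) else val)
                for key, val in self.diagnostics.items()
            },
        }
        if self.optimal_input is not None:
            d["optimal_input"] = self.optimal_input.to_dict()
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)
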