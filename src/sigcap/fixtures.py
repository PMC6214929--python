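"""Built-in benchmark channels with closed-form oracle values.

Each fixture bundles a channel (or network) with the analytically known
quantity it is meant to check — a capacity, a Fisher information, LNA
moments — recomputed from its closed form at load time.  They drive the
test suite and give CLI users ready-made sanity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats

from .core import Channel, make_grid
from .lna import ReactionNetwork
from .reference import DiscretizedChannel
from .sensor import SensorParams, sensor_channel, sensor_fim_noiseless

__all__ = [
    "Fixture",
    "gaussian_location_channel",
    "binomial_sensor_fixture",
    "bsc",
    "birth_death_network",
    "five_state_channel",
    "fixture_channels",
]


@dataclass
class Fixture:
    """A named benchmark object plus its closed-form oracle values."""

    name: str
    obj: Any
    oracle: dict = field(default_factory=dict)
    provenance: str = ""


def gaussian_location_channel(
    sigma: float = 1.0, bounds=None, n_nodes: int = 101
) -> Channel:
    """Scalar Gaussian location family Y ~ N(x, sigma^2).

    The Fisher information is 1/sigma^2 everywhere, so the asymptotic
    capacity has the closed form ``log2(range / (sigma sqrt(2 pi e)))``;
    the default range makes it exactly 0 bits.
    """
    if bounds is None:
        bounds = (0.0, sigma * math.sqrt(2.0 * math.pi * math.e))
    space = make_grid([bounds], n_nodes, "lin")

    def log_density(y, x):
        x = np.atleast_1d(x)[0]
        return stats.norm.logpdf(np.asarray(y, float), loc=x, scale=sigma)

    def sample(x, n, seed):
        rng = np.random.default_rng(seed)
        return rng.normal(np.atleast_1d(x)[0], sigma, size=n)

    def moments(x):
        x = np.atleast_1d(x)[0]
        return np.array([x]), np.array([[sigma**2]])

    def cdf(y, x):
        x = np.atleast_1d(x)[0]
        return stats.norm.cdf(np.asarray(y, float), loc=x, scale=sigma)

    return Channel(
        input_space=space, log_density=log_density, sample=sample,
        output_kind="continuous", moments=moments, cdf=cdf,
        name=f"gaussian_location(sigma={sigma:g})",
    )


def binomial_sensor_fixture(L: int = 100, H: float = 1.0) -> Fixture:
    """Noise-free binomial sensor with the closed-form FIM oracle."""
    params = SensorParams(L=L, H=H, lam=10.0, m_F=0.0, sigma_XF=0.0)
    chan = sensor_channel(params)
    x_check = np.geomspace(0.05 * H, 20.0 * H, 10)
    return Fixture(
        name="binomial_sensor",
        obj=chan,
        oracle={
            "params": params,
            "x_check": x_check,
            "fim": sensor_fim_noiseless(params, x_check),
            "fim_at_1": float(sensor_fim_noiseless(params, np.array([1.0]))[0]),
        },
        provenance="FIM = L H / (S (S+H)^2), S = x + m_F/lambda",
    )


def bsc(crossover: float) -> DiscretizedChannel:
    """Binary symmetric channel; capacity 1 - H2(crossover) bits."""
    e = float(crossover)
    Q = np.array([[1.0 - e, e], [e, 1.0 - e]])
    return DiscretizedChannel(np.array([[0.0], [1.0]]), np.array([0, 1]), Q)


def bsc_capacity(crossover: float) -> float:
    e = float(crossover)
    if e in (0.0, 1.0):
        return 1.0
    h2 = -e * math.log2(e) - (1 - e) * math.log2(1 - e)
    return 1.0 - h2


def birth_death_network(birth: float = 5.0, death: float = 0.5,
                        x0: float = 2.0) -> Fixture:
    """Birth-death process 0 -> A (rate b), A -> 0 (rate k A).

    At stationarity the copy number is Poisson(b/k): mean = variance = b/k,
    and the autocovariance decays as ``(b/k) exp(-k tau)``.
    """

    def prop(phi, t, params, x):
        A = phi[..., 0]
        return np.stack([np.full_like(A, birth), death * A], axis=-1)

    def jac(phi, t, params, x):
        J = np.zeros(phi.shape[:-1] + (2, 1))
        J[..., 1, 0] = death
        return J

    net = ReactionNetwork(
        species=("A",), x0=np.array([float(x0)]),
        stoich=np.array([[1.0, -1.0]]), propensity=prop, propensity_jac=jac,
        name="birth_death",
    )
    return Fixture(
        name="birth_death",
        obj=net,
        oracle={
            "birth": birth, "death": death,
            "stationary_mean": birth / death,
            "stationary_var": birth / death,
            "autocov": lambda tau: (birth / death) * math.exp(-death * tau),
        },
        provenance="Poisson stationary law of the linear birth-death process",
    )


def five_state_channel() -> Fixture:
    """Single-input channel with a fixed 5-state output pmf (sampler check)."""
    pmf = np.array([0.1, 0.2, 0.4, 0.25, 0.05])
    space = make_grid([(0.0, 1.0)], 2, "lin")

    def log_density(y, x):
        return np.log(pmf[np.asarray(y, dtype=int)])

    def sample(x, n, seed):
        rng = np.random.default_rng(seed)
        return rng.choice(5, size=n, p=pmf)

    chan = Channel(
        input_space=space, log_density=log_density, sample=sample,
        output_kind="discrete", y_alphabet=np.arange(5), name="five_state",
    )
    return Fixture(name="five_state", obj=chan, oracle={"pmf": pmf},
                   provenance="fixed categorical pmf")


def fixture_channels() -> dict[str, Fixture]:
    """The named benchmark set used by the tests and the CLI.

    Every oracle value is recomputed from its closed form here, at load
    time — nothing is a stored constant.
    """
    sqrt2pie = math.sqrt(2.0 * math.pi * math.e)
    gauss = gaussian_location_channel()
    out = {
        "gaussian_location": Fixture(
            name="gaussian_location", obj=gauss,
            oracle={
                "sigma": 1.0,
                "capacity_bits": math.log2(
                    (gauss.input_space.bounds[0][1] - gauss.input_space.bounds[0][0])
                    / sqrt2pie
                ),
                "fim": 1.0,
            },
            provenance="C_A = log2(range / (sigma sqrt(2 pi e)))",
        ),
        "binomial_sensor": binomial_sensor_fixture(),
        "bsc11": Fixture(
            name="bsc11", obj=bsc(0.11),
            oracle={"capacity_bits": bsc_capacity(0.11)},
            provenance="C = 1 - H2(p) for the binary symmetric channel",
        ),
        "birth_death": birth_death_network(),
        "five_state": five_state_channel(),
    }
    return out
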