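"""Configuration files, result serialization, and run manifests.

Channels and input grids are describable in a small YAML schema::

    channel:
      type: gaussian_location        # | binomial_sensor | bsc
      sigma: 1.0                     # type-specific keys
    grid:
      bounds: [[0.0, 4.1327]]
      n_nodes: 101
      spacing: lin

Unknown keys are rejected (typos should fail loudly, not be ignored).
Results are emitted as JSON records (capacity results, manifests) and CSV
tables with floats printed at 12 significant digits so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import Channel, ConfigurationError, InputSpace, make_grid
from .fixtures import bsc, gaussian_location_channel
from .lna import ReactionNetwork
from .sensor import SensorParams, sensor_channel

__all__ = [
    "load_config",
    "build_input_space",
    "build_channel",
    "network_from_config",
    "RunManifest",
    "write_csv",
    "PKG_VERSION",
]

PKG_VERSION = "0.1.0"

_CHANNEL_KEYS = {
    "gaussian_location": {"sigma"},
    "binomial_sensor": {"L", "H", "lam", "xf_dist", "m_F", "sigma_XF", "quad_nodes"},
    "bsc": {"crossover"},
}
_GRID_KEYS = {"bounds", "n_nodes", "spacing"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> dict:
    """Parse and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    _check_keys(cfg, {"channel", "grid"}, "config")
    if "channel" in cfg:
        ch = cfg["channel"]
        if not isinstance(ch, dict) or "type" not in ch:
            raise ConfigurationError("channel section needs a 'type' key")
        ctype = ch["type"]
        if ctype not in _CHANNEL_KEYS:
            raise ConfigurationError(f"unknown channel type {ctype!r}")
        _check_keys({k: v for k, v in ch.items() if k != "type"},
                    _CHANNEL_KEYS[ctype], f"channel({ctype})")
    if "grid" in cfg:
        if not isinstance(cfg["grid"], dict):
            raise ConfigurationError("grid section must be a mapping")
        _check_keys(cfg["grid"], _GRID_KEYS, "grid")
    return cfg


def build_input_space(grid_cfg: dict) -> InputSpace:
    return make_grid(
        grid_cfg["bounds"],
        grid_cfg.get("n_nodes", 101),
        grid_cfg.get("spacing", "lin"),
    )


def build_channel(cfg: dict):
    """Instantiate the channel (and grid, if given) described by a config."""
    ch = cfg.get("channel")
    if ch is None:
        raise ConfigurationError("config has no channel section")
    ctype = ch["type"]
    space = build_input_space(cfg["grid"]) if "grid" in cfg else None
    if ctype == "gaussian_location":
        sigma = float(ch.get("sigma", 1.0))
        if space is not None:
            chan = gaussian_location_channel(sigma, bounds=space.bounds[0],
                                             n_nodes=space.grids[0].size)
            chan = Channel(
                input_space=space, log_density=chan.log_density,
                sample=chan.sample, output_kind=chan.output_kind,
                moments=chan.moments, cdf=chan.cdf, name=chan.name,
            )
            return chan
        return gaussian_location_channel(sigma)
    if ctype == "binomial_sensor":
        params = SensorParams(
            L=int(ch.get("L", 100)), H=float(ch.get("H", 1.0)),
            lam=float(ch.get("lam", 10.0)), xf_dist=ch.get("xf_dist", "lognormal"),
            m_F=float(ch.get("m_F", 1.0)), sigma_XF=float(ch.get("sigma_XF", 0.0)),
        )
        return sensor_channel(params, space, int(ch.get("quad_nodes", 32)))
    if ctype == "bsc":
        return bsc(float(ch.get("crossover", 0.0)))
    raise ConfigurationError(f"unknown channel type {ctype!r}")


_REACTION_KEYS = {"reactants", "products", "law", "rate", "vmax", "km",
                  "substrate", "input_factor", "stimulus_only"}


def network_from_config(cfg: dict) -> ReactionNetwork:
    """Build a :class:`~sigcap.lna.ReactionNetwork` from a structured config.

    Schema::

        species: {A: 10, B: 0}              # name -> initial copy number
        stimulus_window: [0.0, 30.0]        # optional
        reactions:
          - reactants: {A: 1}               # consumed (with multiplicity)
            products: {B: 1}                # produced
            law: mass_action                # or michaelis_menten
            rate: 0.5                       # mass-action rate constant
            input_factor: 0                 # optional: multiply by x[i]
            stimulus_only: true             # optional: active only in window
          - {reactants: {}, products: {A: 1}, law: michaelis_menten,
             vmax: 2.0, km: 10.0, substrate: A}

    Mass action: ``rate * prod(species^multiplicity)``.  Michaelis–Menten:
    ``vmax * S / (km + S)`` for the named substrate.  ``input_factor: i``
    multiplies the propensity by input component ``x_i``; ``stimulus_only``
    gates it by the stimulus window.
    """
    if "species" not in cfg or "reactions" not in cfg:
        raise ConfigurationError("network config needs 'species' and 'reactions'")
    names = list(cfg["species"])
    x0 = np.array([float(cfg["species"][s]) for s in names])
    index = {s: i for i, s in enumerate(names)}
    window = cfg.get("stimulus_window")
    if window is not None:
        window = (float(window[0]), float(window[1]))
    reactions = cfg["reactions"]
    d, R = len(names), len(reactions)
    stoich = np.zeros((d, R))
    specs = []
    for r, rx in enumerate(reactions):
        _check_keys(rx, _REACTION_KEYS, f"reaction {r}")
        reac = rx.get("reactants", {}) or {}
        prod = rx.get("products", {}) or {}
        for s, mult in reac.items():
            stoich[index[s], r] -= mult
        for s, mult in prod.items():
            stoich[index[s], r] += mult
        law = rx.get("law", "mass_action")
        if law == "mass_action":
            spec = ("ma", float(rx["rate"]),
                    tuple((index[s], int(m)) for s, m in reac.items()))
        elif law == "michaelis_menten":
            spec = ("mm", float(rx["vmax"]), float(rx["km"]),
                    index[rx["substrate"]])
        else:
            raise ConfigurationError(f"unknown kinetic law {law!r}")
        specs.append((spec, rx.get("input_factor"), bool(rx.get("stimulus_only"))))

    def propensity(phi, t, params, x):
        out = np.empty(phi.shape[:-1] + (R,))
        in_window = window is None or (window[0] <= t <= window[1])
        for r, (spec, input_factor, stim_only) in enumerate(specs):
            if spec[0] == "ma":
                f = np.full(phi.shape[:-1], spec[1])
                for si, mult in spec[2]:
                    f = f * np.maximum(phi[..., si], 0.0) ** mult
            else:
                s_val = np.maximum(phi[..., spec[3]], 0.0)
                f = spec[1] * s_val / (spec[2] + s_val)
            if input_factor is not None:
                xi = x[..., input_factor] if x.ndim == phi.ndim else x[input_factor]
                f = f * xi
            if stim_only and not in_window:
                f = np.zeros_like(f)
            out[..., r] = f
        return out

    return ReactionNetwork(
        species=tuple(names), x0=x0, stoich=stoich, propensity=propensity,
        stimulus_window=window, name=str(cfg.get("name", "config_network")),
    )


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config_hash: str = ""
    seed: int | None = None
    tolerances: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    wall_clock_s: float = 0.0
    package_version: str = PKG_VERSION
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    @staticmethod
    def hash_config(path) -> str:
        data = Path(path).read_bytes()
        return hashlib.sha256(data).hexdigest()

    def finish(self, out_dir) -> Path:
        self.wall_clock_s = round(time.perf_counter() - self._t0, 3)
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        d = {
            "command": self.command,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "tolerances": self.tolerances,
            "outputs": [str(o) for o in self.outputs],
            "wall_clock_s": self.wall_clock_s,
            "package_version": self.package_version,
        }
        path.write_text(json.dumps(d, indent=2) + "\n")
        return path


def write_csv(df, path) -> Path:
    """CSV with a fixed dialect: comma, '.' decimal, header, UTF-8, no index;
    floats at 12 significant digits so reruns are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    return path
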