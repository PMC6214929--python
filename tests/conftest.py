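"""Shared test utilities: a vectorized Gillespie SSA used as the independent
stochastic-simulation oracle for the LNA engine."""

from __future__ import annotations

import numpy as np
import pytest


def gillespie_samples(
    stoich: np.ndarray,
    rate_fn,
    x0: np.ndarray,
    sample_times,
    n_runs: int,
    seed: int,
    max_events: int = 100_000,
) -> np.ndarray:
    """Exact stochastic simulation of a small reaction network.

    Vectorized over replicate trajectories: all runs advance together, one
    reaction event per iteration per active run.  ``rate_fn(states)`` maps
    ``(n_runs, d)`` copy-number states to ``(n_runs, R)`` propensities.
    Returns states at each sample time, shape ``(n_runs, T, d)``.
    """
    rng = np.random.default_rng(seed)
    stoich = np.asarray(stoich, dtype=float)
    d, R = stoich.shape
    sample_times = np.asarray(sample_times, dtype=float)
    T = sample_times.size
    t_max = float(sample_times[-1])
    states = np.tile(np.asarray(x0, dtype=float), (n_runs, 1))
    t = np.zeros(n_runs)
    out = np.empty((n_runs, T, d))
    recorded = np.zeros((n_runs, T), dtype=bool)
    for _ in range(max_events):
        active = t <= t_max
        if not active.any():
            break
        rates = rate_fn(states)
        a0 = rates.sum(axis=1)
        a0 = np.where(active & (a0 > 0), a0, np.inf)
        dt = rng.exponential(1.0, size=n_runs) / a0
        t_new = t + dt
        # record the (piecewise-constant) state at crossed sample times
        for j, s in enumerate(sample_times):
            hit = (~recorded[:, j]) & (t <= s) & (s < t_new)
            out[hit, j] = states[hit]
            recorded[hit, j] = True
        # pick one reaction per run by inverse-CDF on the propensities
        u = rng.random(n_runs) * np.where(np.isfinite(a0), a0, 1.0)
        cum = np.cumsum(rates, axis=1)
        ridx = (u[:, None] > cum).sum(axis=1).clip(0, R - 1)
        upd = np.isfinite(dt)
        states[upd] += stoich.T[ridx[upd]]
        t = np.where(np.isfinite(dt), t_new, t_max + 1.0)
    # runs that ran out of events before t_max: freeze the final state
    for j, s in enumerate(sample_times):
        missing = ~recorded[:, j]
        out[missing, j] = states[missing]
    return out


@pytest.fixture(scope="session")
def birth_death_ssa():
    """SSA samples of the birth-death fixture at two times (session-cached)."""
    from sigcap.fixtures import birth_death_network

    fx = birth_death_network()
    b, k = fx.oracle["birth"], fx.oracle["death"]

    def rate_fn(states):
        return np.stack([np.full(states.shape[0], b), k * states[:, 0]], axis=-1)

    sample_times = np.array([8.0, 12.0])
    samples = gillespie_samples(
        np.array([[1.0, -1.0]]), rate_fn, fx.obj.x0, sample_times,
        n_runs=10_000, seed=20240901,
    )
    return fx, sample_times, samples[:, :, 0]
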