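"""Exact stochastic simulation (Gillespie direct method) of a reaction network.

The stochastic backend shares the :class:`~hipba.network.ReactionNetwork`
definition with the ODE backend. Propensities use combinatorial counting for
multi-copy reactants (``C(x, n)`` ways to pick ``n`` identical molecules), so
HipB dimerization fires at ``beta_B2 * B(B-1)/2`` and complex association at
``mu * A(A-1)/2 * B2``; in the large-count limit these agree with the
deterministic event rates.

Trajectories are stored at full event resolution: the recorded state holds
from its event time until the next event (piecewise constant), and summary
statistics are dwell-time weighted over that piecewise-constant path.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .deterministic import Trajectory, find_equilibrium
from .network import Reaction, ReactionNetwork
from .parameters import ParameterSet

__all__ = [
    "SSARun",
    "SummaryStats",
    "propensity",
    "gillespie_run",
    "time_weighted_stats",
    "weighted_mean_var",
    "default_ssa_init",
]


def _combinations(x: int, n: int) -> float:
    if n == 1:
        return float(x)
    if n == 2:
        return 0.5 * x * (x - 1)
    return float(math.comb(x, n)) if x >= n else 0.0


def propensity(
    reaction: Reaction,
    state: Sequence[int],
    params: ParameterSet,
    network: ReactionNetwork,
) -> float:
    """Stochastic rate (hour^-1) of one reaction at an integer state."""
    x = np.asarray(state)
    if np.any(x < 0):
        raise ValueError("negative molecule counts")
    if not np.all(np.equal(np.mod(x, 1), 0)):
        raise ValueError("SSA states must be integer counts")
    a = reaction.rate_factor * params[reaction.rate]
    for sp, n in reaction.reactants:
        a *= _combinations(int(x[network.species_index(sp)]), n)
    return a


@dataclass
class SSARun:
    """One stochastic trajectory with its provenance.

    ``states[i]`` holds on ``[times[i], times[i+1])``; the last state holds
    until ``t_end`` (or until absorption if the propensity sum vanished).
    """

    trajectory: Trajectory
    seed: int
    t_end: float
    burn_in: float
    event_count: int
    absorbed: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.times

    @property
    def states(self) -> np.ndarray:
        return self.trajectory.states

    @property
    def network(self) -> ReactionNetwork:
        return self.trajectory.network

    def species_series(self, name: str) -> np.ndarray:
        return self.trajectory.species(name)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.network.species))
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def default_ssa_init(
    network: ReactionNetwork, params: ParameterSet
) -> np.ndarray:
    """Deterministic equilibrium rounded to integer counts.

    Minimizes the initial transient. Promoter copies within each gene group
    are assigned to the state with the largest continuous occupancy so the
    copy-number conservation is exact.
    """
    x_eq = find_equilibrium(network, params)
    x0 = np.rint(x_eq).astype(np.int64)
    idx = {s: i for i, s in enumerate(network.species)}
    for group in network.promoter_groups:
        gi = [idx[s] for s in group]
        x0[gi] = 0
        top = gi[int(np.argmax(x_eq[gi]))]
        x0[top] = network.promoter_copies
    return np.maximum(x0, 0)


def gillespie_run(
    network: ReactionNetwork,
    params: ParameterSet,
    init: Sequence[int] | None = None,
    t_end: float = 1000.0,
    seed: int = 0,
    burn_in: float = 100.0,
    max_events: int = 50_000_000,
) -> SSARun:
    """Exact direct-method simulation of ``network`` until ``t_end`` hours.

    Identical arguments (including ``seed``) give identical event sequences.
    If all propensities vanish before ``t_end`` the run is flagged
    ``absorbed`` and the final state is held to ``t_end``.
    """
    if not t_end > burn_in >= 0:
        raise ValueError("require t_end > burn_in >= 0")
    if init is None:
        init = default_ssa_init(network, params)
    x0 = np.asarray(init)
    network.validate_state(x0)
    if not np.all(np.equal(np.mod(x0, 1), 0)):
        raise ValueError("SSA initial state must be integer counts")
    x0 = x0.astype(np.int64)

    m = network.n_reactions
    k_eff = network.rate_vector(params).tolist()
    orders = [list(pairs) for pairs in network.reactant_orders]
    stoich = network.stoichiometry
    changes = [
        [(i, int(d)) for i, d in enumerate(stoich[j]) if d] for j in range(m)
    ]

    rng = random.Random(seed)
    rand = rng.random
    log = math.log

    x = x0.tolist()
    t = 0.0
    times: list[float] = []
    fired: list[int] = []
    props = [0.0] * m
    absorbed = False
    append_t = times.append
    append_j = fired.append

    for _ in range(max_events):
        a0 = 0.0
        for j in range(m):
            a = k_eff[j]
            for i, n in orders[j]:
                xi = x[i]
                if n == 1:
                    a *= xi
                elif n == 2:
                    a *= xi * (xi - 1) * 0.5
                else:
                    a *= _combinations(xi, n)
            props[j] = a
            a0 += a
        if a0 <= 0.0:
            absorbed = True
            break
        t += -log(1.0 - rand()) / a0
        if t >= t_end:
            break
        target = rand() * a0
        acc = 0.0
        for j in range(m):
            acc += props[j]
            if target < acc:
                break
        append_t(t)
        append_j(j)
        for i, d in changes[j]:
            x[i] += d
    else:
        raise RuntimeError(f"event cap {max_events} reached at t={t:.3g} h")

    n_events = len(times)
    all_times = np.empty(n_events + 1)
    all_times[0] = 0.0
    all_times[1:] = times
    states = np.empty((n_events + 1, network.n_species), dtype=np.int64)
    states[0] = x0
    if n_events:
        states[1:] = x0 + np.cumsum(stoich[fired], axis=0)
    traj = Trajectory(
        times=all_times,
        states=states,
        network=network,
        metadata={
            "backend": "ssa",
            "variant": network.variant,
            "seed": seed,
            "t_end": t_end,
            "burn_in": burn_in,
        },
    )
    return SSARun(
        trajectory=traj,
        seed=seed,
        t_end=t_end,
        burn_in=burn_in,
        event_count=n_events,
        absorbed=absorbed,
    )


def weighted_mean_var(
    times: np.ndarray,
    values: np.ndarray,
    t_start: float,
    t_end: float,
) -> tuple[float, float]:
    """Dwell-time-weighted mean and variance of a piecewise-constant path.

    ``values[i]`` holds on ``[times[i], times[i+1])`` and the last value
    holds to ``t_end``. NaN values mark undefined intervals and carry zero
    weight.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    edges = np.append(times, t_end)
    lo = np.clip(edges[:-1], t_start, t_end)
    hi = np.clip(edges[1:], t_start, t_end)
    w = hi - lo
    defined = ~np.isnan(values)
    w = np.where(defined, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no defined dwell time in the requested window")
    v = np.where(defined, values, 0.0)
    mean = float((w * v).sum() / total)
    var = float((w * (v - mean) ** 2).sum() / total)
    return mean, var


@dataclass(frozen=True)
class SummaryStats:
    """Dwell-time-weighted moments of one observable."""

    mean: float
    variance: float

    @property
    def fano(self) -> float:
        """Variance over mean; undefined at zero mean."""
        if self.mean == 0.0:
            if self.variance == 0.0:
                return float("nan")
            raise ValueError("Fano factor undefined: zero mean, nonzero variance")
        return self.variance / self.mean


def time_weighted_stats(
    run: SSARun,
    observable: str | Callable[[np.ndarray], np.ndarray],
) -> SummaryStats:
    """Stationary moments of a species (by name) or derived observable.

    Statistics are taken over ``[burn_in, t_end]`` with each recorded state
    weighted by its dwell time; a callable observable receives the full
    (n_times, n_species) state matrix and returns one value per time.
    """
    if run.event_count < 2:
        raise ValueError("need at least 2 events after burn-in for statistics")
    if callable(observable):
        values = np.asarray(observable(run.states), dtype=float)
    else:
        values = run.species_series(observable).astype(float)
    mean, var = weighted_mean_var(run.times, values, run.burn_in, run.t_end)
    return SummaryStats(mean=mean, variance=var)
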