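"""Deterministic (mass-action ODE) backend for the HipBA networks.

The right-hand side is generated from the :class:`~hipba.network.ReactionNetwork`
reaction list, so the ODE and SSA backends share one model definition. For the
wild-type network the generated system is exactly the printed rate equations
of the operon model, including the half factors on the dimer and complex
balance lines (event-rate convention; see :mod:`hipba.network`).

Equilibria are located by long stiff integration followed by Newton root
polishing, and validated against an infinity-norm residual tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork
from .parameters import ParameterSet

__all__ = [
    "Trajectory",
    "IntegrationError",
    "EquilibriumNotConverged",
    "ode_rhs",
    "make_rhs",
    "simulate_deterministic",
    "find_equilibrium",
    "steady_state",
]


class IntegrationError(RuntimeError):
    """Stiff integration failed; carries the offending setup."""


class EquilibriumNotConverged(RuntimeError):
    """Equilibrium search did not reach the residual tolerance."""


@dataclass
class Trajectory:
    """Time-ordered species amounts with provenance metadata."""

    times: np.ndarray  # hours, strictly increasing
    states: np.ndarray  # (n_times, n_species)
    network: ReactionNetwork
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)  # float (ODE) or int (SSA)
        if len(self.times) != len(self.states):
            raise ValueError("times and states lengths differ")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.network.species_index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def make_rhs(
    network: ReactionNetwork, params: ParameterSet | Mapping[str, float]
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the mass-action right-hand side ``f(t, x)`` for a network.

    Deterministic event rate of reaction j:
    ``rate_factor_j * k_j * prod_i x_i^{n_ij} / n_ij!``.
    """
    S = network.stoichiometry.astype(float)  # (m, s)
    m, s = S.shape
    E = np.zeros((m, s))  # reactant order matrix
    fact = np.ones(m)
    for j, pairs in enumerate(network.reactant_orders):
        for i, n in pairs:
            E[j, i] = n
            fact[j] *= math.factorial(n)
    k_eff = network.rate_vector(params) / fact

    ST = S.T.copy()

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        rates = k_eff * np.prod(
            np.power(x[None, :], E), axis=1
        )
        return ST @ rates

    return rhs


def ode_rhs(
    state,
    params: ParameterSet | Mapping[str, float],
    network: ReactionNetwork,
) -> np.ndarray:
    """Mass-action derivatives (molecules/hour) at a validated state."""
    x = network.validate_state(state)
    return make_rhs(network, params)(0.0, x)


def simulate_deterministic(
    network: ReactionNetwork,
    params: ParameterSet | Mapping[str, float],
    init,
    t_end: float,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    n_output: int = 200,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network ODEs from ``init`` to ``t_end``.

    Promoter conservation is checked at every output time against the
    integrator's absolute tolerance (scaled by promoter copy number).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be positive")
    x0 = network.validate_state(init)
    rhs = make_rhs(network, params)
    t_eval = np.linspace(0.0, t_end, n_output)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed for variant {network.variant!r}: "
            f"{sol.message}; init={x0.tolist()}"
        )
    # drop the duplicate t=0 guard solve_ivp sometimes returns, keep monotone
    traj = Trajectory(
        times=sol.t,
        states=sol.y.T,
        network=network,
        metadata={
            "backend": "ode",
            "variant": network.variant,
            "rel_tol": rel_tol,
            "abs_tol": abs_tol,
            "params": dict(params.as_dict() if hasattr(params, "as_dict") else params),
        },
    )
    return traj


def steady_state(
    network: ReactionNetwork,
    params: ParameterSet | Mapping[str, float],
    init,
    t_max: float = 1000.0,
    residual_tol: float = 1e-4,
    rel_tol: float = 1e-7,
    abs_tol: float = 1e-9,
) -> tuple[np.ndarray, bool]:
    """Endpoint of a long integration, Newton-polished.

    Returns ``(state, converged)`` where ``converged`` means the polished
    residual satisfies ``||f||_inf < residual_tol`` and the state is
    nonnegative (tiny negative round-off is clipped). Never raises on
    non-convergence; callers that must fail loudly use
    :func:`find_equilibrium`.
    """
    x0 = network.validate_state(init)
    rhs = make_rhs(network, params)
    try:
        sol = solve_ivp(
            rhs, (0.0, t_max), x0, method="LSODA",
            t_eval=[t_max], rtol=rel_tol, atol=abs_tol,
        )
    except (ValueError, FloatingPointError):
        return x0, False
    if not sol.success:
        return x0, False
    x_end = sol.y[:, -1]
    f = lambda x: rhs(0.0, x)
    try:
        polished = root(f, x_end, method="hybr")
        x_eq = polished.x if polished.success else x_end
    except Exception:
        x_eq = x_end
    # clip round-off negatives; genuine negative roots are rejected below
    x_eq = np.where((x_eq < 0) & (x_eq > -1e-8), 0.0, x_eq)
    if np.any(x_eq < 0):
        return x_end, False
    converged = bool(np.max(np.abs(f(x_eq))) < residual_tol)
    return x_eq, converged


def find_equilibrium(
    network: ReactionNetwork,
    params: ParameterSet | Mapping[str, float],
    init=None,
    t_max: float = 1000.0,
    residual_tol: float = 1e-6,
) -> np.ndarray:
    """Locate an equilibrium by long integration plus root polishing.

    Raises :class:`EquilibriumNotConverged` if the polished residual exceeds
    ``residual_tol`` (default 1e-6 molecules/hour).
    """
    if init is None:
        init = network.initial_state()
    x_eq, _ = steady_state(
        network, params, init, t_max=t_max, residual_tol=residual_tol,
        rel_tol=1e-9, abs_tol=1e-11,
    )
    rhs = make_rhs(network, params)
    resid = float(np.max(np.abs(rhs(0.0, x_eq))))
    if resid >= residual_tol:
        raise EquilibriumNotConverged(
            f"residual {resid:.3g} >= {residual_tol:.3g} for variant "
            f"{network.variant!r} from init={np.asarray(init).tolist()}"
        )
    return x_eq
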