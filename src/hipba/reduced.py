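"""Quasi-steady-state reduction of the wild-type circuit and phase-plane tools.

The promoter states, mRNA, HipB monomer and HipB dimer relax fast relative to
free HipA (A) and the toxin-antitoxin complex (AB2A). Setting their time
derivatives to zero at given (A, AB2A) collapses the six fast balances to a
single scalar fixed-point equation in the dimer level B2, solved by bracketed
root finding:

* promoter occupancies follow from binding equilibrium,
  ``P' = (theta_B2 B2 / gamma_B2) P``, ``P'' = (theta_AB2A AB2A / gamma_AB2A) P``,
  with the copy-number constraint;
* mRNA balances transcription from the three promoter states against decay;
* monomeric HipB solves the quadratic ``beta_B M = beta_B2 B^2 + delta_B B``;
* the dimer balance then gives an implied B2, whose self-consistent value is
  the unique nonnegative root (the promoter binding/unbinding fluxes cancel
  identically at promoter equilibrium).

The resulting planar vector field (dA/dt, dAB2A/dt) is used to trace
nullclines and count their intersections — each intersection is an
equilibrium of the full model, so a single crossing certifies monostability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, root

from .parameters import ParameterSet

__all__ = [
    "FastStates",
    "NullclineSet",
    "QSSError",
    "qss_fast_states",
    "reduced_rhs",
    "find_equilibria_2d",
    "count_equilibria",
    "nullclines_to_csv",
]

FAST_SPECIES = ("P", "P_b2", "P_ab2a", "M", "B", "B2")


class QSSError(RuntimeError):
    """No nonnegative fast-state solution found on the search bracket."""


@dataclass(frozen=True)
class FastStates:
    """Fast-variable equilibrium at fixed (A, AB2A)."""

    P: float
    P_b2: float
    P_ab2a: float
    M: float
    B: float
    B2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.P_b2, self.P_ab2a, self.M, self.B, self.B2])


def _fast_given_b2(
    b2: float, A: float, AB2A: float, p: ParameterSet, n_prom: float
) -> tuple[float, float, float, float, float]:
    """Promoter occupancies, mRNA and HipB monomer implied by a dimer level."""
    w_b2 = p.theta_B2 * b2 / p.gamma_B2
    w_ab2a = p.theta_AB2A * AB2A / p.gamma_AB2A
    P = n_prom / (1.0 + w_b2 + w_ab2a)
    P_b2 = w_b2 * P
    P_ab2a = w_ab2a * P
    M = (p.alpha * P + p.alpha_B2 * P_b2 + p.alpha_AB2A * P_ab2a) / p.delta_M
    # beta_B M = beta_B2 B^2 + delta_B B  (positive root)
    B = (
        -p.delta_B + np.sqrt(p.delta_B**2 + 4.0 * p.beta_B2 * p.beta_B * M)
    ) / (2.0 * p.beta_B2)
    return P, P_b2, P_ab2a, M, B


def _implied_b2(
    b2: float, A: float, AB2A: float, p: ParameterSet, n_prom: float
) -> float:
    _, _, _, _, B = _fast_given_b2(b2, A, AB2A, p, n_prom)
    # dimer balance with promoter fluxes cancelled at promoter equilibrium
    return (0.5 * p.beta_B2 * B**2 + 0.5 * p.mu_R * AB2A) / (
        0.5 * p.mu * A**2 + p.delta_B2
    )


def qss_fast_states(
    A: float,
    AB2A: float,
    params: ParameterSet,
    promoter_copies: float = 1.0,
) -> FastStates:
    """Solve the six fast balances at fixed slow coordinates (A, AB2A)."""
    if A < 0 or AB2A < 0:
        raise ValueError("A and AB2A must be nonnegative")
    p = params
    g = lambda b2: _implied_b2(b2, A, AB2A, p, promoter_copies) - b2
    # upper bracket: dimer production is bounded by fully active transcription
    m_up = promoter_copies * max(p.alpha, p.alpha_B2, p.alpha_AB2A) / p.delta_M
    b_up = (
        -p.delta_B + np.sqrt(p.delta_B**2 + 4.0 * p.beta_B2 * p.beta_B * m_up)
    ) / (2.0 * p.beta_B2)
    b2_up = (0.5 * p.beta_B2 * b_up**2 + 0.5 * p.mu_R * AB2A) / (
        0.5 * p.mu * A**2 + p.delta_B2
    ) + 1.0
    g0 = g(0.0)
    if g0 < 0:
        b2 = 0.0
    elif g(b2_up) > 0:
        raise QSSError(
            f"no dimer-balance root in [0, {b2_up:.3g}] at A={A}, AB2A={AB2A}"
        )
    else:
        b2 = brentq(g, 0.0, b2_up, xtol=1e-14, rtol=1e-14)
    P, P_b2, P_ab2a, M, B = _fast_given_b2(b2, A, AB2A, p, promoter_copies)
    return FastStates(P=P, P_b2=P_b2, P_ab2a=P_ab2a, M=M, B=B, B2=b2)


def reduced_rhs(
    A: float,
    AB2A: float,
    params: ParameterSet,
    promoter_copies: float = 1.0,
) -> tuple[float, float]:
    """(dA/dt, dAB2A/dt) of the two-dimensional slow model.

    These are the full-model toxin and complex balance lines evaluated with
    the fast species at their conditional equilibrium; the promoter
    binding/unbinding fluxes of the complex cancel there.
    """
    p = params
    fs = qss_fast_states(A, AB2A, params, promoter_copies)
    dA = p.beta_A * fs.M - p.mu * A**2 * fs.B2 + p.mu_R * AB2A - p.delta_A * A
    dAB2A = (
        0.5 * p.mu * A**2 * fs.B2 - 0.5 * p.mu_R * AB2A - p.delta_AB2A * AB2A
    )
    return dA, dAB2A


@dataclass
class NullclineSet:
    """Nullcline traces and their intersections on the (A, AB2A) plane."""

    a_grid: np.ndarray
    ab2a_grid: np.ndarray
    #: points (A, AB2A) where dA/dt = 0
    a_nullcline: np.ndarray
    #: points (A, AB2A) where dAB2A/dt = 0
    ab2a_nullcline: np.ndarray
    #: (n, 2) intersection points
    intersections: np.ndarray
    #: (n, 2) residuals of the planar field at each intersection
    residuals: np.ndarray
    #: True where both Jacobian eigenvalues have negative real part
    stable: np.ndarray

    @property
    def n_equilibria(self) -> int:
        return len(self.intersections)


def _merge_points(
    points: list[np.ndarray], rel_tol: float
) -> list[np.ndarray]:
    """Single-linkage merge of near-duplicate points (relative distance)."""
    merged: list[list[np.ndarray]] = []
    for pt in points:
        placed = False
        for group in merged:
            for other in group:
                denom = np.maximum(np.maximum(np.abs(pt), np.abs(other)), 1e-6)
                if np.max(np.abs(pt - other) / denom) < rel_tol:
                    group.append(pt)
                    placed = True
                    break
            if placed:
                break
        if not placed:
            merged.append([pt])
    return [np.mean(g, axis=0) for g in merged]


def find_equilibria_2d(
    rhs: Callable[[float, float], tuple[float, float]],
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    merge_rel_tol: float = 0.005,
    residual_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Locate equilibria of a planar vector field on a grid.

    Evaluates the field at every grid node, seeds a Newton solve in every
    cell where both components change sign across the cell corners, and
    merges converged roots closer than ``merge_rel_tol`` in relative
    distance. Returns (f1 grid, f2 grid, intersections, residuals, stable).
    """
    nx, ny = len(x_grid), len(y_grid)
    F1 = np.empty((nx, ny))
    F2 = np.empty((nx, ny))
    for i, x in enumerate(x_grid):
        for j, y in enumerate(y_grid):
            F1[i, j], F2[i, j] = rhs(x, y)

    def vec(z):
        return np.array(rhs(max(z[0], 0.0), max(z[1], 0.0)))

    candidates: list[np.ndarray] = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            c1 = F1[i : i + 2, j : j + 2]
            c2 = F2[i : i + 2, j : j + 2]
            if c1.min() <= 0 <= c1.max() and c2.min() <= 0 <= c2.max():
                x0 = np.array(
                    [
                        np.sqrt(x_grid[i] * x_grid[i + 1])
                        if x_grid[i] > 0
                        else 0.5 * (x_grid[i] + x_grid[i + 1]),
                        np.sqrt(y_grid[j] * y_grid[j + 1])
                        if y_grid[j] > 0
                        else 0.5 * (y_grid[j] + y_grid[j + 1]),
                    ]
                )
                sol = root(vec, x0, method="hybr")
                if sol.success and np.all(sol.x > -1e-9):
                    pt = np.maximum(sol.x, 0.0)
                    if np.max(np.abs(vec(pt))) < max(
                        residual_tol, 1e-9 * np.max(np.abs(pt) + 1.0)
                    ):
                        candidates.append(pt)
    merged = _merge_points(candidates, merge_rel_tol)
    if merged:
        inter = np.array(merged)
        resid = np.array([vec(pt) for pt in inter])
        stable = np.array([_is_stable(rhs, pt) for pt in inter])
    else:
        inter = np.empty((0, 2))
        resid = np.empty((0, 2))
        stable = np.empty(0, dtype=bool)
    return F1, F2, inter, resid, stable


def _is_stable(rhs, pt, h_rel: float = 1e-6) -> bool:
    """Sign check of the finite-difference Jacobian eigenvalues."""
    x, y = pt
    hx = h_rel * max(abs(x), 1.0)
    hy = h_rel * max(abs(y), 1.0)
    f = lambda a, b: np.array(rhs(max(a, 0.0), max(b, 0.0)))
    J = np.column_stack(
        [
            (f(x + hx, y) - f(max(x - hx, 0.0), y)) / (x + hx - max(x - hx, 0.0)),
            (f(x, y + hy) - f(x, max(y - hy, 0.0))) / (y + hy - max(y - hy, 0.0)),
        ]
    )
    eig = np.linalg.eigvals(J)
    return bool(np.all(eig.real < 0))


def _trace_nullcline(
    component: int,
    F: np.ndarray,
    rhs,
    x_grid: np.ndarray,
    y_grid: np.ndarray,
) -> np.ndarray:
    """Bisection-refined zero crossings of one field component along grid lines."""
    pts: list[tuple[float, float]] = []
    # scan along x at fixed y
    for j, y in enumerate(y_grid):
        col = F[:, j]
        for i in range(len(x_grid) - 1):
            if col[i] == 0.0:
                pts.append((x_grid[i], y))
            elif col[i] * col[i + 1] < 0:
                f = lambda x: rhs(x, y)[component]
                pts.append((brentq(f, x_grid[i], x_grid[i + 1]), y))
    # scan along y at fixed x (catches segments parallel to the x sweep)
    for i, x in enumerate(x_grid):
        row = F[i, :]
        for j in range(len(y_grid) - 1):
            if row[j] * row[j + 1] < 0:
                f = lambda y: rhs(x, y)[component]
                pts.append((x, brentq(f, y_grid[j], y_grid[j + 1])))
    return np.array(pts) if pts else np.empty((0, 2))


def count_equilibria(
    params: ParameterSet,
    a_range: tuple[float, float] = (1e-2, 1e3),
    ab2a_range: tuple[float, float] = (1e-2, 1e3),
    n_grid: int = 60,
    promoter_copies: float = 1.0,
    merge_rel_tol: float = 0.005,
) -> tuple[int, NullclineSet]:
    """Count nullcline intersections of the reduced model on a log grid.

    The default ranges bracket the nominal equilibrium by more than an order
    of magnitude in each direction. Returns the number of distinct
    intersections plus the traced nullclines for plotting.
    """
    a_grid = np.geomspace(*a_range, n_grid)
    ab2a_grid = np.geomspace(*ab2a_range, n_grid)
    rhs = lambda a, c: reduced_rhs(a, c, params, promoter_copies)
    F1, F2, inter, resid, stable = find_equilibria_2d(
        rhs, a_grid, ab2a_grid, merge_rel_tol=merge_rel_tol
    )
    ncs = NullclineSet(
        a_grid=a_grid,
        ab2a_grid=ab2a_grid,
        a_nullcline=_trace_nullcline(0, F1, rhs, a_grid, ab2a_grid),
        ab2a_nullcline=_trace_nullcline(1, F2, rhs, a_grid, ab2a_grid),
        intersections=inter,
        residuals=resid,
        stable=stable,
    )
    return ncs.n_equilibria, ncs


def nullclines_to_csv(ncs: NullclineSet, path) -> None:
    """Write nullcline points as CSV with columns A, AB2A, which_nullcline."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["A", "AB2A", "which_nullcline"])
        for a, c in ncs.a_nullcline:
            writer.writerow([f"{a:.10g}", f"{c:.10g}", "dA_dt"])
        for a, c in ncs.ab2a_nullcline:
            writer.writerow([f"{a:.10g}", f"{c:.10g}", "dAB2A_dt"])
        for (a, c), st in zip(ncs.intersections, ncs.stable):
            writer.writerow(
                [f"{a:.10g}", f"{c:.10g}", "stable" if st else "unstable"]
            )
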