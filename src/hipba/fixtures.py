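"""Synthetic control networks with known behaviour.

These are not models of the HipBA circuit; they are small mass-action
systems with analytically placed equilibria, used as positive/negative
controls for the numerical machinery (multistability detection, SSA
calibration).
"""

from __future__ import annotations

import numpy as np

from .network import (
    ROLE_MRNA,
    ROLE_PROMOTER_FREE,
    ROLE_PROTEIN,
    Reaction,
    ReactionNetwork,
)

__all__ = [
    "bistable_network",
    "BISTABLE_RATES",
    "BISTABLE_STABLE_STATES",
    "birth_death_network",
    "two_state_promoter_network",
    "toggle_rhs",
]

# Schloegl-type autocatalytic switch. With the event-rate convention
# rate = k * x^n / n!, the deterministic balance is
#   dx/dt = k3 + (k1/2) x^2 - (k2/6) x^3 - k4 x = -c (x-100)(x-250)(x-400)
# for c = 1e-4, i.e. stable states at x = 100 and 400, unstable at 250.
BISTABLE_RATES = {"k1": 0.15, "k2": 6e-4, "k3": 1000.0, "k4": 16.5}
BISTABLE_STABLE_STATES = (100.0, 400.0)


def bistable_network() -> ReactionNetwork:
    """One-species autocatalytic network with two stable states (synthetic)."""
    reactions = (
        Reaction("autocatalysis", (("X", 2),), (("X", 3),), "k1"),
        Reaction("reverse autocatalysis", (("X", 3),), (("X", 2),), "k2"),
        Reaction("constitutive birth", (), (("X", 1),), "k3"),
        Reaction("decay", (("X", 1),), (), "k4"),
    )
    return ReactionNetwork(
        variant="bistable_control",
        species=("X",),
        reactions=reactions,
        roles={"X": ROLE_PROTEIN},
        promoter_groups=(),
        promoter_copies=1,
    )


def birth_death_network() -> ReactionNetwork:
    """Constitutive transcription/decay only: stationary law is Poisson.

    Uses the circuit's transcription and mRNA decay constants, so the
    stationary mean is alpha/delta_M and the Fano factor is one (synthetic
    calibration fixture).
    """
    reactions = (
        Reaction("transcription", (("P", 1),), (("P", 1), ("M", 1)), "alpha"),
        Reaction("decay", (("M", 1),), (), "delta_M"),
    )
    return ReactionNetwork(
        variant="birth_death_control",
        species=("P", "M"),
        reactions=reactions,
        roles={"P": ROLE_PROMOTER_FREE, "M": ROLE_MRNA},
        promoter_groups=(("P",),),
        promoter_copies=1,
    )


def two_state_promoter_network() -> ReactionNetwork:
    """Promoter toggling P <-> P' with a single repressor copy (synthetic).

    With one dimer present, the stationary bound-state occupancy is the
    two-state closed form theta_B2 / (theta_B2 + gamma_B2).
    """
    reactions = (
        Reaction(
            "binding", (("P", 1), ("B2", 1)), (("P_b2", 1),), "theta_B2"
        ),
        Reaction(
            "unbinding", (("P_b2", 1),), (("P", 1), ("B2", 1)), "gamma_B2"
        ),
    )
    return ReactionNetwork(
        variant="two_state_control",
        species=("P", "P_b2", "B2"),
        reactions=reactions,
        roles={
            "P": ROLE_PROMOTER_FREE,
            "P_b2": "promoter_bound",
            "B2": ROLE_PROTEIN,
        },
        promoter_groups=(("P", "P_b2"),),
        promoter_copies=1,
    )


def toggle_rhs(a: float = 4.0, n: float = 2.0):
    """Planar mutual-repression switch with three known equilibria.

    ``dx/dt = a/(1+y^n) - x``, ``dy/dt = a/(1+x^n) - y``. For a = 4, n = 2
    the equilibria are (2-sqrt(3), 2+sqrt(3)), its mirror image (both
    stable) and a symmetric saddle (synthetic phase-plane fixture).
    """

    def rhs(x: float, y: float) -> tuple[float, float]:
        return a / (1.0 + y**n) - x, a / (1.0 + x**n) - y

    return rhs
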