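"""Reaction networks for the HipBA circuit and its alternative architectures.

A :class:`ReactionNetwork` is the single source of truth shared by the
deterministic (ODE) and stochastic (SSA) backends. Reactions are mass-action:
each carries reactant and product stoichiometries and the name of the rate
constant that scales it. A per-reaction ``rate_factor`` encodes event-rate
conventions that differ from the bare constant — here only the complex
dissociation, whose event rate is half the printed constant so that one
dissociation event releasing two toxin molecules reproduces the deterministic
rate equations of the wild-type model.

Three architectures are provided:

``wild_type``
    The native operon: one promoter with free (P), dimer-repressed (P') and
    complex-repressed (P'') states, one shared mRNA, 17 reactions, 8 species.
``uncoupled``
    hipA and hipB transcribed from two independent promoters (each with the
    three repression states) into separate mRNAs; 12 species. All rate
    constants equal the wild-type values, for a controlled comparison.
``no_feedback``
    Autorepression removed: only the free promoter state exists and
    transcription is constitutive; all remaining constants are wild type.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "UnknownVariantError",
    "VARIANTS",
    "build_network",
    "build_wild_type",
    "build_uncoupled",
    "build_no_feedback",
]

VARIANTS = ("wild_type", "uncoupled", "no_feedback")

# species roles used when randomizing initial conditions
ROLE_PROMOTER_FREE = "promoter_free"
ROLE_PROMOTER_BOUND = "promoter_bound"
ROLE_MRNA = "mrna"
ROLE_PROTEIN = "protein"


class UnknownVariantError(ValueError):
    """Raised when an architecture tag is not one of the known variants."""


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction channel.

    ``reactants``/``products`` map species name -> stoichiometric count.
    The event rate is ``rate_factor * k * h(state)`` where ``k`` is the rate
    constant named by ``rate``, and ``h`` is the mass-action kinetic term:
    ``prod x_i^n_i / n_i!`` for the ODE backend and the combinatorial
    ``prod C(x_i, n_i)`` for the SSA backend (identical in the large-count
    limit).
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: str
    rate_factor: float = 1.0


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, reactions and bookkeeping for one circuit architecture."""

    variant: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    roles: Mapping[str, str]
    #: groups of promoter-state species whose total copy number is conserved
    promoter_groups: tuple[tuple[str, ...], ...]
    promoter_copies: int = 1

    # --- derived, cached arrays -------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def stoichiometry(self) -> np.ndarray:
        """(n_reactions, n_species) net change matrix."""
        cached = getattr(self, "_stoich", None)
        if cached is None:
            S = np.zeros((self.n_reactions, self.n_species), dtype=np.int64)
            idx = {s: i for i, s in enumerate(self.species)}
            for j, rxn in enumerate(self.reactions):
                for sp, n in rxn.reactants:
                    S[j, idx[sp]] -= n
                for sp, n in rxn.products:
                    S[j, idx[sp]] += n
            object.__setattr__(self, "_stoich", S)
            cached = S
        return cached

    @property
    def reactant_orders(self) -> tuple[tuple[tuple[int, int], ...], ...]:
        """Per reaction: ((species_index, order), ...) for its reactants."""
        cached = getattr(self, "_orders", None)
        if cached is None:
            idx = {s: i for i, s in enumerate(self.species)}
            cached = tuple(
                tuple((idx[sp], n) for sp, n in rxn.reactants)
                for rxn in self.reactions
            )
            object.__setattr__(self, "_orders", cached)
        return cached

    def rate_vector(self, params: Mapping[str, float] | ParameterSet) -> np.ndarray:
        """Effective per-reaction constants (rate_factor folded in)."""
        return np.array(
            [rxn.rate_factor * params[rxn.rate] for rxn in self.reactions]
        )

    # --- initial conditions ----------------------------------------------
    def initial_state(self) -> np.ndarray:
        """All species zero except free promoters at full copy number."""
        x = np.zeros(self.n_species)
        for i, sp in enumerate(self.species):
            if self.roles[sp] == ROLE_PROMOTER_FREE:
                x[i] = self.promoter_copies
        return x

    def promoter_totals(self, state: Sequence[float]) -> np.ndarray:
        """Total promoter copies per gene group at a given state."""
        x = np.asarray(state, dtype=float)
        idx = {s: i for i, s in enumerate(self.species)}
        return np.array(
            [sum(x[idx[sp]] for sp in group) for group in self.promoter_groups]
        )

    def validate_state(self, state: Sequence[float]) -> np.ndarray:
        x = np.asarray(state, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(
                f"state must have {self.n_species} entries for variant "
                f"{self.variant!r}, got shape {x.shape}"
            )
        if np.any(x < 0):
            bad = [self.species[i] for i in np.where(x < 0)[0]]
            raise ValueError(f"negative amounts for species {bad}")
        return x

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "promoter_copies": self.promoter_copies,
            "species": list(self.species),
            "roles": dict(self.roles),
            "promoter_groups": [list(g) for g in self.promoter_groups],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": {sp: n for sp, n in r.reactants},
                    "products": {sp: n for sp, n in r.products},
                    "rate": r.rate,
                    "rate_factor": r.rate_factor,
                }
                for r in self.reactions
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReactionNetwork":
        return cls(
            variant=data["variant"],
            species=tuple(data["species"]),
            reactions=tuple(
                Reaction(
                    name=r["name"],
                    reactants=tuple(r["reactants"].items()),
                    products=tuple(r["products"].items()),
                    rate=r["rate"],
                    rate_factor=r.get("rate_factor", 1.0),
                )
                for r in data["reactions"]
            ),
            roles=dict(data["roles"]),
            promoter_groups=tuple(tuple(g) for g in data["promoter_groups"]),
            promoter_copies=data.get("promoter_copies", 1),
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(json.loads(text))


def _rxn(name, reactants, products, rate, factor=1.0) -> Reaction:
    return Reaction(
        name=name,
        reactants=tuple(reactants),
        products=tuple(products),
        rate=rate,
        rate_factor=factor,
    )


def _protein_reactions() -> list[Reaction]:
    """Post-translational reactions shared verbatim by all three variants."""
    return [
        _rxn("HipB degradation", [("B", 1)], [], "delta_B"),
        _rxn("HipA degradation", [("A", 1)], [], "delta_A"),
        _rxn("HipB dimerization", [("B", 2)], [("B2", 1)], "beta_B2"),
        _rxn("HipB dimer degradation", [("B2", 1)], [], "delta_B2"),
        _rxn(
            "complex association",
            [("A", 2), ("B2", 1)],
            [("AB2A", 1)],
            "mu",
        ),
        # one dissociation event releases 2 A + B2; the event rate is half
        # the printed constant so the toxin release rate is mu_R * [AB2A]
        _rxn(
            "complex dissociation",
            [("AB2A", 1)],
            [("A", 2), ("B2", 1)],
            "mu_R",
            factor=0.5,
        ),
        _rxn("complex degradation", [("AB2A", 1)], [], "delta_AB2A"),
    ]


def _promoter_reactions(p, pp, ppp, mrna) -> list[Reaction]:
    """Transcription and repressor binding for one promoter (3 states)."""
    return [
        _rxn(f"transcription {p}", [(p, 1)], [(p, 1), (mrna, 1)], "alpha"),
        _rxn(f"transcription {pp}", [(pp, 1)], [(pp, 1), (mrna, 1)], "alpha_B2"),
        _rxn(
            f"transcription {ppp}",
            [(ppp, 1)],
            [(ppp, 1), (mrna, 1)],
            "alpha_AB2A",
        ),
        _rxn(f"B2 binds {p}", [(p, 1), ("B2", 1)], [(pp, 1)], "theta_B2"),
        _rxn(f"B2 unbinds {pp}", [(pp, 1)], [(p, 1), ("B2", 1)], "gamma_B2"),
        _rxn(
            f"AB2A binds {p}",
            [(p, 1), ("AB2A", 1)],
            [(ppp, 1)],
            "theta_AB2A",
        ),
        _rxn(
            f"AB2A unbinds {ppp}",
            [(ppp, 1)],
            [(p, 1), ("AB2A", 1)],
            "gamma_AB2A",
        ),
    ]


def build_wild_type(promoter_copies: int = 1) -> ReactionNetwork:
    """Native operon: 8 species, 17 reactions."""
    species = ("P", "P_b2", "P_ab2a", "M", "B", "A", "B2", "AB2A")
    reactions = (
        _promoter_reactions("P", "P_b2", "P_ab2a", "M")
        + [
            _rxn("mRNA degradation", [("M", 1)], [], "delta_M"),
            _rxn("HipB translation", [("M", 1)], [("M", 1), ("B", 1)], "beta_B"),
            # translated at beta_A (the HipA translation rate of the table)
            _rxn("HipA translation", [("M", 1)], [("M", 1), ("A", 1)], "beta_A"),
        ]
        + _protein_reactions()
    )
    roles = {
        "P": ROLE_PROMOTER_FREE,
        "P_b2": ROLE_PROMOTER_BOUND,
        "P_ab2a": ROLE_PROMOTER_BOUND,
        "M": ROLE_MRNA,
        "B": ROLE_PROTEIN,
        "A": ROLE_PROTEIN,
        "B2": ROLE_PROTEIN,
        "AB2A": ROLE_PROTEIN,
    }
    return ReactionNetwork(
        variant="wild_type",
        species=species,
        reactions=tuple(reactions),
        roles=roles,
        promoter_groups=(("P", "P_b2", "P_ab2a"),),
        promoter_copies=promoter_copies,
    )


def build_uncoupled(promoter_copies: int = 1) -> ReactionNetwork:
    """hipA and hipB on independent promoters with separate mRNAs: 12 species.

    Both promoters keep the wild-type binding, unbinding and transcription
    constants; both repressors (B2 and AB2A) can bind either promoter.
    """
    species = (
        "P_A", "P_A_b2", "P_A_ab2a",
        "P_B", "P_B_b2", "P_B_ab2a",
        "M_A", "M_B", "B", "A", "B2", "AB2A",
    )
    reactions = (
        _promoter_reactions("P_A", "P_A_b2", "P_A_ab2a", "M_A")
        + _promoter_reactions("P_B", "P_B_b2", "P_B_ab2a", "M_B")
        + [
            _rxn("mRNA_A degradation", [("M_A", 1)], [], "delta_M"),
            _rxn("mRNA_B degradation", [("M_B", 1)], [], "delta_M"),
            _rxn(
                "HipA translation",
                [("M_A", 1)],
                [("M_A", 1), ("A", 1)],
                "beta_A",
            ),
            _rxn(
                "HipB translation",
                [("M_B", 1)],
                [("M_B", 1), ("B", 1)],
                "beta_B",
            ),
        ]
        + _protein_reactions()
    )
    roles = {
        "P_A": ROLE_PROMOTER_FREE,
        "P_A_b2": ROLE_PROMOTER_BOUND,
        "P_A_ab2a": ROLE_PROMOTER_BOUND,
        "P_B": ROLE_PROMOTER_FREE,
        "P_B_b2": ROLE_PROMOTER_BOUND,
        "P_B_ab2a": ROLE_PROMOTER_BOUND,
        "M_A": ROLE_MRNA,
        "M_B": ROLE_MRNA,
        "B": ROLE_PROTEIN,
        "A": ROLE_PROTEIN,
        "B2": ROLE_PROTEIN,
        "AB2A": ROLE_PROTEIN,
    }
    return ReactionNetwork(
        variant="uncoupled",
        species=species,
        reactions=tuple(reactions),
        roles=roles,
        promoter_groups=(
            ("P_A", "P_A_b2", "P_A_ab2a"),
            ("P_B", "P_B_b2", "P_B_ab2a"),
        ),
        promoter_copies=promoter_copies,
    )


def build_no_feedback(promoter_copies: int = 1) -> ReactionNetwork:
    """Autorepression removed: constitutive transcription, 6 species."""
    species = ("P", "M", "B", "A", "B2", "AB2A")
    reactions = (
        [
            _rxn("transcription P", [("P", 1)], [("P", 1), ("M", 1)], "alpha"),
            _rxn("mRNA degradation", [("M", 1)], [], "delta_M"),
            _rxn("HipB translation", [("M", 1)], [("M", 1), ("B", 1)], "beta_B"),
            _rxn("HipA translation", [("M", 1)], [("M", 1), ("A", 1)], "beta_A"),
        ]
        + _protein_reactions()
    )
    roles = {
        "P": ROLE_PROMOTER_FREE,
        "M": ROLE_MRNA,
        "B": ROLE_PROTEIN,
        "A": ROLE_PROTEIN,
        "B2": ROLE_PROTEIN,
        "AB2A": ROLE_PROTEIN,
    }
    return ReactionNetwork(
        variant="no_feedback",
        species=species,
        reactions=tuple(reactions),
        roles=roles,
        promoter_groups=(("P",),),
        promoter_copies=promoter_copies,
    )


def build_network(variant: str, promoter_copies: int = 1) -> ReactionNetwork:
    """Build one of the three architectures by tag."""
    if promoter_copies < 1:
        raise ValueError("promoter_copies must be >= 1")
    builders = {
        "wild_type": build_wild_type,
        "uncoupled": build_uncoupled,
        "no_feedback": build_no_feedback,
    }
    try:
        builder = builders[variant]
    except KeyError:
        raise UnknownVariantError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        ) from None
    return builder(promoter_copies)
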