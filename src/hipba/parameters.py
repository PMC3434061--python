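"""Rate constants of the hipBA operon model.

All amounts are molecule counts per cell; time is in hours. Bimolecular
constants therefore carry units of hour^-1 per molecule (or per molecule
squared for the termolecular complex-association step). Each constant has a
nominal value and a tested (low, high) range spanning a factor of ten on
either side of the nominal; the ranges drive the log-normal parameter scans.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = ["ParameterSet", "PARAMETER_TABLE", "PARAMETER_ORDER"]

# name -> (nominal, low, high); order follows the reaction table of the model
# (transcription, promoter binding/unbinding, mRNA turnover, translation,
# protein turnover, dimerization, complex association/dissociation).
PARAMETER_TABLE: dict[str, tuple[float, float, float]] = {
    "alpha": (60.0, 6.0, 600.0),  # transcription from free promoter P, hr^-1
    "alpha_B2": (6.0, 0.6, 60.0),  # transcription from B2-bound promoter P'
    "alpha_AB2A": (6.0, 0.6, 60.0),  # transcription from complex-bound P''
    "theta_B2": (1500.0, 150.0, 15000.0),  # B2 binds promoter, hr^-1 molec^-1
    "gamma_B2": (60.0, 6.0, 600.0),  # B2 unbinds promoter, hr^-1
    "theta_AB2A": (1500.0, 150.0, 15000.0),  # AB2A binds promoter
    "gamma_AB2A": (60.0, 6.0, 600.0),  # AB2A unbinds promoter
    "delta_M": (6.0, 0.6, 60.0),  # mRNA degradation, hr^-1
    "beta_B": (60.0, 6.0, 600.0),  # HipB translation, molec hr^-1 mRNA^-1
    "beta_A": (12.0, 1.2, 120.0),  # HipA translation, molec hr^-1 mRNA^-1
    "delta_B": (18.0, 1.8, 180.0),  # HipB degradation, hr^-1
    "delta_A": (1.2, 0.12, 12.0),  # HipA degradation, hr^-1
    "beta_B2": (60.0, 6.0, 600.0),  # HipB dimerization, hr^-1 molec^-1
    "delta_B2": (5.0, 0.5, 50.0),  # HipB dimer degradation, hr^-1
    "mu": (60.0, 6.0, 600.0),  # complex association, hr^-1 molec^-2
    "mu_R": (60.0, 6.0, 600.0),  # complex dissociation, hr^-1
    "delta_AB2A": (1.2, 0.12, 12.0),  # complex degradation, hr^-1
}

#: Table row order, used by the single-parameter scan.
PARAMETER_ORDER: tuple[str, ...] = tuple(PARAMETER_TABLE)


@dataclass(frozen=True)
class ParameterSet:
    """The 17 rate constants of the HipBA circuit.

    Defaults are the nominal values; :attr:`ranges` holds the tested
    (low, high) interval for each constant. All values must be strictly
    positive.
    """

    alpha: float = PARAMETER_TABLE["alpha"][0]
    alpha_B2: float = PARAMETER_TABLE["alpha_B2"][0]
    alpha_AB2A: float = PARAMETER_TABLE["alpha_AB2A"][0]
    theta_B2: float = PARAMETER_TABLE["theta_B2"][0]
    gamma_B2: float = PARAMETER_TABLE["gamma_B2"][0]
    theta_AB2A: float = PARAMETER_TABLE["theta_AB2A"][0]
    gamma_AB2A: float = PARAMETER_TABLE["gamma_AB2A"][0]
    delta_M: float = PARAMETER_TABLE["delta_M"][0]
    beta_B: float = PARAMETER_TABLE["beta_B"][0]
    beta_A: float = PARAMETER_TABLE["beta_A"][0]
    delta_B: float = PARAMETER_TABLE["delta_B"][0]
    delta_A: float = PARAMETER_TABLE["delta_A"][0]
    beta_B2: float = PARAMETER_TABLE["beta_B2"][0]
    delta_B2: float = PARAMETER_TABLE["delta_B2"][0]
    mu: float = PARAMETER_TABLE["mu"][0]
    mu_R: float = PARAMETER_TABLE["mu_R"][0]
    delta_AB2A: float = PARAMETER_TABLE["delta_AB2A"][0]

    #: per-name (low, high) tested range, shared by all instances
    ranges = {name: (lo, hi) for name, (_, lo, hi) in PARAMETER_TABLE.items()}

    def __post_init__(self) -> None:
        for name in PARAMETER_ORDER:
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(
                    f"rate constant {name!r} must be strictly positive, "
                    f"got {value!r}"
                )

    @classmethod
    def nominal(cls) -> "ParameterSet":
        return cls()

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        """Build from a name->value mapping; unknown names are rejected."""
        unknown = set(mapping) - set(PARAMETER_ORDER)
        if unknown:
            raise KeyError(
                f"unknown rate constant(s): {sorted(unknown)}; "
                f"valid names are {list(PARAMETER_ORDER)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_ORDER}

    def __getitem__(self, name: str) -> float:
        if name not in PARAMETER_ORDER:
            raise KeyError(name)
        return getattr(self, name)

    def __iter__(self) -> Iterator[str]:
        return iter(PARAMETER_ORDER)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_mapping(json.loads(text))
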