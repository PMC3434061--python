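"""Monte-Carlo multistability scans over the tested parameter ranges.

Two study designs are supported, mirroring the deterministic robustness
analysis of the circuit:

* ``single_parameter`` — one rate constant at a time is redrawn from a
  log-normal distribution anchored to its tested range while all others stay
  nominal; repeated for each of the 17 constants.
* ``all_parameters`` — every constant is redrawn simultaneously.

For each parameter draw the full model is integrated to steady state from
many random initial conditions (mRNA uniform on [0, 100], proteins uniform
on [0, 1000], promoters held at the free state), and the final states are
clustered under a 1% maximum-relative-difference metric: a single cluster
for every draw is evidence of monostability.

The log-normal is parameterized with median equal to the nominal value and
log-scale sigma chosen so the central 95% interval spans the tested range
(for the ten-fold ranges used here, ``sigma = ln(10)/1.96``); draws are not
truncated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .deterministic import steady_state
from .network import (
    ROLE_MRNA,
    ROLE_PROMOTER_BOUND,
    ROLE_PROMOTER_FREE,
    ROLE_PROTEIN,
    ReactionNetwork,
)
from .parameters import PARAMETER_ORDER, ParameterSet

__all__ = [
    "ScanConfig",
    "ScanResult",
    "sample_lognormal",
    "sample_parameters",
    "sample_initial_conditions",
    "cluster_final_states",
    "run_scan",
]

#: relative-difference guard for zero amounts, in molecules
ZERO_GUARD = 1e-6


@dataclass(frozen=True)
class ScanConfig:
    """Scan design; defaults follow the published study sizes."""

    mode: str = "all_parameters"  # or "single_parameter"
    #: combinations (all_parameters) or repeats per parameter
    #: (single_parameter); None selects the study defaults 1000 / 100
    n_parameter_draws: int | None = None
    n_initial_conditions: int = 500
    mrna_range: tuple[float, float] = (0.0, 100.0)
    protein_range: tuple[float, float] = (0.0, 1000.0)
    cluster_rel_tol: float = 0.01
    t_max: float = 1000.0
    residual_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single_parameter", "all_parameters"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.n_parameter_draws is None:
            object.__setattr__(
                self,
                "n_parameter_draws",
                100 if self.mode == "single_parameter" else 1000,
            )
        if self.n_parameter_draws < 1 or self.n_initial_conditions < 1:
            raise ValueError("draw and initial-condition counts must be >= 1")
        if not 0.0 < self.cluster_rel_tol < 1.0:
            raise ValueError("cluster_rel_tol must lie in (0, 1)")


def sample_lognormal(
    nominal: float, low: float, high: float, rng: np.random.Generator
) -> float:
    """Log-normal draw with median ``nominal`` and 95% interval (low, high).

    ``low`` and ``high`` anchor sigma on the log scale; samples are not
    truncated to the interval.
    """
    if not (0 < low <= nominal <= high):
        raise ValueError("require 0 < low <= nominal <= high")
    sigma = np.log(high / low) / (2.0 * 1.959963984540054)
    return float(nominal * np.exp(sigma * rng.standard_normal()))


def sample_parameters(
    mode: str,
    which_parameter: str | None,
    params_nominal: ParameterSet,
    rng: np.random.Generator,
) -> ParameterSet:
    """Draw a parameter set for one scan repetition."""
    if mode == "single_parameter":
        if which_parameter not in PARAMETER_ORDER:
            raise KeyError(
                f"unknown parameter {which_parameter!r}; "
                f"expected one of {list(PARAMETER_ORDER)}"
            )
        lo, hi = params_nominal.ranges[which_parameter]
        value = sample_lognormal(
            params_nominal[which_parameter], lo, hi, rng
        )
        return params_nominal.replace(**{which_parameter: value})
    if mode == "all_parameters":
        draws = {
            name: sample_lognormal(
                params_nominal[name], *params_nominal.ranges[name], rng
            )
            for name in PARAMETER_ORDER
        }
        return ParameterSet.from_mapping(draws)
    raise ValueError(f"unknown scan mode {mode!r}")


def sample_initial_conditions(
    network: ReactionNetwork,
    rng: np.random.Generator,
    mrna_range: tuple[float, float] = (0.0, 100.0),
    protein_range: tuple[float, float] = (0.0, 1000.0),
) -> np.ndarray:
    """Random initial state: uniform mRNA and proteins, promoters held free."""
    if mrna_range[0] < 0 or protein_range[0] < 0:
        raise ValueError("initial-condition ranges must be nonnegative")
    x = np.zeros(network.n_species)
    for i, sp in enumerate(network.species):
        role = network.roles[sp]
        if role == ROLE_PROMOTER_FREE:
            x[i] = network.promoter_copies
        elif role == ROLE_PROMOTER_BOUND:
            x[i] = 0.0
        elif role == ROLE_MRNA:
            x[i] = rng.uniform(*mrna_range)
        elif role == ROLE_PROTEIN:
            x[i] = rng.uniform(*protein_range)
        else:  # pragma: no cover - roles are fixed by the builders
            raise ValueError(f"species {sp!r} has unknown role {role!r}")
    return x


def cluster_final_states(
    states: Sequence[Sequence[float]], rel_tol: float = 0.01
) -> int:
    """Number of equilibrium clusters under the 1% relative-difference metric.

    Distance between two states is the maximum over species of
    ``|x - y| / max(x, y, eps)`` with ``eps`` = 1e-6 molecules; clusters are
    single-linkage connected components of the "within tolerance" graph, so
    one cluster is evidence of monostability.
    """
    X = np.asarray(states, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a nonempty list of states")
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    n = len(X)
    denom = np.maximum(
        np.maximum(X[:, None, :], X[None, :, :]), ZERO_GUARD
    )
    dist = np.max(np.abs(X[:, None, :] - X[None, :, :]) / denom, axis=2)
    adjacency = dist <= rel_tol
    # connected components by label propagation over the boolean graph
    labels = -np.ones(n, dtype=int)
    n_clusters = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = n_clusters
        while stack:
            j = stack.pop()
            neighbors = np.where(adjacency[j] & (labels < 0))[0]
            labels[neighbors] = n_clusters
            stack.extend(neighbors.tolist())
        n_clusters += 1
    return n_clusters


@dataclass
class ScanResult:
    """Per-draw parameters, cluster counts and the overall verdict."""

    config: ScanConfig
    variant: str
    #: one entry per draw: {"parameter": name or None, "params": {...},
    #: "n_clusters": int, "n_converged": int, "n_failed": int}
    draws: list[dict] = field(default_factory=list)

    @property
    def cluster_counts(self) -> list[int]:
        return [d["n_clusters"] for d in self.draws]

    @property
    def n_failed_total(self) -> int:
        return sum(d["n_failed"] for d in self.draws)

    @property
    def multistable(self) -> bool:
        return any(c > 1 for c in self.cluster_counts)

    @property
    def verdict(self) -> str:
        return "multistable" if self.multistable else "monostable"

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(
            {
                "config": dataclasses.asdict(self.config),
                "variant": self.variant,
                "verdict": self.verdict,
                "n_failed_total": self.n_failed_total,
                "draws": self.draws,
            },
            **kwargs,
        )

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for d in self.draws:
            row = {
                "parameter": d["parameter"],
                "n_clusters": d["n_clusters"],
                "n_converged": d["n_converged"],
                "n_failed": d["n_failed"],
            }
            row.update(d["params"])
            rows.append(row)
        return pd.DataFrame(rows)


def _scan_one_draw(
    network: ReactionNetwork,
    params,
    config: ScanConfig,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Integrate from random ICs, cluster the converged finals."""
    finals = []
    n_failed = 0
    for _ in range(config.n_initial_conditions):
        x0 = sample_initial_conditions(
            network, rng, config.mrna_range, config.protein_range
        )
        x_eq, converged = steady_state(
            network,
            params,
            x0,
            t_max=config.t_max,
            residual_tol=config.residual_tol,
        )
        if converged:
            finals.append(x_eq)
        else:
            n_failed += 1
    if not finals:
        return 0, 0, n_failed
    n_clusters = cluster_final_states(finals, config.cluster_rel_tol)
    return n_clusters, len(finals), n_failed


def run_scan(
    config: ScanConfig,
    network: ReactionNetwork,
    params_nominal: ParameterSet | Mapping[str, float] | None = None,
) -> ScanResult:
    """Execute a full multistability scan, reproducible from ``config.seed``.

    With a :class:`ParameterSet`, constants are redrawn per the scan mode;
    with a plain mapping (used by test fixtures with non-circuit networks)
    the rates stay fixed across draws and only initial conditions vary.
    Per-draw integration failures are excluded from clustering and counted.
    """
    if params_nominal is None:
        params_nominal = ParameterSet.nominal()
    result = ScanResult(config=config, variant=network.variant)
    master = np.random.SeedSequence(config.seed)

    def record(name, params, sub_seq):
        rng = np.random.default_rng(sub_seq)
        n_clusters, n_conv, n_failed = _scan_one_draw(
            network, params, config, rng
        )
        result.draws.append(
            {
                "parameter": name,
                "params": dict(
                    params.as_dict()
                    if isinstance(params, ParameterSet)
                    else params
                ),
                "n_clusters": n_clusters,
                "n_converged": n_conv,
                "n_failed": n_failed,
            }
        )

    sampled = isinstance(params_nominal, ParameterSet)
    if config.mode == "single_parameter" and sampled:
        # deterministic sub-seeds: one stream per (parameter, repeat)
        children = master.spawn(len(PARAMETER_ORDER))
        for name, param_seq in zip(PARAMETER_ORDER, children):
            repeats = param_seq.spawn(config.n_parameter_draws)
            for rep_seq in repeats:
                rng = np.random.default_rng(rep_seq)
                params = sample_parameters(
                    "single_parameter", name, params_nominal, rng
                )
                record(name, params, rep_seq.spawn(1)[0])
    else:
        children = master.spawn(config.n_parameter_draws)
        for rep_seq in children:
            if sampled and config.mode == "all_parameters":
                rng = np.random.default_rng(rep_seq)
                params = sample_parameters(
                    "all_parameters", None, params_nominal, rng
                )
            else:
                params = params_nominal
            record(None, params, rep_seq.spawn(1)[0])
    return result
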