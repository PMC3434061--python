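"""Persistence statistics: the R ratio, threshold crossings, and the
comparison of circuit architectures by mean and noise of R.

A cell is scored by ``R = free HipA / (free HipA + free HipB)``. Free HipA
is the unbound monomer A (toxin in the AB2A complex is neutralized and
excluded). Free HipB counts every antitoxin not sequestered in the toxin
complex: the monomer B plus two per dimer B2, since the dimer is the active
antitoxin form that captures HipA — ``R = A / (A + B + 2*B2)`` by default.
When R exceeds 0.5 the cell holds more free toxin than free antitoxin and
is classified a persister; the fraction of dwell time above threshold
estimates how often stochastic expression noise pushes a cell over.

The sensitivity option ``count_dimers=False`` restricts free HipB to the
monomer, ``R = A / (A + B)``. At nominal parameters that reading puts most
of the R mass above 0.5 (free monomeric HipB is scarcer than HipA because
dimerization is fast), so persistence would be the majority state; the
dimer-inclusive default is the reading consistent with rare persistence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .network import ReactionNetwork, build_network
from .parameters import ParameterSet
from .ssa import SSARun, default_ssa_init, gillespie_run, weighted_mean_var

__all__ = [
    "RSeries",
    "ArchitectureComparison",
    "compute_R",
    "detect_persistence",
    "r_histogram",
    "total_toxin",
    "total_antitoxin",
    "compare_architectures",
]

DEFAULT_THRESHOLD = 0.5


@dataclass
class RSeries:
    """Piecewise-constant R(t); NaN marks intervals with no free protein."""

    times: np.ndarray
    values: np.ndarray  # R in [0, 1] or NaN where undefined
    t_end: float
    burn_in: float
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("defined R values must lie in [0, 1]")

    def stats(self) -> tuple[float, float]:
        """Dwell-weighted (mean, variance) over [burn_in, t_end]."""
        return weighted_mean_var(
            self.times, self.values, self.burn_in, self.t_end
        )


def compute_R(
    run: SSARun,
    threshold: float = DEFAULT_THRESHOLD,
    count_dimers: bool = True,
) -> RSeries:
    """Toxin/antitoxin balance ratio along one stochastic trajectory."""
    A = run.species_series("A").astype(float)
    B = run.species_series("B").astype(float)
    denom = A + B + (2.0 * run.species_series("B2") if count_dimers else 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, A / np.where(denom > 0, denom, 1.0), np.nan)
    return RSeries(
        times=run.times,
        values=values,
        t_end=run.t_end,
        burn_in=run.burn_in,
        threshold=threshold,
        metadata={"seed": run.seed, "variant": run.network.variant,
                  "count_dimers": count_dimers},
    )


def detect_persistence(
    series: RSeries,
) -> tuple[list[tuple[float, float]], float]:
    """Maximal intervals with R above threshold, within [burn_in, t_end].

    Returns ``(events, fraction)`` where ``events`` is a list of
    (start, end) hour pairs and ``fraction`` is the dwell-time fraction of
    the defined observation window spent above threshold. Undefined (NaN)
    intervals break events and carry no weight.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    if np.all(np.isnan(v)):
        raise ValueError("R is undefined over the whole series")
    edges = np.append(t, series.t_end)
    lo = np.clip(edges[:-1], series.burn_in, series.t_end)
    hi = np.clip(edges[1:], series.burn_in, series.t_end)
    w = hi - lo
    defined = ~np.isnan(v)
    above = defined & (v > series.threshold) & (w > 0)
    events: list[tuple[float, float]] = []
    start = None
    end = None
    for i in range(len(v)):
        if above[i]:
            if start is None:
                start = lo[i]
            end = hi[i]
        elif w[i] > 0 and start is not None:
            events.append((start, end))
            start = None
    if start is not None:
        events.append((start, end))
    total_defined = float(np.where(defined, w, 0.0).sum())
    if total_defined <= 0:
        raise ValueError("no defined dwell time in the observation window")
    frac = float(np.where(above, w, 0.0).sum() / total_defined)
    return events, frac


def r_histogram(
    series_list: Sequence[RSeries], bins: int | np.ndarray = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Dwell-time-weighted ensemble histogram of R on [0, 1], mass one.

    Returns ``(edges, mass)`` with ``mass.sum() == 1``.
    """
    edges = (
        np.linspace(0.0, 1.0, bins + 1)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    mass = np.zeros(len(edges) - 1)
    total = 0.0
    for series in series_list:
        t = np.append(series.times, series.t_end)
        lo = np.clip(t[:-1], series.burn_in, series.t_end)
        hi = np.clip(t[1:], series.burn_in, series.t_end)
        w = hi - lo
        defined = ~np.isnan(series.values)
        w = np.where(defined, w, 0.0)
        v = np.where(defined, series.values, 0.0)
        h, _ = np.histogram(v, bins=edges, weights=w)
        mass += h
        total += w.sum()
    if total <= 0:
        raise ValueError("no defined R values to histogram")
    return edges, mass / total


def total_toxin(states: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Total HipA copies: free monomer plus two per complex."""
    A = states[:, network.species_index("A")]
    AB2A = states[:, network.species_index("AB2A")]
    return A + 2.0 * AB2A


def total_antitoxin(states: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Total HipB copies: free monomer plus two per dimer and per complex."""
    B = states[:, network.species_index("B")]
    B2 = states[:, network.species_index("B2")]
    AB2A = states[:, network.species_index("AB2A")]
    return B + 2.0 * B2 + 2.0 * AB2A


@dataclass
class ArchitectureComparison:
    """Replicate-level and summary R statistics for the three architectures."""

    replicates: pd.DataFrame  # one row per (architecture, seed)
    summary: pd.DataFrame  # one row per architecture
    #: one-sided Mann-Whitney p-values for the expected orderings
    order_tests: dict
    seeds: tuple[int, ...]
    horizon: float
    burn_in: float

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


ARCHITECTURES = ("wild_type", "uncoupled", "no_feedback")


def compare_architectures(
    params: ParameterSet,
    seeds: Sequence[int],
    horizon: float = 1000.0,
    burn_in: float = 100.0,
    count_dimers: bool = True,
    min_seeds_for_tests: int = 10,
) -> ArchitectureComparison:
    """Mean R and noise (sigma^2/mu of R) across replicate simulated cells.

    Each seed is one simulated cell per architecture, started at the
    architecture's deterministic equilibrium (rounded to counts) and run for
    ``horizon`` hours; statistics use dwell-time weighting after ``burn_in``.
    Expected orderings (uncoupled > wild type > no feedback, for both mean R
    and Fano of R) are scored with one-sided Mann-Whitney rank tests across
    replicates when at least ``min_seeds_for_tests`` seeds are supplied.
    """
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) < 3:
        raise ValueError("need at least 3 replicate seeds")
    rows = []
    for variant in ARCHITECTURES:
        network = build_network(variant)
        init = default_ssa_init(network, params)
        for seed in seeds:
            run = gillespie_run(
                network, params, init=init, t_end=horizon,
                seed=seed, burn_in=burn_in,
            )
            series = compute_R(run, count_dimers=count_dimers)
            mean, var = series.stats()
            _, frac = detect_persistence(series)
            rows.append(
                {
                    "architecture": variant,
                    "seed": seed,
                    "mean_R": mean,
                    "var_R": var,
                    "fano_R": var / mean if mean > 0 else float("nan"),
                    "persistence_fraction": frac,
                }
            )
    replicates = pd.DataFrame(rows)
    grouped = replicates.groupby("architecture", sort=False)
    summary = grouped.agg(
        n_replicates=("seed", "size"),
        mean_R=("mean_R", "mean"),
        sd_mean_R=("mean_R", "std"),
        fano_R=("fano_R", "mean"),
        sd_fano_R=("fano_R", "std"),
        persistence_fraction=("persistence_fraction", "mean"),
    ).reset_index()

    order_tests: dict = {}
    if len(seeds) >= min_seeds_for_tests:
        by_arch = {
            arch: replicates[replicates.architecture == arch]
            for arch in ARCHITECTURES
        }
        for metric in ("mean_R", "fano_R"):
            for hi_arch, lo_arch in (
                ("uncoupled", "wild_type"),
                ("wild_type", "no_feedback"),
            ):
                stat = mannwhitneyu(
                    by_arch[hi_arch][metric],
                    by_arch[lo_arch][metric],
                    alternative="greater",
                )
                order_tests[f"{metric}: {hi_arch} > {lo_arch}"] = float(
                    stat.pvalue
                )
    return ArchitectureComparison(
        replicates=replicates,
        summary=summary,
        order_tests=order_tests,
        seeds=seeds,
        horizon=float(horizon),
        burn_in=float(burn_in),
    )
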