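"""Mutation-selection transfer simulation of the death-probability trait.

Mimics the serial-transfer settling experiment: clusters grow under the
population-simulation rules with a heritable per-cell death probability
that mutates (uniform redraw within a range) each generation; when the
growth phase has added its budget of new cells, clusters are sampled
without replacement with probability proportional to their diameter
(the settling-speed proxy) until the retained clusters hold the
selection fraction of all living cells, and everything else is
discarded.  Starting from a low death probability, selection for large
(fast-settling) clusters nevertheless drives the population mean
upward, because dying cells free the attachment sites and shell space
that limit growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._arena import Arena
from .cluster import Cluster, diameter as cluster_diameter

__all__ = [
    "EvoConfig",
    "EvoTrajectory",
    "simulate_evolution",
    "settle_select",
]

WEIGHT_MODES = ("diameter", "diameter_squared", "rank", "uniform")


@dataclass
class EvoConfig:
    """Parameters of one evolutionary run.

    ``growth_budget`` is the number of *new cells* a growth phase must
    add before selection strikes (default 2^14, a desk-scale stand-in
    for the experiment-scale 2^21).  ``mutation_prob`` is scaled so the
    mutational supply N*mu per generation matches what a 2^21-cell
    population would see at a per-cell rate of 1e-4; without that
    scaling a desk-scale run is pure bottleneck drift.
    ``max_gens_per_phase`` guards against stalled phases in which
    volume-saturated clusters cannot add cells fast enough.
    """

    initial_p_death: float = 0.005
    mutation_prob: float = 1e-2
    mutation_range: tuple[float, float] = (0.0, 0.3)
    growth_budget: int = 2**14
    selection_fraction: float = 0.10
    transfers: int = 100
    degree_cap: Optional[int] = None
    volume_limited: bool = True
    death_delay: int = 0
    free_severed_links: bool = True
    weight: str = "diameter"
    max_gens_per_phase: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        p_min, p_max = self.mutation_range
        if not 0.0 <= p_min < p_max <= 1.0:
            raise ValueError("mutation_range must satisfy 0 <= p_min < p_max <= 1")
        if not 0.0 <= self.initial_p_death <= 1.0:
            raise ValueError("initial_p_death must be in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")
        if self.weight not in WEIGHT_MODES:
            raise ValueError(f"weight must be one of {WEIGHT_MODES}")


@dataclass
class EvoTrajectory:
    """Per-transfer time course of the evolving population.

    Arrays are indexed by transfer (entry 0 = state after the first
    transfer's selection).  ``mean_p_death`` is cell-weighted over
    living cells.  ``extinct`` flags a run that lost every living cell
    (arrays are truncated at that transfer); ``stalled_phases`` counts
    growth phases cut off by the generation guard.
    """

    config: EvoConfig
    mean_p_death: np.ndarray
    n_clusters: np.ndarray
    living_cells: np.ndarray
    extinct: bool = False
    stalled_phases: int = 0


def _retention_order(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling-without-replacement order (Efraimidis-Spirakis).

    Sorting by ``U**(1/w)`` descending reproduces sequential draws with
    probability proportional to weight; zero-weight items sort last in
    uniform random order (picked only if everything else is exhausted).
    """
    w = weights.astype(float)
    keys = np.zeros(w.size)
    pos = w > 0
    keys[pos] = rng.random(pos.sum()) ** (1.0 / w[pos])
    # zero weights: keys stay 0; break ties uniformly
    tie = rng.random(w.size)
    return np.lexsort((tie, -keys))


def _select_indices(
    weights: np.ndarray,
    living: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Indices retained by diameter-weighted settling selection."""
    total = living.sum()
    target = fraction * total
    order = _retention_order(weights, rng)
    kept = np.cumsum(living[order])
    n_keep = int(np.searchsorted(kept, target - 1e-9) + 1)
    n_keep = min(n_keep, order.size)
    return order[:n_keep]


def settle_select(
    clusters: Sequence[Cluster],
    fraction: float,
    rng: np.random.Generator,
    weight: str = "diameter",
) -> list[Cluster]:
    """Diameter-weighted selection over a list of clusters.

    Samples clusters without replacement, weight proportional to their
    diameter (or its square, or rank), until the retained clusters hold
    at least ``fraction`` of all living cells.
    """
    if not clusters:
        raise ValueError("empty population")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    diams = np.array([cluster_diameter(c) for c in clusters], dtype=float)
    living = np.array([c.living_count() for c in clusters], dtype=np.int64)
    w = _make_weights(diams, weight)
    idx = _select_indices(w, living, fraction, rng)
    return [clusters[i] for i in idx]


def _make_weights(diams: np.ndarray, weight: str) -> np.ndarray:
    if weight == "diameter":
        return diams.astype(float)
    if weight == "diameter_squared":
        return diams.astype(float) ** 2
    if weight == "rank":
        order = np.argsort(np.argsort(diams))
        return (order + 1).astype(float)
    if weight == "uniform":
        # neutral control: the same 10% bottleneck without any settling
        # bias (selection_fraction=1, i.e. no culling at all, makes the
        # population double every transfer and is not runnable for long)
        return np.ones(diams.size)
    raise ValueError(f"weight must be one of {WEIGHT_MODES}")


def simulate_evolution(config: EvoConfig) -> EvoTrajectory:
    """Run growth-mutation-selection transfers; see module docstring."""
    rng = np.random.default_rng(config.seed)
    arena = Arena(
        rng=rng,
        degree_cap=config.degree_cap,
        volume_limited=config.volume_limited,
        death_delay=config.death_delay,
        link_rule="branch_size_biased",
        free_severed_links=config.free_severed_links,
    )
    arena.add_founder(gen0=0, p_death=config.initial_p_death)
    p_min, p_max = config.mutation_range
    mean_p: list[float] = []
    n_clusters: list[int] = []
    living_cells: list[int] = []
    stalled = 0
    extinct = False
    gen = 0
    for _ in range(config.transfers):
        added = 0
        phase_gens = 0
        while added < config.growth_budget:
            gen += 1
            phase_gens += 1
            births, _ = arena.step(gen)
            if config.mutation_prob > 0:
                arena.mutate(config.mutation_prob, p_min, p_max)
            added += births
            if arena.living() == 0:
                extinct = True
                break
            if phase_gens >= config.max_gens_per_phase:
                stalled += 1
                break
        if extinct:
            break
        if config.selection_fraction < 1.0:
            labels, _ = arena.cluster_index()
            weights = _make_weights(arena.diameters().astype(float), config.weight)
            living = arena.living_sizes()
            keep = _select_indices(weights, living, config.selection_fraction, rng)
            arena.keep_clusters(labels[keep])
        alive = arena.alive
        mean_p.append(float(arena.p_death[alive].mean()))
        n_clusters.append(arena.n_clusters())
        living_cells.append(arena.living())
    return EvoTrajectory(
        config=config,
        mean_p_death=np.asarray(mean_p),
        n_clusters=np.asarray(n_clusters),
        living_cells=np.asarray(living_cells),
        extinct=extinct,
        stalled_phases=stalled,
    )
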