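"""Agent-based generational simulation of a population of clusters.

One run grows a whole population from a single founding cell.  Each
generation: (i) every cell that is alive, below the degree cap and has
room in the next shell of its own cluster buds one daughter
(synchronized, judged on the pre-step state); (ii) every susceptible
living cell then dies independently with probability ``p_death`` —
susceptible meaning at least ``death_delay`` generations have passed
since it last reproduced; (iii) each death severs one of the dead
cell's links (by default biased toward large branches), splitting its
cluster in two.  Dead cells stay attached, keep occupying shell space,
and never bud again.

The default 21 generations match the time a free-living cell population
would need to reach ~2^21 cells; the paradox probed here is that under
degree caps and volume limits a *higher* death probability can leave
*more* living cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._arena import Arena
from .cluster import Cell

__all__ = [
    "DEFAULT_P_DEATH_GRID",
    "SimConfig",
    "PopulationResult",
    "simulate_population",
    "susceptible",
    "clusters_above_threshold",
    "strategy_sweep",
]

#: Death probabilities used throughout the strategy comparisons: four
#: values on the rising limb of the living-cells response for capped,
#: volume-limited growth (death relieves geometric constraints there).
DEFAULT_P_DEATH_GRID: tuple[float, ...] = (0.0005, 0.001, 0.0025, 0.005)


@dataclass
class SimConfig:
    """Parameters of one population run."""

    degree_cap: Optional[int] = 3
    p_death: float = 0.005
    death_delay: int = 0
    volume_limited: bool = True
    generations: int = 21
    seed: int = 0
    severance: str = "branch_size_biased"
    reroot_shells: bool = True
    free_severed_links: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_death <= 1.0:
            raise ValueError("p_death must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.death_delay < 0:
            raise ValueError("death_delay must be >= 0")


@dataclass
class PopulationResult:
    """Per-generation totals and the final cluster census of one run.

    Generation arrays have ``generations + 1`` entries (index 0 is the
    founding state).  ``cluster_sizes`` counts living cells per cluster
    (clusters whose cells are all dead appear as 0).  ``splits`` has one
    row per severance: generation, parent-cluster size and both
    fragment sizes, all in total (living + dead) cells at the moment of
    the split.
    """

    config: SimConfig
    living_per_gen: np.ndarray
    dead_per_gen: np.ndarray
    clusters_per_gen: np.ndarray
    cluster_sizes: np.ndarray
    diameters: np.ndarray
    splits: pd.DataFrame = field(repr=False)

    @property
    def final_living(self) -> int:
        return int(self.living_per_gen[-1])

    def mean_offspring_fraction(self) -> float:
        """Mean smaller-fragment share over every recorded split."""
        if len(self.splits) == 0:
            return float("nan")
        frac = (
            np.minimum(self.splits["fragment_a"], self.splits["fragment_b"])
            / self.splits["parent_size"]
        )
        return float(frac.mean())


def susceptible(cell: Cell, gen: int, delay: int) -> bool:
    """Whether a living cell can die this generation.

    A cell is protected while it keeps reproducing: it becomes
    susceptible once at least ``delay`` generations have passed since
    its last reproductive event (``delay = 0``: always susceptible).
    """
    if not cell.alive:
        raise ValueError("susceptibility is defined for living cells")
    return gen - cell.last_repro_gen >= delay


def simulate_population(config: SimConfig) -> PopulationResult:
    """Run the generational simulation described in the module docstring."""
    rng = np.random.default_rng(config.seed)
    arena = Arena(
        rng=rng,
        degree_cap=config.degree_cap,
        volume_limited=config.volume_limited,
        death_delay=config.death_delay,
        link_rule=config.severance,
        reroot_shells=config.reroot_shells,
        free_severed_links=config.free_severed_links,
    )
    arena.add_founder(gen0=0, p_death=config.p_death)
    living = [arena.living()]
    dead = [arena.n_cells - arena.living()]
    n_clusters = [arena.n_clusters()]
    for gen in range(1, config.generations + 1):
        arena.step(gen)
        living.append(arena.living())
        dead.append(arena.n_cells - arena.living())
        n_clusters.append(arena.n_clusters())
    splits = pd.DataFrame(
        arena.splits,
        columns=["generation", "parent_size", "fragment_a", "fragment_b"],
    )
    return PopulationResult(
        config=config,
        living_per_gen=np.asarray(living),
        dead_per_gen=np.asarray(dead),
        clusters_per_gen=np.asarray(n_clusters),
        cluster_sizes=arena.living_sizes(),
        diameters=arena.diameters(),
        splits=splits,
    )


def clusters_above_threshold(
    result: PopulationResult, theta: int, measure: str = "clusters"
) -> int:
    """Clusters holding >= theta living cells, or the living cells they
    contain."""
    if theta < 1:
        raise ValueError("theta must be >= 1")
    if measure not in ("clusters", "cells"):
        raise ValueError("measure must be 'clusters' or 'cells'")
    sizes = result.cluster_sizes
    big = sizes[sizes >= theta]
    return int(big.size if measure == "clusters" else big.sum())


def strategy_sweep(
    caps: Sequence[Optional[int]],
    p_deaths: Sequence[float] = DEFAULT_P_DEATH_GRID,
    delays: Sequence[int] = (0,),
    thetas: Sequence[int] = (1,),
    replicates: int = 100,
    seed: int = 0,
    base_config: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Replicate runs over a grid of (degree cap, p_death, delay).

    Returns one row per strategy x threshold with the mean and variance
    of clusters above threshold and of living cells in those clusters,
    plus the strategy's mean living-cell total and mean smaller-offspring
    fraction.  Each (strategy, replicate) pair gets its own seed spawned
    from the master seed, so results do not depend on sweep ordering.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = base_config if base_config is not None else SimConfig()
    strategies = list(itertools.product(caps, p_deaths, delays))
    master = np.random.SeedSequence(seed)
    strategy_seeds = master.spawn(len(strategies))
    rows = []
    for (cap, p, delay), strat_ss in zip(strategies, strategy_seeds):
        rep_seeds = [
            int(ss.generate_state(1)[0] % (2**31)) for ss in strat_ss.spawn(replicates)
        ]
        results = [
            simulate_population(
                replace(base, degree_cap=cap, p_death=p, death_delay=delay, seed=s)
            )
            for s in rep_seeds
        ]
        living = np.array([r.final_living for r in results], dtype=float)
        frac = np.array([r.mean_offspring_fraction() for r in results])
        frac = frac[~np.isnan(frac)]
        for theta in thetas:
            n_above = np.array(
                [clusters_above_threshold(r, theta, "clusters") for r in results],
                dtype=float,
            )
            c_above = np.array(
                [clusters_above_threshold(r, theta, "cells") for r in results],
                dtype=float,
            )
            rows.append(
                {
                    "degree_cap": -1 if cap is None else cap,
                    "p_death": p,
                    "death_delay": delay,
                    "theta": theta,
                    "mean_clusters_above": n_above.mean(),
                    "var_clusters_above": n_above.var(ddof=1) if replicates > 1 else 0.0,
                    "mean_cells_above": c_above.mean(),
                    "var_cells_above": c_above.var(ddof=1) if replicates > 1 else 0.0,
                    "mean_living_cells": living.mean(),
                    "mean_offspring_fraction": (
                        float(frac.mean()) if frac.size else float("nan")
                    ),
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
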