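"""Cluster division by death-triggered link severance.

Because a cluster is a tree, breaking any single mother-daughter link
splits it into exactly two connected pieces — that is how a cluster
reproduces.  Cell death is taken as the primary severance mechanism:
which cell dies (uniformly random vs the oldest, most central cell) and
which of its links breaks (uniformly vs biased toward large branches,
which put more strain on their link) together set how symmetric the two
offspring are.

The expected smaller-offspring fraction is computed by *exact
enumeration* over every (victim, link) outcome on the deterministic
unconstrained tree, weighted by the mode's probabilities.  Closed forms
exist for oldest-cell death on the uncapped tree and are kept as
independent cross-checks: with branch-size-biased severance the
fraction is ``(4^t - 1) / (3 (2^t - 1) 2^t)``, which tends to 1/3; with
an unbiased link choice it is ``(2^t - 1) / (t 2^t)``, which tends to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cluster import (
    NO_PARENT,
    Cluster,
    branch_partition,
)

__all__ = [
    "SeveranceMode",
    "SplitResult",
    "sever",
    "death_and_sever",
    "expected_smaller_fraction",
    "asymptotic_biased_fraction",
    "biased_fraction_oldest",
    "uniform_fraction_oldest",
]

VICTIM_RULES = ("uniform_random_cell", "oldest_cell")
LINK_RULES = ("uniform_link", "branch_size_biased")


@dataclass(frozen=True)
class SeveranceMode:
    """How a death picks its victim and which of its links breaks."""

    victim_rule: str = "uniform_random_cell"
    link_rule: str = "branch_size_biased"

    def __post_init__(self) -> None:
        if self.victim_rule not in VICTIM_RULES:
            raise ValueError(f"victim_rule must be one of {VICTIM_RULES}")
        if self.link_rule not in LINK_RULES:
            raise ValueError(f"link_rule must be one of {LINK_RULES}")


@dataclass
class SplitResult:
    """Outcome of severing one link of a cluster.

    ``fragment_a`` keeps the original root; ``fragment_b`` is re-rooted
    at the severed daughter (``None`` for the degenerate single-cell
    death, which has no link to sever).  Dead cells travel with
    whichever fragment contains them.
    """

    fragment_a: Cluster
    fragment_b: Optional[Cluster]
    severed_link: Optional[tuple[int, int]]
    smaller_fraction: float


def sever(
    cluster: Cluster, link: tuple[int, int], free_link: bool = True
) -> SplitResult:
    """Split a cluster at one mother-daughter link.

    The input cluster is left unchanged; both fragments are fresh
    clusters (the daughter side re-rooted at the severed daughter, its
    shells recomputed from there).  By default the broken attachment
    frees a site on both endpoints (``links_used`` drops by one), which
    is what lets degree-capped cells reproduce again after a neighbour
    dies; pass ``free_link=False`` to leave a permanent bud scar
    instead.
    """
    mother, daughter = link
    if (
        not 0 <= daughter < len(cluster)
        or cluster._parent[daughter] != mother
    ):
        raise KeyError(f"no link {link} in cluster")
    fragment_b = cluster.extract(daughter)
    # rebuild the mother side by detaching the daughter subtree
    keep = np.ones(len(cluster), dtype=bool)
    stack = [daughter]
    while stack:
        u = stack.pop()
        keep[u] = False
        stack.extend(cluster._children[u])
    fragment_a = _subset(cluster, keep)
    if free_link:
        fragment_b._links_used[0] -= 1  # daughter lost her mother link
        # the mother keeps her id ordering inside fragment_a: cells with
        # id < daughter keep their position
        mother_new = sum(1 for i in range(mother) if keep[i])
        fragment_a._links_used[mother_new] -= 1
    n = len(cluster)
    nb = len(fragment_b)
    return SplitResult(
        fragment_a=fragment_a,
        fragment_b=fragment_b,
        severed_link=(mother, daughter),
        smaller_fraction=min(nb, n - nb) / n,
    )


def _subset(cluster: Cluster, keep: np.ndarray) -> Cluster:
    """Copy of the connected, root-containing subset flagged by ``keep``."""
    assert keep[0]
    frag = Cluster(founding_gen=cluster.founding_gen)
    old_to_new: dict[int, int] = {}
    old_ids: list[int] = []
    for old in range(len(cluster)):
        if not keep[old]:
            continue
        p = cluster._parent[old]
        old_to_new[old] = len(old_ids)
        old_ids.append(old)
        frag._add_cell(
            NO_PARENT if p == NO_PARENT else old_to_new[p],
            cluster._birth[old],
            alive=cluster._alive[old],
            shell=cluster._shell[old],
            last_repro=cluster._last_repro[old],
        )
    frag._links_used = [cluster._links_used[old] for old in old_ids]
    return frag


def death_and_sever(
    cluster: Cluster,
    mode: SeveranceMode,
    rng: np.random.Generator,
    free_link: bool = True,
) -> SplitResult:
    """Kill one cell per the victim rule and sever one of its links.

    The victim is chosen among living cells, marked dead *in place*, and
    one of its incident links breaks per the link rule.  A single-cell
    cluster dies without severance (degenerate result, no fragment_b).
    """
    living = [i for i in range(len(cluster)) if cluster._alive[i]]
    if not living:
        raise ValueError("cluster has no living cells")
    if mode.victim_rule == "oldest_cell":
        victim = min(living, key=lambda i: (cluster._birth[i], i))
    else:
        victim = living[int(rng.integers(len(living)))]
    cluster._alive[victim] = False
    if len(cluster) == 1:
        return SplitResult(
            fragment_a=cluster.copy(),
            fragment_b=None,
            severed_link=None,
            smaller_fraction=0.0,
        )
    branches = branch_partition(cluster, victim)
    links = [link for link, _ in branches]
    sizes = np.array([s for _, s in branches], dtype=float)
    if mode.link_rule == "branch_size_biased":
        probs = sizes / sizes.sum()
    else:
        probs = np.full(len(links), 1.0 / len(links))
    chosen = links[int(rng.choice(len(links), p=probs))]
    return sever(cluster, chosen, free_link=free_link)


# -- exact expected offspring asymmetry -------------------------------


def _unconstrained_arrays(
    t: int, degree_cap: Optional[int]
) -> tuple[np.ndarray, np.ndarray]:
    """(parent, depth) arrays of the deterministic tree after t rounds.

    Flat-array twin of :func:`snowflakesim.cluster.build_unconstrained_tree`
    (cross-checked against it in the test suite); fast enough for exact
    enumeration at ``t = 20`` uncapped (2^20 cells).
    """
    parent = np.full(1, NO_PARENT, dtype=np.int64)
    depth = np.zeros(1, dtype=np.int64)
    links = np.zeros(1, dtype=np.int64)
    for _ in range(t):
        if degree_cap is None:
            mothers = np.arange(parent.size, dtype=np.int64)
        else:
            mothers = np.flatnonzero(links < degree_cap).astype(np.int64)
        links[mothers] += 1
        parent = np.concatenate([parent, mothers])
        depth = np.concatenate([depth, depth[mothers] + 1])
        links = np.concatenate([links, np.ones(mothers.size, dtype=np.int64)])
    return parent, depth


def _subtree_sizes(parent: np.ndarray, depth: np.ndarray) -> np.ndarray:
    sizes = np.ones(parent.size, dtype=np.int64)
    order = np.argsort(depth, kind="stable")
    bounds = np.searchsorted(depth[order], np.arange(depth.max() + 2))
    for d in range(int(depth.max()), 0, -1):
        layer = order[bounds[d]: bounds[d + 1]]
        np.add.at(sizes, parent[layer], sizes[layer])
    return sizes


def expected_smaller_fraction(
    t: int, degree_cap: Optional[int], mode: SeveranceMode
) -> float:
    """E[min(s, n-s)] / n over all (victim, link) outcomes at generation t.

    Exact enumeration on the deterministic unconstrained tree: every
    link (m, c) can be severed either because the mother m died and
    chose it, or because the daughter c died and chose it; both routes
    are weighted by the victim and link probabilities of ``mode``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    parent, depth = _unconstrained_arrays(t, degree_cap)
    n = parent.size
    sub = _subtree_sizes(parent, depth)
    child = np.arange(1, n, dtype=np.int64)  # every non-root cell = one link
    mother = parent[child]
    s = sub[child].astype(float)
    branch_min = np.minimum(s, n - s)
    n_children = np.bincount(mother, minlength=n).astype(float)
    deg = n_children + (np.arange(n) != 0)

    if mode.victim_rule == "oldest_cell":
        w_mother = (mother == 0).astype(float)  # victim is always the root
        w_child = np.zeros_like(w_mother)
    else:
        w_mother = np.full(child.size, 1.0 / n)
        w_child = np.full(child.size, 1.0 / n)

    if mode.link_rule == "uniform_link":
        p_via_mother = 1.0 / deg[mother]
        p_via_child = 1.0 / deg[child]
    else:
        p_via_mother = s / (n - 1.0)
        p_via_child = (n - s) / (n - 1.0)

    e_min = np.sum(branch_min * (w_mother * p_via_mother + w_child * p_via_child))
    return float(e_min / n)


def biased_fraction_oldest(t: int) -> float:
    """Closed form: uncapped tree, root dies, branch-biased severance."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return (4.0**t - 1.0) / (3.0 * (2.0**t - 1.0) * 2.0**t)


def uniform_fraction_oldest(t: int) -> float:
    """Closed form: uncapped tree, root dies, unbiased link choice."""
    if t < 1:
        raise ValueError("t must be >= 1")
    return (2.0**t - 1.0) / (t * 2.0**t)


def asymptotic_biased_fraction() -> float:
    """Large-t limit of the biased oldest-cell fraction: exactly 1/3."""
    return 1.0 / 3.0
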