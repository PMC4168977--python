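"""Lineage-tree data model for a snowflake yeast cluster.

A cluster is a connected acyclic graph (tree) of cells: nodes are cells,
edges are the physical mother-daughter attachments left by budding.  The
founding cell ("Node 0") is the root; every other cell is attached to
exactly one mother and any number of daughters, so severing any single
edge splits the cluster into exactly two connected pieces.

Growth is synchronized: once per generation every cell that (1) is alive,
(2) has spare attachment sites under the degree cap and (3) has room in
the next concentric shell buds exactly one daughter.  Eligibility is
evaluated against the pre-step state, so the unconstrained tree doubles
every generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

from . import geometry

__all__ = [
    "Cell",
    "Cluster",
    "GrowthConstraints",
    "new_founder",
    "grow_step",
    "branch_partition",
    "diameter",
    "build_unconstrained_tree",
]

NO_PARENT = -1


@dataclass(frozen=True)
class Cell:
    """Read-only view of one cell (node) of a cluster's lineage tree.

    ``links_used`` counts occupied attachment sites: the link to the
    mother (if any) plus one per daughter.  By default a severed
    attachment frees its site on both endpoints (severance operations
    take ``free_link=False`` to leave permanent bud scars instead).
    """

    id: int
    parent: Optional[int]
    children: tuple[int, ...]
    birth_gen: int
    last_repro_gen: int
    alive: bool
    shell: int
    links_used: int


@dataclass
class GrowthConstraints:
    """Constraints gating synchronized growth.

    degree_cap
        Maximum attachments per cell (mother link + daughters), or ``None``
        for unlimited.  The root has no mother, so a cap of ``d`` allows it
        ``d`` daughters while every other cell gets ``d - 1``.
    volume_limited
        If true, a birth into shell ``k`` is refused whenever it would push
        the cumulative occupancy of any shell ``>= k`` past its capacity.
    shell_capacity_fn
        Map from shell index to the maximum cumulative cell count enclosed
        by that shell; defaults to the spherical-shell law ``(2k+1)**3``.
    """

    degree_cap: Optional[int] = None
    volume_limited: bool = False
    shell_capacity_fn: Callable[[int], int] = field(
        default=geometry.shell_capacity
    )

    def __post_init__(self) -> None:
        if self.degree_cap is not None and self.degree_cap < 2:
            raise ValueError("degree_cap must be >= 2 or None")


class Cluster:
    """One connected lineage tree; the unit that fragments and is selected.

    Cells are keyed by dense integer ids assigned in breadth-first order
    from the root, so a mother's id is always smaller than her daughters'
    (relied on for linear-time subtree passes).  Shell indices are
    root-relative link distances.
    """

    __slots__ = (
        "_parent",
        "_children",
        "_birth",
        "_last_repro",
        "_alive",
        "_shell",
        "_links_used",
        "founding_gen",
    )

    def __init__(self, founding_gen: int = 0) -> None:
        self._parent: list[int] = []
        self._children: list[list[int]] = []
        self._birth: list[int] = []
        self._last_repro: list[int] = []
        self._alive: list[bool] = []
        self._shell: list[int] = []
        self._links_used: list[int] = []
        self.founding_gen = founding_gen

    # -- construction -------------------------------------------------

    def _add_cell(
        self,
        parent: int,
        birth_gen: int,
        *,
        alive: bool = True,
        shell: Optional[int] = None,
        links_used: Optional[int] = None,
        last_repro: Optional[int] = None,
    ) -> int:
        cid = len(self._parent)
        self._parent.append(parent)
        self._children.append([])
        self._birth.append(birth_gen)
        self._last_repro.append(birth_gen if last_repro is None else last_repro)
        self._alive.append(alive)
        if shell is None:
            shell = 0 if parent == NO_PARENT else self._shell[parent] + 1
        self._shell.append(shell)
        self._links_used.append(
            (0 if parent == NO_PARENT else 1) if links_used is None else links_used
        )
        if parent != NO_PARENT:
            self._children[parent].append(cid)
            self._links_used[parent] += 1
        return cid

    # -- basic queries -------------------------------------------------

    @property
    def root_id(self) -> int:
        return 0

    def __len__(self) -> int:
        return len(self._parent)

    @property
    def n_cells(self) -> int:
        return len(self._parent)

    @property
    def n_edges(self) -> int:
        return len(self._parent) - 1

    def living_count(self) -> int:
        return sum(self._alive)

    def cell(self, cid: int) -> Cell:
        if not 0 <= cid < len(self._parent):
            raise KeyError(f"no cell with id {cid}")
        p = self._parent[cid]
        return Cell(
            id=cid,
            parent=None if p == NO_PARENT else p,
            children=tuple(self._children[cid]),
            birth_gen=self._birth[cid],
            last_repro_gen=self._last_repro[cid],
            alive=self._alive[cid],
            shell=self._shell[cid],
            links_used=self._links_used[cid],
        )

    def cells(self) -> Iterator[Cell]:
        for cid in range(len(self._parent)):
            yield self.cell(cid)

    def edges(self) -> Iterator[tuple[int, int]]:
        """(mother, daughter) pairs, one per physical attachment."""
        for cid, p in enumerate(self._parent):
            if p != NO_PARENT:
                yield (p, cid)

    def parent_array(self) -> np.ndarray:
        return np.asarray(self._parent, dtype=np.int64)

    def shell_array(self) -> np.ndarray:
        return np.asarray(self._shell, dtype=np.int64)

    def alive_array(self) -> np.ndarray:
        return np.asarray(self._alive, dtype=bool)

    def shell_counts(self) -> np.ndarray:
        """Number of cells in each shell, index = shell."""
        return np.bincount(self.shell_array())

    def subtree_sizes(self) -> np.ndarray:
        """Cells in the subtree rooted at each cell (inclusive).

        Linear pass in reverse id order; correct because ids are
        topologically ordered (mother id < daughter id).
        """
        n = len(self._parent)
        sizes = np.ones(n, dtype=np.int64)
        for cid in range(n - 1, 0, -1):
            sizes[self._parent[cid]] += sizes[cid]
        return sizes

    # -- structural copies --------------------------------------------

    def extract(self, new_root: int) -> "Cluster":
        """Copy of the subtree rooted at ``new_root`` as its own cluster.

        Ids are re-assigned in ascending old-id order (which keeps
        mothers before daughters, so ``copy()`` is an identity); shells
        become distances to the new root; ``links_used`` is copied
        verbatim (severance operations decide whether a broken link
        frees a site).
        """
        members = set()
        stack = [new_root]
        while stack:
            u = stack.pop()
            members.add(u)
            stack.extend(self._children[u])
        old_ids = sorted(members)
        old_to_new = {old: new for new, old in enumerate(old_ids)}
        frag = Cluster(founding_gen=self._birth[new_root])
        base_shell = self._shell[new_root]
        for old in old_ids:
            p = self._parent[old]
            frag._add_cell(
                NO_PARENT if old == new_root else old_to_new[p],
                self._birth[old],
                alive=self._alive[old],
                shell=self._shell[old] - base_shell,
                last_repro=self._last_repro[old],
            )
        frag._links_used = [self._links_used[old] for old in old_ids]
        return frag

    def copy(self) -> "Cluster":
        return self.extract(0)

    # -- validation ----------------------------------------------------

    def validate(self, degree_cap: Optional[int] = None) -> None:
        """Check the tree invariants; raise AssertionError on violation."""
        n = len(self._parent)
        assert n >= 1
        roots = [i for i, p in enumerate(self._parent) if p == NO_PARENT]
        assert roots == [0], "exactly one root with id 0"
        assert self._shell[0] == 0
        n_edges = sum(1 for p in self._parent if p != NO_PARENT)
        assert n_edges == n - 1
        for cid, p in enumerate(self._parent):
            if p != NO_PARENT:
                assert self._shell[cid] == self._shell[p] + 1
                assert cid in self._children[p]
            if degree_cap is not None:
                assert self._links_used[cid] <= degree_cap


def new_founder(gen0: int = 0) -> Cluster:
    """Cluster consisting of the single living founding cell (Node 0)."""
    c = Cluster(founding_gen=gen0)
    c._add_cell(NO_PARENT, gen0)
    return c


def _volume_grants(
    cluster: Cluster,
    eligible: Sequence[int],
    capacity_fn: Callable[[int], int],
    rng: Optional[np.random.Generator],
) -> list[int]:
    """Subset of ``eligible`` granted a birth under the shell capacities.

    Cumulative occupancy of shell ``k`` (cells in shells ``0..k``) may
    never exceed ``capacity_fn(k)``.  A birth into shell ``j`` consumes one
    unit of headroom of every shell ``>= j``, so slots are granted from
    the innermost contested shell outward; when a shell's remaining slots
    cannot serve all contenders, winners are drawn uniformly at random
    (or lowest-id first when no rng is supplied).
    """
    if not eligible:
        return []
    shells = cluster.shell_counts()
    max_k = len(shells)  # births can reach shell max_k
    counts = np.zeros(max_k + 1, dtype=np.int64)
    by_shell: dict[int, list[int]] = {}
    for cid in eligible:
        j = cluster._shell[cid] + 1
        by_shell.setdefault(j, []).append(cid)
        counts[j] += 1
    occ = np.zeros(max_k + 1, dtype=np.int64)
    occ[: len(shells)] = shells
    cum = np.cumsum(occ)
    caps = np.array([capacity_fn(k) for k in range(max_k + 1)], dtype=np.int64)
    rem = caps - cum
    # headroom for a birth into shell j is min over k >= j of rem[k]
    suffix_min = np.minimum.accumulate(rem[::-1])[::-1]
    granted: list[int] = []
    consumed = 0  # births already granted this step, all at shells <= current j
    for j in sorted(by_shell):
        avail = int(suffix_min[j]) - consumed
        group = by_shell[j]
        if avail <= 0:
            continue
        if avail >= len(group):
            chosen = group
        elif rng is None:
            chosen = group[:avail]
        else:
            chosen = [group[i] for i in rng.choice(len(group), size=avail, replace=False)]
        granted.extend(chosen)
        consumed += len(chosen)
    return granted


def grow_step(
    cluster: Cluster,
    constraints: GrowthConstraints,
    gen: int,
    rng: Optional[np.random.Generator] = None,
) -> Cluster:
    """Advance the cluster by one synchronized round of budding.

    Every cell that is alive, below the degree cap and has shell room
    (all judged on the pre-step state) gains exactly one living daughter
    with ``birth_gen = gen``.  Returns the (mutated) cluster.
    """
    if any(b >= gen for b in cluster._birth):
        raise ValueError("gen must exceed every birth generation in the cluster")
    cap = constraints.degree_cap
    eligible = [
        cid
        for cid in range(len(cluster))
        if cluster._alive[cid] and (cap is None or cluster._links_used[cid] < cap)
    ]
    if constraints.volume_limited:
        eligible = _volume_grants(
            cluster, eligible, constraints.shell_capacity_fn, rng
        )
    for cid in eligible:
        cluster._add_cell(cid, gen)
        cluster._last_repro[cid] = gen
    return cluster


def build_unconstrained_tree(
    t: int, degree_cap: Optional[int] = None
) -> Cluster:
    """Deterministic tree after ``t`` growth rounds with no volume limit."""
    cluster = new_founder(0)
    constraints = GrowthConstraints(degree_cap=degree_cap, volume_limited=False)
    for gen in range(1, t + 1):
        grow_step(cluster, constraints, gen)
    return cluster


def branch_partition(
    cluster: Cluster, cell_id: int
) -> list[tuple[tuple[int, int], int]]:
    """Sizes of the branches hanging off each attachment of a cell.

    Returns ``[((mother, daughter), size), ...]`` with one entry per link
    incident to ``cell_id``; ``size`` is the number of cells on the far
    side of that link, so the sizes sum to ``len(cluster) - 1``.
    """
    if not 0 <= cell_id < len(cluster):
        raise KeyError(f"no cell with id {cell_id}")
    sizes = cluster.subtree_sizes()
    n = len(cluster)
    out: list[tuple[tuple[int, int], int]] = []
    p = cluster._parent[cell_id]
    if p != NO_PARENT:
        out.append(((p, cell_id), n - int(sizes[cell_id])))
    for c in cluster._children[cell_id]:
        out.append(((cell_id, c), int(sizes[c])))
    return out


def _farthest(cluster: Cluster, start: int) -> tuple[int, int]:
    """(cell, distance) farthest from ``start`` along tree edges."""
    n = len(cluster)
    dist = [-1] * n
    dist[start] = 0
    queue = [start]
    far, far_d = start, 0
    while queue:
        nxt: list[int] = []
        for u in queue:
            neighbours = list(cluster._children[u])
            if cluster._parent[u] != NO_PARENT:
                neighbours.append(cluster._parent[u])
            for v in neighbours:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    if dist[v] > far_d:
                        far, far_d = v, dist[v]
                    nxt.append(v)
        queue = nxt
    return far, far_d


def diameter(cluster: Cluster) -> int:
    """Longest path (in edges) between any two cells, dead cells included.

    Dead cells remain attached, so they still carry path length; used as
    the settling-speed proxy during selection.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    a, _ = _farthest(cluster, cluster.root_id)
    _, d = _farthest(cluster, a)
    return d
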