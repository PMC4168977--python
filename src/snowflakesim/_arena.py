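"""Flat-array population engine for the agent-based cluster simulation.

Holds every cell of every cluster in parallel numpy arrays so that a
full generation (synchronized budding, volume rationing, death,
severance, component relabeling) costs a handful of vectorized passes
over the population.  Severed mother links are recorded by clearing the
``hpl`` ("has parent link") flag — the mother's id stays in ``parent``
as a bud scar, and component roots are exactly the cells with
``hpl == False``.

Within one generation all deaths and their severances are processed
against a single pre-death snapshot of subtree and cluster sizes
(synchronous update); duplicate choices of the same link collapse to
one severance.  Cluster labels are the root cell's id, recomputed by
pointer doubling after severance; depths (= shells, when fragments are
re-rooted) follow as ``depth - depth[new root]``.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .geometry import shell_capacity

NO_PARENT = -1


class Arena:
    """A growing population of snowflake clusters."""

    def __init__(
        self,
        rng: np.random.Generator,
        degree_cap: Optional[int] = None,
        volume_limited: bool = True,
        death_delay: int = 0,
        link_rule: str = "branch_size_biased",
        reroot_shells: bool = True,
        free_severed_links: bool = True,
        capacity_fn: Callable[[int], int] = shell_capacity,
    ) -> None:
        if degree_cap is not None and degree_cap < 2:
            raise ValueError("degree_cap must be >= 2 or None")
        if link_rule not in ("uniform_link", "branch_size_biased"):
            raise ValueError(f"unknown link_rule {link_rule!r}")
        self.rng = rng
        self.degree_cap = degree_cap
        self.volume_limited = volume_limited
        self.death_delay = death_delay
        self.link_rule = link_rule
        self.reroot_shells = reroot_shells
        self.free_severed_links = free_severed_links
        self.capacity_fn = capacity_fn

        self.parent = np.empty(0, dtype=np.int64)
        self.hpl = np.empty(0, dtype=bool)  # parent link intact
        self.depth = np.empty(0, dtype=np.int64)  # links to cluster root
        self.shell_static = np.empty(0, dtype=np.int64)  # birth shell
        self.birth = np.empty(0, dtype=np.int64)
        self.last_repro = np.empty(0, dtype=np.int64)
        self.alive = np.empty(0, dtype=bool)
        self.links_used = np.empty(0, dtype=np.int64)
        self.p_death = np.empty(0, dtype=np.float64)
        self.root_of = np.empty(0, dtype=np.int64)
        self.children: list[list[int]] = []
        self.splits: list[tuple[int, int, int, int]] = []  # gen, parent, frag, rest

    # -- basic state ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.parent.size

    def living(self) -> int:
        return int(self.alive.sum())

    def n_clusters(self) -> int:
        return int(np.count_nonzero(~self.hpl))

    @property
    def shell(self) -> np.ndarray:
        return self.depth if self.reroot_shells else self.shell_static

    def add_founder(self, gen0: int = 0, p_death: float = 0.0) -> int:
        cid = self.n_cells
        self._append(
            parent=np.array([NO_PARENT]),
            hpl=np.array([False]),
            depth=np.array([0]),
            shell_static=np.array([0]),
            birth=np.array([gen0]),
            last_repro=np.array([gen0]),
            alive=np.array([True]),
            links_used=np.array([0]),
            p_death=np.array([p_death]),
            root_of=np.array([cid]),
        )
        return cid

    def _append(self, **arrays: np.ndarray) -> None:
        n_new = arrays["parent"].size
        for name, arr in arrays.items():
            old = getattr(self, name)
            setattr(
                self, name, np.concatenate([old, arr.astype(old.dtype)])
            )
        self.children.extend([] for _ in range(n_new))

    # -- one generation ------------------------------------------------

    def step(self, gen: int) -> tuple[int, int]:
        """One synchronized round of budding then death; returns
        (births, deaths)."""
        births = self._reproduce(gen)
        deaths = self._die_and_sever(gen)
        return births, deaths

    def _reproduce(self, gen: int) -> int:
        eligible = self.alive.copy()
        if self.degree_cap is not None:
            eligible &= self.links_used < self.degree_cap
        mothers = np.flatnonzero(eligible)
        if self.volume_limited and mothers.size:
            mothers = self._volume_grants(mothers)
        if mothers.size == 0:
            return 0
        base = self.n_cells
        n_new = mothers.size
        self.links_used[mothers] += 1
        self.last_repro[mothers] = gen
        self._append(
            parent=mothers,
            hpl=np.ones(n_new, dtype=bool),
            depth=self.depth[mothers] + 1,
            shell_static=self.shell_static[mothers] + 1,
            birth=np.full(n_new, gen),
            last_repro=np.full(n_new, gen),
            alive=np.ones(n_new, dtype=bool),
            links_used=np.ones(n_new, dtype=np.int64),
            p_death=self.p_death[mothers],
            root_of=self.root_of[mothers],
        )
        for i, m in enumerate(mothers.tolist()):
            self.children[m].append(base + i)
        return n_new

    def _volume_grants(self, mothers: np.ndarray) -> np.ndarray:
        """Mothers granted a birth under per-cluster shell capacities.

        Cumulative occupancy of shell k must stay <= capacity(k); a
        birth into shell j consumes headroom of every shell >= j, so
        slots are granted innermost first, contested slots going to a
        uniform random subset.
        """
        shell = self.shell
        labels, inv = np.unique(self.root_of, return_inverse=True)
        n_cl = labels.size
        k_max = int(shell.max()) + 1
        occ = np.zeros((n_cl, k_max + 1), dtype=np.int64)
        np.add.at(occ, (inv, shell), 1)
        caps = np.array(
            [self.capacity_fn(k) for k in range(k_max + 1)], dtype=np.int64
        )
        rem = caps[None, :] - np.cumsum(occ, axis=1)
        headroom = np.minimum.accumulate(rem[:, ::-1], axis=1)[:, ::-1]

        m_inv = inv[mothers]
        m_shell = shell[mothers] + 1  # birth shell
        cnt = np.zeros((n_cl, k_max + 1), dtype=np.int64)
        np.add.at(cnt, (m_inv, m_shell), 1)
        consumed = np.zeros(n_cl, dtype=np.int64)
        grants = np.zeros((n_cl, k_max + 1), dtype=np.int64)
        for j in range(k_max + 1):
            avail = np.maximum(headroom[:, j] - consumed, 0)
            grants[:, j] = np.minimum(cnt[:, j], avail)
            consumed += grants[:, j]
        if np.array_equal(grants, cnt):
            return mothers
        keep = np.ones(mothers.size, dtype=bool)
        short = np.argwhere(grants < cnt)
        for ci, j in short:
            group = np.flatnonzero((m_inv == ci) & (m_shell == j))
            n_drop = group.size - grants[ci, j]
            drop = self.rng.choice(group, size=n_drop, replace=False)
            keep[drop] = False
        return mothers[keep]

    def _die_and_sever(self, gen: int) -> int:
        susceptible = self.alive & (gen - self.last_repro >= self.death_delay)
        idx = np.flatnonzero(susceptible)
        if idx.size == 0:
            return 0
        dies = self.rng.random(idx.size) < self.p_death[idx]
        victims = idx[dies]
        if victims.size == 0:
            return 0
        # pre-death snapshot of branch sizes (living + dead cells count)
        sub = self.subtree_sizes()
        csize = np.bincount(self.root_of, minlength=self.n_cells)
        self.alive[victims] = False
        severed: set[int] = set()
        for v in victims.tolist():
            endpoints: list[int] = []
            sizes: list[int] = []
            if self.hpl[v]:
                endpoints.append(v)
                sizes.append(int(csize[self.root_of[v]] - sub[v]))
            for c in self.children[v]:
                if self.hpl[c]:
                    endpoints.append(c)
                    sizes.append(int(sub[c]))
            if not endpoints:
                continue  # isolated cell: death without severance
            if self.link_rule == "branch_size_biased":
                w = np.asarray(sizes, dtype=np.float64)
                k = int(self.rng.choice(len(endpoints), p=w / w.sum()))
            else:
                k = int(self.rng.integers(len(endpoints)))
            x = endpoints[k]
            if x not in severed:
                severed.add(x)
                parent_size = int(csize[self.root_of[v]])
                self.splits.append(
                    (gen, parent_size, int(sub[x]), parent_size - int(sub[x]))
                )
        if severed:
            cut = list(severed)
            if self.free_severed_links:
                # a broken attachment frees both sites, letting a cell at
                # the degree cap reproduce again and start a new branch
                self.links_used[cut] -= 1
                self.links_used[self.parent[cut]] -= 1
            self.hpl[cut] = False
            self._relabel()
        return victims.size

    def _relabel(self) -> None:
        """Recompute cluster labels and depths after severances."""
        idx = np.arange(self.n_cells)
        anc = np.where(self.hpl, self.parent, idx)
        while True:
            nxt = anc[anc]
            if np.array_equal(nxt, anc):
                break
            anc = nxt
        self.root_of = anc
        self.depth = self.depth - self.depth[anc]

    # -- derived structure --------------------------------------------

    def _depth_layers(self) -> tuple[np.ndarray, np.ndarray, int]:
        order = np.argsort(self.depth, kind="stable")
        d_max = int(self.depth.max()) if self.n_cells else 0
        bounds = np.searchsorted(self.depth[order], np.arange(d_max + 2))
        return order, bounds, d_max

    def subtree_sizes(self) -> np.ndarray:
        """Cells in the subtree below each cell (inclusive), over intact
        links only."""
        sizes = np.ones(self.n_cells, dtype=np.int64)
        order, bounds, d_max = self._depth_layers()
        for d in range(d_max, 0, -1):
            layer = order[bounds[d]: bounds[d + 1]]
            layer = layer[self.hpl[layer]]
            np.add.at(sizes, self.parent[layer], sizes[layer])
        return sizes

    def cluster_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(labels, inverse): dense cluster numbering of every cell."""
        return np.unique(self.root_of, return_inverse=True)

    def living_sizes(self) -> np.ndarray:
        """Living cells per cluster (dense cluster order)."""
        labels, inv = self.cluster_index()
        return np.bincount(inv[self.alive], minlength=labels.size)

    def total_sizes(self) -> np.ndarray:
        labels, inv = self.cluster_index()
        return np.bincount(inv, minlength=labels.size)

    def diameters(self) -> np.ndarray:
        """Tree diameter (edges) of every cluster, dead cells included.

        Longest path through a cell is the sum of its two largest
        downward path lengths; heights are accumulated bottom-up per
        depth layer, all vectorized.
        """
        n = self.n_cells
        h = np.zeros(n, dtype=np.int64)  # height: longest downward path
        order, bounds, d_max = self._depth_layers()
        for d in range(d_max, 0, -1):
            layer = order[bounds[d]: bounds[d + 1]]
            layer = layer[self.hpl[layer]]
            np.maximum.at(h, self.parent[layer], h[layer] + 1)
        kids = np.flatnonzero(self.hpl)
        val = h[kids] + 1
        par = self.parent[kids]
        m1 = np.zeros(n, dtype=np.int64)
        np.maximum.at(m1, par, val)
        at_max = val == m1[par]
        n_at_max = np.zeros(n, dtype=np.int64)
        np.add.at(n_at_max, par[at_max], 1)
        m2 = np.zeros(n, dtype=np.int64)
        below = ~at_max
        np.maximum.at(m2, par[below], val[below])
        m2 = np.where(n_at_max >= 2, m1, m2)
        through = m1 + m2
        labels, inv = self.cluster_index()
        diam = np.zeros(labels.size, dtype=np.int64)
        np.maximum.at(diam, inv, through)
        return diam

    # -- population surgery -------------------------------------------

    def keep_clusters(self, keep_labels: np.ndarray) -> None:
        """Discard every cluster whose root id is not in ``keep_labels``."""
        mask = np.isin(self.root_of, keep_labels)
        old_ids = np.flatnonzero(mask)
        new_id = np.full(self.n_cells, -1, dtype=np.int64)
        new_id[old_ids] = np.arange(old_ids.size)
        self.parent = np.where(
            self.hpl[old_ids], new_id[self.parent[old_ids]], NO_PARENT
        )
        for name in (
            "hpl",
            "depth",
            "shell_static",
            "birth",
            "last_repro",
            "alive",
            "links_used",
            "p_death",
        ):
            setattr(self, name, getattr(self, name)[old_ids])
        self.root_of = new_id[self.root_of[old_ids]]
        self.children = [
            [int(new_id[c]) for c in self.children[o] if mask[c]]
            for o in old_ids.tolist()
        ]

    def mutate(self, mutation_prob: float, p_min: float, p_max: float) -> int:
        """Redraw p_death uniformly for a random subset of living cells."""
        idx = np.flatnonzero(self.alive)
        hits = idx[self.rng.random(idx.size) < mutation_prob]
        self.p_death[hits] = self.rng.uniform(p_min, p_max, size=hits.size)
        return hits.size
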