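# snowflakesim

Models for the geometry, fragmentation and evolution of **snowflake
yeast** clusters — multicellular groups of *Saccharomyces cerevisiae*
in which daughter cells stay attached to their mothers after budding.
A cluster is then exactly a lineage tree: nodes are cells, edges are
mother–daughter bonds, and severing any single bond (for instance when
a cell undergoes apoptosis) splits the group into exactly two
offspring clusters.  The package is aimed at researchers studying
evolutionary transitions to multicellularity who want a quantitative
handle on why groups under settling selection evolve *higher* rates of
programmed cell death.

It provides:

* **`cluster`** — the lineage-tree data model: synchronized budding
  gated by a *degree cap* `d` (max attachments per cell) and by
  concentric-shell volume limits; branch partitions; tree diameters.
* **`geometry`** — closed-form/recursive analytics.  Shell `k` holds at
  most `(2k+1)^3` cells interior to it; branch sizes follow the
  order-`(d−1)` generalized Fibonacci recursion
  `n(a) = n(a−1) + … + n(a−(d−1))` (cap 3 → Fibonacci, cap 4 →
  tribonacci), and the whole tree is twice its largest branch.
* **`division`** — death-triggered severance and the exact expected
  smaller-offspring fraction `E[min(s, n−s)]/n` under each death/
  severance mode, e.g. `(4^t−1)/(3(2^t−1)2^t) → 1/3` for oldest-cell
  death with branch-size-biased severance.
* **`optimal_policy`** — the backwards recursion
  `V(n,t) = max_a [V(g(a), t+1) + V(g(n−a), t+1)]` for optimal cluster
  division under a survival function `s(n)` and cluster- or cell-count
  fitness.
* **`popsim`** — the agent-based population simulation (synchronized
  reproduction, probabilistic death, biased link severance, degree and
  volume constraints, death delay).
* **`evolution`** — mutation–selection transfer cycles: heritable
  per-cell death probability, diameter-weighted settling selection.

## Worked example

When does a growing cluster run out of space?  Shell `k` of the
cluster encloses the volume of a sphere of radius `(2k+1)` cell radii:

```sh
$ snowflakesim geometry overflow --cap none
degree_cap,overflow_generation,shells_exceeded
none,12,4;5;6

$ snowflakesim geometry overflow --cap 3
degree_cap,overflow_generation,shells_exceeded
3,20,14;15
```

An unconstrained tree doubles every generation and already exceeds the
volume of shells 4–6 at the 12th round of budding (so only 11 rounds
are limit-free), while a degree-cap-3 tree grows Fibonacci-slowly and
lasts until round 20, when shells 14–15 overflow.

How symmetric is cluster reproduction?  If the oldest, most central
cell dies and bonds break in proportion to the branch they carry:

```sh
$ snowflakesim division --t-max 4 --victim oldest_cell --link branch_size_biased
t,degree_cap,victim_rule,link_rule,expected_smaller_fraction
1,none,oldest_cell,branch_size_biased,0.5
2,none,oldest_cell,branch_size_biased,0.41666666666666663
3,none,oldest_cell,branch_size_biased,0.37499999999999994
4,none,oldest_cell,branch_size_biased,0.35416666666666663
```

The smaller offspring starts at half the parent and converges to 1/3
of it — far more symmetric than random cell death, which mostly breaks
off single newborn cells.

The same library calls are available in Python:

```python
from snowflakesim import SimConfig, simulate_population

result = simulate_population(SimConfig(degree_cap=3, p_death=0.005, seed=1))
print(result.final_living, result.clusters_per_gen[-1])
```

which for this seed prints `57325 753`: after 21 generations a
population seeded by one cell holds ~57k living cells in 753 clusters —
*more* cells than the ~35k a deathless cap-3 tree can reach, because
each death frees an attachment site and founds a new branch.

Other entry points: `snowflakesim dp` (optimal-division tables),
`snowflakesim popsim run|sweep` (population runs and strategy sweeps),
`snowflakesim evolve` (transfer experiments), `snowflakesim export`
(cluster JSON → Newick).  See `docs/methods.md` for the model details,
parameter meanings and numerical choices.

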