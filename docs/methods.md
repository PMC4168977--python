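# Methods

`snowflakesim` models the growth, fragmentation and evolution of
"snowflake" yeast clusters: multicellular groups that arise when
daughter cells stay attached to their mothers after budding, so that a
cluster is exactly a lineage tree — nodes are cells, edges are the
physical mother–daughter bonds, and breaking any single bond splits
the group into exactly two connected pieces.

## The lineage-tree model

Growth is synchronized and generation-clocked.  Once per generation
every cell buds one daughter provided it (1) is alive, (2) has a spare
attachment site under the *degree cap* and (3) has room in the next
concentric shell.  Eligibility is evaluated against the pre-step state,
so an unconstrained tree doubles each generation (shell `j` then holds
`C(t, j)` cells).  The founding cell has no mother, so a degree cap of
`d` allows it `d` daughters while every other cell gets `d − 1`;
consequently per-generation births in a branch obey the
order-`(d − 1)` generalized Fibonacci recursion
`n(a) = n(a−1) + … + n(a−(d−1))` (cap 3 → Fibonacci, cap 4 →
tribonacci, no cap → doubling), the branch sizes are its partial sums
`f_d`, and the whole tree holds `2·f_d(t−1)` cells for `t ≥ d`.

When a cell's bond is severed, the freed attachment sites are reusable
by default (`free_severed_links=True`): a cell at its degree cap whose
neighbour died can bud again and found a new branch.  This is the
mechanism by which cell death *increases* the living population under
degree caps.  The alternative "bud scar" rule, in which a severed site
stays occupied forever, is available (`free_severed_links=False`); under
it death can only shrink a degree-capped population, and several of
the directional results below disappear.

## Shell geometry

Cells are identical spheres of radius `r` arranged in concentric
shells around the founder; the shell index is the link distance to the
root.  Shell `k` encloses the volume of a sphere of radius `(2k+1)r`,
which ignoring sphere-packing corrections holds at most `(2k+1)^3`
cell volumes, and every cell of shells `0..k` sits inside it.  Growth
therefore overflows when the cumulative occupancy of some shell
exceeds `(2k+1)^3`.  On the unconstrained trajectory this first
happens at round 12 (shells 4–6) for uncapped trees, at round 15
(shells 8–11) for cap 4 — i.e. 14 limit-free generations — and at
round 20 (shells 14–15) for cap 3; cap 2 grows filaments and never
overflows.  The capacity law and the shell-resolved capped recursion
`m(j,t) = Σ_{i=1..d−1} m(j−1, t−i)` are both validated against
brute-force tree enumeration in the test suite.

In the simulator (as opposed to the analytic overflow calculation,
which runs on the unconstrained trajectory) volume checks actually
block births.  Because the update is synchronized, several mothers can
target a nearly-full shell in the same step; capacity is then rationed
innermost-shell-first, contested slots going to a uniformly random
subset of the eligible mothers.  This keeps the hard invariant that
occupancy never exceeds capacity while preserving pre-step eligibility
semantics.  After a split the daughter-side fragment is re-rooted at
the severed daughter and its shells are recomputed from there
(`reroot_shells=False` keeps birth shells instead).

## Division by death-triggered severance

A death severs one of the victim's bonds.  Which cell dies
(`uniform_random_cell` vs `oldest_cell`) and which bond breaks
(`uniform_link` vs `branch_size_biased`, probability proportional to
the cells carried by the branch) control offspring symmetry.  The
expected smaller-offspring fraction is computed by exact enumeration
over every (victim, link) outcome of the deterministic tree; closed
forms for oldest-cell death on the uncapped tree —
`(4^t−1)/(3(2^t−1)2^t)` → 1/3 biased, `(2^t−1)/(t·2^t)` → 0 unbiased —
serve as independent cross-checks.  Enumeration is exact throughout
the tested range (vectorized, 2^20 cells at t = 20 in under a second);
no Monte Carlo fallback is needed below t ≈ 22 uncapped.

## The population simulator

`simulate_population` tracks every cell of every cluster in flat
arrays.  Per generation: synchronized budding (with degree and volume
gates), then death — each living cell that has been idle at least
`death_delay` generations dies independently with its `p_death` — then
severance of one bond per victim.  All deaths in a generation are
resolved against one pre-death snapshot of subtree and cluster sizes
(synchronous update; two victims choosing the same bond collapse to
one severance).  Dead cells remain attached, occupy shell space, and
never bud.  Cluster labels are recomputed by pointer doubling; subtree
sizes, heights and tree diameters by vectorized depth-layer sweeps.

Default conditions: 21 generations (the time a free-living population
would need to reach ~2^21 cells) and the death-probability grid
{0.0005, 0.001, 0.0025, 0.005}.  The grid was fixed from a one-off
scan of the response surface: living cells at generation 21 for cap-3
volume-limited growth rise with `p_death` up to a peak near 0.0075 and
fall beyond it, so the four values sit on the rising limb where death
relieves the geometric constraints.  On this grid (100 replicates per
point) living cells at cap 3 increase monotonically in `p_death`,
while with cap 4 and volume checks removed the ordering inverts — the
highest death rate is no longer the best — and very large size
thresholds favour the lowest death rate, which rewards clusters that
never divide.

## Optimal division (dynamic programme)

A cluster of `n` cells survives settling selection with probability
`s(n)` (non-decreasing).  Over each of `T` steps a cluster divides
into parts `a` and `n − a` (`a = 0`: none) and each part grows by
`g` (default doubling, clipped at the table bound `n_max`):

    V(n, t) = max_{0 ≤ a ≤ n/2} [ V(g(a), t+1) + V(g(n−a), t+1) ],

dropping the `a = 0` term's empty part, with terminal value `s(n)`
(cluster-count fitness) or `n·s(n)` (cell-count fitness).  Ties break
toward the smallest part.  With concave, strictly increasing `s` and
cluster-count fitness the optimum is to halve (as evenly as the
integers allow) at every state; with cell-count fitness it is never to
divide; a convex region (steep Hill function) mixes no-split and
halving states.  Two numerical boundaries matter and are excluded from
the halving check: states that can reach the clipped bound within the
horizon (`n > n_max/2^(T−t)`), where ties become arbitrary, and
survival functions that flat-top at 1 inside the table, which create
equal-value splits.  The solver is validated against exhaustive
recursion over all division trees for `T ≤ 3`, `n_max ≤ 32`.

## The evolutionary simulation

`simulate_evolution` alternates growth phases with settling selection.
During growth, every cell carries a heritable `p_death`; each
generation a cell mutates with probability `mutation_prob`, redrawing
`p_death` uniformly from `mutation_range` (default (0, 0.3)).  When
the phase has added `growth_budget` new cells, clusters are sampled
without replacement with probability proportional to their diameter
(the settling-speed proxy; `diameter_squared`, `rank` and `uniform`
weightings are options) until the retained clusters hold
`selection_fraction` (default 10%) of the living cells; the rest are
discarded.

Scaling: the experiment-scale growth budget is ~2^21 cells per
transfer.  Desk-scale runs use 2^14 with the mutation probability
raised to 1e-2 so that the mutational supply `N·μ` per generation
matches what a 2^21-cell population sees at a per-cell rate of 1e-4.
Without this supply-matching, a small population passes through the
10% bottleneck as a handful of clonal clusters and the trajectory is
pure drift.  Under the default regime the population-mean `p_death`
rises well above its initial 0.005 within 60–100 transfers; with
mutation off it is exactly constant.  The no-selection control uses
the `uniform` weighting (same bottleneck, no settling bias) started
from the midpoint of the mutation range: culling nothing at all
(`selection_fraction = 1`) makes the population double every transfer
and is not computable over 50 transfers, and starting a control from a
low `p_death` conflates selection with the directional pull of the
uniform-redraw mutation kernel and of viability (high-`p` cells die
more).  A growth phase that cannot reach its budget within
`max_gens_per_phase` generations (volume-saturated population with too
little death to free space) is cut short and counted in
`stalled_phases`.

## What the generator does and does not emulate

All data are self-generated; there are no external inputs.  The model
keeps cells identical spheres on integer shells, ignores sphere
packing, nutrient and waste gradients, and physical strain as an
independent severance channel; death is the only bond-breaking
mechanism, one bond per death, so multi-way "multiple births" cannot
occur.  Passing tests therefore say nothing about mechanically induced
fragmentation or resource-limited death in real clusters; they
validate the geometric-constraint logic, the exact division
combinatorics, and the direction of the selection responses under the
stated conditions.

## Numerical choices

* Cell ids are dense integers in creation order, so a mother's id is
  always below her daughters' — subtree passes are single linear
  sweeps.
* All randomness flows from one `numpy` `Generator` per run; sweep
  replicates draw child seeds from `SeedSequence.spawn`, so results
  are independent of sweep ordering and reproducible bit-for-bit.
* Weighted sampling-without-replacement in selection uses the
  Efraimidis–Spirakis key trick (`U^(1/w)`); zero-weight
  (single-cell, diameter-0) clusters are retained only after every
  positive-weight cluster, in uniform random order.
* A cluster of one cell "dies without severance": the degenerate split
  has no second fragment and a smaller fraction of 0.
* Expected-fraction enumeration weights each link by both routes to
  severance (mother dies and picks it; daughter dies and picks it).

## Known limitations

Living populations above ~10^6 cells per replicate make the
death-severance loop the bottleneck; the shipped study conditions keep
runs to seconds–minutes on one CPU.  The evolved `p_death` plateau
depends on the desk-scale budget and the mutation kernel, so only its
direction — not its level — is a stable output.  The `a = 0` no-split
convention means a "split" of size 0 is never recorded as an
offspring.
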