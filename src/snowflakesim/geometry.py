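"""Shell-capacity and branch-size analytics for snowflake clusters.

Cells are identical spheres of radius ``r`` arranged in concentric
shells around the founding cell: shell ``k`` holds the cells ``k`` links
from the root.  Shell ``k`` encloses a volume equal to a sphere of
radius ``(2k+1)r``, which (ignoring sphere-packing corrections) can hold
at most ``(2k+1)**3`` cell volumes.  Because daughters sit one shell
outside their mothers, the cells *inside* shell ``k`` are exactly those
of shells ``0..k``; growth overflows when that cumulative count exceeds
the capacity.

Branch sizes follow generalized Fibonacci recursions: with a degree cap
``d`` only cells born within the last ``d - 1`` generations still bud,
so per-generation births in a branch satisfy an order-``(d-1)``
recursion (cap 3 -> Fibonacci, cap 4 -> tribonacci); the uncapped tree
is the "Fibonacci sequence of infinite order", i.e. plain doubling.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb
from typing import Optional

__all__ = [
    "shell_capacity",
    "shell_occupancy",
    "first_overflow",
    "branch_series",
    "total_size",
    "NO_OVERFLOW",
]

#: Distinguished result of :func:`first_overflow` for geometries that
#: never exceed any shell (filaments, degree cap 2).
NO_OVERFLOW: tuple[None, frozenset] = (None, frozenset())


def shell_capacity(k: int) -> int:
    """Maximum number of cells enclosed by shell ``k``: ``(2k+1)**3``."""
    if k < 0:
        raise ValueError("shell index must be >= 0")
    return (2 * k + 1) ** 3


@lru_cache(maxsize=None)
def _birth_table(degree_cap: int, k_max: int, t_max: int) -> tuple[tuple[int, ...], ...]:
    """m[j][t]: births into shell ``j`` at generation ``t`` under cap d.

    The root (shell 0, born at t=0, no mother link) buds in generations
    1..d, so shell 1 receives one birth in each of those generations.
    Every other cell buds in the ``d - 1`` generations after its birth:
    ``m(j, t) = sum_{i=1..d-1} m(j-1, t-i)`` for ``j >= 2``.
    """
    d = degree_cap
    m = [[0] * (t_max + 1) for _ in range(k_max + 1)]
    m[0][0] = 1
    if k_max >= 1:
        for t in range(1, min(d, t_max) + 1):
            m[1][t] = 1
    for j in range(2, k_max + 1):
        for t in range(1, t_max + 1):
            m[j][t] = sum(m[j - 1][t - i] for i in range(1, d) if t - i >= 0)
    return tuple(tuple(row) for row in m)


def shell_occupancy(degree_cap: Optional[int], k: int, t: int) -> int:
    """Cells within the volume of shell ``k`` after ``t`` rounds.

    Cumulative count over shells ``0..k`` of the *unconstrained* growth
    trajectory (volume checks off).  Uncapped growth puts ``C(t, j)``
    cells in shell ``j``; capped growth follows the shell-resolved birth
    recursion.
    """
    if k < 0 or t < 0:
        raise ValueError("k and t must be >= 0")
    if degree_cap is None:
        return sum(comb(t, j) for j in range(k + 1))
    if degree_cap < 2:
        raise ValueError("degree_cap must be >= 2 or None")
    m = _birth_table(degree_cap, k, t)
    return sum(m[j][tau] for j in range(k + 1) for tau in range(t + 1))


def first_overflow(
    degree_cap: Optional[int], t_max: int = 64
) -> tuple[Optional[int], frozenset]:
    """First generation at which some shell's volume is exceeded.

    Returns ``(t, shells)`` where ``t`` is the smallest generation with
    ``shell_occupancy(k, t) > shell_capacity(k)`` for at least one ``k``
    and ``shells`` is the set of shells exceeded at that generation.
    Degree cap 2 grows filaments (one cell per shell) and never
    overflows: returns :data:`NO_OVERFLOW`.
    """
    if degree_cap is not None and degree_cap < 2:
        raise ValueError("degree_cap must be >= 2 or None")
    if degree_cap == 2:
        return NO_OVERFLOW
    for t in range(1, t_max + 1):
        exceeded = frozenset(
            k
            for k in range(t + 1)
            if shell_occupancy(degree_cap, k, t) > shell_capacity(k)
        )
        if exceeded:
            return t, exceeded
    raise RuntimeError(f"no overflow within {t_max} generations")


def branch_series(degree_cap: Optional[int], max_age: int) -> list[int]:
    """Cells in a branch of age ``a`` for ``a = 0..max_age``.

    A branch starts as a single cell; per-generation births follow
    ``n(a) = sum_{i=1..min(a, d-1)} n(a-i)`` with ``n(0) = 1`` (for the
    uncapped tree this is doubling, ``f(a) = 2**a``); the branch size is
    the cumulative sum.  Cap 3 gives 1, 2, 4, 7, 12, 20, 33, ... which
    equals ``Fib(a+3) - 1``.
    """
    if max_age < 0:
        raise ValueError("max_age must be >= 0")
    if degree_cap is None:
        return [2**a for a in range(max_age + 1)]
    if degree_cap < 2:
        raise ValueError("degree_cap must be >= 2 or None")
    order = degree_cap - 1
    births = [1]
    for a in range(1, max_age + 1):
        births.append(sum(births[max(0, a - order): a]))
    series = []
    total = 0
    for b in births:
        total += b
        series.append(total)
    return series


def total_size(degree_cap: Optional[int], t: int) -> int:
    """Total cells of the unconstrained tree after ``t`` rounds.

    For capped trees at ``t >= d`` this is twice the size of the oldest
    branch, ``2 * f_d(t-1)``; earlier generations fall back to the direct
    sum of root plus branches (the root spawns branch ``i`` at
    generation ``i``, ``i = 1..min(t, d)``).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if degree_cap is None:
        return 2**t
    f = branch_series(degree_cap, t)
    if t >= degree_cap:
        return 2 * f[t - 1]
    return 1 + sum(f[t - i] for i in range(1, min(t, degree_cap) + 1))
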