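"""Optimal cluster division as a finite-horizon dynamic programme.

A cluster of ``n`` cells survives settling selection with probability
``s(n)`` (non-decreasing: bigger clusters sink faster).  Over each of
``T`` time steps a cluster first divides into parts ``a`` and ``n - a``
(``a = 0`` means no division) and each part then grows by the map
``g`` (default doubling, clipped at the table bound ``n_max``).  The
maximal reproductive output ``V(n, t)`` satisfies the backwards
recursion

    V(n, t) = max_{0 <= a <= n/2} [ V(g(a), t+1) + V(g(n-a), t+1) ]

with the ``a = 0`` branch contributing the single term ``V(g(n), t+1)``,
and the terminal condition ``V(n, T) = s(n)`` when fitness counts
surviving clusters or ``n * s(n)`` when it counts surviving cells.
Ties are broken toward the smallest part, so "no division" wins over an
equivalent split.

Known regimes: concave ``s`` with cluster-count fitness makes halving
(as evenly as integers allow) optimal everywhere; with cell-count
fitness the same concave ``s`` makes never splitting optimal; survival
functions with a convex region (e.g. a steep Hill function) mix
no-split and halving states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "DPModel",
    "Policy",
    "solve",
    "survival_families",
    "policy_regimes",
]

FITNESS_MODES = ("clusters", "cells")


def _default_growth(n: int) -> int:
    return 2 * n


@dataclass
class DPModel:
    """Specification of one optimal-division problem.

    T: growth/division steps before settling selection.
    s: survival probability, non-decreasing over 0..n_max, s(0) = 0.
    g: within-step growth map (default doubling); clipped at n_max.
    fitness_mode: 'clusters' or 'cells'.
    n_max: largest tabulated size (a boundary artifact: near n_max the
        clipped growth map understates the no-split payoff).
    """

    s: Callable[[int], float]
    T: int = 5
    g: Callable[[int], int] = field(default=_default_growth)
    fitness_mode: str = "clusters"
    n_max: int = 256

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")
        if self.fitness_mode not in FITNESS_MODES:
            raise ValueError(f"fitness_mode must be one of {FITNESS_MODES}")
        self._validate_survival()

    def _validate_survival(self) -> None:
        vals = [self.s(n) for n in range(self.n_max + 1)]
        if abs(vals[0]) > 1e-12:
            raise ValueError("survival must satisfy s(0) = 0")
        prev = -1.0
        for n, v in enumerate(vals):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"s({n}) = {v} outside [0, 1]")
            if v < prev - 1e-12:
                raise ValueError(f"survival decreases at n = {n}")
            prev = v

    def growth(self, n: int) -> int:
        if n == 0:
            return 0
        return min(self.g(n), self.n_max)

    def terminal(self, n: int) -> float:
        if self.fitness_mode == "cells":
            return n * self.s(n)
        return self.s(n)


@dataclass
class Policy:
    """Solved value table and optimal split per (size, time) state.

    ``V[t, n]`` is the maximal reproductive output from a cluster of
    ``n`` cells at time ``t``; ``split[t, n]`` the optimal smaller part
    (0 = no division); both for ``0 <= t <= T`` (``split`` is undefined
    at ``t = T`` and stored as 0).
    """

    model: DPModel
    V: np.ndarray
    split: np.ndarray

    def smaller_fraction(self, n: int, t: int) -> float:
        """Optimal smaller-offspring fraction of a size-n cluster at t."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return self.split[t, n] / n


def solve(model: DPModel) -> Policy:
    """Tabulate the backwards recursion exactly for all states."""
    n_max, T = model.n_max, model.T
    grown = np.array([model.growth(n) for n in range(n_max + 1)])
    V = np.zeros((T + 1, n_max + 1))
    split = np.zeros((T + 1, n_max + 1), dtype=np.int64)
    V[T] = [model.terminal(n) for n in range(n_max + 1)]
    for t in range(T - 1, -1, -1):
        nxt = V[t + 1]
        for n in range(1, n_max + 1):
            best_v = nxt[grown[n]]  # a = 0: no division
            best_a = 0
            for a in range(1, n // 2 + 1):
                v = nxt[grown[a]] + nxt[grown[n - a]]
                if v > best_v + 1e-12:
                    best_v, best_a = v, a
            V[t, n] = best_v
            split[t, n] = best_a
    return Policy(model=model, V=V, split=split)


def survival_families(name: str, **params: float) -> Callable[[int], float]:
    """Standard non-decreasing survival functions s(n) on [0, 1].

    power(beta, scale):  min(1, (n / scale) ** beta)
    linear_capped(slope): min(1, slope * n)
    hill(h, K):          n**h / (n**h + K**h)  (convex below K for h > 1)
    step(n_star):        0 below n_star, 1 at or above
    """
    if name == "power":
        beta = float(params.get("beta", 0.5))
        scale = float(params.get("scale", 10.0))
        if beta <= 0 or scale <= 0:
            raise ValueError("power family needs beta > 0 and scale > 0")
        return lambda n: 0.0 if n <= 0 else min(1.0, (n / scale) ** beta)
    if name == "linear_capped":
        slope = float(params.get("slope", 0.01))
        if slope <= 0:
            raise ValueError("linear_capped needs slope > 0")
        return lambda n: min(1.0, slope * n)
    if name == "hill":
        h = float(params.get("h", 4.0))
        K = float(params.get("K", 50.0))
        if h <= 0 or K <= 0:
            raise ValueError("hill needs h > 0 and K > 0")
        return lambda n: 0.0 if n <= 0 else n**h / (n**h + K**h)
    if name == "step":
        n_star = float(params.get("n_star", 10))
        if n_star < 1:
            raise ValueError("step needs n_star >= 1")
        return lambda n: 1.0 if n >= n_star else 0.0
    raise ValueError(f"unknown survival family {name!r}")


def policy_regimes(policy: Policy) -> np.ndarray:
    """Label each (t, n) state 'no-split', 'halve' or 'asymmetric'.

    'halve' means the split is as even as the integers allow
    (``a = floor(n/2)``); a size-1 cluster cannot divide and is labeled
    'no-split'.
    """
    T, width = policy.split.shape
    labels = np.empty((T, width), dtype=object)
    for t in range(T):
        for n in range(width):
            a = policy.split[t, n]
            if a == 0:
                labels[t, n] = "no-split"
            elif a == n // 2:
                labels[t, n] = "halve"
            else:
                labels[t, n] = "asymmetric"
    return labels
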