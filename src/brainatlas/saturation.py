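"""Prospective multinomial sampling-saturation model for rare cell types.

Given k rare types of per-cell sampling probability p each, the success
probability at n sequenced cells is P(N_1 >= c, ..., N_k >= c) under the
multinomial; the required depth is n* = min{n : P >= p*}. The default
evaluation uses the independent-Poisson approximation
[P(Poisson(n p) >= c)]^k, accurate when k*p is small; an exact-multinomial
Monte-Carlo mode is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, poisson

__all__ = [
    "SaturationSpec",
    "success_probability",
    "success_probability_mc",
    "required_cells",
    "saturation_curve",
    "required_count_for_fraction",
]


@dataclass
class SaturationSpec:
    """k rare types at per-type probability p_type, needing >= c cells each
    at success probability target p_star."""

    k: int
    p_type: float
    c: int
    p_star: float = 0.9

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.p_type <= 1.0 / self.k:
            raise ValueError("need 0 < p_type <= 1/k")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not 0 < self.p_star < 1:
            raise ValueError("p_star must be in (0, 1)")


def required_count_for_fraction(n_rarest: int, fraction: float = 0.8) -> int:
    """c = ceil(fraction * N_rarest): cells needed per type for sufficient
    sampling of the rarest type."""
    return math.ceil(fraction * n_rarest)


def success_probability(n: int, spec: SaturationSpec) -> float:
    """P(all k types reach >= c cells) at depth n.

    For k = 1 the multinomial marginal is binomial and is evaluated exactly;
    for k > 1 the independent-Poisson approximation
    [P(Poisson(n p) >= c)]^k is used."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if spec.k == 1:
        return float(binom.sf(spec.c - 1, max(n, 0), spec.p_type)) if n > 0 else 0.0
    lam = n * spec.p_type
    per_type = poisson.sf(spec.c - 1, lam)
    return float(per_type**spec.k)


def success_probability_mc(n: int, spec: SaturationSpec, n_reps: int = 10_000,
                           seed: int = 0) -> tuple[float, float]:
    """Exact-multinomial Monte-Carlo estimate (mean, standard error)."""
    rng = np.random.default_rng(seed)
    p = np.full(spec.k, spec.p_type)
    rest = 1.0 - p.sum()
    probs = np.append(p, rest)
    draws = rng.multinomial(n, probs, size=n_reps)[:, : spec.k]
    success = (draws >= spec.c).all(axis=1)
    mean = float(success.mean())
    se = float(np.sqrt(mean * (1 - mean) / n_reps))
    return mean, se


def required_cells(spec: SaturationSpec, n_max: int = 10**10) -> int:
    """n* = min{n : success_probability(n) >= p_star}, by bisection on the
    monotone curve."""
    lo, hi = 0, max(spec.c, 1)
    while success_probability(hi, spec) < spec.p_star:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"p_star={spec.p_star} unreachable below n={n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if success_probability(mid, spec) >= spec.p_star:
            hi = mid
        else:
            lo = mid + 1
    return lo


def saturation_curve(spec: SaturationSpec, n_grid) -> list[tuple[int, float]]:
    """Success probability over an ascending grid of depths."""
    grid = list(n_grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_grid must be ascending")
    return [(int(n), success_probability(int(n), spec)) for n in grid]
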