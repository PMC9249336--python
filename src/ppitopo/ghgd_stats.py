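"""Random-overlap model for elements shared by several subsets of a universe.

Given ``m`` subsets of sizes :math:`n_1, \\dots, n_m` drawn independently
and uniformly (without replacement within each subset) from a universe of
``N`` elements, the count of elements that land in at least ``k`` of the
subsets follows a generalized hypergeometric-type distribution.  This
module evaluates its exact mean and variance, bounds the count with
Chebyshev's inequality (which needs no distributional shape), and turns an
observed overlap count into a significance report:

    sig = observed - floor(upper bound of the random-overlap count).

The mean is ``N * P(B >= k)`` where ``B`` is a Poisson-binomial sum of the
per-subset membership indicators with success probability ``n_i / N``.
The variance adds the exact pairwise covariance between two fixed distinct
elements, whose joint per-subset membership probabilities are
``n_i (n_i - 1) / (N (N - 1))`` (both in subset i) and
``n_i (N - n_i) / (N (N - 1))`` (exactly one), independent across subsets.
Both moments are evaluated by exact enumeration over joint membership
patterns (``2^m`` and ``4^m`` terms), so they are closed-form for the
handful of datasets typical of interaction studies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "OverlapModel",
    "OverlapMoments",
    "ConfidenceBounds",
    "SignificanceReport",
    "overlap_mean",
    "overlap_variance",
    "overlap_moments",
    "chebyshev_ci",
    "significance_report",
    "simulate_overlap_counts",
]


@dataclass(frozen=True)
class OverlapModel:
    """Universe size, subset sizes, and the overlap threshold ``k``."""

    universe_size: int
    subset_sizes: tuple[int, ...]
    k: int

    def __post_init__(self):
        if self.universe_size < 1:
            raise ValueError("universe_size must be positive")
        if not self.subset_sizes:
            raise ValueError("need at least one subset")
        for n in self.subset_sizes:
            if not (0 < n <= self.universe_size):
                raise ValueError(f"subset size {n} outside (0, N={self.universe_size}]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class OverlapMoments:
    mean: float
    variance: float


@dataclass(frozen=True)
class ConfidenceBounds:
    lower: float
    upper: float
    alpha: float


@dataclass(frozen=True)
class SignificanceReport:
    observed: int
    random_up: int
    sig_count: int
    false_positive_pct: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _single_tail(model: OverlapModel) -> float:
    """P(one fixed element falls in >= k subsets)."""
    N = model.universe_size
    ps = [n / N for n in model.subset_sizes]
    total = 0.0
    for pattern in product((0, 1), repeat=len(ps)):
        if sum(pattern) >= model.k:
            pr = 1.0
            for bit, p in zip(pattern, ps):
                pr *= p if bit else 1.0 - p
            total += pr
    return total


def _pair_tail(model: OverlapModel) -> float:
    """P(two fixed distinct elements each fall in >= k subsets)."""
    N = model.universe_size
    denom = N * (N - 1)
    per_subset = []
    for n in model.subset_sizes:
        per_subset.append(
            {
                (1, 1): n * (n - 1) / denom,
                (1, 0): n * (N - n) / denom,
                (0, 1): n * (N - n) / denom,
                (0, 0): (N - n) * (N - n - 1) / denom,
            }
        )
    total = 0.0
    states = ((1, 1), (1, 0), (0, 1), (0, 0))
    for pattern in product(states, repeat=len(per_subset)):
        c1 = sum(s[0] for s in pattern)
        c2 = sum(s[1] for s in pattern)
        if c1 >= model.k and c2 >= model.k:
            pr = 1.0
            for probs, state in zip(per_subset, pattern):
                pr *= probs[state]
            total += pr
    return total


def overlap_mean(model: OverlapModel) -> float:
    """Exact expected number of elements in at least ``k`` subsets."""
    if model.k > len(model.subset_sizes):
        warnings.warn("k exceeds the number of subsets; overlap count is 0")
        return 0.0
    return model.universe_size * _single_tail(model)


def overlap_variance(model: OverlapModel) -> float:
    """Exact variance of the >=k-fold overlap count.

    ``Var = N p (1 - p) + N (N - 1) (p2 - p^2)`` with ``p`` the
    single-element tail and ``p2`` the two-element joint tail.
    """
    if model.k > len(model.subset_sizes):
        warnings.warn("k exceeds the number of subsets; overlap count is 0")
        return 0.0
    N = model.universe_size
    p = _single_tail(model)
    if N == 1:
        return p * (1 - p)
    p2 = _pair_tail(model)
    var = N * p * (1 - p) + N * (N - 1) * (p2 - p * p)
    return max(var, 0.0)


def overlap_moments(model: OverlapModel) -> OverlapMoments:
    return OverlapMoments(mean=overlap_mean(model), variance=overlap_variance(model))


def chebyshev_ci(moments: OverlapMoments, alpha: float = 0.05) -> ConfidenceBounds:
    """Distribution-free bounds: mean +/- sqrt(1/alpha) standard deviations.

    Chebyshev's inequality guarantees the count falls inside with
    probability at least ``1 - alpha``; the lower bound is clipped at 0.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if moments.variance < 0:
        raise ValueError("variance must be non-negative")
    k_cheb = math.sqrt(1.0 / alpha)
    half = k_cheb * math.sqrt(moments.variance)
    return ConfidenceBounds(
        lower=max(0.0, moments.mean - half), upper=moments.mean + half, alpha=alpha
    )


def significance_report(observed: int, bounds: ConfidenceBounds) -> SignificanceReport:
    """Count of overlaps that exceed what random subset choice explains.

    ``random_up`` is the floor of the Chebyshev upper bound ("at most that
    many overlaps by chance"); the significant count is the excess of the
    observation over it, floored at zero, and the false-positive
    percentage is the chance bound as a share of the observation.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    random_up = math.floor(bounds.upper)
    sig = max(0, observed - random_up)
    fp = 100.0 * random_up / observed if observed > 0 else 0.0
    return SignificanceReport(
        observed=observed, random_up=random_up, sig_count=sig, false_positive_pct=fp
    )


def simulate_overlap_counts(
    model: OverlapModel, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of the >=k-fold overlap count (oracle for moments).

    Each replicate samples every subset uniformly without replacement from
    the universe and counts elements present in at least ``k`` subsets.
    Vectorized over replicates; intended for small universes.
    """
    N = model.universe_size
    counts = np.zeros(n_replicates, dtype=np.int64)
    membership = np.zeros((n_replicates, N), dtype=np.int16)
    for n in model.subset_sizes:
        u = rng.random((n_replicates, N))
        # the n smallest uniforms per row mark a uniform n-subset
        kth = np.partition(u, n - 1, axis=1)[:, n - 1 : n]
        membership += u <= kth
    counts = (membership >= model.k).sum(axis=1)
    return counts
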