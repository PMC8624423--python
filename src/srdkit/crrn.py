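"""Comparison of ranks with random numbers (CRRN).

The permutation null of SRD: how large the sum of ranking differences is when
the candidate ranking is a uniformly random permutation of the reference's
own rank multiset (so ties are respected — like is compared with like). An
observed scaled SRD far below the bulk of this distribution marks a candidate
as significantly closer to the benchmark than chance.

The distribution is enumerated exactly for small row counts (all n!
arrangements; default limit n <= 8, i.e. 40320 permutations) and sampled by
seeded Monte Carlo otherwise. Three probability levels are reported on the
scaled-SRD axis: XX1 (5%), Med (50%) and XX19 (95%), each by discrete
inverse-CDF (the smallest support value whose CDF reaches the level — the
null is discrete, so no interpolation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .srd import max_srd

__all__ = [
    "CrrnDistribution",
    "exact_distribution",
    "monte_carlo_distribution",
    "crrn_null",
    "crrn_levels",
    "randomness_probability",
    "ENUMERATION_LIMIT",
    "DEFAULT_PERMUTATIONS",
]

ENUMERATION_LIMIT = 8
DEFAULT_PERMUTATIONS = 100_000

_EPS = 1e-9


@dataclass(frozen=True)
class CrrnDistribution:
    """Null distribution of SRD under random ranking.

    ``support`` holds the distinct raw SRD values ascending; ``probabilities``
    their null masses. ``srd_max`` scales raw SRD to the 0-100 axis shared
    with the observed values.
    """

    n: int
    support: np.ndarray
    probabilities: np.ndarray
    srd_max: float
    method: str  # "exact" | "monte_carlo"
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=float)
        prob = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "probabilities", prob)
        if sup.shape != prob.shape or sup.ndim != 1:
            raise ValueError("support and probabilities must be 1-D and aligned")
        if np.any(sup < 0) or np.any(np.diff(sup) <= 0):
            raise ValueError("support must be non-negative and strictly ascending")
        if abs(prob.sum() - 1.0) > 1e-8 or np.any(prob < 0):
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def scaled_support(self) -> np.ndarray:
        if self.srd_max > 0:
            return 100.0 * self.support / self.srd_max
        return np.zeros_like(self.support)

    @property
    def cdf(self) -> np.ndarray:
        return np.minimum(np.cumsum(self.probabilities), 1.0)

    def _level(self, p: float) -> float:
        idx = int(np.argmax(self.cdf >= p - _EPS))
        return float(self.scaled_support[idx])

    @property
    def xx1(self) -> float:
        """Scaled SRD at the 5% probability level."""
        return self._level(0.05)

    @property
    def med(self) -> float:
        """Scaled SRD at the median of the null."""
        return self._level(0.5)

    @property
    def xx19(self) -> float:
        """Scaled SRD at the 95% probability level."""
        return self._level(0.95)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "srd": self.support,
                "scaled_srd": self.scaled_support,
                "probability": self.probabilities,
                "cdf": self.cdf,
            }
        )

    def to_dict(self) -> dict:
        meta: dict = {
            "n": self.n,
            "method": self.method,
            "srd_max": self.srd_max,
            "xx1": self.xx1,
            "med": self.med,
            "xx19": self.xx19,
        }
        if self.method == "monte_carlo":
            meta["n_permutations"] = self.n_permutations
            meta["seed"] = self.seed
        return meta


def _tabulate(srd_samples: np.ndarray, weights: np.ndarray | None = None):
    vals = np.round(srd_samples, 9)
    support, counts = np.unique(vals, return_counts=True)
    return support, counts


def exact_distribution(reference_ranks, limit: int = ENUMERATION_LIMIT) -> CrrnDistribution:
    """Exact CRRN null by enumerating all n! permutations of the reference
    rank multiset. Refuses n above ``limit`` — use Monte Carlo there."""
    ref = np.asarray(reference_ranks, dtype=float).ravel()
    n = ref.size
    if n < 2:
        raise ValueError("CRRN needs at least 2 rows")
    if n > limit:
        raise ValueError(
            f"n={n} exceeds the enumeration limit {limit}; "
            "use monte_carlo_distribution instead"
        )
    perms = np.array(list(itertools.permutations(ref)), dtype=float)
    srd = np.abs(perms - ref).sum(axis=1)
    support, counts = _tabulate(srd)
    return CrrnDistribution(
        n=n,
        support=support,
        probabilities=counts / counts.sum(),
        srd_max=max_srd(ref),
        method="exact",
    )


def monte_carlo_distribution(
    reference_ranks,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    batch_size: int = 20_000,
) -> CrrnDistribution:
    """Seeded Monte-Carlo CRRN null: uniform random permutations of the
    reference rank multiset, in memory-bounded batches."""
    ref = np.asarray(reference_ranks, dtype=float).ravel()
    n = ref.size
    if n < 2:
        raise ValueError("CRRN needs at least 2 rows")
    if n_permutations < 1000:
        raise ValueError("n_permutations must be >= 1000 for a usable null")
    rng = np.random.default_rng(seed)
    counts: dict[float, int] = {}
    remaining = int(n_permutations)
    while remaining > 0:
        b = min(batch_size, remaining)
        block = rng.permuted(np.tile(ref, (b, 1)), axis=1)
        srd = np.abs(block - ref).sum(axis=1)
        sup, cnt = _tabulate(srd)
        for s, c in zip(sup, cnt):
            counts[float(s)] = counts.get(float(s), 0) + int(c)
        remaining -= b
    support = np.array(sorted(counts))
    freq = np.array([counts[s] for s in support], dtype=float)
    return CrrnDistribution(
        n=n,
        support=support,
        probabilities=freq / freq.sum(),
        srd_max=max_srd(ref),
        method="monte_carlo",
        n_permutations=int(n_permutations),
        seed=int(seed),
    )


def crrn_null(
    reference_ranks,
    limit: int = ENUMERATION_LIMIT,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> CrrnDistribution:
    """Exact null when n is within the enumeration limit, Monte Carlo otherwise."""
    ref = np.asarray(reference_ranks, dtype=float).ravel()
    if ref.size <= limit:
        return exact_distribution(ref, limit=limit)
    return monte_carlo_distribution(ref, n_permutations=n_permutations, seed=seed)


def crrn_levels(dist: CrrnDistribution) -> tuple[float, float, float]:
    """The (XX1, Med, XX19) scaled-SRD probability levels of a null."""
    return dist.xx1, dist.med, dist.xx19


def randomness_probability(scaled_srd: float, dist: CrrnDistribution) -> float:
    """Left-tail null probability P(random SRD <= observed).

    The chance that a random ranking comes at least this close to the
    benchmark; small values mean the observed closeness is unlikely to be
    chance.
    """
    mask = dist.scaled_support <= scaled_srd + _EPS
    return float(dist.probabilities[mask].sum())
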