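"""Pooled-resampling (permutation) test for a difference in mean values.

The two input vectors — typically per-chromosome or per-SNP mean
heterozygosities of two populations — are pooled, and random partitions into
groups of the original sizes are drawn without replacement. The test
statistic is the absolute difference of group means; permuted statistics at
least as large as the observed one (ties count as extreme) contribute to the
p-value. When no permuted statistic reaches the observed one the p-value is
reported as the strict bound "< 1/n_permutations".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np


@dataclass
class RandomizationResult:
    observed_stat: float
    p_value: float
    p_string: str
    n_permutations: int
    n_as_extreme: int
    exact: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not 0 <= self.n_as_extreme <= self.n_permutations:
            raise ValueError("n_as_extreme out of range")


def randomization_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> RandomizationResult:
    """Permutation test of |mean(A) - mean(B)| by pooled resampling.

    Parameters
    ----------
    values_a, values_b
        Non-empty numeric vectors.
    n_permutations
        Number of random partitions (ignored in exact mode).
    seed
        Seed for the permutation stream; required for reproducibility.
    exact
        Enumerate all C(n, n_a) partitions instead of sampling; refused
        when that count exceeds 1e5.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both input vectors must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = abs(a.mean() - b.mean())
    total = pooled.sum()
    n_b = b.size
    # |mean(A') - mean(B')| from the A'-subset sum alone
    def stat_from_subset_sum(s_a: np.ndarray) -> np.ndarray:
        return np.abs(s_a / n_a - (total - s_a) / n_b)

    tol = 1e-12 * (1.0 + observed)
    if exact:
        n_part = comb(pooled.size, n_a)
        if n_part > 100_000:
            raise ValueError(f"exact mode refused: C(n, n_a) = {n_part} > 1e5")
        sums = np.fromiter(
            (pooled[list(idx)].sum() for idx in combinations(range(pooled.size), n_a)),
            dtype=float,
            count=n_part,
        )
        stats = stat_from_subset_sum(sums)
        n_extreme = int((stats >= observed - tol).sum())
        p = n_extreme / n_part
        return RandomizationResult(observed, p, f"{p:.6g}", n_part, n_extreme, True, seed)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    chunk = max(1, min(n_permutations, 2_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        # random partition: first n_a entries of each shuffled row form A'
        order = np.argsort(rng.random((m, pooled.size)), axis=1)[:, :n_a]
        sums = pooled[order].sum(axis=1)
        stats = stat_from_subset_sum(sums)
        n_extreme += int((stats >= observed - tol).sum())
        done += m
    if n_extreme == 0:
        p = 1.0 / n_permutations
        p_string = f"< {1.0 / n_permutations:g}"
    else:
        p = n_extreme / n_permutations
        p_string = f"{p:.6g}"
    return RandomizationResult(observed, p, p_string, n_permutations, n_extreme, False, seed)
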