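"""Exact conditional test of Hardy-Weinberg genotype proportions.

The test conditions on the observed allele counts: with ``n`` diploids and
``nA`` copies of allele A, every possible heterozygote count ``h`` compatible
with those allele counts is enumerated, and each outcome's probability is the
Levene/Haldane conditional probability

    P(h | n, nA) = n! / (nAA! h! naa!) * 2^h * nA! * na! / (2n)!

Outcomes are ranked by a likelihood-ratio statistic (the G-like log ratio of
the multinomial likelihood at the observed table to the likelihood under
Hardy-Weinberg proportions at the conditioned allele frequency); the p-value
sums the probabilities of all outcomes whose statistic is at least as extreme
as the observed one. A probability ordering (smaller conditional probability
= more extreme) is available as an alternative.
"""

from __future__ import annotations

from functools import lru_cache
from math import lgamma, log

import numpy as np

_TIE_TOL = 1e-9

ORDERINGS = ("lr", "prob")


def _log_cond_prob(n: int, n_a: int, h: int) -> float:
    """Log Levene/Haldane conditional probability of ``h`` heterozygotes."""
    n_b = 2 * n - n_a
    n_aa = (n_a - h) // 2
    n_bb = (n_b - h) // 2
    return (
        lgamma(n + 1)
        - lgamma(n_aa + 1)
        - lgamma(h + 1)
        - lgamma(n_bb + 1)
        + h * log(2.0)
        + lgamma(n_a + 1)
        + lgamma(n_b + 1)
        - lgamma(2 * n + 1)
    )


def _lr_statistic(n: int, n_a: int, h: int) -> float:
    """G-like log likelihood-ratio of the table (larger = more extreme)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - h) // 2
    n_bb = (n_b - h) // 2
    p = n_a / (2.0 * n)
    q = 1.0 - p
    expected = (p * p, 2.0 * p * q, q * q)
    stat = 0.0
    for obs, exp in zip((n_aa, h, n_bb), expected):
        if obs > 0:
            stat += obs * log(obs / (n * exp))
    return 2.0 * stat


@lru_cache(maxsize=None)
def _conditional_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """All heterozygote counts compatible with (n, n_a) and their probabilities."""
    n_b = 2 * n - n_a
    h_values = np.arange(n_a % 2, min(n_a, n_b) + 1, 2, dtype=np.int64)
    logp = np.array([_log_cond_prob(n, n_a, int(h)) for h in h_values])
    probs = np.exp(logp)
    probs /= probs.sum()  # guard against log-gamma rounding
    return h_values, probs


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int, ordering: str = "lr") -> float:
    """Exact conditional Hardy-Weinberg p-value for one genotype table.

    Parameters
    ----------
    n_aa, n_ab, n_bb
        Observed counts of the two homozygote classes and the heterozygote
        class (allele labels are interchangeable).
    ordering
        ``"lr"`` ranks outcomes by the likelihood-ratio statistic;
        ``"prob"`` ranks them by conditional probability.

    Returns
    -------
    float
        p-value in [0, 1]. A locus monomorphic in the sample has a single
        possible outcome and p = 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    if ordering not in ORDERINGS:
        raise ValueError(f"ordering must be one of {ORDERINGS}")
    n = int(n_aa + n_ab + n_bb)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = int(2 * n_aa + n_ab)
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0

    h_values, probs = _conditional_distribution(n, n_a)
    if ordering == "prob":
        i = int(np.searchsorted(h_values, n_ab))
        p_obs = probs[i]
        return float(probs[probs <= p_obs * (1.0 + _TIE_TOL)].sum())

    stats = np.array([_lr_statistic(n, n_a, int(h)) for h in h_values])
    stat_obs = _lr_statistic(n, n_a, int(n_ab))
    extreme = stats >= stat_obs - _TIE_TOL
    return float(min(probs[extreme].sum(), 1.0))


def hwe_pvalues_for_counts(counts: np.ndarray, ordering: str = "lr") -> np.ndarray:
    """Vector of exact HWE p-values for an (n_loci, 3) genotype-count table.

    Loci with zero genotyped individuals get NaN. Results are memoized on
    the (n, allele-count, het-count) triple, which keeps genome-scale sweeps
    cheap because per-population sample sizes are small.
    """
    counts = np.asarray(counts, dtype=np.int64)
    out = np.full(len(counts), np.nan)
    cache: dict[tuple[int, int, int], float] = {}
    for i, (a, h, b) in enumerate(counts):
        n = a + h + b
        if n == 0:
            continue
        key = (int(n), int(2 * a + h), int(h))
        p = cache.get(key)
        if p is None:
            p = hwe_exact_test(int(a), int(h), int(b), ordering=ordering)
            cache[key] = p
        out[i] = p
    return out
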