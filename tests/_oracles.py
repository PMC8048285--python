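"""Independent reference implementations used only to check the package.

Each oracle recomputes a statistic from first principles through a code
path deliberately different from the implementation it verifies:

* HWE: exact-fraction enumeration of the Levene/Haldane conditional
  distribution (math.comb arithmetic, no log-gamma).
* F_ST: nested ANOVA on per-gamete allele indicators (sums of squares and
  mean squares), not the closed-form variance-component expressions.
* Permutation p: full enumeration of all group partitions.
* kNN: dense all-pairs distance matrix.
* Effect calls: codon-by-codon translation with a hand-written codon table.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, log

import numpy as np


# -- HWE -------------------------------------------------------------------


def hwe_enumeration_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE p-value with likelihood-ratio ordering."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a
    if n_a == 0 or n_b == 0:
        return 1.0
    support = list(range(n_a % 2, min(n_a, n_b) + 1, 2))
    # conditional probability as exact fractions
    weights = {}
    for h in support:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        # multinomial(n; a, h, b) * 2^h
        weights[h] = Fraction(
            comb(n, a) * comb(n - a, h) * 2**h
        )
    total = sum(weights.values())

    p_freq = n_a / (2 * n)
    q_freq = 1.0 - p_freq
    expected = (p_freq * p_freq, 2 * p_freq * q_freq, q_freq * q_freq)

    def lr_stat(h: int) -> float:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        s = 0.0
        for obs, exp in zip((a, h, b), expected):
            if obs > 0:
                s += obs * log(obs / (n * exp))
        return 2.0 * s

    observed = lr_stat(n_ab)
    p = sum(weights[h] for h in support if lr_stat(h) >= observed - 1e-9)
    return float(p / total)


# -- Weir & Cockerham theta via nested ANOVA -------------------------------


def anova_theta(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> np.ndarray:
    """Per-locus WC theta from gamete-indicator sums of squares.

    ``genotypes_*`` are (samples, loci) dosage arrays with -1 for missing.
    """
    genotypes_a = np.atleast_2d(genotypes_a)
    genotypes_b = np.atleast_2d(genotypes_b)
    n_loci = genotypes_a.shape[1]
    out = np.full(n_loci, np.nan)
    r = 2
    for j in range(n_loci):
        groups = []
        for g in (genotypes_a[:, j], genotypes_b[:, j]):
            g = g[g >= 0]
            groups.append(np.asarray(g, dtype=float))
        n_i = np.array([len(g) for g in groups], dtype=float)
        if (n_i < 2).any():
            continue
        total_copies = 2.0 * n_i.sum()
        p_bar = sum(g.sum() for g in groups) / total_copies
        if p_bar == 0.0 or p_bar == 1.0:
            continue
        p_i = np.array([g.sum() / (2 * len(g)) for g in groups])
        # gamete indicator x in {0,1}: within-individual SS is 0.5 per het
        ss_within = sum(float((g == 1.0).sum()) for g in groups) * 0.5
        ss_ind = sum(
            2.0 * ((g / 2.0 - p) ** 2).sum() for g, p in zip(groups, p_i)
        )
        ss_pop = 2.0 * float((n_i * (p_i - p_bar) ** 2).sum())
        n_tot = n_i.sum()
        ms_within = ss_within / n_tot
        ms_ind = ss_ind / (n_tot - r)
        ms_pop = ss_pop / (r - 1)
        n_c = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
        var_within = ms_within
        var_ind = (ms_ind - ms_within) / 2.0
        var_pop = (ms_pop - ms_ind) / (2.0 * n_c)
        denom = var_pop + var_ind + var_within
        if abs(denom) > 0:
            out[j] = var_pop / denom
    return out


def genotype_counts(genotypes: np.ndarray) -> np.ndarray:
    """(loci, 3) genotype-class counts from a (samples, loci) dosage array."""
    genotypes = np.atleast_2d(genotypes)
    return np.stack(
        [(genotypes == g).sum(axis=0) for g in (0, 1, 2)], axis=1
    ).astype(np.int64)


# -- exact permutation test ------------------------------------------------


def exact_permutation_p(values_a, values_b) -> float:
    """All-partitions permutation p for |mean(A) - mean(B)| (ties >= extreme)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n_extreme = 0
    n_total = 0
    idx = range(pooled.size)
    for subset in combinations(idx, a.size):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(subset)] = True
        stat = abs(pooled[sel].mean() - pooled[~sel].mean())
        n_total += 1
        if stat >= observed - 1e-12 * (1 + observed):
            n_extreme += 1
    return n_extreme / n_total


# -- brute-force kNN -------------------------------------------------------


def brute_force_knn_distance(vectors: np.ndarray, k: int) -> np.ndarray:
    """Distance to the k-th nearest neighbor via the full distance matrix."""
    vectors = np.atleast_2d(vectors)
    d = np.sqrt(((vectors[:, None, :] - vectors[None, :, :]) ** 2).sum(axis=2))
    d_sorted = np.sort(d, axis=1)
    return d_sorted[:, k]  # column 0 is self-distance 0


def brute_force_medoid(vectors: np.ndarray) -> int:
    d = np.sqrt(((vectors[:, None, :] - vectors[None, :, :]) ** 2).sum(axis=2))
    return int(np.argmin(d.sum(axis=1)))


# -- codon-table translation ----------------------------------------------

_T = {}
_bases = "TCAG"
_aas = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_bases):
    for _j, _b2 in enumerate(_bases):
        for _k, _b3 in enumerate(_bases):
            _T[_b1 + _b2 + _b3] = _aas[16 * _i + 4 * _j + _k]


def translate_codons(seq: str) -> str:
    """Codon-by-codon translation with a hand-written standard code table."""
    return "".join(_T[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def classify_by_translation(orf_seq: str, offset: int, alt: str) -> str:
    """Synonymous/nonsynonymous by translating both full sequences."""
    alt_seq = orf_seq[:offset] + alt + orf_seq[offset + 1 :]
    return (
        "synonymous"
        if translate_codons(orf_seq) == translate_codons(alt_seq)
        else "nonsynonymous"
    )
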