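"""Genotype-, sample- and locus-level filters.

The canonical chain, in order: depth mask -> high-missing sample drop ->
call-rate filter -> minor-allele-count filter -> per-population HWE
exclusion. Every step is functional (returns a new matrix) and idempotent,
and never edits retained genotype values except the depth mask, which only
sets calls to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hwe import hwe_pvalues_for_counts
from .matrix import MISSING, FilterReport, GenotypeMatrix


def mask_low_depth(gm: GenotypeMatrix, min_depth: int = 5) -> GenotypeMatrix:
    """Set genotypes supported by fewer than *min_depth* reads to missing.

    The comparison is strict: a call at exactly *min_depth* reads is kept.
    """
    if gm.depth is None:
        raise ValueError(
            "genotype matrix has no depth layer; skip mask_low_depth explicitly "
            "if depths are unavailable"
        )
    calls = gm.calls.copy()
    calls[gm.depth < min_depth] = MISSING
    return GenotypeMatrix(gm.samples, gm.populations, gm.loci, calls, gm.depth)


def drop_high_missing_samples(
    gm: GenotypeMatrix, max_missing_fraction: float = 0.90
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove samples whose missing-call fraction strictly exceeds the cutoff."""
    frac = gm.missing_fraction_per_sample()
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("all samples exceed the missing-data threshold")
    removed = pd.DataFrame(
        {
            "sample": [s for s, k in zip(gm.samples, keep) if not k],
            "missing_fraction": frac[~keep],
        }
    )
    out = gm.take_samples([s for s, k in zip(gm.samples, keep) if k])
    report = FilterReport(
        "drop_high_missing_samples",
        gm.n_samples,
        out.n_samples,
        gm.n_loci,
        out.n_loci,
        removed,
    )
    return out, report


def filter_call_rate(gm: GenotypeMatrix, min_rate: float = 0.80) -> GenotypeMatrix:
    """Keep loci genotyped in at least *min_rate* of the (retained) samples."""
    called = (gm.calls != MISSING).sum(axis=0)
    # >= with a small epsilon so exact-boundary loci (e.g. 80.0%) are kept
    keep = called >= min_rate * gm.n_samples - 1e-9
    return gm.take_loci(np.flatnonzero(keep))


def filter_minor_allele(gm: GenotypeMatrix, min_minor_copies: int = 2) -> GenotypeMatrix:
    """Keep loci whose minor-allele copy count reaches *min_minor_copies*.

    Copies are counted over all non-missing calls pooled across samples; a
    single minor-allele homozygote therefore qualifies at the default of 2.
    A frequency-based mode is available through
    :func:`filter_minor_allele_frequency`.
    """
    alt = np.where(gm.calls == MISSING, 0, gm.calls).sum(axis=0)
    n = (gm.calls != MISSING).sum(axis=0)
    minor = np.minimum(alt, 2 * n - alt)
    return gm.take_loci(np.flatnonzero(minor >= min_minor_copies))


def filter_minor_allele_frequency(gm: GenotypeMatrix, min_maf: float = 0.025) -> GenotypeMatrix:
    """Frequency form of the minor-allele filter: keep loci with MAF >= cutoff."""
    alt = np.where(gm.calls == MISSING, 0, gm.calls).sum(axis=0)
    n = (gm.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n > 0, np.minimum(alt, 2 * n - alt) / (2.0 * n), 0.0)
    return gm.take_loci(np.flatnonzero(maf >= min_maf - 1e-12))


@dataclass
class HweFilterResult:
    """Per-population locus retention after the HWE exclusion.

    ``kept[pop]`` is a boolean mask over the matrix's loci: True where the
    locus is genotyped in >= 1 individual of that population AND its exact
    HWE p-value is >= alpha. Monomorphic-within-population loci have p = 1
    and are retained. ``p_values[pop]`` holds the per-locus p-values (NaN
    where the population has no genotyped individual).
    """

    kept: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    alpha: float

    def shared_loci(self, pop_a: str, pop_b: str) -> np.ndarray:
        """Mask of loci usable for the (pop_a, pop_b) pairwise comparison."""
        return self.kept[pop_a] & self.kept[pop_b]


def filter_hwe(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    populations: list[str] | None = None,
    ordering: str = "lr",
) -> HweFilterResult:
    """Per-population exact-HWE exclusion (p < alpha drops the locus).

    Each population is tested independently; pairwise analyses downstream
    use :meth:`HweFilterResult.shared_loci`, the intersection of the two
    populations' kept sets.
    """
    pops = populations if populations is not None else gm.population_labels
    kept: dict[str, np.ndarray] = {}
    p_values: dict[str, np.ndarray] = {}
    for pop in pops:
        counts = gm.genotype_counts(pop)
        p = hwe_pvalues_for_counts(counts, ordering=ordering)
        p_values[pop] = p
        genotyped = counts.sum(axis=1) > 0
        kept[pop] = genotyped & ~(p < alpha)
    return HweFilterResult(kept, p_values, alpha)


def apply_standard_filters(
    gm: GenotypeMatrix,
    min_depth: int | None = 5,
    max_missing_fraction: float = 0.90,
    min_call_rate: float = 0.80,
    min_minor_copies: int = 2,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Run the depth/sample/call-rate/MAC chain in its canonical order."""
    reports: list[FilterReport] = []
    if min_depth is not None and gm.depth is not None:
        before = gm
        gm = mask_low_depth(gm, min_depth)
        reports.append(
            FilterReport(
                "mask_low_depth", before.n_samples, gm.n_samples, before.n_loci, gm.n_loci
            )
        )
    gm, rep = drop_high_missing_samples(gm, max_missing_fraction)
    reports.append(rep)
    before = gm
    gm = filter_call_rate(gm, min_call_rate)
    reports.append(
        FilterReport("filter_call_rate", before.n_samples, gm.n_samples, before.n_loci, gm.n_loci)
    )
    before = gm
    gm = filter_minor_allele(gm, min_minor_copies)
    reports.append(
        FilterReport(
            "filter_minor_allele", before.n_samples, gm.n_samples, before.n_loci, gm.n_loci
        )
    )
    return gm, reports
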