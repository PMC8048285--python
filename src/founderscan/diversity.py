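"""Observed heterozygosity and nucleotide diversity, per locus and summarized.

Definitions (biallelic SNPs, allele-copy based):

* ``Ho`` — fraction of genotyped individuals that are heterozygous.
* ``pi`` within a population — mean pairwise difference over all unordered
  pairs of allele copies: with n copies and j alt copies,
  ``pi = 2 j (n - j) / (n (n - 1))`` (the unbiased n/(n-1) form).
* ``pi`` between two populations (d_xy) — probability that one copy drawn
  from each population differs: ``p1 (1 - p2) + p2 (1 - p1)``.

Genome-wide summaries are unweighted means over loci (not means of
chromosome means); per-chromosome summaries are unweighted means over the
loci on that chromosome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Ho for one locus from a 1-D vector of genotype codes."""
    calls = np.asarray(calls)
    genotyped = calls != MISSING
    n = int(genotyped.sum())
    if n == 0:
        raise ValueError("no genotyped samples at locus")
    return float((calls == 1).sum() / n)


def pi_within(calls: np.ndarray) -> float:
    """Within-population nucleotide diversity for one locus."""
    calls = np.asarray(calls)
    genotyped = calls != MISSING
    n_ind = int(genotyped.sum())
    if n_ind < 2:
        raise ValueError("pi requires >= 2 genotyped samples")
    n = 2 * n_ind
    j = int(calls[genotyped].sum())
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def pi_between(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Between-population diversity (d_xy) for one locus."""
    p = []
    for calls in (calls_a, calls_b):
        calls = np.asarray(calls)
        genotyped = calls != MISSING
        n = int(genotyped.sum())
        if n == 0:
            raise ValueError("each population needs >= 1 genotyped sample")
        p.append(calls[genotyped].sum() / (2.0 * n))
    p1, p2 = p
    return float(p1 * (1.0 - p2) + p2 * (1.0 - p1))


# -- vectorized tables -----------------------------------------------------


def locus_diversity_table(
    gm: GenotypeMatrix, populations: list[str] | None = None
) -> pd.DataFrame:
    """Per-locus Ho, pi-within per population and d_xy per population pair.

    Loci where a population has no genotyped individual (Ho) or fewer than
    two (pi) get NaN for that population's columns. Columns are
    ``ho_<pop>``, ``pi_<pop>``, ``n_<pop>`` and ``dxy_<popA>__<popB>``.
    """
    pops = populations if populations is not None else gm.population_labels
    out = gm.loci[["chrom", "pos"]].copy()
    freqs: dict[str, np.ndarray] = {}
    for pop in pops:
        counts = gm.genotype_counts(pop)
        n_ind = counts.sum(axis=1)
        j = counts[:, 1] + 2 * counts[:, 2]
        n = 2.0 * n_ind
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n_ind > 0, counts[:, 1] / n_ind, np.nan)
            pi = np.where(n_ind >= 2, 2.0 * j * (n - j) / (n * (n - 1.0)), np.nan)
            freqs[pop] = np.where(n_ind > 0, j / n, np.nan)
        out[f"ho_{pop}"] = ho
        out[f"pi_{pop}"] = pi
        out[f"n_{pop}"] = n_ind
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            p1, p2 = freqs[a], freqs[b]
            out[f"dxy_{a}__{b}"] = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return out


def chromosome_means(
    diversity: pd.DataFrame, populations: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome and genome-wide unweighted means of Ho and pi.

    Returns
    -------
    (per_chromosome, genome_wide)
        ``per_chromosome``: one row per (chromosome, population) with
        ``mean_ho``, ``mean_pi``, ``n_loci``. ``genome_wide``: one row per
        population, means taken over all loci.
    """
    chrom_rows = []
    genome_rows = []
    for pop in populations:
        ho = diversity[f"ho_{pop}"]
        pi = diversity[f"pi_{pop}"]
        grouped = diversity.assign(_ho=ho, _pi=pi).groupby("chrom", sort=True)
        for chrom, g in grouped:
            chrom_rows.append(
                {
                    "chrom": chrom,
                    "population": pop,
                    "mean_ho": g["_ho"].mean(),
                    "mean_pi": g["_pi"].mean(),
                    "n_loci": int(g["_ho"].notna().sum()),
                }
            )
        genome_rows.append(
            {
                "population": pop,
                "mean_ho": ho.mean(),
                "mean_pi": pi.mean(),
                "n_loci": int(ho.notna().sum()),
            }
        )
    return pd.DataFrame(chrom_rows), pd.DataFrame(genome_rows)


def percent_reduction(ho_focal: float, ho_reference: float) -> float:
    """Percent diversity reduction of a focal population vs a reference.

    Returns the full-precision value ``100 * (1 - focal / reference)``;
    round to the nearest integer for headline reporting.
    """
    if ho_reference <= 0:
        raise ValueError("reference diversity must be positive")
    return 100.0 * (1.0 - ho_focal / ho_reference)
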