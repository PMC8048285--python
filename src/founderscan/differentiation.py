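"""Pairwise genetic differentiation and outlier detection.

Per-locus F_ST is the Weir & Cockerham (1984) two-population estimator
theta-hat = a / (a + b + c), built from the among-population (a),
among-individual-within-population (b) and within-individual (c) variance
components. Negative estimates are retained — clamping them would bias both
the genome-wide mean and the standard deviation that the Z-score outlier
rule (Z(F_ST) > 5, strict) depends on.

The module also provides the absolute allele-frequency difference (AFD) and
its Z-score as a cross-validation statistic, fixed non-overlapping window
means for plotting-style summaries, a kNN/medoid scan over the per-SNP
vector of pairwise F_ST values (positive delta-F_ST entries mark the
local-adaptation direction), and local diversity profiles around outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

from .matrix import GenotypeMatrix

# -- Weir & Cockerham (1984) per-locus theta-hat ---------------------------


def weir_cockerham_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components (a, b, c) for two populations, vectorized.

    Parameters
    ----------
    n
        (2, n_loci) genotyped diploid counts per population.
    p
        (2, n_loci) alt-allele sample frequencies.
    h
        (2, n_loci) observed heterozygote *proportions*.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = 2.0
    n_bar = n.mean(axis=0)
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
    c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Per-locus theta-hat from genotype counts of two populations.

    ``counts_*`` are (n_loci, 3) arrays of (hom-ref, het, hom-alt) counts.
    Loci monomorphic across the pooled pair, with fewer than two genotyped
    diploids in either population, or with a zero total variance get NaN
    (undefined, excluded from downstream summaries).
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    n = np.stack([counts_a.sum(axis=1), counts_b.sum(axis=1)])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.stack(
            [
                (counts_a[:, 1] + 2 * counts_a[:, 2]) / (2 * n[0]),
                (counts_b[:, 1] + 2 * counts_b[:, 2]) / (2 * n[1]),
            ]
        )
        h = np.stack([counts_a[:, 1] / n[0], counts_b[:, 1] / n[1]])
    a, b, c = weir_cockerham_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        p_pool = (n * p).sum(axis=0) / n.sum(axis=0)
    pooled_poly = (p_pool > 0) & (p_pool < 1)
    valid = (n >= 2).all(axis=0) & pooled_poly & (np.abs(denom) > 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(valid, a / denom, np.nan)
    return theta


def pairwise_fst_table(
    gm: GenotypeMatrix, pop_a: str, pop_b: str, loci_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-locus theta-hat and AFD for one population pair.

    Returns a DataFrame aligned to the (masked) loci with columns
    ``chrom, pos, fst, afd, p_<a>, p_<b>``; loci with undefined theta-hat
    carry NaN and are excluded by callers from means and Z-scores.
    """
    counts_a = gm.genotype_counts(pop_a)
    counts_b = gm.genotype_counts(pop_b)
    if loci_mask is not None:
        idx = np.flatnonzero(loci_mask)
    else:
        idx = np.arange(gm.n_loci)
    fst = weir_cockerham_fst(counts_a[idx], counts_b[idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        na = counts_a[idx].sum(axis=1)
        nb = counts_b[idx].sum(axis=1)
        pa = (counts_a[idx, 1] + 2 * counts_a[idx, 2]) / (2.0 * na)
        pb = (counts_b[idx, 1] + 2 * counts_b[idx, 2]) / (2.0 * nb)
    out = gm.loci.iloc[idx][["chrom", "pos"]].reset_index(drop=True)
    out["fst"] = fst
    out["afd"] = np.abs(pa - pb)
    out[f"p_{pop_a}"] = pa
    out[f"p_{pop_b}"] = pb
    return out


def mean_fst(fst_values: np.ndarray) -> float:
    """Unweighted mean of per-locus theta-hat over defined loci."""
    fst_values = np.asarray(fst_values, dtype=float)
    defined = fst_values[~np.isnan(fst_values)]
    if defined.size == 0:
        raise ValueError("no defined F_ST values to average")
    return float(defined.mean())


def ratio_of_sums_fst(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham estimate sum(a)/sum(a+b+c) (optional form)."""
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    n = np.stack([counts_a.sum(axis=1), counts_b.sum(axis=1)])
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.stack(
            [
                (counts_a[:, 1] + 2 * counts_a[:, 2]) / (2 * n[0]),
                (counts_b[:, 1] + 2 * counts_b[:, 2]) / (2 * n[1]),
            ]
        )
        h = np.stack([counts_a[:, 1] / n[0], counts_b[:, 1] / n[1]])
    a, b, c = weir_cockerham_components(n, p, h)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        raise ValueError("zero total variance")
    return float(a[ok].sum() / denom)


# -- Z-scores and outliers -------------------------------------------------


def z_transform(values: np.ndarray) -> np.ndarray:
    """Standardize with the sample (n-1) SD; NaNs pass through.

    Raises on fewer than two defined values or zero variance.
    """
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    if defined.size < 2:
        raise ValueError("z_transform needs >= 2 defined values")
    sd = defined.std(ddof=1)
    if sd == 0:
        raise ValueError("z_transform undefined for zero-variance input")
    return (values - defined.mean()) / sd


def detect_outliers(z_values: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """Indices with z strictly greater than the threshold (NaNs never flag)."""
    z_values = np.asarray(z_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.flatnonzero(z_values > threshold)


def allele_frequency_difference(p1: float | np.ndarray, p2: float | np.ndarray):
    """AFD: absolute alt-allele frequency difference between two populations."""
    return np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))


def fst_afd_concordance(
    fst: np.ndarray, afd: np.ndarray, z_threshold: float = 5.0
) -> dict:
    """Correlations between per-locus F_ST and AFD plus outlier-set overlap."""
    fst = np.asarray(fst, dtype=float)
    afd = np.asarray(afd, dtype=float)
    ok = ~np.isnan(fst) & ~np.isnan(afd)
    pearson = pearsonr(fst[ok], afd[ok]).statistic
    spearman = spearmanr(fst[ok], afd[ok]).statistic
    z_fst = np.full(fst.shape, np.nan)
    z_afd = np.full(afd.shape, np.nan)
    z_fst[ok] = z_transform(fst[ok])
    z_afd[ok] = z_transform(afd[ok])
    set_fst = set(detect_outliers(z_fst, z_threshold).tolist())
    set_afd = set(detect_outliers(z_afd, z_threshold).tolist())
    return {
        "pearson_r": float(pearson),
        "spearman_rho": float(spearman),
        "n_outlier_fst": len(set_fst),
        "n_outlier_afd": len(set_afd),
        "n_outlier_both": len(set_fst & set_afd),
        "outliers_fst": sorted(set_fst),
        "outliers_afd": sorted(set_afd),
    }


# -- windows ---------------------------------------------------------------


def window_mean_fst(
    chrom: np.ndarray, pos: np.ndarray, fst: np.ndarray, window_bp: int = 100_000
) -> pd.DataFrame:
    """Mean theta-hat in fixed, non-overlapping 1-based windows.

    Window k on a chromosome spans [k*w + 1, (k+1)*w]; windows containing no
    SNP with a defined theta-hat are omitted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "fst": fst}).dropna(subset=["fst"])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_fst", "n_snps"])
    df["win"] = (df["pos"].astype(np.int64) - 1) // window_bp
    grouped = (
        df.groupby(["chrom", "win"], sort=True)["fst"]
        .agg(mean_fst="mean", n_snps="size")
        .reset_index()
    )
    grouped["start"] = grouped["win"] * window_bp + 1
    grouped["end"] = (grouped["win"] + 1) * window_bp
    grouped["n_snps"] = grouped["n_snps"].astype(int)
    return grouped[["chrom", "start", "end", "mean_fst", "n_snps"]]


# -- kNN / medoid scan -----------------------------------------------------


@dataclass
class KnnScanResult:
    """Result of the medoid-centred kNN scan in pairwise-F_ST space."""

    vectors: np.ndarray  # (n_snps, n_comparisons)
    medoid_index: int
    medoid: np.ndarray
    delta_fst: np.ndarray  # vectors - medoid
    knn_distance: np.ndarray  # distance to k-th nearest neighbor
    outlier_flag: np.ndarray  # bool
    k: int
    quantile: float
    threshold: float
    kept_index: np.ndarray  # original SNP indices with complete vectors


def _medoid_index(vectors: np.ndarray, chunk: int = 2048) -> int:
    """Index of the observed vector minimizing summed Euclidean distance."""
    n = len(vectors)
    totals = np.empty(n)
    for start in range(0, n, chunk):
        block = vectors[start : start + chunk]
        totals[start : start + chunk] = cdist(block, vectors).sum(axis=1)
    return int(np.argmin(totals))


def knn_scan(
    vectors: np.ndarray, k: int = 10, quantile: float = 0.999
) -> KnnScanResult:
    """Medoid-centred k-nearest-neighbor outlier scan.

    Each SNP is a point in comparison-space (one pairwise F_ST per axis).
    SNPs with any undefined component are dropped. The medoid is the
    observed vector with minimal summed Euclidean distance to all others;
    delta-F_ST = vector - medoid (positive entries point toward local
    adaptation in that comparison, negative toward reduced divergence). A
    SNP is flagged when its distance to its k-th nearest neighbor exceeds
    the given quantile of all such distances.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    complete = ~np.isnan(vectors).any(axis=1)
    kept = np.flatnonzero(complete)
    v = vectors[kept]
    n = len(v)
    if n == 0:
        raise ValueError("no SNPs with complete F_ST vectors")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of SNPs ({n})")
    med_idx = _medoid_index(v)
    medoid = v[med_idx]
    delta = v - medoid
    tree = cKDTree(v)
    # k+1 because the query point itself is its own nearest neighbor
    dist, _ = tree.query(v, k=k + 1)
    knn_distance = dist[:, k]
    threshold = float(np.quantile(knn_distance, quantile))
    flags = knn_distance > threshold
    return KnnScanResult(
        v, med_idx, medoid, delta, knn_distance, flags, k, quantile, threshold, kept
    )


# -- local diversity profiles ----------------------------------------------


@dataclass
class LocalDiversityProfile:
    """Diversity and differentiation at an outlier vs its flanking window."""

    chrom: str
    pos: int
    flank_bp: int
    outlier_fst: float
    window_mean_fst: float
    outlier_dxy: float
    window_mean_dxy: float
    outlier_pi: dict[str, float]
    window_mean_pi: dict[str, float]
    n_snps_window: int
    complete: bool
    fst_elevated: bool
    dxy_elevated: bool
    pi_depressed: dict[str, bool]


def local_diversity_profile(
    outlier_chrom: str,
    outlier_pos: int,
    table: pd.DataFrame,
    fst_col: str,
    dxy_col: str,
    pi_cols: list[str],
    flank_bp: int = 50_000,
) -> LocalDiversityProfile:
    """Compare an outlier SNP's statistics to its +-flank_bp window means.

    ``table`` must hold one row per SNP with ``chrom``/``pos`` plus the
    named statistic columns (a merged diversity + differentiation table).
    Window means include every SNP within the window (outlier included,
    single fixed window — no sliding). The profile is marked incomplete when
    the window contains no SNP besides the outlier itself.
    """
    here = table[(table["chrom"] == outlier_chrom) & (table["pos"] == outlier_pos)]
    if here.empty:
        raise KeyError(f"outlier {outlier_chrom}:{outlier_pos} not present in table")
    row = here.iloc[0]
    window = table[
        (table["chrom"] == outlier_chrom)
        & (table["pos"] >= outlier_pos - flank_bp)
        & (table["pos"] <= outlier_pos + flank_bp)
    ]
    n_window = int(len(window))
    complete = n_window > 1
    wmean = window.mean(numeric_only=True)
    out_pi = {c: float(row[c]) for c in pi_cols}
    win_pi = {c: float(wmean[c]) for c in pi_cols}
    return LocalDiversityProfile(
        chrom=outlier_chrom,
        pos=int(outlier_pos),
        flank_bp=int(flank_bp),
        outlier_fst=float(row[fst_col]),
        window_mean_fst=float(wmean[fst_col]),
        outlier_dxy=float(row[dxy_col]),
        window_mean_dxy=float(wmean[dxy_col]),
        outlier_pi=out_pi,
        window_mean_pi=win_pi,
        n_snps_window=n_window,
        complete=complete,
        fst_elevated=bool(complete and row[fst_col] > wmean[fst_col]),
        dxy_elevated=bool(complete and row[dxy_col] > wmean[dxy_col]),
        pi_depressed={c: bool(complete and row[c] < wmean[c]) for c in pi_cols},
    )
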