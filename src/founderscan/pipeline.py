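"""End-to-end orchestration: filters -> diversity -> differentiation ->
annotation, per population pair and for the whole dataset.

All tabular outputs are delimited text written with fixed float formatting,
so identical inputs + config + seed give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, classify_snps, read_gene_models
from .config import AnalysisConfig
from .differentiation import (
    detect_outliers,
    knn_scan,
    local_diversity_profile,
    mean_fst,
    pairwise_fst_table,
    window_mean_fst,
    z_transform,
)
from .diversity import chromosome_means, locus_diversity_table, percent_reduction
from .filters import HweFilterResult, apply_standard_filters, filter_hwe, filter_minor_allele_frequency
from .io import read_population_table, read_vcf
from .matrix import MISSING, FilterReport, GenotypeMatrix
from .randomization import RandomizationResult, randomization_test

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class ComparisonReport:
    """Everything computed for one ordered population pair."""

    comparison: tuple[str, str]
    n_shared_loci: int
    n_fst_defined: int
    mean_fst: float
    table: pd.DataFrame  # per-locus: chrom pos fst z_fst afd z_afd is_outlier ...
    n_outlier_snps: int
    outlier_genes: pd.DataFrame  # gene_id, n_outlier_snps, category
    n_outlier_genes: int
    n_genes_with_nonsynonymous: int
    effects: pd.DataFrame
    windows: pd.DataFrame
    randomization: RandomizationResult
    profiles: pd.DataFrame

    def audit(self) -> None:
        """Check that every headline count recounts from its table."""
        assert self.n_shared_loci == len(self.table)
        assert self.n_outlier_snps == int(self.table["is_outlier"].sum())
        assert self.n_outlier_genes == len(self.outlier_genes)
        assert self.n_outlier_genes <= self.n_outlier_snps
        n_nonsyn = int((self.outlier_genes["category"] == "nonsynonymous").sum()) if len(self.outlier_genes) else 0
        assert self.n_genes_with_nonsynonymous == n_nonsyn


def run_comparison(
    gm: GenotypeMatrix,
    hwe_result: HweFilterResult,
    pair: tuple[str, str],
    genes: list[GeneModel] | None,
    config: AnalysisConfig,
    diversity: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Per-locus F_ST/AFD scan with outlier calling for one population pair.

    Assumes the standard filter chain has already run; the shared locus set
    is the intersection of the two populations' HWE-kept sets.
    """
    pop_a, pop_b = pair
    shared = hwe_result.shared_loci(pop_a, pop_b)
    if not shared.any():
        raise ValueError(f"empty shared locus set for {pop_a} vs {pop_b}")
    table = pairwise_fst_table(gm, pop_a, pop_b, shared)

    fst = table["fst"].to_numpy()
    defined = ~np.isnan(fst)
    z_fst = np.full(len(table), np.nan)
    z_fst[defined] = z_transform(fst[defined])
    table["z_fst"] = z_fst
    afd = table["afd"].to_numpy()
    z_afd = np.full(len(table), np.nan)
    z_afd[defined] = z_transform(afd[defined])
    table["z_afd"] = z_afd
    outlier_idx = detect_outliers(z_fst, config.z_threshold)
    table["is_outlier"] = False
    table.loc[outlier_idx, "is_outlier"] = True

    outliers = table[table["is_outlier"]]
    if genes is not None and len(outliers):
        snp_meta = gm.loci.merge(outliers[["chrom", "pos"]], on=["chrom", "pos"])
        effects = classify_snps(snp_meta, genes, config.min_orf_len)
        genic = effects[effects["gene_id"] != ""]
        gene_rows = []
        for gene_id, grp in genic.groupby("gene_id", sort=True):
            category = (
                "nonsynonymous"
                if (grp["effect"] == "nonsynonymous").any()
                else "synonymous_or_other"
            )
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "n_outlier_snps": int(len(grp)),
                    "category": category,
                }
            )
        outlier_genes = pd.DataFrame(
            gene_rows, columns=["gene_id", "n_outlier_snps", "category"]
        )
    else:
        effects = pd.DataFrame()
        outlier_genes = pd.DataFrame(columns=["gene_id", "n_outlier_snps", "category"])

    windows = window_mean_fst(
        table["chrom"].to_numpy(), table["pos"].to_numpy(), fst, config.window_bp
    )

    # randomization test on per-chromosome (or per-SNP) mean heterozygosity
    if diversity is None:
        diversity = locus_diversity_table(gm, [pop_a, pop_b])
    if config.randomization_unit == "chromosome":
        chrom_means, _ = chromosome_means(diversity, [pop_a, pop_b])
        va = chrom_means[chrom_means["population"] == pop_a]["mean_ho"].to_numpy()
        vb = chrom_means[chrom_means["population"] == pop_b]["mean_ho"].to_numpy()
    else:
        va = diversity[f"ho_{pop_a}"].dropna().to_numpy()
        vb = diversity[f"ho_{pop_b}"].dropna().to_numpy()
    rand = randomization_test(va, vb, config.n_permutations, seed=config.seed)

    # local diversity profiles around each outlier
    merged = table.merge(diversity, on=["chrom", "pos"], how="left")
    pi_cols = [f"pi_{pop_a}", f"pi_{pop_b}"]
    dxy_col = next(
        (c for c in (f"dxy_{pop_a}__{pop_b}", f"dxy_{pop_b}__{pop_a}") if c in merged),
        None,
    )
    profile_rows = []
    for _, row in outliers.iterrows():
        prof = local_diversity_profile(
            row["chrom"], int(row["pos"]), merged, "fst", dxy_col, pi_cols, config.flank_bp
        )
        profile_rows.append(
            {
                "chrom": prof.chrom,
                "pos": prof.pos,
                "fst": prof.outlier_fst,
                "window_mean_fst": prof.window_mean_fst,
                "dxy": prof.outlier_dxy,
                "window_mean_dxy": prof.window_mean_dxy,
                "n_snps_window": prof.n_snps_window,
                "complete": prof.complete,
                "fst_elevated": prof.fst_elevated,
                "dxy_elevated": prof.dxy_elevated,
                "pi_depressed_all": all(prof.pi_depressed.values()),
            }
        )
    profiles = pd.DataFrame(
        profile_rows,
        columns=[
            "chrom",
            "pos",
            "fst",
            "window_mean_fst",
            "dxy",
            "window_mean_dxy",
            "n_snps_window",
            "complete",
            "fst_elevated",
            "dxy_elevated",
            "pi_depressed_all",
        ],
    )

    report = ComparisonReport(
        comparison=pair,
        n_shared_loci=int(shared.sum()),
        n_fst_defined=int(defined.sum()),
        mean_fst=mean_fst(fst),
        table=table,
        n_outlier_snps=int(len(outlier_idx)),
        outlier_genes=outlier_genes,
        n_outlier_genes=int(len(outlier_genes)),
        n_genes_with_nonsynonymous=int(
            (outlier_genes["category"] == "nonsynonymous").sum()
        ) if len(outlier_genes) else 0,
        effects=effects,
        windows=windows,
        randomization=rand,
        profiles=profiles,
    )
    report.audit()
    return report


@dataclass
class AnalysisBundle:
    """Full-dataset results: diversity summaries, all pairwise reports, kNN."""

    genotypes: GenotypeMatrix
    filter_reports: list[FilterReport]
    hwe: HweFilterResult
    diversity: pd.DataFrame
    chromosome_summary: pd.DataFrame
    genome_summary: pd.DataFrame
    percent_reductions: dict[str, float]
    comparisons: dict[tuple[str, str], ComparisonReport]
    knn: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_dataset(
    gm: GenotypeMatrix,
    genes: list[GeneModel] | None,
    config: AnalysisConfig,
) -> AnalysisBundle:
    """Filter chain + diversity + all pairwise comparisons + kNN scan."""
    pops = gm.population_labels
    if len(pops) < 2:
        raise ValueError("at least two populations required")

    min_depth = config.min_depth if gm.depth is not None else None
    count_mode = config.maf_mode != "frequency"
    filtered, reports = apply_standard_filters(
        gm,
        min_depth=min_depth,
        max_missing_fraction=config.max_sample_missing,
        min_call_rate=config.min_call_rate,
        min_minor_copies=config.min_minor_copies if count_mode else 0,
    )
    if not count_mode:
        filtered = filter_minor_allele_frequency(filtered, config.min_maf)
    for rep in reports:
        logger.info(
            "%s: samples %d -> %d, loci %d -> %d",
            rep.step,
            rep.n_samples_in,
            rep.n_samples_out,
            rep.n_loci_in,
            rep.n_loci_out,
        )

    pops = filtered.population_labels
    hwe_result = filter_hwe(filtered, config.hwe_alpha, pops, config.hwe_ordering)
    for pop in pops:
        logger.info(
            "HWE filter (%s): %d of %d loci kept", pop, int(hwe_result.kept[pop].sum()), filtered.n_loci
        )

    diversity = locus_diversity_table(filtered, pops)
    chrom_summary, genome_summary = chromosome_means(diversity, pops)

    ref_pop = config.reference_population or pops[0]
    ref_ho = float(
        genome_summary.loc[genome_summary["population"] == ref_pop, "mean_ho"].iloc[0]
    )
    reductions = {}
    for pop in pops:
        if pop == ref_pop:
            continue
        ho = float(
            genome_summary.loc[genome_summary["population"] == pop, "mean_ho"].iloc[0]
        )
        reductions[pop] = percent_reduction(ho, ref_ho)

    comparisons: dict[tuple[str, str], ComparisonReport] = {}
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            comparisons[(a, b)] = run_comparison(
                filtered, hwe_result, (a, b), genes, config, diversity
            )

    # kNN scan across the per-SNP vector of all pairwise F_ST values
    knn_table = pd.DataFrame()
    if len(comparisons) >= 2:
        pair_names = list(comparisons)
        base = filtered.loci[["chrom", "pos"]]
        vec = pd.DataFrame(index=pd.MultiIndex.from_frame(base))
        for pair in pair_names:
            t = comparisons[pair].table.set_index(["chrom", "pos"])["fst"]
            vec[f"fst_{pair[0]}__{pair[1]}"] = t
        vectors = vec.to_numpy()
        complete = ~np.isnan(vectors).any(axis=1)
        if complete.sum() > config.knn_k:
            scan = knn_scan(vectors, config.knn_k, config.knn_quantile)
            knn_table = vec.iloc[scan.kept_index].reset_index()
            for j, pair in enumerate(pair_names):
                knn_table[f"delta_fst_{pair[0]}__{pair[1]}"] = scan.delta_fst[:, j]
            knn_table["knn_distance"] = scan.knn_distance
            knn_table["is_outlier"] = scan.outlier_flag

    return AnalysisBundle(
        genotypes=filtered,
        filter_reports=reports,
        hwe=hwe_result,
        diversity=diversity,
        chromosome_summary=chrom_summary,
        genome_summary=genome_summary,
        percent_reductions=reductions,
        comparisons=comparisons,
        knn=knn_table,
    )


def run_full_analysis(
    vcf_path: str | Path,
    population_table: str | Path,
    gff3_path: str | Path | None,
    fasta_path: str | Path | None,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> AnalysisBundle:
    """Load inputs, run the whole analysis and write the report bundle."""
    gm, n_skipped = read_vcf(vcf_path, read_population_table(population_table))
    logger.info("loaded %d samples x %d loci (%d records skipped)", gm.n_samples, gm.n_loci, n_skipped)
    genes = None
    if gff3_path is not None and fasta_path is not None:
        genes = read_gene_models(gff3_path, fasta_path)
    bundle = analyze_dataset(gm, genes, config)
    write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    """Write all tables plus a machine-readable JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT)

    dump(bundle.diversity, "diversity_per_locus.tsv")
    dump(bundle.chromosome_summary, "diversity_per_chromosome.tsv")
    dump(bundle.genome_summary, "diversity_genome.tsv")
    dump(pd.DataFrame([r.as_row() for r in bundle.filter_reports]), "filter_log.tsv")
    if len(bundle.knn):
        dump(bundle.knn, "knn_scan.tsv")

    summary: dict = {
        "percent_reductions": {k: round(v, 6) for k, v in sorted(bundle.percent_reductions.items())},
        "populations": bundle.genotypes.population_labels,
        "n_samples": bundle.genotypes.n_samples,
        "n_loci_after_filters": bundle.genotypes.n_loci,
        "comparisons": {},
    }
    for (a, b), rep in bundle.comparisons.items():
        tag = f"{a}__{b}"
        dump(rep.table, f"differentiation_{tag}.tsv")
        dump(rep.windows, f"windows_{tag}.tsv")
        if len(rep.effects):
            dump(rep.effects, f"effects_{tag}.tsv")
        dump(rep.outlier_genes, f"outlier_genes_{tag}.tsv")
        if len(rep.profiles):
            dump(rep.profiles, f"profiles_{tag}.tsv")
        summary["comparisons"][tag] = {
            "n_shared_loci": rep.n_shared_loci,
            "n_fst_defined": rep.n_fst_defined,
            "mean_fst": round(rep.mean_fst, 6),
            "n_outlier_snps": rep.n_outlier_snps,
            "n_outlier_genes": rep.n_outlier_genes,
            "n_genes_with_nonsynonymous": rep.n_genes_with_nonsynonymous,
            "randomization_p": rep.randomization.p_string,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def tissue_concordance(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix
) -> tuple[pd.DataFrame, float]:
    """Genotype concordance between two calls of the same individuals.

    Loci are matched on (chrom, pos); per shared sample, the concordance is
    the fraction of loci non-missing in both matrices with identical
    genotype codes. Returns (per-sample table, overall fraction).
    """
    shared_samples = [s for s in gm_a.samples if s in set(gm_b.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between the two matrices")
    key_a = pd.MultiIndex.from_frame(gm_a.loci[["chrom", "pos"]])
    key_b = pd.MultiIndex.from_frame(gm_b.loci[["chrom", "pos"]])
    common = key_a.intersection(key_b)
    ia = key_a.get_indexer(common)
    ib = key_b.get_indexer(common)
    rows = []
    total_match = 0
    total_n = 0
    for s in shared_samples:
        ra = gm_a.calls[gm_a.samples.index(s)][ia]
        rb = gm_b.calls[gm_b.samples.index(s)][ib]
        both = (ra != MISSING) & (rb != MISSING)
        n = int(both.sum())
        match = int((ra[both] == rb[both]).sum())
        rows.append(
            {
                "sample": s,
                "n_compared": n,
                "n_identical": match,
                "concordance": match / n if n else np.nan,
            }
        )
        total_match += match
        total_n += n
    overall = total_match / total_n if total_n else float("nan")
    return pd.DataFrame(rows), overall
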