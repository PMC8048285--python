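"""Founder-effect dataset generator.

Emulates the downstream genotype structure of a three-population
colonization scenario: one high-diversity source population and two derived
populations, each founded by a small number of diploids and drifting for a
fixed number of Wright-Fisher generations at the founder size. SNPs are
clustered inside gene intervals laid out along many chromosomes (the
signature of transcriptome-derived genotypes), genotypes are drawn under
Hardy-Weinberg proportions from the final allele frequencies, per-genotype
read depths follow a negative-binomial law, and a small set of CDS loci per
derived population is deterministically shifted toward fixation to mimic
divergent selection.

Modeling notes:

* Ancestral alt-allele frequencies are Beta(0.5, 0.5) (U-shaped, neutral-SFS
  flavored), truncated so the expected minor-allele count in the source
  sample is at least one.
* The founding binomial draw counts as the first of ``generations_drift``
  Wright-Fisher generations, so expected heterozygosity decays exactly as
  H_t = H_0 (1 - 1/(2N))^t with N = founder_size.
* Selection is a post-drift frequency shift (direct control of effect size),
  pushed toward fixation of the allele that is minor in the source, and
  clamped to [0, 1]; the realized shift is recorded in the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .annotation import GeneModel, revcomp
from .io import write_population_table, write_vcf
from .matrix import MISSING, GenotypeMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Scenario parameters; defaults mirror a three-population RNA-seq panel
    (14 source + 15/12 derived diploids, tens of thousands of genic SNPs)."""

    n_chromosomes: int = 20
    chromosome_length_bp: int = 1_000_000
    n_genes: int = 1_000
    snps_per_gene_mean: float = 50.0
    ancestral_n_loci: int = 50_000
    source_sample_size: int = 14
    derived_sample_sizes: tuple[int, ...] = (15, 12)
    founder_size: int = 50
    generations_drift: int = 30
    n_selected_loci: int = 0
    selection_target_freq_shift: float = 0.9
    selection_shared_targets: bool = False  # plant the SAME loci in every derived pop
    mean_depth: float = 20.0
    depth_dispersion: float = 3.0
    missing_base_rate: float = 0.01
    seed: int = 0
    population_names: tuple[str, ...] = ("source", "derived_a", "derived_b")

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_genes": self.n_genes,
            "ancestral_n_loci": self.ancestral_n_loci,
            "source_sample_size": self.source_sample_size,
            "generations_drift": self.generations_drift,
            "n_selected_loci": self.n_selected_loci,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.ancestral_n_loci == 0:
            raise ValueError("refusing to simulate zero loci")
        if self.source_sample_size == 0 or any(n == 0 for n in self.derived_sample_sizes):
            raise ValueError("refusing to simulate a population with zero samples")
        if self.founder_size < 1:
            raise ValueError("founder_size must be >= 1")
        for name, value in (
            ("selection_target_freq_shift", self.selection_target_freq_shift),
            ("missing_base_rate", self.missing_base_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.derived_sample_sizes) + 1 != len(self.population_names):
            raise ValueError("population_names must name source + each derived population")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    genes: list[GeneModel]
    reference: dict[str, str]
    truth: pd.DataFrame
    config: SimulationConfig
    allele_frequencies: pd.DataFrame = field(default_factory=pd.DataFrame)


# -- gene structure --------------------------------------------------------


def _transcript_to_genomic(
    exons0: list[tuple[int, int]], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval [t0, t1) to genomic intervals.

    ``exons0`` are 0-based half-open genomic exons in genomic order; the
    transcript traverses them 5'->3' (reverse order for minus strand).
    Returned intervals are 0-based half-open, in genomic order.
    """
    ordered = exons0 if strand == "+" else list(reversed(exons0))
    out = []
    off = 0
    for s, e in ordered:
        length = e - s
        a, b = max(t0, off), min(t1, off + length)
        if a < b:
            if strand == "+":
                out.append((s + (a - off), s + (b - off)))
            else:
                out.append((e - (b - off), e - (a - off)))
        off += length
    return sorted(out)


def _build_gene(
    rng: np.random.Generator, chrom: str, slot_start: int, slot_len: int, gene_id: str
) -> GeneModel:
    n_exons = int(rng.integers(1, 5))
    exon_lens = rng.integers(150, 600, n_exons)
    intron_lens = rng.integers(80, 400, max(n_exons - 1, 0))
    total = int(exon_lens.sum() + intron_lens.sum())
    if total > slot_len - 2:
        n_exons = 1
        exon_lens = np.array([min(450, slot_len - 2)])
        intron_lens = np.array([], dtype=int)
        total = int(exon_lens[0])
    gstart0 = slot_start + int(rng.integers(0, max(slot_len - total, 1)))

    exons0 = []
    cursor = gstart0
    for i in range(n_exons):
        exons0.append((cursor, cursor + int(exon_lens[i])))
        cursor += int(exon_lens[i])
        if i < n_exons - 1:
            cursor += int(intron_lens[i])
    transcript_len = int(exon_lens.sum())

    u5 = int(rng.integers(20, max(21, transcript_len // 6)))
    u3 = int(rng.integers(20, max(21, transcript_len // 6)))
    cds_len = transcript_len - u5 - u3
    cds_len -= cds_len % 3
    if cds_len < 60:
        u5 = min(u5, 20)
        cds_len = transcript_len - u5 - 20
        cds_len -= cds_len % 3
    u3 = transcript_len - u5 - cds_len
    strand = "+" if rng.random() < 0.5 else "-"

    utr5_t = (0, u5)
    cds_t = (u5, u5 + cds_len)
    utr3_t = (u5 + cds_len, transcript_len)

    def to1(intervals0):
        return [(s + 1, e) for s, e in intervals0]

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=gstart0 + 1,
        end=cursor,
        exons=to1(exons0),
        cds=to1(_transcript_to_genomic(exons0, strand, *cds_t)),
        utr5=to1(_transcript_to_genomic(exons0, strand, *utr5_t)),
        utr3=to1(_transcript_to_genomic(exons0, strand, *utr3_t)),
    )


def _layout_genome(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[list[str], list[GeneModel]]:
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    gid = 0
    for chrom in chroms:
        n_here = min(per_chrom, config.n_genes - gid)
        if n_here <= 0:
            break
        slot = config.chromosome_length_bp // n_here
        if slot < 500:
            raise ValueError("chromosome too short for the requested gene count")
        for k in range(n_here):
            gid += 1
            genes.append(_build_gene(rng, chrom, k * slot, slot, f"gene{gid:05d}"))
    return chroms, genes


# -- frequencies and drift -------------------------------------------------


def _ancestral_frequencies(
    rng: np.random.Generator, shape: np.ndarray, source_n: int
) -> np.ndarray:
    """Truncated symmetric-Beta ancestral alt-allele frequencies.

    ``shape`` is a per-locus Beta concentration (0.5 recovers the U-shaped
    neutral-SFS flavored baseline); the truncation keeps the expected
    minor-allele count in the source sample at >= 1. Chromosome-level
    variation in ``shape`` gives chromosomes genuinely different expected
    diversity, as real genomes show.
    """
    shape = np.asarray(shape, dtype=float)
    c = 1.0 / (4.0 * source_n)
    lo = beta_dist.cdf(c, shape, shape)
    hi = beta_dist.cdf(1.0 - c, shape, shape)
    u = rng.uniform(lo, hi)
    return beta_dist.ppf(u, shape, shape)


def _drift(
    rng: np.random.Generator, p: np.ndarray, founder_size: int, generations: int
) -> np.ndarray:
    """Wright-Fisher drift at constant size; the founding draw is generation 1."""
    n_copies = 2 * founder_size
    for _ in range(generations):
        p = rng.binomial(n_copies, p) / n_copies
    return p


# -- main entry ------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full founder-bottleneck dataset from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    chroms, genes = _layout_genome(rng, config)

    # reference sequences
    reference: dict[str, str] = {}
    seq_codes: dict[str, np.ndarray] = {}
    for chrom in chroms:
        codes = rng.integers(0, 4, size=config.chromosome_length_bp)
        seq_codes[chrom] = codes
        reference[chrom] = _BASES[codes].tobytes().decode()
    for gene in genes:
        pieces = [reference[gene.chrom][s - 1 : e] for s, e in gene.cds]
        spliced = "".join(pieces)
        gene.spliced_cds = spliced if gene.strand == "+" else revcomp(spliced)

    # SNP placement: loci clustered within gene spans, Poisson gene weights
    weights = rng.poisson(config.snps_per_gene_mean, size=len(genes)).astype(float)
    if weights.sum() == 0:
        weights[:] = 1.0
    weights /= weights.sum()
    gene_idx = rng.choice(len(genes), size=config.ancestral_n_loci, p=weights)
    gene_start0 = np.array([g.start - 1 for g in genes])
    gene_len = np.array([g.end - g.start + 1 for g in genes])
    pos0 = gene_start0[gene_idx] + (
        rng.random(config.ancestral_n_loci) * gene_len[gene_idx]
    ).astype(np.int64)
    snp = pd.DataFrame(
        {
            "chrom": [genes[i].chrom for i in gene_idx],
            "pos": pos0 + 1,
            "gene_index": gene_idx,
        }
    )
    snp = snp.drop_duplicates(subset=["chrom", "pos"]).sort_values(["chrom", "pos"])
    snp = snp.reset_index(drop=True)
    n_loci = len(snp)

    ref_codes = np.array(
        [seq_codes[c][p - 1] for c, p in zip(snp["chrom"], snp["pos"])], dtype=np.int64
    )
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_loci)) % 4
    snp["ref"] = [chr(_BASES[c]) for c in ref_codes]
    snp["alt"] = [chr(_BASES[c]) for c in alt_codes]

    # allele frequencies; a per-chromosome Beta concentration gives
    # chromosomes distinct expected diversity levels
    chrom_shape = dict(
        zip(chroms, rng.uniform(0.35, 0.9, size=len(chroms)))
    )
    locus_shape = snp["chrom"].map(chrom_shape).to_numpy()
    p_source = _ancestral_frequencies(rng, locus_shape, config.source_sample_size)
    derived_freqs = []
    for _ in config.derived_sample_sizes:
        derived_freqs.append(
            _drift(rng, p_source, config.founder_size, config.generations_drift)
        )

    # planted selection in CDS loci, distinct per derived population
    truth_rows = []
    if config.n_selected_loci > 0:
        in_cds = np.array(
            [
                genes[g].feature_class_at(int(p)) == "CDS"
                for g, p in zip(snp["gene_index"], snp["pos"])
            ]
        )
        cds_pool = np.flatnonzero(in_cds)
        shared = config.selection_shared_targets
        need = config.n_selected_loci * (1 if shared else len(config.derived_sample_sizes))
        if len(cds_pool) < need:
            raise ValueError(
                f"selection requested for {need} CDS loci but only "
                f"{len(cds_pool)} CDS SNPs are available"
            )
        chosen = rng.choice(cds_pool, size=need, replace=False)
        for d, pop in enumerate(config.population_names[1:]):
            if shared:
                sel = chosen
            else:
                sel = chosen[d * config.n_selected_loci : (d + 1) * config.n_selected_loci]
            p = derived_freqs[d]
            direction = np.where(p_source[sel] <= 0.5, 1.0, -1.0)
            before = p[sel].copy()
            p[sel] = np.clip(
                before + direction * config.selection_target_freq_shift, 0.0, 1.0
            )
            for locus, b, a in zip(sel, before, p[sel]):
                truth_rows.append(
                    {
                        "chrom": snp.at[locus, "chrom"],
                        "pos": int(snp.at[locus, "pos"]),
                        "is_selected": True,
                        "target_population": pop,
                        "realized_freq_shift": float(a - b),
                        "p_source": float(p_source[locus]),
                        "p_final": float(a),
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "is_selected",
            "target_population",
            "realized_freq_shift",
            "p_source",
            "p_final",
        ],
    )

    # genotypes under HWE at the final frequencies
    samples: list[str] = []
    populations: dict[str, str] = {}
    blocks = []
    sizes = [config.source_sample_size, *config.derived_sample_sizes]
    freqs = [p_source, *derived_freqs]
    for pop, size, p in zip(config.population_names, sizes, freqs):
        for i in range(size):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            populations[name] = pop
        blocks.append(rng.binomial(2, p, size=(size, n_loci)).astype(np.int8))
    calls = np.vstack(blocks)

    # negative-binomial depth (gamma-poisson mixture) + base missingness
    shape = config.depth_dispersion
    lam = rng.gamma(shape, config.mean_depth / shape, size=calls.shape)
    depth = rng.poisson(lam).astype(np.int32)
    dropped = rng.random(calls.shape) < config.missing_base_rate
    calls[dropped] = MISSING

    loci = snp[["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    gm = GenotypeMatrix(samples, populations, loci, calls, depth)

    freq_table = snp[["chrom", "pos"]].copy()
    freq_table["p_" + config.population_names[0]] = p_source
    for pop, p in zip(config.population_names[1:], derived_freqs):
        freq_table["p_" + pop] = p

    return SimulatedDataset(gm, genes, reference, truth, config, freq_table)


# -- emission --------------------------------------------------------------


def _gff3_attrs(**kwargs: str) -> str:
    return ";".join(f"{k}={v}" for k, v in kwargs.items())


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tfounderscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"{_gff3_attrs(ID=g.gene_id)}\n"
            )
            fh.write(
                f"{g.chrom}\tfounderscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"{_gff3_attrs(ID=tid, Parent=g.gene_id)}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tfounderscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"{_gff3_attrs(ID=f'{tid}.exon{i}', Parent=tid)}\n"
                )
            cds_tx_order = g.cds if g.strand == "+" else list(reversed(g.cds))
            cum = 0
            phases = []
            for s, e in cds_tx_order:
                phases.append((3 - cum % 3) % 3)
                cum += e - s + 1
            phase_of = dict(zip(cds_tx_order, phases))
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tfounderscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t"
                    f"{phase_of[(s, e)]}\t{_gff3_attrs(ID=f'{tid}.cds{i}', Parent=tid)}\n"
                )
            for kind, intervals in (
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for i, (s, e) in enumerate(intervals, 1):
                    fh.write(
                        f"{g.chrom}\tfounderscan\t{kind}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"{_gff3_attrs(ID=f'{tid}.{kind}{i}', Parent=tid)}\n"
                    )


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def emit_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + GFF3 + FASTA + population table + truth table.

    Re-reading the VCF through :func:`founderscan.io.read_vcf` reproduces
    the genotype matrix exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "gff3": out / "annotation.gff3",
        "fasta": out / "reference.fa",
        "populations": out / "populations.tsv",
        "truth": out / "truth.tsv",
    }
    contig_lengths = {c: len(s) for c, s in ds.reference.items()}
    write_vcf(ds.genotypes, paths["vcf"], contig_lengths)
    write_gff3(ds.genes, paths["gff3"])
    write_fasta(ds.reference, paths["fasta"])
    write_population_table(ds.genotypes.populations, paths["populations"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
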