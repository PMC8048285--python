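"""Reading and writing the on-disk formats: VCF 4.2, population tables.

VCF parsing goes through cyvcf2. Only biallelic SNP records are loaded;
multiallelic sites and indels are skipped and counted. Genotypes become
alt-allele dosage codes; any genotype with a missing allele becomes MISSING.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_NUCLEOTIDES = {"A", "C", "G", "T"}


def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, population) delimited table.

    Accepts tab/comma/whitespace delimiters; lines starting with '#' and an
    optional header line named 'sample'/'sample_id' are ignored.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ValueError(f"population table line has <2 fields: {line!r}")
        if parts[0].lower() in ("sample", "sample_id"):
            continue
        mapping[parts[0]] = parts[1]
    if not mapping:
        raise ValueError(f"population table {path} is empty")
    return mapping


def write_population_table(populations: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")


def read_vcf(
    path: str | Path, populations: dict[str, str] | str | Path
) -> tuple[GenotypeMatrix, int]:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF file with GT and, optionally, DP FORMAT fields.
    populations
        sample -> population mapping, or a path to a population table.

    Returns
    -------
    (matrix, n_skipped)
        The matrix, plus the count of records skipped for being
        multiallelic or non-SNP.
    """
    if not isinstance(populations, dict):
        populations = read_population_table(populations)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in populations]
    if unknown:
        raise ValueError(
            f"VCF samples absent from the population table: {', '.join(unknown)}"
        )

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    any_depth = False
    n_skipped = 0

    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or rec.REF not in _NUCLEOTIDES
            or rec.ALT[0] not in _NUCLEOTIDES
        ):
            n_skipped += 1
            continue
        geno = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int16)
        col = geno.sum(axis=1).astype(np.int8)
        col[(geno < 0).any(axis=1)] = MISSING
        call_cols.append(col)

        dp = rec.format("DP")
        if dp is not None:
            any_depth = True
            d = np.asarray(dp, dtype=np.int64).reshape(len(samples))
            d = np.where(d < 0, 0, d)
            depth_cols.append(d.astype(np.int32))
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))

        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])

    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    depth = (
        np.stack(depth_cols, axis=1)
        if (any_depth and depth_cols)
        else None
    )
    gm = GenotypeMatrix(samples, {s: populations[s] for s in samples}, loci, calls, depth)
    return gm, n_skipped


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal, valid VCF 4.2 with GT and DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=founderscan\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in pd.unique(gm.loci["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        has_depth = gm.depth is not None
        for j in range(gm.n_loci):
            row = gm.loci.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
                "GT:DP" if has_depth else "GT",
            ]
            for i in range(gm.n_samples):
                gt = _GT_STRINGS[int(gm.calls[i, j])]
                if has_depth:
                    fields.append(f"{gt}:{int(gm.depth[i, j])}")
                else:
                    fields.append(gt)
            fh.write("\t".join(fields) + "\n")
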