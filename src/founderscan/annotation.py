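"""Gene models, SNP-to-feature mapping, ORF finding and effect calls.

Coordinate conventions (single authority for the whole package):

* Annotation intervals are GFF3-style 1-based inclusive on the genome.
* Spliced CDS sequences are stored in *transcript orientation* (minus-strand
  genes are reverse-complemented), and positions within them are 0-based
  half-open.

A SNP inside the CDS of a gene is classified as synonymous or nonsynonymous
by locating the longest qualifying open reading frame in the spliced CDS,
substituting the alternative allele, translating both ORFs with the standard
genetic code and comparing the peptides (a premature stop counts as
nonsynonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyranges as pr
from Bio.Seq import Seq
from pyfaidx import Fasta

Interval = tuple[int, int]  # 1-based inclusive genomic interval

#: Standard-code initiation codons accepted in "ATG and alternative starts" mode.
ALTERNATIVE_START_CODONS = ("ATG", "GTG", "TTG", "CTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene with its exon/CDS/UTR structure and spliced CDS sequence."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive gene span
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    spliced_cds: str = ""

    def __post_init__(self) -> None:
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(self, name, sorted(getattr(self, name)))
        if self.spliced_cds:
            expected = sum(e - s + 1 for s, e in self.cds)
            if len(self.spliced_cds) != expected:
                raise ValueError(
                    f"{self.gene_id}: spliced CDS length {len(self.spliced_cds)} "
                    f"!= sum of CDS interval lengths {expected}"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def _in_any(self, pos: int, intervals: list[Interval]) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def feature_class_at(self, pos: int) -> str:
        """Most specific feature at a genomic position inside the gene span."""
        if self._in_any(pos, self.cds):
            return "CDS"
        if self._in_any(pos, self.utr5):
            return "5'UTR"
        if self._in_any(pos, self.utr3):
            return "3'UTR"
        if self.contains(pos):
            return "intron"
        raise ValueError(f"position {pos} outside gene {self.gene_id}")

    def cds_offset(self, pos: int) -> int | None:
        """Transcript-oriented 0-based offset of a genomic position in the CDS.

        Returns None when the position is not inside any CDS interval.
        """
        offset = 0
        plus_offset = None
        for s, e in self.cds:  # genomic order
            if s <= pos <= e:
                plus_offset = offset + (pos - s)
                break
            offset += e - s + 1
        if plus_offset is None:
            return None
        if self.strand == "+":
            return plus_offset
        return self.cds_length - 1 - plus_offset

    def transcript_alleles(self, ref: str, alt: str) -> tuple[str, str]:
        """Ref/alt alleles on the transcript strand."""
        if self.strand == "+":
            return ref, alt
        return ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)


# -- loading from GFF3 + FASTA ---------------------------------------------


def read_gene_models(gff3_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Build gene models from a GFF3 annotation and its reference FASTA.

    Features are grouped by gene via the mRNA Parent chain; the spliced CDS
    is extracted from the reference and reverse-complemented into transcript
    orientation for minus-strand genes.
    """
    df = pr.read_gff3(str(gff3_path)).df
    df["Start"] = df["Start"] + 1  # back to 1-based inclusive
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    for _, row in df[df["Feature"] == "gene"].iterrows():
        gid = row["ID"]
        genes[gid] = GeneModel(
            gene_id=gid,
            chrom=str(row["Chromosome"]),
            strand=str(row["Strand"]),
            start=int(row["Start"]),
            end=int(row["End"]),
        )
    for _, row in df[df["Feature"] == "mRNA"].iterrows():
        mrna_to_gene[row["ID"]] = row["Parent"]
    kind_map = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_UTR": "utr5",
        "three_prime_UTR": "utr3",
    }
    for feature, attr in kind_map.items():
        for _, row in df[df["Feature"] == feature].iterrows():
            parent = row["Parent"]
            gid = mrna_to_gene.get(parent, parent)
            if gid in genes:
                getattr(genes[gid], attr).append((int(row["Start"]), int(row["End"])))

    fasta = Fasta(str(fasta_path))
    out = []
    for gene in genes.values():
        gene.exons.sort()
        gene.cds.sort()
        gene.utr5.sort()
        gene.utr3.sort()
        pieces = [str(fasta[gene.chrom][s - 1 : e]).upper() for s, e in gene.cds]
        spliced = "".join(pieces)
        gene.spliced_cds = spliced if gene.strand == "+" else revcomp(spliced)
        out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


# -- SNP-to-feature mapping ------------------------------------------------


def map_snps_to_features(
    snps: pd.DataFrame, genes: list[GeneModel]
) -> pd.DataFrame:
    """Assign each SNP its gene and most specific feature class.

    ``snps`` needs ``chrom`` and ``pos`` columns. SNPs outside every gene
    span map to gene_id '' / class 'intergenic'. A SNP inside overlapping
    genes yields one row per gene with ``ambiguous=True``.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for _, snp in snps.iterrows():
        pos = int(snp["pos"])
        hits = [
            g for g in by_chrom.get(str(snp["chrom"]), []) if g.contains(pos)
        ]
        if not hits:
            rows.append(
                {
                    "chrom": snp["chrom"],
                    "pos": pos,
                    "gene_id": "",
                    "feature_class": "intergenic",
                    "ambiguous": False,
                }
            )
            continue
        for g in hits:
            rows.append(
                {
                    "chrom": snp["chrom"],
                    "pos": pos,
                    "gene_id": g.gene_id,
                    "feature_class": g.feature_class_at(pos),
                    "ambiguous": len(hits) > 1,
                }
            )
    return pd.DataFrame(rows)


# -- ORF finding -----------------------------------------------------------


@dataclass
class OrfCall:
    """An open reading frame within a spliced CDS (transcript orientation)."""

    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive; includes the stop codon when present
    sequence: str
    peptide: str
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


def find_orf(
    spliced_cds: str,
    min_orf_len: int = 30,
    start_codons: tuple[str, ...] = ALTERNATIVE_START_CODONS,
    allow_open_end: bool = True,
) -> OrfCall | None:
    """Longest ORF (>= min_orf_len nt) across the three forward frames.

    A candidate runs from an allowed start codon to the first in-frame stop
    codon (stop included in the ORF span) or, when ``allow_open_end``, to
    the last complete codon of the sequence. Ties on length break to the
    5'-most start. Returns None when no candidate qualifies.
    """
    seq = spliced_cds.upper()
    if any(ch not in "ACGTN" for ch in seq):
        raise ValueError("sequence contains non-nucleotide characters")
    best: tuple[int, int] | None = None  # (start, end)
    for frame in range(3):
        codon_starts = range(frame, len(seq) - 2, 3)
        stops = [i for i in codon_starts if seq[i : i + 3] in STOP_CODONS]
        for i in codon_starts:
            if seq[i : i + 3] not in start_codons:
                continue
            next_stops = [s for s in stops if s >= i]
            if next_stops:
                end = next_stops[0] + 3
            elif allow_open_end:
                end = i + 3 * ((len(seq) - i) // 3)
            else:
                continue
            length = end - i
            if length < min_orf_len:
                continue
            if best is None or length > best[1] - best[0] or (
                length == best[1] - best[0] and i < best[0]
            ):
                best = (i, end)
    if best is None:
        return None
    start, end = best
    orf_seq = seq[start:end]
    translated = str(Seq(orf_seq).translate())
    has_stop = translated.endswith("*")
    peptide = translated[:-1] if has_stop else translated
    return OrfCall(start, end, orf_seq, peptide, has_stop)


# -- effect classification -------------------------------------------------


@dataclass
class EffectClassification:
    chrom: str
    pos: int
    gene_id: str
    feature_class: str
    effect: str  # 'synonymous' | 'nonsynonymous' | 'unclassified'
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    start_loss: bool = False


def classify_effect(
    orf: OrfCall,
    snp_offset: int,
    ref_allele: str,
    alt_allele: str,
    start_codons: tuple[str, ...] = ALTERNATIVE_START_CODONS,
) -> dict:
    """Synonymous/nonsynonymous call for a SNP inside an ORF.

    Parameters
    ----------
    orf
        The chosen ORF of the gene's spliced CDS.
    snp_offset
        0-based SNP position within the spliced CDS (transcript orientation).
    ref_allele, alt_allele
        Single-nucleotide alleles on the *transcript* strand.

    Returns a dict with effect, the affected codons and amino acids, and a
    start-loss flag. Raises KeyError when the SNP lies outside the ORF and
    ValueError when the reference allele disagrees with the ORF sequence
    (a strand or coordinate bug upstream).
    """
    if not orf.start <= snp_offset < orf.end:
        raise KeyError("SNP outside ORF")
    within = snp_offset - orf.start
    if orf.sequence[within] != ref_allele.upper():
        raise ValueError(
            f"reference allele {ref_allele!r} does not match ORF base "
            f"{orf.sequence[within]!r} at offset {snp_offset}"
        )
    alt_seq = orf.sequence[:within] + alt_allele.upper() + orf.sequence[within + 1 :]
    ref_pep = str(Seq(orf.sequence).translate())
    alt_pep = str(Seq(alt_seq).translate())
    codon_index = within // 3
    ref_codon = orf.sequence[3 * codon_index : 3 * codon_index + 3]
    alt_codon = alt_seq[3 * codon_index : 3 * codon_index + 3]
    effect = "synonymous" if ref_pep == alt_pep else "nonsynonymous"
    start_loss = (
        codon_index == 0
        and effect == "synonymous"
        and alt_codon not in start_codons
    )
    return {
        "effect": effect,
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "ref_aa": ref_pep[codon_index] if codon_index < len(ref_pep) else "",
        "alt_aa": alt_pep[codon_index] if codon_index < len(alt_pep) else "",
        "start_loss": start_loss,
    }


def classify_snps(
    snps: pd.DataFrame,
    genes: list[GeneModel],
    min_orf_len: int = 30,
    start_codons: tuple[str, ...] = ALTERNATIVE_START_CODONS,
) -> pd.DataFrame:
    """Full feature-mapping + effect classification for a SNP table.

    ``snps`` needs chrom, pos, ref, alt. Every SNP yields at least one row;
    only CDS SNPs that fall inside their gene's chosen ORF get a
    synonymous/nonsynonymous call, all others are 'unclassified'.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    orf_cache: dict[str, OrfCall | None] = {}
    mapped = map_snps_to_features(snps, genes)
    allele = {
        (row["chrom"], int(row["pos"])): (row["ref"], row["alt"])
        for _, row in snps.iterrows()
    }
    records = []
    for _, row in mapped.iterrows():
        rec = EffectClassification(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            gene_id=row["gene_id"],
            feature_class=row["feature_class"],
            effect="unclassified",
        )
        if row["feature_class"] == "CDS":
            gene = gene_by_id[row["gene_id"]]
            if gene.gene_id not in orf_cache:
                orf_cache[gene.gene_id] = find_orf(
                    gene.spliced_cds, min_orf_len, start_codons
                )
            orf = orf_cache[gene.gene_id]
            offset = gene.cds_offset(rec.pos)
            if orf is not None and offset is not None and orf.start <= offset < orf.end:
                ref, alt = allele[(row["chrom"], rec.pos)]
                t_ref, t_alt = gene.transcript_alleles(ref, alt)
                call = classify_effect(orf, offset, t_ref, t_alt, start_codons)
                rec.effect = call["effect"]
                rec.ref_codon = call["ref_codon"]
                rec.alt_codon = call["alt_codon"]
                rec.ref_aa = call["ref_aa"]
                rec.alt_aa = call["alt_aa"]
                rec.start_loss = call["start_loss"]
        records.append(vars(rec) | {"ambiguous": bool(row["ambiguous"])})
    return pd.DataFrame(records)
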