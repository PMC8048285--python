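"""Gene models, ORF finding and synonymous/nonsynonymous classification."""

import numpy as np
import pandas as pd
import pytest

from founderscan import (
    GeneModel,
    classify_effect,
    classify_snps,
    find_orf,
    map_snps_to_features,
    read_gene_models,
)
from founderscan.annotation import revcomp

from _oracles import classify_by_translation


class TestFindOrf:
    def test_minimal_start_to_stop(self):
        orf = find_orf("ATGAAATAG", min_orf_len=9)
        assert (orf.start, orf.end) == (0, 9)
        assert orf.peptide == "MK"
        assert orf.has_stop

    def test_short_orf_rejected_by_length_floor(self):
        # 27-nt ORF only: below the 30-nt minimum
        seq = "CC" + "ATG" + "GCA" * 7 + "TGA" + "CC"
        assert find_orf(seq, min_orf_len=30, allow_open_end=False) is None
        assert find_orf(seq, min_orf_len=27, allow_open_end=False) is not None

    def test_longest_orf_wins(self):
        # frame 0: 33-nt ORF; frame 1 (offset by 1): 45-nt ORF
        orf33 = "ATG" + "GCA" * 9 + "TAA"
        orf45 = "ATG" + "GTT" * 13 + "TGA"
        seq = orf33 + "C" + orf45
        found = find_orf(seq, min_orf_len=30, allow_open_end=False)
        assert found.end - found.start == 45
        assert found.start == len(orf33) + 1

    def test_alternative_start_codons_accepted(self):
        seq = "GTG" + "AAA" * 10 + "TAA"
        orf = find_orf(seq, min_orf_len=30)
        assert orf is not None and orf.start == 0
        assert find_orf(seq, min_orf_len=30, start_codons=("ATG",)) is None

    def test_open_ended_orf(self):
        seq = "ATG" + "CCA" * 12  # no stop codon
        orf = find_orf(seq, min_orf_len=30, allow_open_end=True)
        assert orf is not None and not orf.has_stop
        assert find_orf(seq, min_orf_len=30, allow_open_end=False) is None

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            find_orf("ATGXXXTAA")


class TestClassifyEffect:
    def _orf(self, seq):
        orf = find_orf(seq, min_orf_len=len(seq) - len(seq) % 3)
        assert orf is not None
        return orf

    def test_third_position_synonymous(self):
        orf = self._orf("ATG" + "GGA" + "AAA" * 8 + "TAA")
        call = classify_effect(orf, 5, "A", "G")  # GGA -> GGG, Gly -> Gly
        assert call["effect"] == "synonymous"
        assert call["ref_aa"] == call["alt_aa"] == "G"

    def test_missense_nonsynonymous(self):
        orf = self._orf("ATG" + "GAT" + "AAA" * 8 + "TAA")
        call = classify_effect(orf, 4, "A", "T")  # GAT -> GTT, Asp -> Val
        assert call["effect"] == "nonsynonymous"
        assert (call["ref_aa"], call["alt_aa"]) == ("D", "V")

    def test_premature_stop_is_nonsynonymous(self):
        orf = self._orf("ATG" + "TGG" + "AAA" * 8 + "TAA")
        call = classify_effect(orf, 5, "G", "A")  # TGG -> TGA, Trp -> stop
        assert call["effect"] == "nonsynonymous"
        assert call["alt_aa"] == "*"

    def test_reference_mismatch_raises(self):
        orf = self._orf("ATG" + "AAA" * 10 + "TAA")
        with pytest.raises(ValueError, match="reference allele"):
            classify_effect(orf, 4, "C", "G")

    def test_outside_orf_raises(self):
        orf = find_orf("CCC" + "ATG" + "AAA" * 10 + "TAA", min_orf_len=30)
        with pytest.raises(KeyError):
            classify_effect(orf, 0, "C", "A")

    def test_matches_codon_table_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        n_checked = 0
        while n_checked < 150:
            body = "".join(rng.choice(list(bases), size=3 * rng.integers(12, 40)))
            seq = "ATG" + body
            orf = find_orf(seq, min_orf_len=30)
            if orf is None:
                continue
            offset = int(rng.integers(orf.start, orf.end))
            ref = orf.sequence[offset - orf.start]
            alt = rng.choice([b for b in bases if b != ref])
            call = classify_effect(orf, offset, ref, alt)
            expected = classify_by_translation(orf.sequence, offset - orf.start, alt)
            assert call["effect"] == expected
            n_checked += 1


class TestGeneModelCoordinates:
    def _plus_gene(self):
        # two CDS pieces: 11-20 and 31-40 on the plus strand
        return GeneModel(
            gene_id="g+",
            chrom="chr1",
            strand="+",
            start=1,
            end=50,
            exons=[(5, 22), (29, 45)],
            cds=[(11, 20), (31, 40)],
            utr5=[(5, 10)],
            utr3=[(41, 45)],
            spliced_cds="ATGAAACCCG" + "GGTTTACCTA",
        )

    def _minus_gene(self):
        plus = self._plus_gene()
        return GeneModel(
            gene_id="g-",
            chrom="chr1",
            strand="-",
            start=1,
            end=50,
            exons=plus.exons,
            cds=plus.cds,
            utr5=[(41, 45)],
            utr3=[(5, 10)],
            spliced_cds=revcomp("ATGAAACCCG" + "GGTTTACCTA"),
        )

    def test_offsets_plus_strand(self):
        g = self._plus_gene()
        assert g.cds_offset(11) == 0
        assert g.cds_offset(20) == 9
        assert g.cds_offset(31) == 10
        assert g.cds_offset(25) is None  # intron

    def test_offsets_minus_strand_mirror(self):
        g = self._minus_gene()
        assert g.cds_offset(40) == 0  # transcript starts at the genomic 3' end
        assert g.cds_offset(11) == 19

    def test_feature_classes(self):
        g = self._plus_gene()
        assert g.feature_class_at(15) == "CDS"
        assert g.feature_class_at(7) == "5'UTR"
        assert g.feature_class_at(43) == "3'UTR"
        assert g.feature_class_at(25) == "intron"

    def test_strand_round_trip_consistency(self):
        """A minus-strand classification equals classifying the
        reverse-complemented alleles on the transcript strand."""
        plus, minus = self._plus_gene(), self._minus_gene()
        pos = 15  # genomic CDS position in both models
        ref_plus = plus.spliced_cds[plus.cds_offset(pos)]
        alt_plus = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_plus]
        off_minus = minus.cds_offset(pos)
        t_ref, t_alt = minus.transcript_alleles(ref_plus, alt_plus)
        assert minus.spliced_cds[off_minus] == t_ref
        # same codon-level decision either way
        orf_like_plus = find_orf("ATG" + plus.spliced_cds[3:] , min_orf_len=9)
        assert orf_like_plus is not None


class TestFeatureMapping:
    def _genes(self):
        return [
            GeneModel(
                gene_id="gene1",
                chrom="chr1",
                strand="+",
                start=100,
                end=400,
                exons=[(100, 200), (300, 400)],
                cds=[(150, 200), (300, 350)],
                utr5=[(100, 149)],
                utr3=[(351, 400)],
            )
        ]

    @pytest.mark.parametrize(
        "pos,expected",
        [(160, "CDS"), (120, "5'UTR"), (360, "3'UTR"), (250, "intron"), (900, "intergenic")],
    )
    def test_feature_assignment(self, pos, expected):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]})
        out = map_snps_to_features(snps, self._genes())
        assert out["feature_class"].iloc[0] == expected
        if expected == "intergenic":
            assert out["gene_id"].iloc[0] == ""

    def test_overlapping_genes_flagged_ambiguous(self):
        genes = self._genes() + [
            GeneModel(
                gene_id="gene2", chrom="chr1", strand="-", start=380, end=600
            )
        ]
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [390]})
        out = map_snps_to_features(snps, genes)
        assert len(out) == 2
        assert out["ambiguous"].all()


class TestSimulatedAnnotationRoundTrip:
    def test_gene_models_survive_gff3_fasta_round_trip(
        self, small_dataset, emitted_small_dataset
    ):
        genes = read_gene_models(
            emitted_small_dataset["gff3"], emitted_small_dataset["fasta"]
        )
        by_id = {g.gene_id: g for g in genes}
        assert len(genes) == len(small_dataset.genes)
        for g in small_dataset.genes:
            h = by_id[g.gene_id]
            assert (g.strand, g.start, g.end) == (h.strand, h.start, h.end)
            assert g.exons == h.exons and g.cds == h.cds
            assert g.utr5 == h.utr5 and g.utr3 == h.utr3
            assert g.spliced_cds == h.spliced_cds

    def test_classify_snps_on_simulated_cds(self, small_dataset):
        gm = small_dataset.genotypes
        table = classify_snps(gm.loci.head(200), small_dataset.genes)
        assert set(table["feature_class"]) <= {
            "CDS",
            "5'UTR",
            "3'UTR",
            "intron",
            "intergenic",
        }
        cds = table[table["feature_class"] == "CDS"]
        assert (table.loc[table["feature_class"] != "CDS", "effect"] == "unclassified").all()
        assert {"synonymous", "nonsynonymous"} & set(cds["effect"])
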