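"""ORF finding and synonymous/nonsynonymous classification of CDS SNPs.

Finds the longest open reading frame (>= 30 nt, ATG or alternative start
codons) in a spliced CDS, substitutes a SNP's alternative allele, and
compares the two translations.
"""

import pandas as pd

from founderscan import SimulationConfig, classify_snps, find_orf, simulate_dataset

# a hand-built miniature: third-position change is silent, second is not
orf = find_orf("ATG" + "GGA" + "GAT" + "AAA" * 8 + "TAA", min_orf_len=30)
print(f"ORF: {orf.start}..{orf.end} ({len(orf.peptide)} aa), peptide {orf.peptide}")

from founderscan import classify_effect

silent = classify_effect(orf, 5, "A", "G")  # GGA -> GGG
missense = classify_effect(orf, 7, "A", "T")  # GAT -> GTT
print(f"GGA->GGG: {silent['effect']} ({silent['ref_aa']} -> {silent['alt_aa']})")
print(f"GAT->GTT: {missense['effect']} ({missense['ref_aa']} -> {missense['alt_aa']})")

# on a full simulated dataset: map every SNP to its feature and classify
dataset = simulate_dataset(
    SimulationConfig(
        n_chromosomes=4,
        chromosome_length_bp=300_000,
        n_genes=80,
        ancestral_n_loci=4_000,
        seed=8,
    )
)
table = classify_snps(dataset.genotypes.loci, dataset.genes)
print("\nfeature classes of simulated transcriptome SNPs:")
print(table["feature_class"].value_counts().to_string())
print("\neffect calls among CDS SNPs inside the chosen ORF:")
print(table.loc[table["effect"] != "unclassified", "effect"].value_counts().to_string())
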