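"""Generate a synthetic founder-bottleneck dataset and look at its truth table.

Simulates one high-diversity source population and two bottlenecked derived
populations with a handful of CDS loci under divergent selection, then emits
standard files (VCF, GFF3, FASTA, population table, truth table).
"""

from pathlib import Path

from founderscan import SimulationConfig, emit_dataset, simulate_dataset

config = SimulationConfig(
    n_chromosomes=6,
    chromosome_length_bp=500_000,
    n_genes=200,
    ancestral_n_loci=10_000,
    n_selected_loci=10,
    seed=42,
)
dataset = simulate_dataset(config)

gm = dataset.genotypes
print(f"samples: {gm.n_samples} in populations {gm.population_labels}")
print(f"loci: {gm.n_loci} SNPs across {config.n_chromosomes} chromosomes")
print(f"genes: {len(dataset.genes)}")

# the truth table records every planted selected locus and the frequency
# shift actually applied after drift (the 'effect size' for power studies)
print("\nplanted selected loci:")
print(dataset.truth[["chrom", "pos", "target_population", "realized_freq_shift"]].head(10))

out = Path("scratch_example_data")
paths = emit_dataset(dataset, out)
print("\nemitted files:")
for kind, path in paths.items():
    print(f"  {kind}: {path}")
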