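"""Filter a genotype matrix and summarize genetic diversity.

Runs the standard filter chain (depth >= 5 reads, <= 90% per-sample
missingness, >= 80% call rate, minor-allele count >= 2, per-population exact
HWE exclusion), then reports observed heterozygosity per population and the
percent reduction of each derived population against the source — the
founder-effect signal.
"""

from founderscan import (
    SimulationConfig,
    apply_standard_filters,
    chromosome_means,
    filter_hwe,
    locus_diversity_table,
    percent_reduction,
    simulate_dataset,
)

dataset = simulate_dataset(SimulationConfig(ancestral_n_loci=20_000, seed=1))
gm = dataset.genotypes

filtered, reports = apply_standard_filters(gm)
for rep in reports:
    print(
        f"{rep.step:28s} samples {rep.n_samples_in:>3} -> {rep.n_samples_out:<3} "
        f"loci {rep.n_loci_in:>6} -> {rep.n_loci_out}"
    )
hwe = filter_hwe(filtered)
for pop in filtered.population_labels:
    print(f"HWE-kept loci in {pop}: {int(hwe.kept[pop].sum())}")

diversity = locus_diversity_table(filtered)
_, genome = chromosome_means(diversity, filtered.population_labels)
print("\ngenome-wide means (unweighted over loci):")
print(genome.to_string(index=False))

ho = dict(zip(genome["population"], genome["mean_ho"]))
for pop in ("derived_a", "derived_b"):
    red = percent_reduction(ho[pop], ho["source"])
    print(f"{pop}: {red:.1f}% diversity reduction vs source (~{round(red)}% headline)")
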