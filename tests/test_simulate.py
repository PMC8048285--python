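"""Synthetic founder-bottleneck generator: determinism, drift law, validity."""

import filecmp

import numpy as np
import pytest
from cyvcf2 import VCF

from founderscan import (
    SimulationConfig,
    emit_dataset,
    simulate_dataset,
)


def _tiny(**overrides):
    base = dict(
        n_chromosomes=3,
        chromosome_length_bp=200_000,
        n_genes=30,
        snps_per_gene_mean=20,
        ancestral_n_loci=800,
        seed=5,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_zero_loci_refused(self):
        with pytest.raises(ValueError, match="zero loci"):
            simulate_dataset(_tiny(ancestral_n_loci=0))

    def test_zero_samples_refused(self):
        with pytest.raises(ValueError, match="zero samples"):
            simulate_dataset(_tiny(derived_sample_sizes=(0, 12)))

    def test_selection_without_enough_cds_refused(self):
        with pytest.raises(ValueError, match="CDS"):
            simulate_dataset(_tiny(ancestral_n_loci=5, n_selected_loci=50))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(selection_target_freq_shift=1.5).validate()


class TestDeterminism:
    def test_same_seed_same_dataset(self):
        ds1 = simulate_dataset(_tiny())
        ds2 = simulate_dataset(_tiny())
        assert ds1.genotypes.equals(ds2.genotypes)
        assert ds1.truth.equals(ds2.truth)
        assert ds1.reference == ds2.reference

    def test_emitted_files_byte_identical(self, tmp_path):
        ds1 = simulate_dataset(_tiny(n_selected_loci=3))
        ds2 = simulate_dataset(_tiny(n_selected_loci=3))
        p1 = emit_dataset(ds1, tmp_path / "a")
        p2 = emit_dataset(ds2, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self):
        ds1 = simulate_dataset(_tiny(seed=1))
        ds2 = simulate_dataset(_tiny(seed=2))
        assert not np.array_equal(ds1.genotypes.calls, ds2.genotypes.calls)


class TestDriftModel:
    def test_no_drift_preserves_source_frequencies(self):
        cfg = _tiny(
            ancestral_n_loci=10_000,
            n_genes=100,
            n_chromosomes=5,
            chromosome_length_bp=400_000,
            generations_drift=0,
            founder_size=10**6,
        )
        ds = simulate_dataset(cfg)
        f = ds.allele_frequencies
        diff = np.abs(f["p_source"] - f["p_derived_a"])
        assert diff.mean() < 0.01

    def test_heterozygosity_decay_matches_closed_form(self):
        # E[H_t] = H_0 (1 - 1/(2N))^t with N=25, t=50 -> ratio ~ 0.364
        expected = (1 - 1 / 50) ** 50
        ratios = []
        for seed in range(4):
            cfg = _tiny(
                ancestral_n_loci=12_000,
                n_genes=60,
                founder_size=25,
                generations_drift=50,
                seed=seed,
            )
            ds = simulate_dataset(cfg)
            f = ds.allele_frequencies
            h_src = (2 * f["p_source"] * (1 - f["p_source"])).mean()
            h_der = (2 * f["p_derived_a"] * (1 - f["p_derived_a"])).mean()
            ratios.append(h_der / h_src)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - expected) < 3 * se + 0.01


class TestTruthAndStructure:
    def test_truth_loci_are_emitted_cds_loci(self):
        ds = simulate_dataset(_tiny(n_selected_loci=4))
        gm = ds.genotypes
        key = set(zip(gm.loci["chrom"], gm.loci["pos"]))
        genes_by_chrom = {}
        for g in ds.genes:
            genes_by_chrom.setdefault(g.chrom, []).append(g)
        assert len(ds.truth) == 8  # 4 per derived population
        for _, row in ds.truth.iterrows():
            assert (row["chrom"], row["pos"]) in key
            hit = [
                g
                for g in genes_by_chrom[row["chrom"]]
                if g.contains(row["pos"]) and g.feature_class_at(row["pos"]) == "CDS"
            ]
            assert hit, "planted locus must lie within a CDS feature"

    def test_no_selection_gives_empty_truth(self):
        ds = simulate_dataset(_tiny(n_selected_loci=0))
        assert len(ds.truth) == 0

    def test_shared_targets_mode_plants_same_loci(self):
        ds = simulate_dataset(_tiny(n_selected_loci=4, selection_shared_targets=True))
        per_pop = ds.truth.groupby("target_population")
        sets = [set(zip(g["chrom"], g["pos"])) for _, g in per_pop]
        assert sets[0] == sets[1]

    def test_selection_shifts_derived_frequency(self):
        ds = simulate_dataset(_tiny(n_selected_loci=5, seed=3))
        shifts = ds.truth["realized_freq_shift"].abs()
        assert (shifts > 0).all()
        assert (ds.truth["p_final"] >= 0).all() and (ds.truth["p_final"] <= 1).all()


class TestEmittedFormats:
    def test_vcf_parses_and_contains_planted_records(self, tmp_path):
        ds = simulate_dataset(_tiny(n_selected_loci=3))
        paths = emit_dataset(ds, tmp_path)
        records = {(v.CHROM, v.POS) for v in VCF(str(paths["vcf"]))}
        assert len(records) == ds.genotypes.n_loci
        for _, row in ds.truth.iterrows():
            assert (row["chrom"], row["pos"]) in records

    def test_gff3_parses_with_standard_reader(self, emitted_small_dataset):
        import pyranges as pr

        df = pr.read_gff3(str(emitted_small_dataset["gff3"])).df
        assert set(df["Feature"]) >= {"gene", "mRNA", "exon", "CDS"}
        # CDS intervals nest inside their gene span
        genes = df[df["Feature"] == "gene"]
        cds = df[df["Feature"] == "CDS"]
        assert cds["Start"].min() >= genes["Start"].min()

    def test_fasta_lengths_match_config(self, emitted_small_dataset, small_config):
        from pyfaidx import Fasta

        fa = Fasta(str(emitted_small_dataset["fasta"]))
        assert len(fa.keys()) == small_config.n_chromosomes
        for chrom in fa.keys():
            assert len(fa[chrom]) == small_config.chromosome_length_bp

    def test_depth_layer_mean_near_config(self, small_dataset, small_config):
        d = small_dataset.genotypes.depth
        assert abs(d.mean() - small_config.mean_depth) < 1.0
        assert (d >= 0).all()


def test_derived_ho_below_source_in_most_replicates():
    wins = 0
    reps = 6
    for seed in range(reps):
        ds = simulate_dataset(_tiny(ancestral_n_loci=3_000, n_genes=40, seed=seed))
        gm = ds.genotypes
        ho = {}
        for pop in gm.population_labels:
            sub = gm.calls[gm.sample_indices(pop)]
            ho[pop] = ((sub == 1).sum() / (sub != -1).sum())
        if ho["derived_a"] < ho["source"] and ho["derived_b"] < ho["source"]:
            wins += 1
    assert wins == reps
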