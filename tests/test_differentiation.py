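"""Weir-Cockerham F_ST, Z-score outliers, AFD, windows, kNN scan, profiles."""

import numpy as np
import pandas as pd
import pytest

from founderscan import (
    allele_frequency_difference,
    detect_outliers,
    fst_afd_concordance,
    knn_scan,
    local_diversity_profile,
    mean_fst,
    pairwise_fst_table,
    weir_cockerham_fst,
    window_mean_fst,
    z_transform,
)

from _oracles import anova_theta, brute_force_knn_distance, brute_force_medoid, genotype_counts


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        theta = weir_cockerham_fst(np.array([[10, 0, 0]]), np.array([[0, 0, 10]]))
        assert theta[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_union_undefined(self):
        theta = weir_cockerham_fst(np.array([[10, 0, 0]]), np.array([[8, 0, 0]]))
        assert np.isnan(theta[0])

    def test_textbook_example_against_independent_derivation(self):
        # (AA,Aa,aa) = (6,3,1) vs (1,4,5); frozen value from the nested-ANOVA
        # oracle (both derivations agree to machine precision)
        theta = weir_cockerham_fst(np.array([[6, 3, 1]]), np.array([[1, 4, 5]]))
        assert theta[0] == pytest.approx(0.2962962962962963, abs=1e-10)
        ga = np.array([0] * 6 + [1] * 3 + [2] * 1).reshape(10, 1)
        gb = np.array([0] * 1 + [1] * 4 + [2] * 5).reshape(10, 1)
        assert theta[0] == pytest.approx(anova_theta(ga, gb)[0], abs=1e-12)

    def test_matches_anova_oracle_on_random_loci(self):
        rng = np.random.default_rng(42)
        n_loci = 300
        ga = rng.binomial(2, rng.uniform(0, 1, n_loci), size=(15, n_loci))
        gb = rng.binomial(2, rng.uniform(0, 1, n_loci), size=(12, n_loci))
        ga[rng.random(ga.shape) < 0.08] = -1
        gb[rng.random(gb.shape) < 0.08] = -1
        mine = weir_cockerham_fst(genotype_counts(ga), genotype_counts(gb))
        oracle = anova_theta(ga, gb)
        assert np.array_equal(np.isnan(mine), np.isnan(oracle))
        ok = ~np.isnan(mine)
        assert np.max(np.abs(mine[ok] - oracle[ok])) < 1e-8

    def test_negative_estimates_are_retained(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, size=(30, 400))
        theta = weir_cockerham_fst(genotype_counts(g[:15]), genotype_counts(g[15:]))
        assert np.nanmin(theta) < 0  # null data yields negatives by design
        assert np.nanmax(theta) <= 1.0 + 1e-12

    def test_mean_fst(self):
        assert mean_fst(np.array([1.0, 0.0])) == 0.5
        assert mean_fst(np.array([1.0, np.nan, 1.0])) == 1.0
        with pytest.raises(ValueError):
            mean_fst(np.array([np.nan]))


class TestZScores:
    def test_unit_example(self):
        assert z_transform(np.array([1.0, 2.0, 3.0])) == pytest.approx([-1, 0, 1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            z_transform(np.full(5, 0.3))

    def test_output_standardized(self):
        rng = np.random.default_rng(2)
        z = z_transform(rng.gamma(2.0, 1.0, 500))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_outlier_rule_is_strict(self):
        z = np.array([0.0, 1.0, 5.2, -3.0, 5.0, np.nan])
        assert detect_outliers(z, 5.0).tolist() == [2]

    def test_outliers_invariant_under_affine_transform(self):
        rng = np.random.default_rng(3)
        fst = rng.beta(0.5, 3.0, 2000)
        base = detect_outliers(z_transform(fst))
        shifted = detect_outliers(z_transform(0.25 * fst + 0.1))
        assert np.array_equal(base, shifted)


class TestAfd:
    def test_examples(self):
        assert allele_frequency_difference(0.8, 0.3) == pytest.approx(0.5)
        assert allele_frequency_difference(1.0, 0.0) == 1.0
        assert allele_frequency_difference(0.4, 0.4) == 0.0

    def test_concordance_on_simulation(self, small_dataset):
        gm = small_dataset.genotypes
        tab = pairwise_fst_table(gm, "source", "derived_a")
        res = fst_afd_concordance(tab["fst"].to_numpy(), tab["afd"].to_numpy())
        assert res["spearman_rho"] > 0.8
        assert res["pearson_r"] > 0.8


class TestWindows:
    def test_single_window_mean(self):
        out = window_mean_fst(
            np.array(["chr1", "chr1"]), np.array([10_000, 90_000]), np.array([0.2, 0.4])
        )
        assert len(out) == 1
        assert out["mean_fst"].iloc[0] == pytest.approx(0.3)
        assert out["start"].iloc[0] == 1 and out["end"].iloc[0] == 100_000

    def test_boundary_position_opens_second_window(self):
        out = window_mean_fst(
            np.array(["chr1", "chr1"]),
            np.array([100_000, 100_001]),
            np.array([0.1, 0.5]),
        )
        assert len(out) == 2
        assert list(out["start"]) == [1, 100_001]

    def test_empty_and_invalid(self):
        out = window_mean_fst(np.array([]), np.array([]), np.array([]))
        assert out.empty
        with pytest.raises(ValueError):
            window_mean_fst(np.array(["chr1"]), np.array([1]), np.array([0.1]), 0)


class TestKnnScan:
    def test_identical_vectors_have_zero_delta(self):
        v = np.tile([0.2, 0.3, 0.1], (30, 1))
        res = knn_scan(v, k=5)
        assert np.allclose(res.delta_fst, 0.0)
        assert not res.outlier_flag.any()

    def test_planted_distant_vector_flagged(self):
        rng = np.random.default_rng(5)
        v = np.vstack([rng.normal(0.1, 0.01, size=(100, 3)), [[0.9, 0.9, 0.9]]])
        res = knn_scan(v, k=5, quantile=0.99)
        oracle = brute_force_knn_distance(v, 5)
        assert np.allclose(res.knn_distance, oracle, atol=1e-12)
        assert res.outlier_flag[100]
        assert res.outlier_flag.sum() <= 2  # essentially only the planted vector
        assert res.medoid_index == brute_force_medoid(v)
        # positive delta in the elevated comparisons marks local adaptation
        assert (res.delta_fst[100] > 0).all()

    def test_incomplete_vectors_excluded_and_k_bounds(self):
        v = np.array([[0.1, 0.2], [np.nan, 0.3], [0.2, 0.1], [0.15, 0.12]])
        res = knn_scan(v, k=1)
        assert res.kept_index.tolist() == [0, 2, 3]
        with pytest.raises(ValueError):
            knn_scan(v, k=3)  # k >= number of complete SNPs


class TestLocalProfile:
    def _table(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": np.arange(1, n + 1) * 10_000,
                "fst": values,
                "dxy": values,
                "pi_a": values,
            }
        )

    def test_uniform_window_gives_no_indicators(self):
        table = self._table([0.2] * 9)
        prof = local_diversity_profile("chr1", 50_000, table, "fst", "dxy", ["pi_a"])
        assert prof.complete
        assert not prof.fst_elevated and not prof.dxy_elevated
        assert prof.pi_depressed == {"pi_a": False}
        assert prof.outlier_fst == pytest.approx(prof.window_mean_fst)

    def test_zero_flank_is_incomplete(self):
        table = self._table([0.2] * 9)
        prof = local_diversity_profile(
            "chr1", 50_000, table, "fst", "dxy", ["pi_a"], flank_bp=0
        )
        assert not prof.complete

    def test_missing_outlier_raises(self):
        table = self._table([0.2] * 3)
        with pytest.raises(KeyError):
            local_diversity_profile("chr1", 999, table, "fst", "dxy", ["pi_a"])
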