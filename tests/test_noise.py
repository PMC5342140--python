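import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from popnoise.noise import (
    NoiseTable,
    gene_noise,
    log_ratio_histogram,
    noise_table,
    permutation_null,
    summarize_comparison,
)
from popnoise.simulate import SimulationConfig, simulate_cohort


class TestGeneNoise:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 2, 2, 2], 0.0),
            ([1, 2, 3], 0.5),  # sample SD 1, mean 2
            ([10, 20, 30], 0.5),  # scale invariance
        ],
    )
    def test_examples(self, values, expected):
        assert gene_noise(values) == pytest.approx(expected, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            gene_noise([0, 0, 0])

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            gene_noise([5.0])

    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=30),
        st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, values, c):
        x = np.asarray(values)
        if x.mean() <= 0 or x.std(ddof=1) == 0:
            return
        assert gene_noise(c * x) == pytest.approx(gene_noise(x), rel=1e-9)


class TestNoiseTable:
    def test_hand_oracle(self, toy_cohort, normal_group, tumor_group):
        nt = noise_table(toy_cohort, normal_group, tumor_group)
        row = nt.table.set_index("gene_id").loc["g1"]
        assert row["noise_a"] == pytest.approx(0.5)
        assert row["noise_b"] == pytest.approx(math.sqrt(13) / 5)  # SD(2,4,9)=sqrt(13)
        assert row["ratio"] == pytest.approx(math.sqrt(13) / 5 / 0.5)
        assert row["log_ratio"] == pytest.approx(math.log10(math.sqrt(13) / 2.5))

    def test_zero_mean_gene_excluded(self, toy_cohort, normal_group, tumor_group):
        nt = noise_table(toy_cohort, normal_group, tumor_group)
        assert "g3" not in set(nt.table["gene_id"])
        assert nt.n_excluded == 1

    def test_overlapping_groups_rejected(self, toy_cohort, normal_group):
        with pytest.raises(ValueError, match="overlap"):
            noise_table(toy_cohort, normal_group, normal_group)

    def test_small_group_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="at least 2"):
            noise_table(toy_cohort, ["N1"], ["T1", "T2"])

    def test_ratio_consistency(self, toy_cohort, normal_group, tumor_group):
        nt = noise_table(toy_cohort, normal_group, tumor_group)
        np.testing.assert_allclose(
            nt.ratios, nt.table["noise_b"] / nt.table["noise_a"], rtol=1e-12
        )
        np.testing.assert_allclose(nt.log_ratios, np.log10(nt.ratios), rtol=1e-12)


def _table_from_ratios(ratios):
    r = np.asarray(ratios, dtype=float)
    return NoiseTable(
        table=pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(r))],
                "noise_a": np.ones_like(r),
                "noise_b": r,
                "ratio": r,
                "log_ratio": np.log10(r),
            }
        ),
        n_excluded=0,
    )


class TestSummarizeComparison:
    def test_fraction_increased(self):
        s = summarize_comparison(_table_from_ratios([2.0, 0.5, 3.0, 1.5]))
        assert s.fraction_increased == 0.75

    def test_all_ratios_one_errors(self):
        with pytest.raises(ValueError, match="all values zero"):
            summarize_comparison(_table_from_ratios([1.0, 1.0, 1.0]))

    def test_empty_table_errors(self):
        empty = NoiseTable(
            table=pd.DataFrame(
                columns=["gene_id", "noise_a", "noise_b", "ratio", "log_ratio"]
            ),
            n_excluded=5,
        )
        with pytest.raises(ValueError, match="empty"):
            summarize_comparison(empty)

    def test_group_swap_antisymmetry(self):
        cfg = SimulationConfig(n_genes=100, n_patients=12, seed=5)
        cohort, _ = simulate_cohort(cfg)
        tumors = cohort.sheet.samples_with_tissue("tumor")
        normals = cohort.sheet.samples_with_tissue("normal")
        fwd = noise_table(cohort, normals, tumors)
        rev = noise_table(cohort, tumors, normals)
        np.testing.assert_allclose(fwd.log_ratios, -rev.log_ratios, rtol=1e-12)
        sf = summarize_comparison(fwd)
        sr = summarize_comparison(rev)
        assert sr.fraction_increased == pytest.approx(
            1 - sf.fraction_increased - sf.tie_fraction
        )
        assert sr.p_value == pytest.approx(sf.p_value, rel=1e-9)


class TestPermutationNull:
    def test_deterministic_given_seed(self, toy_cohort, normal_group, tumor_group):
        a = permutation_null(toy_cohort, normal_group, tumor_group, 1, seed=42)
        b = permutation_null(toy_cohort, normal_group, tumor_group, 1, seed=42)
        assert a[0].equals(b[0])

    def test_null_median_near_zero_when_groups_identical(self):
        cfg = SimulationConfig(
            n_genes=500, n_patients=15, inflation_factor=1.0, fraction_affected=0.0, seed=2
        )
        cohort, _ = simulate_cohort(cfg)
        tumors = cohort.sheet.samples_with_tissue("tumor")
        normals = cohort.sheet.samples_with_tissue("normal")
        null = permutation_null(cohort, normals, tumors, n_perm=100, seed=3)
        pooled = np.concatenate([s.to_numpy() for s in null])
        assert abs(np.median(pooled)) < 0.02

    def test_observed_median_exceeds_null_under_inflation(self):
        cfg = SimulationConfig(
            n_genes=1000, n_patients=50, inflation_factor=1.5, fraction_affected=1.0, seed=4
        )
        cohort, _ = simulate_cohort(cfg)
        tumors = cohort.sheet.samples_with_tissue("tumor")
        normals = cohort.sheet.samples_with_tissue("normal")
        observed = np.median(noise_table(cohort, normals, tumors).log_ratios)
        null = permutation_null(cohort, normals, tumors, n_perm=100, seed=5)
        null_medians = np.array([np.median(s.to_numpy()) for s in null])
        assert observed > np.percentile(null_medians, 97.5)

    def test_paired_swap_structure_used(self, toy_cohort, normal_group, tumor_group):
        # tumor/normal groups pair within patients: each permuted vector still
        # covers all computable genes
        null = permutation_null(toy_cohort, normal_group, tumor_group, 5, seed=0)
        for s in null:
            assert set(s.index) <= {"g1", "g2", "g3"}


class TestHistogram:
    def test_all_zeros_single_bin(self):
        h = log_ratio_histogram([0.0, 0.0, 0.0], 0.1)
        assert len(h) == 1
        assert h["bin_left"].iloc[0] == pytest.approx(0.0)
        assert h["frequency"].iloc[0] == 1.0

    def test_straddling_zero(self):
        h = log_ratio_histogram([-0.05, 0.05], 0.1)
        assert list(h["frequency"]) == [0.5, 0.5]
        assert h["bin_left"].tolist() == pytest.approx([-0.1, 0.0])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=200), st.floats(0.01, 2.0))
    def test_frequencies_sum_to_one(self, values, width):
        h = log_ratio_histogram(values, width)
        assert h["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            log_ratio_histogram([], 0.1)

    def test_bad_width_errors(self):
        with pytest.raises(ValueError, match="bin_width"):
            log_ratio_histogram([1.0], 0.0)
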