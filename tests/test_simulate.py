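import numpy as np
import pytest
from scipy.stats import spearmanr

from popnoise.io import ValidationError
from popnoise.noise import noise_table
from popnoise.simulate import (
    IMMUNE_MARKERS,
    P53_MARKERS,
    SimulationConfig,
    assign_stages,
    mix_purity,
    simulate_cohort,
    with_mean_purity,
)
from popnoise.stratify import activity_score


class TestMixPurity:
    @pytest.mark.parametrize(
        "tumor,contaminant,purity,expected",
        [(10, 2, 1.0, 10.0), (10, 2, 0.0, 2.0), (10, 2, 0.5, 6.0)],
    )
    def test_examples(self, tumor, contaminant, purity, expected):
        assert mix_purity(tumor, contaminant, purity) == expected

    def test_purity_out_of_range(self):
        with pytest.raises(ValidationError, match="purity"):
            mix_purity(10, 2, 1.5)

    def test_array_broadcast(self):
        out = mix_purity(np.array([10.0, 4.0]), np.array([2.0, 0.0]), 0.25)
        np.testing.assert_allclose(out, [4.0, 1.0])


class TestAssignStages:
    def test_degenerate_probs(self):
        assert assign_stages(10, (1, 0, 0, 0), seed=0) == ["I"] * 10

    def test_uniform_counts_within_binomial_bound(self):
        stages = assign_stages(4000, (0.25, 0.25, 0.25, 0.25), seed=123)
        for s in ("I", "II", "III", "IV"):
            assert abs(stages.count(s) - 1000) <= 150  # ~5 sigma

    def test_invalid_probs(self):
        with pytest.raises(ValidationError, match="stage_probs"):
            assign_stages(5, (0.5, 0.6, 0, 0), seed=0)

    def test_deterministic(self):
        assert assign_stages(50, (0.3, 0.35, 0.25, 0.1), 9) == assign_stages(
            50, (0.3, 0.35, 0.25, 0.1), 9
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"sigma_normal": 0.0}, "sigma_normal"),
            ({"inflation_factor": 0.9}, "inflation_factor"),
            ({"fraction_affected": 1.5}, "fraction_affected"),
            ({"purity_model": "gamma"}, "purity_model"),
            ({"stage_probs": (0.5, 0.6, 0.0, 0.0)}, "stage_probs"),
            ({"couple_inflation_to": "stage"}, "couple_inflation_to"),
            ({"marker_effects": {"BRCA1": 1.0}}, "marker"),
        ],
    )
    def test_invalid_field_named(self, kwargs, field):
        with pytest.raises(ValidationError, match=field):
            SimulationConfig(**kwargs).validate()


class TestSimulateCohort:
    def test_bit_identical_under_same_seed(self):
        cfg = SimulationConfig(n_genes=50, n_patients=8, seed=7)
        c1, t1 = simulate_cohort(cfg)
        c2, t2 = simulate_cohort(cfg)
        assert c1.matrix.data.equals(c2.matrix.data)
        assert c1.sheet.data.equals(c2.sheet.data)
        assert t1.affected_genes == t2.affected_genes
        assert t1.patient_activity_p53.equals(t2.patient_activity_p53)

    def test_paired_structure(self):
        cfg = SimulationConfig(n_genes=20, n_patients=6, seed=1)
        cohort, _ = simulate_cohort(cfg)
        assert len(cohort.sheet.paired_patients()) == 6

    def test_affected_count_matches_fraction(self):
        cfg = SimulationConfig(n_genes=101, n_patients=5, fraction_affected=0.3, seed=2)
        _, truth = simulate_cohort(cfg)
        assert len(truth.affected_genes) == round(0.3 * 101)

    def test_lognormal_cv_concentration(self):
        # closed-form lognormal CV: sqrt(exp(sigma^2) - 1)
        cfg = SimulationConfig(
            n_genes=50,
            n_patients=5000,
            sigma_normal=0.5,
            inflation_factor=1.0,
            fraction_affected=0.0,
            marker_effects={},
            seed=8,
        )
        cohort, _ = simulate_cohort(cfg)
        normals = cohort.sheet.samples_with_tissue("normal")
        vals = cohort.matrix.values_for(normals)
        cv = vals.std(axis=1, ddof=1) / vals.mean(axis=1)
        expected = np.sqrt(np.exp(0.25) - 1)
        assert np.median(cv) == pytest.approx(expected, rel=0.03)

    def test_marker_coherence(self):
        cfg = SimulationConfig(n_genes=100, n_patients=200, seed=3)
        cohort, truth = simulate_cohort(cfg)
        tumors = cohort.sheet.samples_with_tissue("tumor")
        for markers, latent in (
            (P53_MARKERS, truth.patient_activity_p53),
            (IMMUNE_MARKERS, truth.patient_activity_immune),
        ):
            scores = activity_score(cohort.matrix, markers, tumors)
            patients = [s[:-2] for s in scores.table["sample_id"]]
            rho = spearmanr(scores.table["score"], latent.loc[patients]).statistic
            assert rho > 0.8

    def test_purity_monotonicity(self):
        # lower mean purity must not decrease the median tumor-group noise
        base = SimulationConfig(
            n_genes=500, n_patients=50, inflation_factor=1.0, fraction_affected=0.0, seed=11
        )
        medians = []
        for mean_purity in (0.95, 0.8, 0.6):
            cohort, _ = simulate_cohort(with_mean_purity(base, mean_purity))
            tumors = cohort.sheet.samples_with_tissue("tumor")
            vals = cohort.matrix.values_for(tumors)
            medians.append(np.median(vals.std(axis=1, ddof=1) / vals.mean(axis=1)))
        assert medians[0] <= medians[1] <= medians[2]

    def test_purity_recorded_on_tumor_rows_only(self):
        cfg = with_mean_purity(SimulationConfig(n_genes=20, n_patients=5, seed=4), 0.8)
        cohort, truth = simulate_cohort(cfg)
        df = cohort.sheet.data
        assert df.loc[df["tissue"] == "tumor", "purity"].notna().all()
        assert df.loc[df["tissue"] == "normal", "purity"].isna().all()
        assert ((truth.patient_purity > 0) & (truth.patient_purity <= 1)).all()

    def test_inflation_raises_tumor_noise(self):
        cfg = SimulationConfig(
            n_genes=200, n_patients=40, inflation_factor=2.0, fraction_affected=0.5, seed=6
        )
        cohort, truth = simulate_cohort(cfg)
        pairs = cohort.sheet.paired_patients()
        nt = noise_table(
            cohort, [n for _, _, n in pairs], [t for _, t, _ in pairs]
        )
        table = nt.table.set_index("gene_id")
        affected = [g for g in table.index if g in truth.affected_genes]
        unaffected = [g for g in table.index if g not in truth.affected_genes]
        assert table.loc[affected, "log_ratio"].median() > 0.1
        assert abs(table.loc[unaffected, "log_ratio"].median()) < 0.1
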