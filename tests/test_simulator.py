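"""Clonal-architecture simulator: analytic VAFs, noise models, cohorts,
single-cell matrices."""

import numpy as np
import pytest

from tp53state.classifier import classify_novel
from tp53state.simulate import (GT_HET, GT_HOM, GT_MISSING, GT_WT,
                                ClonalArchitecture, Clone, SimulationParams,
                                bulk_decision_stat, combined_expected_vaf,
                                draw_architecture, expected_vaf,
                                generate_cohort, generate_single_cell_matrix,
                                make_architecture, sample_bulk_vaf,
                                simulate_survival)
from tp53state.survival import SurvivalSample, cox_fit, km_median

FRACTION_GRID = np.round(np.arange(0.1, 1.01, 0.1), 10)


class TestExpectedVaf:
    @pytest.mark.parametrize("f", FRACTION_GRID)
    def test_closed_forms_single_clone(self, f):
        assert expected_vaf(make_architecture("het_mono", f), "mutA") == \
            pytest.approx(f / 2, abs=1e-12)
        assert expected_vaf(make_architecture("hemizygous", f), "mutA") == \
            pytest.approx(f / (2 - f), abs=1e-12)
        assert expected_vaf(make_architecture("upd_hom", f), "mutA") == \
            pytest.approx(f, abs=1e-12)

    @pytest.mark.parametrize("f", FRACTION_GRID)
    def test_compound_het_sum_rule(self, f):
        arch = make_architecture("compound_het", f)
        va = expected_vaf(arch, "mutA")
        vb = expected_vaf(arch, "mutB")
        assert va == pytest.approx(f / 2, abs=1e-12)
        assert va + vb == pytest.approx(f, abs=1e-12)

    def test_full_clonal_examples(self):
        assert expected_vaf(make_architecture("het_mono", 1.0), "mutA") == 0.5
        assert expected_vaf(make_architecture("hemizygous", 1.0), "mutA") == 1.0
        assert expected_vaf(make_architecture("upd_hom", 0.6), "mutA") == \
            pytest.approx(0.6)

    def test_mosaic_sum_below_half(self):
        arch = make_architecture("mosaic_two_mono", 0.2, 0.2)
        assert expected_vaf(arch, "mutA") == pytest.approx(0.1)
        assert combined_expected_vaf(arch) == pytest.approx(0.2)

    def test_vaf_bounded(self, rng):
        params = SimulationParams()
        for i in range(500):
            label = rng.choice(
                ["het_mono", "hemizygous", "upd_hom", "compound_het",
                 "mosaic_two_mono", "nested_biallelic_subclone"])
            arch = draw_architecture(str(label), params, rng)
            for v in arch.variants:
                assert 0.0 <= expected_vaf(arch, v) <= 1.0

    def test_invalid_clone_rejected(self):
        with pytest.raises(ValueError):
            Clone(0.5, "deleted", "deleted")
        with pytest.raises(ValueError):
            Clone(1.5, "mutA", "wt")
        with pytest.raises(ValueError):
            make_architecture("mosaic_two_mono", 0.7, 0.7)


class TestBulkDichotomy:
    def test_fig3a_dichotomy_random_architectures(self, rng):
        """Bulk arithmetic (summed VAF + del(17p) clonality) separates
        dominant-biallelic from purely monoallelic architectures: a
        biallelic clone above half the cells forces the statistic above
        50%, and purely monoallelic architectures stay strictly below."""
        params = SimulationParams()
        labels = ["het_mono", "hemizygous", "upd_hom", "compound_het",
                  "mosaic_two_mono", "nested_biallelic_subclone"]
        for i in range(2000):
            arch = draw_architecture(str(rng.choice(labels)), params, rng)
            stat = bulk_decision_stat(arch)
            if arch.biallelic_fraction > 0.5:
                assert stat > 0.5
            if arch.biallelic_fraction == 0.0:
                assert stat < 0.5


class TestBulkSampling:
    def test_zero_vaf_always_zero(self, rng):
        assert all(sample_bulk_vaf(0.0, 100, rng) == 0.0 for _ in range(50))

    def test_binomial_concentration(self, rng):
        obs = sample_bulk_vaf(0.5, 10 ** 6, rng)
        assert abs(obs - 0.5) < 0.002

    def test_mean_unbiased(self, rng):
        draws = [sample_bulk_vaf(0.3, 100, rng) for _ in range(10 ** 4)]
        se = np.sqrt(0.3 * 0.7 / 100 / 10 ** 4)
        assert abs(np.mean(draws) - 0.3) < 3 * se


class TestSurvivalModel:
    def test_null_hazards_similar_medians(self, rng):
        params = SimulationParams(lambda_low=0.02, lambda_high=0.02)
        lo = [simulate_survival(False, params, rng) for _ in range(2000)]
        hi = [simulate_survival(True, params, rng) for _ in range(2000)]
        m_lo = km_median(np.array([x[0] for x in lo]),
                         np.array([x[1] for x in lo]))
        m_hi = km_median(np.array([x[0] for x in hi]),
                         np.array([x[1] for x in hi]))
        assert abs(m_lo - m_hi) / m_lo < 0.10

    def test_cox_recovers_hazard_ratio_three(self, rng):
        params = SimulationParams()  # lambda ratio 3 by default
        ok = 0
        for rep in range(10):
            flags = np.repeat([False, True], 1000)
            draws = [simulate_survival(f, params, rng) for f in flags]
            t = np.array([d[0] for d in draws])
            e = np.array([d[1] for d in draws])
            hr = cox_fit(SurvivalSample(t, e),
                         flags.astype(float))["hr"].iloc[0]
            ok += 2.6 <= hr <= 3.4
        assert ok >= 9

    def test_zero_horizon_all_censored(self, rng):
        params = SimulationParams(horizon=0.0)
        t, e = simulate_survival(True, params, rng)
        assert t == 0.0 and not e


class TestGenerateCohort:
    def test_same_seed_identical(self):
        params = SimulationParams(n_patients=60, seed=5)
        c1, t1 = generate_cohort(params)
        c2, t2 = generate_cohort(SimulationParams(n_patients=60, seed=5))
        assert [p.patient_id for p in c1] == [p.patient_id for p in c2]
        assert [p.os_time for p in c1] == [p.os_time for p in c2]
        assert t1.equals(t2)

    def test_pure_monoallelic_mixture_no_biallelic_truth(self):
        params = SimulationParams(n_patients=120, wt_share=0.0,
                                  mixture={"het_mono": 1.0}, seed=3)
        _, truth = generate_cohort(params)
        assert truth["has_biallelic"].sum() == 0

    def test_upd_with_flag_always_obligatory(self):
        """Patients whose dominant-UPD clone is visible to cytogenetics must
        be caught by the classifier every time (rule oracle on truth)."""
        params = SimulationParams(
            n_patients=200, wt_share=0.0, seed=11,
            mixture={"upd_hom": 0.5, "het_mono": 0.5},
            clone_fraction_beta=(8.0, 2.0))  # large clones
        cohort, truth = generate_cohort(params)
        tested = 0
        for p, (_, row) in zip(cohort, truth.iterrows()):
            if row["config_label"] == "upd_hom" and p.cytogenetics.tp53_upd:
                assert classify_novel(p).state == "obligatory_biallelic"
                tested += 1
        assert tested > 30

    def test_cohort_readable_by_pipeline(self, tmp_path):
        from tp53state.cohort import read_cohort_tsv, write_cohort_tsv

        cohort, _ = generate_cohort(SimulationParams(n_patients=40, seed=2))
        path = tmp_path / "sim.tsv"
        write_cohort_tsv(cohort, path)
        back = read_cohort_tsv(path)
        assert len(back) == 40


class TestSingleCellGeneration:
    def test_compound_het_biallelic_cell_fraction(self, rng):
        arch = make_architecture("compound_het", 0.32)
        obs, truth = generate_single_cell_matrix(arch, 10 ** 4, 0.0, 0.0, rng)
        both = ((obs["mutA"] != GT_WT) & (obs["mutB"] != GT_WT)).mean()
        assert both == pytest.approx(0.32, abs=0.01)

    def test_mosaic_no_co_mutant_cells(self, rng):
        arch = make_architecture("mosaic_two_mono", 0.3, 0.3)
        obs, _ = generate_single_cell_matrix(arch, 3000, 0.0, 0.0, rng)
        both = ((obs["mutA"] != GT_WT) & (obs["mutB"] != GT_WT)).sum()
        assert both == 0

    def test_dropout_on_hom_cells_closed_form(self, rng):
        """UPD-homozygous cells under per-allele dropout d: both alleles
        lost with probability d^2 -> MISSING; otherwise every observed
        allele is mutant -> HOM_or_HEMI."""
        arch = make_architecture("upd_hom", 1.0)
        obs, _ = generate_single_cell_matrix(arch, 10 ** 4, 0.5, 0.0, rng)
        missing = (obs["mutA"] == GT_MISSING).mean()
        hom = (obs["mutA"] == GT_HOM).mean()
        assert missing == pytest.approx(0.25, abs=0.02)
        assert hom == pytest.approx(0.75, abs=0.02)
        assert (obs["mutA"] == GT_HET).sum() == 0

    def test_het_dropout_splits_wt_and_hom(self, rng):
        """Het cells: mut allele dropped -> WT (d(1-d)), wt allele dropped
        -> HOM (d(1-d)), both dropped -> MISSING (d^2)."""
        arch = make_architecture("het_mono", 1.0)
        obs, _ = generate_single_cell_matrix(arch, 10 ** 4, 0.4, 0.0, rng)
        frac = obs["mutA"].value_counts(normalize=True)
        assert frac.get(GT_MISSING, 0) == pytest.approx(0.16, abs=0.02)
        assert frac.get(GT_WT, 0) == pytest.approx(0.24, abs=0.02)
        assert frac.get(GT_HOM, 0) == pytest.approx(0.24, abs=0.02)
        assert frac.get(GT_HET, 0) == pytest.approx(0.36, abs=0.02)

    def test_hemizygous_cells_have_cn_one(self, rng):
        arch = make_architecture("hemizygous", 0.5)
        obs, truth = generate_single_cell_matrix(arch, 2000, 0.0, 0.0, rng)
        mutant = obs["mutA"] == GT_HOM
        assert (obs.loc[mutant, "cn17p"] == 1).all()
        assert mutant.mean() == pytest.approx(0.5, abs=0.03)

    def test_truth_matrix_noise_free(self, rng):
        arch = make_architecture("compound_het", 0.4)
        obs, truth = generate_single_cell_matrix(arch, 1000, 0.3, 0.05, rng)
        assert set(np.unique(truth[["mutA", "mutB"]])) <= {GT_WT, GT_HET}
        assert (truth["mutA"] == GT_HET).mean() == pytest.approx(0.4, abs=0.05)
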