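import numpy as np
import pandas as pd
import pytest

from microherit import genoqc, varcomp
from microherit.features import TaxonCountTable
from microherit.genoqc import build_grm, hwe_test
from microherit.synthdata import (
    PedigreeStructure,
    SimTruth,
    simulate_count_table,
    simulate_genotypes,
    simulate_metadata,
    simulate_polygenic_trait,
    simulate_qtl_trait,
)
from microherit.varcomp import FixedEffectsDesign


def intercept_design(sample_ids):
    return FixedEffectsDesign(list(sample_ids), np.ones((len(sample_ids), 1)), ["intercept"])


class TestSimulateGenotypes:
    def test_same_seed_gives_identical_panels(self):
        ped = PedigreeStructure(5, 4, 10)
        a = simulate_genotypes(ped, 100, seed=3)
        b = simulate_genotypes(ped, 100, seed=3)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_hwe_mean_dosage_at_fixed_half_frequency(self):
        panel = simulate_genotypes(PedigreeStructure(0, 0, 10_000), 1,
                                   maf_range=(0.5, 0.5), seed=4)
        se = np.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert panel.dosages.mean() == pytest.approx(1.0, abs=3 * se)

    def test_half_sib_and_unrelated_grm_expectations(self):
        # half-sibs share half the sire genome: expected relationship 0.25
        ped = PedigreeStructure(50, 10)
        panel = simulate_genotypes(ped, 2000, seed=5)
        g = build_grm(panel).g
        fam = np.repeat(np.arange(50), 10)
        same_fam = (fam[:, None] == fam[None, :]) & ~np.eye(500, dtype=bool)
        assert g[same_fam].mean() == pytest.approx(0.25, abs=0.05)
        assert g[fam[:, None] != fam[None, :]].mean() == pytest.approx(0.0, abs=0.05)

    def test_marker_map_ordered_within_chromosomes(self):
        panel = simulate_genotypes(PedigreeStructure(2, 3), 90, n_chromosomes=5, seed=6)
        assert set(panel.markers["chrom"]) == {1, 2, 3, 4, 5}
        for _, grp in panel.markers.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_unrelated_markers_pass_hwe(self):
        panel = simulate_genotypes(PedigreeStructure(0, 0, 500), 2000, seed=7)
        fails = 0
        for k in range(panel.n_markers):
            d = panel.dosages[:, k]
            _, p = hwe_test(int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum()))
            fails += p <= 1e-6
        assert fails / panel.n_markers <= 0.001

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PedigreeStructure(0, 5, 0)
        with pytest.raises(ValueError, match="maf_range"):
            simulate_genotypes(PedigreeStructure(1, 1), 10, maf_range=(0.001, 0.5))


class TestPolygenicTrait:
    def test_zero_genetic_variance_leaves_residual_variance(self):
        panel = simulate_genotypes(PedigreeStructure(0, 0, 650), 300, seed=8)
        grm = build_grm(panel)
        truth = SimTruth(sigma_a2=0.0, sigma_e2=2.0)
        trait = simulate_polygenic_trait(grm, intercept_design(panel.sample_ids),
                                         truth, seed=9)
        assert trait.values.var() == pytest.approx(2.0, rel=0.2)

    def test_pure_genetic_draw_reproduces_grm_covariance(self):
        # with sigma_e -> 0, replicate draws have sample covariance sigma_a2 * G
        rng_seeds = range(400)
        panel = simulate_genotypes(PedigreeStructure(4, 5), 400, seed=10)
        grm = build_grm(panel)
        truth = SimTruth(sigma_a2=1.0, sigma_e2=1e-8)
        draws = np.stack([
            simulate_polygenic_trait(grm, intercept_design(panel.sample_ids),
                                     truth, seed=s).values.to_numpy()
            for s in rng_seeds])
        emp = np.cov(draws, rowvar=False)
        assert np.abs(emp - grm.g).mean() < 0.15

    def test_variance_bookkeeping(self):
        panel = simulate_genotypes(PedigreeStructure(0, 0, 1000), 2000, seed=11)
        grm = build_grm(panel)
        truth = SimTruth(sigma_a2=0.6, sigma_e2=1.4)
        totals = [simulate_polygenic_trait(grm, intercept_design(panel.sample_ids),
                                           truth, seed=12 + s).values.var()
                  for s in range(5)]
        assert np.mean(totals) == pytest.approx(2.0, rel=0.08)

    def test_truth_invariants(self):
        truth = SimTruth(sigma_a2=1.0, sigma_e2=3.0)
        assert truth.true_h2 == pytest.approx(0.25, abs=1e-12)
        with pytest.raises(ValueError, match="inconsistent"):
            SimTruth(true_h2=0.5, sigma_a2=1.0, sigma_e2=3.0)
        with pytest.raises(ValueError, match="correlation"):
            SimTruth(basis_correlations={(0, 1): 1.5})


class TestQtlTrait:
    @pytest.fixture(scope="class")
    def small(self):
        panel = simulate_genotypes(PedigreeStructure(10, 10), 300, seed=13)
        return panel, build_grm(panel)

    def test_zero_fraction_reduces_to_polygenic(self, small):
        panel, grm = small
        truth = SimTruth(sigma_a2=0.3, sigma_e2=0.7)
        qtl = simulate_qtl_trait(panel, grm, panel.marker_ids[0], 0.0, truth, seed=14)
        poly = simulate_polygenic_trait(grm, intercept_design(panel.sample_ids),
                                        truth, seed=14)
        pd.testing.assert_series_equal(qtl.values, poly.values)

    def test_causal_marker_explains_requested_variance(self, small):
        panel, grm = small
        shares = []
        for s in range(30):
            truth = SimTruth(sigma_a2=0.2, sigma_e2=0.8)
            trait = simulate_qtl_trait(panel, grm, panel.marker_ids[5], 0.2, truth, seed=s)
            g = panel.dosages[:, 5]
            beta = truth.causal_betas[0]
            shares.append(beta**2 * g.var() / trait.values.var())
        assert np.mean(shares) == pytest.approx(0.2, abs=0.05)

    def test_effect_sign_flip_mirrors_beta(self, small):
        panel, grm = small
        up = SimTruth(sigma_a2=0.2, sigma_e2=0.8, causal_betas=[1.0])
        down = SimTruth(sigma_a2=0.2, sigma_e2=0.8, causal_betas=[-1.0])
        a = simulate_qtl_trait(panel, grm, panel.marker_ids[3], 0.1, up, seed=15)
        b = simulate_qtl_trait(panel, grm, panel.marker_ids[3], 0.1, down, seed=15)
        assert up.causal_betas[0] == pytest.approx(-down.causal_betas[0])
        g = panel.dosages[:, 3]
        centered = g - g.mean()
        np.testing.assert_allclose(a.values - b.values, 2 * up.causal_betas[0] * centered,
                                   atol=1e-10)

    def test_monomorphic_causal_marker_rejected(self, small):
        panel, grm = small
        mono = panel.subset_markers(panel.marker_ids)
        mono.dosages[:, 2] = 2.0
        truth = SimTruth(sigma_a2=0.2, sigma_e2=0.8)
        with pytest.raises(ValueError, match="monomorphic"):
            simulate_qtl_trait(mono, grm, mono.marker_ids[2], 0.1, truth, seed=16)


class TestCountTable:
    def test_rows_sum_to_depth_exactly(self):
        table, _ = simulate_count_table(30, 15, 500, seed=17)
        assert (table.totals() == 500).all()
        assert isinstance(table, TaxonCountTable)

    def test_seed_determinism(self):
        a, _ = simulate_count_table(10, 12, 200, seed=18)
        b, _ = simulate_count_table(10, 12, 200, seed=18)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_non_positive_definite_correlations_rejected(self):
        bad = {(0, 1): 0.9, (1, 2): 0.9, (0, 2): -0.9}
        with pytest.raises(ValueError, match="positive definite"):
            simulate_count_table(20, 10, 100, basis_correlations=bad, seed=19)

    def test_minimum_taxa_enforced(self):
        with pytest.raises(ValueError, match="10 taxa"):
            simulate_count_table(20, 5, 100, seed=20)

    def test_truth_records_planted_pairs(self):
        _, truth = simulate_count_table(20, 12, 100,
                                        basis_correlations={(0, 3): 0.7}, seed=21)
        assert truth.basis_correlations == {("taxon001", "taxon004"): 0.7}


def test_metadata_has_requested_structure():
    meta = simulate_metadata([f"s{i}" for i in range(100)], seed=22)
    assert meta["breed"].nunique() == 3
    assert meta["sex"].nunique() == 3
    assert meta["diet"].nunique() == 4
    assert meta["age"].between(200, 400).all()


def test_parameter_recovery_of_simulated_heritability(cohort):
    """End-to-end consistency: traits simulated at h2 = 0.25 are recovered
    by the REML animal model without systematic bias."""
    truth = SimTruth(sigma_a2=0.25, sigma_e2=0.75)
    est = []
    for seed in range(8):
        trait = simulate_polygenic_trait(cohort["grm"], cohort["design"], truth,
                                         seed=100 + seed)
        est.append(varcomp.fit_animal_model(trait, cohort["design"], cohort["grm"]).h2)
    assert abs(np.mean(est) - 0.25) < 0.12  # n=200 cohort: generous Monte-Carlo band
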