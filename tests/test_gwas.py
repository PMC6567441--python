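import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microherit import synthdata
from microherit.features import TraitVector
from microherit.gwas import (
    adjust_phenotype,
    bh_fdr,
    classify_association,
    gwas_eligible,
    mixed_model_scan,
)
from microherit.varcomp import FixedEffectsDesign, RemlFit


def brute_force_bh(p):
    """Step-up BH by direct evaluation: q_(i) = min_{j>=i} p_(j) * n / j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestAdjustPhenotype:
    def test_exact_linear_combination_gives_zero_residuals(self, cohort):
        design = cohort["design"]
        y = design.x @ np.arange(1.0, design.x.shape[1] + 1)
        trait = TraitVector(pd.Series(y, index=design.sample_ids))
        adj = adjust_phenotype(trait, design)
        np.testing.assert_allclose(adj.dropna().to_numpy(), 0.0, atol=1e-8)

    def test_intercept_only_mean_centers(self, rng):
        ids = [f"s{i}" for i in range(20)]
        design = FixedEffectsDesign(ids, np.ones((20, 1)), ["intercept"])
        y = pd.Series(rng.normal(5, 1, 20), index=ids)
        adj = adjust_phenotype(TraitVector(y), design)
        np.testing.assert_allclose(adj.dropna().to_numpy(), (y - y.mean()).to_numpy(),
                                   atol=1e-10)

    def test_one_factor_equals_group_mean_centering(self):
        ids = list("abcdef")
        groups = ["g1", "g1", "g1", "g2", "g2", "g2"]
        x = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        design = FixedEffectsDesign(ids, x, ["intercept", "group[g2]"])
        y = pd.Series([1.0, 2.0, 3.0, 10.0, 12.0, 14.0], index=ids)
        adj = adjust_phenotype(TraitVector(y), design)
        expected = y - y.groupby(groups).transform("mean").to_numpy()
        np.testing.assert_allclose(adj.values.to_numpy(), expected.to_numpy(), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, cohort, rng):
        design = cohort["design"]
        y = pd.Series(rng.normal(size=len(design.sample_ids)), index=design.sample_ids)
        adj = adjust_phenotype(TraitVector(y), design)
        proj = design.x.T @ adj.dropna().reindex(design.sample_ids).to_numpy()
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_degenerate_cases(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])
        assert bh_fdr([]).size == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    def test_matches_brute_force_and_is_monotone(self, pvals):
        q = bh_fdr(pvals)
        np.testing.assert_allclose(q, brute_force_bh(pvals), atol=1e-12)
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # monotone in order statistics
        assert (q >= p - 1e-12).all()


class TestClassification:
    @pytest.mark.parametrize("fdr, tier", [
        (0.006, "significant"), (0.17, "suggestive"), (0.25, "none"),
        (0.1, "none"), (0.2, "none"), (0.099, "significant"), (0.199, "suggestive"),
    ])
    def test_tiers_with_strict_boundaries(self, fdr, tier):
        assert classify_association(fdr) == tier

    @pytest.mark.parametrize("h2, eligible", [(0.12, True), (0.05, False), (0.1, True)])
    def test_scan_eligibility_threshold_inclusive(self, h2, eligible):
        fit = RemlFit(sigma_a2=h2, sigma_e2=1 - h2, h2=h2, se_h2=0.05, loglik_reml=0.0,
                      n_used=100, converged=True, boundary=False)
        assert gwas_eligible(fit) is eligible


class TestMixedModelScan:
    def _adjusted_trait(self, cohort, rng):
        ids = cohort["panel"].sample_ids
        y = rng.standard_normal(len(ids))
        return TraitVector(pd.Series(y - y.mean(), index=ids))

    def test_zero_genetic_variance_reduces_to_ols(self, cohort, rng):
        trait = self._adjusted_trait(cohort, rng)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:50])
        scan = mixed_model_scan(trait, panel, cohort["grm"],
                                variance_components=(0.0, 1.0))
        y = trait.values.reindex(panel.sample_ids).to_numpy()
        for mid in panel.marker_ids[:10]:
            j = panel.markers.index.get_loc(mid)
            ols = stats.linregress(panel.dosages[:, j] - 1.0, y)
            row = scan.set_index("marker_id").loc[mid]
            assert row["beta"] == pytest.approx(ols.slope, abs=1e-8)
            assert row["p_value"] == pytest.approx(ols.pvalue, abs=1e-8)

    def test_genotype_recoding_flips_beta_only(self, cohort, rng):
        trait = self._adjusted_trait(cohort, rng)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:30])
        flipped = panel.subset_markers(panel.marker_ids)
        flipped.dosages = 2.0 - flipped.dosages
        a = mixed_model_scan(trait, panel, cohort["grm"]).set_index("marker_id")
        b = mixed_model_scan(trait, flipped, cohort["grm"]).set_index("marker_id")
        np.testing.assert_allclose(a["beta"], -b["beta"], atol=1e-10)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-10)

    def test_monomorphic_marker_flagged_not_tested(self, cohort, rng):
        trait = self._adjusted_trait(cohort, rng)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:10])
        panel.dosages[:, 0] = 2.0
        scan = mixed_model_scan(trait, panel, cohort["grm"]).set_index("marker_id")
        row = scan.loc[panel.marker_ids[0]]
        assert bool(row["monomorphic"])
        assert row["p_value"] == 1.0 and row["beta"] == 0.0

    def test_unmapped_markers_excluded_from_scan(self, cohort, rng):
        trait = self._adjusted_trait(cohort, rng)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:20])
        panel.markers.loc[panel.marker_ids[0], "pos"] = np.nan
        scan = mixed_model_scan(trait, panel, cohort["grm"])
        assert panel.marker_ids[0] not in set(scan["marker_id"])
        assert len(scan) == 19

    def test_p3d_and_exact_agree_in_rank(self, cohort):
        truth = synthdata.SimTruth(sigma_a2=0.3, sigma_e2=0.7)
        trait = synthdata.simulate_polygenic_trait(
            cohort["grm"],
            FixedEffectsDesign(cohort["panel"].sample_ids,
                               np.ones((cohort["panel"].n_samples, 1)), ["intercept"]),
            truth, seed=77)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:60])
        p3d = mixed_model_scan(trait, panel, cohort["grm"], mode="P3D")
        exact = mixed_model_scan(trait, panel, cohort["grm"], mode="exact")
        rho = stats.spearmanr(p3d["p_value"], exact["p_value"]).statistic
        assert rho > 0.99

    def test_records_sorted_by_chromosome_and_position(self, cohort, rng):
        trait = self._adjusted_trait(cohort, rng)
        panel = cohort["panel"].subset_markers(cohort["panel"].marker_ids[:100])
        scan = mixed_model_scan(trait, panel, cohort["grm"])
        key = list(zip(scan["chromosome"], scan["position"]))
        assert key == sorted(key)
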