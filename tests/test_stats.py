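"""Two-group inference: t tests, effect sizes, chi-square, FDR, voxelwise
maps and cluster extraction."""

import numpy as np
import pytest
from scipy import stats as sps

from plp import reference
from plp.atlas import make_fixture_atlas, network_mask
from plp.stats import (
    StatMap,
    chi_square_2x2,
    cohens_d,
    extract_clusters,
    fdr_bh,
    region_comparison,
    two_sample_t,
    voxelwise_comparison,
)

from conftest import make_cohort_from_matrix


class TestTwoSampleT:
    def test_identical_samples_give_zero(self):
        t, df, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_pooled_formula(self):
        """Independent oracle: the pooled-variance formula written out."""
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_hand = 2 * sps.t.sf(abs(t_hand), n1 + n2 - 2)
        t, df, p = two_sample_t(x, y)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == n1 + n2 - 2
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 5, 10)
        tp, dfp, _ = two_sample_t(x, y, variant="pooled")
        tw, dfw, _ = two_sample_t(x, y, variant="welch")
        assert dfw < dfp
        assert tp != tw

    def test_null_rejection_rate_calibrated(self):
        """Both groups N(1.0, 0.08^2) at n=174/206: alpha=0.05 rejection
        rate over 2000 replicates lies in [0.04, 0.06]."""
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(1.0, 0.08, 174)
            y = rng.normal(1.0, 0.08, 206)
            _, _, p = two_sample_t(x, y)
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            two_sample_t([1.0, 1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError, match="at least 2"):
            two_sample_t([1.0], [1.0, 2.0])


class TestCohensD:
    @pytest.mark.parametrize(
        "m1,s1,m2,s2,expected",
        [
            (0.862, 0.079, 0.814, 0.083, 0.59),   # patient hypermetabolic region
            (1.109, 0.070, 1.080, 0.064, 0.43),
            (1.126, 0.051, 1.141, 0.044, -0.32),  # hypometabolic: signed
        ],
    )
    def test_published_worked_examples(self, m1, s1, m2, s2, expected):
        assert cohens_d(m1, s1, 174, m2, s2, 206) == pytest.approx(expected, abs=0.01)

    def test_equal_means_give_zero(self):
        assert cohens_d(1.0, 0.1, 20, 1.0, 0.2, 30) == 0.0

    def test_full_published_table_regression(self):
        """Every published |d| is reproduced from its printed means/SDs
        at n=174/206 to within the printing tolerance."""
        for row in reference.REGION_STATS.itertuples(index=False):
            d = cohens_d(row.mean_csvd, row.sd_csvd, 174, row.mean_hc, row.sd_hc, 206)
            assert abs(abs(d) - row.d_printed) <= 0.02, row.label

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 10, 1.0, 0.0, 10)
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.1, 1, 1.0, 0.1, 10)


class TestChiSquare:
    def test_identical_proportions(self):
        stat, p = chi_square_2x2([[20, 80], [40, 160]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_pearson_matches_closed_form(self):
        """Published hypertension counts: hand-computed Pearson statistic."""
        a, b, c, d = 52.0, 122.0, 39.0, 167.0
        n = a + b + c + d
        stat_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, p = chi_square_2x2([[52, 122], [39, 167]])
        assert stat == pytest.approx(stat_hand, abs=1e-10)
        assert p == pytest.approx(sps.chi2.sf(stat_hand, 1), abs=1e-12)

    def test_exact_matches_hypergeometric_enumeration(self):
        """Fisher's exact p equals the sum of hypergeometric probabilities
        of tables at least as extreme (enumeration oracle)."""
        table = np.array([[52, 122], [39, 167]])
        n1, n2 = table[0].sum(), table[1].sum()
        k = table[:, 0].sum()
        obs_p = sps.hypergeom.pmf(table[0, 0], n1 + n2, k, n1)
        total = sum(
            sps.hypergeom.pmf(x, n1 + n2, k, n1)
            for x in range(max(0, k - n2), min(k, n1) + 1)
            if sps.hypergeom.pmf(x, n1 + n2, k, n1) <= obs_p * (1 + 1e-9)
        )
        _, p_exact = chi_square_2x2(table, correction="exact")
        assert p_exact == pytest.approx(total, rel=1e-8)

    @pytest.mark.parametrize("table", [[[52, 122], [39, 167]], [[5, 10], [12, 3]], [[30, 30], [20, 40]]])
    def test_yates_never_exceeds_pearson(self, table):
        stat_none, _ = chi_square_2x2(table, correction="none")
        stat_yates, _ = chi_square_2x2(table, correction="yates")
        assert stat_yates <= stat_none

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 10]])


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )
        # second hand-worked vector: q_i = min_{j>=i} p_(j) * m / j
        np.testing.assert_allclose(
            fdr_bh([0.005, 0.04, 0.03, 0.10]),
            [0.02, 0.053333333, 0.053333333, 0.10],
            atol=1e-8,
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), 0.2, atol=1e-12)

    def test_q_dominates_p_and_preserves_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 40)
        q = fdr_bh(p)
        assert (q >= p - 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()
        # order preservation
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        # adjustment can only grow values on re-application, and is a
        # fixed point on flat vectors
        assert (fdr_bh(q) >= q - 1e-12).all()
        np.testing.assert_allclose(fdr_bh([0.04, 0.04, 0.04, 0.04]), 0.04, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestRegionComparison:
    def test_duplicated_group_gives_null_results(self, atlas, cohort):
        X = cohort.group_suv("CSVD").to_numpy()
        c = make_cohort_from_matrix(X, X, list(cohort.suv.columns))
        table = region_comparison(c, atlas)
        np.testing.assert_allclose(table.p, 1.0, atol=1e-12)
        np.testing.assert_allclose(table.cohens_d, 0.0, atol=1e-12)

    def test_layout_and_fdr_families(self, atlas, cohort):
        table = region_comparison(cohort, atlas)
        assert table.is_network_row.sum() == 7
        assert (~table.is_network_row).sum() == len(atlas.regions)
        assert (table.q >= table.p - 1e-12).all()
        # q within a family depends only on that family's p-values
        fam = table[(table.scope == "visual") & ~table.is_network_row]
        np.testing.assert_allclose(fam.q.to_numpy(), fdr_bh(fam.p.to_numpy()), atol=1e-12)

    def test_sign_convention_patients_first(self, atlas, cohort):
        table = region_comparison(cohort, atlas)
        sign_t = np.sign(table.t)
        sign_diff = np.sign(table.mean1 - table.mean2)
        np.testing.assert_array_equal(sign_t, sign_diff)

    def test_injected_effect_size_recovery(self, atlas):
        """Cohorts generated with the published trunk-region means/SDs
        recover the generating Cohen's D on average within +-0.15."""
        from plp.cohort import CohortDesign, simulate_cohort

        gen_d = cohens_d(0.862, 0.079, 174, 0.814, 0.083, 206)
        estimates = []
        for i in range(100):
            d = CohortDesign(
                regions=["R"],
                region_network={"R": "somatomotor"},
                baseline_means={"R": 0.814},
                baseline_sds={"R": 0.081},
                point_effects=[("R", "CSVD", 0.048)],
                seed=20_000 + i,
            )
            c = simulate_cohort(d)
            x, y = c.group_suv("CSVD")["R"], c.group_suv("HC")["R"]
            estimates.append(
                cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
            )
        assert abs(np.mean(estimates) - gen_d) < 0.15


class TestVoxelwise:
    def test_single_voxel_reduces_to_t_test(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(1.0, 0.1, 12)
        V = vals.reshape(12, 1, 1, 1)
        labels = np.array(["P"] * 5 + ["C"] * 7)
        mask = np.ones((1, 1, 1), dtype=bool)
        sm = voxelwise_comparison(V, labels, mask)
        t, df, _ = two_sample_t(vals[:5], vals[5:])
        assert sm.t[0, 0, 0] == pytest.approx(t, abs=1e-12)
        assert sm.df == df

    def test_null_has_no_suprathreshold_voxels(self):
        """Identical group distributions: median FDR-surviving voxel count
        over 20 replicates is 0."""
        rng = np.random.default_rng(7)
        mask = np.ones((8, 8, 8), dtype=bool)
        labels = np.array(["P"] * 30 + ["C"] * 30)
        counts = []
        for _ in range(20):
            V = rng.normal(1.0, 0.1, (60, 8, 8, 8))
            pos, neg = voxelwise_comparison(V, labels, mask).significance_masks(0.05)
            counts.append(int(pos.sum() + neg.sum()))
        assert np.median(counts) == 0

    def test_painted_effect_detected_with_positive_sign(self):
        """A +0.6 pooled-SD shift painted into one region is recovered in
        >= 80% of that region's voxels across 10 replicates."""
        rng = np.random.default_rng(8)
        atlas = make_fixture_atlas(seed=1)
        region = atlas.regions_in_network("somatomotor")[0]
        rmask = atlas.label_volume == region.id
        nmask = network_mask(atlas, "somatomotor")
        labels = np.array(["P"] * 174 + ["C"] * 206)
        fractions = []
        for _ in range(10):
            V = rng.normal(1.0, 0.1, (380, *atlas.label_volume.shape))
            V[:174, rmask] += 0.06
            pos, neg = voxelwise_comparison(V, labels, nmask).significance_masks(0.05)
            fractions.append(pos[rmask].sum() / rmask.sum())
            assert neg[rmask].sum() == 0
        assert np.mean(fractions) >= 0.8

    def test_region_constant_volumes_match_region_t(self, atlas, cohort):
        """When every region is internally constant, the voxelwise t inside
        a region equals the region-level t (degenerate equality)."""
        from plp.cohort import render_volumes
        from test_cohort import _subset

        sub = cohort.subjects[:6] + cohort.subjects[-6:]
        c = _subset(cohort, sub)
        vols = render_volumes(c, atlas, voxel_noise_sd=0.0, fwhm_mm=0.0)
        V = np.stack([vols[s] for s in sub])
        nmask = network_mask(atlas, "somatomotor")
        sm = voxelwise_comparison(V, c.group.to_numpy(), nmask)
        for r in atlas.regions_in_network("somatomotor"):
            abbr = r.abbreviation
            t_region, _, _ = two_sample_t(
                c.group_suv("CSVD")[abbr], c.group_suv("HC")[abbr]
            )
            rmask = atlas.label_volume == r.id
            np.testing.assert_allclose(sm.t[rmask], t_region, atol=1e-9)

    def test_errors(self):
        V = np.ones((3, 2, 2, 2))
        with pytest.raises(ValueError, match="2 groups"):
            voxelwise_comparison(V, ["a", "a", "a"], np.ones((2, 2, 2), bool))


class TestClusters:
    def _statmap(self, t, mask=None):
        mask = np.ones(t.shape, bool) if mask is None else mask
        return StatMap(t=t, mask=mask, df=100.0)

    def test_empty_mask_gives_empty_list(self):
        t = np.zeros((4, 4, 4))
        recs = extract_clusters(self._statmap(t), np.zeros((4, 4, 4), bool), np.eye(4))
        assert recs == []

    def test_single_voxel_centroid_through_affine(self):
        t = np.zeros((5, 5, 5))
        t[1, 2, 3] = 4.0
        sig = t > 0
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-10, -10, -10]
        (rec,) = extract_clusters(self._statmap(t), sig, affine)
        assert rec.size == 1
        assert rec.centroid_mm == (-8.0, -6.0, -4.0)
        assert rec.peak_t == 4.0

    def test_painted_blobs_recovered_exactly(self):
        """Two disjoint blobs of 25 and 58 voxels: sizes exact, centroids
        at the painted blob centers, sorted largest first."""
        t = np.zeros((20, 20, 20))
        blob_a = np.zeros_like(t, dtype=bool)
        blob_a[2:7, 2:7, 2] = True  # 5x5x1 = 25 voxels
        blob_b = np.zeros_like(t, dtype=bool)
        blob_b[10:13, 10:14, 10:15] = True  # 3x4x5 = 60 ...
        blob_b[12, 13, 13] = False
        blob_b[12, 13, 14] = False  # ... minus 2 = 58 voxels
        assert blob_a.sum() == 25 and blob_b.sum() == 58
        t[blob_a] = 3.0
        t[blob_b] = 4.2
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-20, -20, -20]
        recs = extract_clusters(self._statmap(t), t > 0, affine)
        assert [r.size for r in recs] == [58, 25]
        for rec, blob in zip(recs, (blob_b, blob_a)):
            expected_vox = np.argwhere(blob).mean(axis=0)
            expected_mm = (affine @ np.append(expected_vox, 1))[:3]
            np.testing.assert_allclose(rec.centroid_mm, expected_mm, atol=1e-12)
        assert recs[0].peak_t == 4.2 and recs[1].peak_t == 3.0

    def test_positive_and_negative_clusters_split(self):
        t = np.zeros((6, 6, 6))
        t[0:2, 0:2, 0:2] = 3.0
        t[4:6, 4:6, 4:6] = -3.0
        sig = t != 0
        recs = extract_clusters(self._statmap(t), sig, np.eye(4))
        assert len(recs) == 2
        assert {r.peak_t for r in recs} == {3.0, -3.0}

    def test_diagonal_touching_voxels_join_with_26_connectivity(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = 2.0
        t[1, 1, 1] = 2.5
        recs = extract_clusters(self._statmap(t), t > 0, np.eye(4))
        assert len(recs) == 1
        assert recs[0].size == 2

    def test_mask_containment_enforced(self):
        t = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[0] = True
        sig = np.ones((3, 3, 3), bool)
        with pytest.raises(ValueError, match="outside"):
            extract_clusters(self._statmap(t, mask), sig, np.eye(4))
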