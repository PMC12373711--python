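"""Synthetic cohort generator: determinism, calibration, effect injection,
covariance structure, and volume rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from plp.cohort import CohortDesign, default_design, render_volumes, simulate_cohort
from plp.suv import roi_suvmean, smooth_volume

from conftest import null_design


class TestSimulateCohort:
    def test_seed_determinism(self, atlas):
        d = default_design(atlas, seed=5)
        a = simulate_cohort(d)
        b = simulate_cohort(d)
        assert a.suv.equals(b.suv)
        assert a.covariates.equals(b.covariates)
        assert list(a.group) == list(b.group)

    def test_group_sizes_and_positivity(self, cohort):
        assert (cohort.group == "CSVD").sum() == 174
        assert (cohort.group == "HC").sum() == 206
        assert (cohort.suv.to_numpy() > 0).all()

    def test_null_design_means_near_baseline(self, atlas):
        """Law-of-large-numbers bound: sample means within 4 SD/sqrt(n)."""
        d = null_design(atlas, seed=2, rho=0.0)
        c = simulate_cohort(d)
        for label, n in zip(d.group_labels, d.n_per_group):
            sub = c.group_suv(label)
            for r in d.regions:
                bound = 4 * d.baseline_sds[r] / np.sqrt(n)
                assert abs(sub[r].mean() - d.baseline_means[r]) < bound

    def test_point_effect_power(self, atlas):
        """A +0.048 SUV shift (baseline SD 0.083) at n=174/206 is detected
        by the region t test in at least 95% of replicates."""
        base = null_design(atlas, rho=0.0)
        region = base.regions[0]
        rejections = 0
        reps = 200
        for i in range(reps):
            d = CohortDesign(
                regions=[region],
                region_network={region: base.region_network[region]},
                baseline_means={region: 0.814},
                baseline_sds={region: 0.083},
                point_effects=[(region, "CSVD", 0.048)],
                seed=10_000 + i,
            )
            c = simulate_cohort(d)
            t, p = sps.ttest_ind(c.group_suv("CSVD")[region], c.group_suv("HC")[region])
            rejections += p < 0.05
        assert rejections / reps >= 0.95

    def test_edge_effect_targets_only_its_entry(self, atlas):
        """An edge override changes the targeted correlation, leaves other
        within-network correlations and all means at their design values."""
        base = null_design(atlas, seed=8, rho=0.3, n_per_group=(800, 800))
        dorsal = [r for r in base.regions if base.region_network[r] == "dorsal_attention"]
        d = CohortDesign(
            regions=base.regions,
            region_network=base.region_network,
            baseline_means=base.baseline_means,
            baseline_sds=base.baseline_sds,
            n_per_group=(800, 800),
            network_correlation=0.3,
            edge_effects=[(dorsal[0], dorsal[1], "CSVD", 0.8)],
            seed=8,
        )
        c = simulate_cohort(d)
        r_target = np.corrcoef(c.group_suv("CSVD")[dorsal[0]], c.group_suv("CSVD")[dorsal[1]])[0, 1]
        r_control = np.corrcoef(c.group_suv("HC")[dorsal[0]], c.group_suv("HC")[dorsal[1]])[0, 1]
        assert abs(r_target - 0.8) < 0.05
        assert abs(r_control - 0.3) < 0.12
        # untouched network block keeps its baseline correlation
        visual = [r for r in base.regions if base.region_network[r] == "visual"]
        r_vis = np.corrcoef(c.group_suv("CSVD")[visual[0]], c.group_suv("CSVD")[visual[1]])[0, 1]
        assert abs(r_vis - 0.3) < 0.12
        for r in d.regions:
            assert abs(c.group_suv("CSVD")[r].mean() - d.baseline_means[r]) < 4 * d.baseline_sds[r] / np.sqrt(800)

    def test_nonpd_target_is_repaired_with_warning(self, atlas, caplog):
        """Contradictory correlation targets trigger eigenvalue-clipping
        repair (logged), never a silent invalid draw."""
        base = null_design(atlas, rho=0.9)
        visual = [r for r in base.regions if base.region_network[r] == "visual"]
        # an anticorrelated pair whose members both correlate 0.9 with a
        # third block is geometrically impossible -> non-PD target
        d2 = CohortDesign(
            regions=visual + [r for r in base.regions if base.region_network[r] == "default"],
            region_network=base.region_network,
            baseline_means=base.baseline_means,
            baseline_sds=base.baseline_sds,
            network_correlation=0.95,
            global_correlation=0.9,
            edge_effects=[(visual[0], visual[1], "CSVD", -0.95)],
            n_per_group=(50, 50),
            seed=1,
        )
        with caplog.at_level("WARNING", logger="plp.cohort"):
            c = simulate_cohort(d2)
        assert any("positive definite" in r.message for r in caplog.records)
        assert np.isfinite(c.suv.to_numpy()).all()

    def test_design_validation(self, atlas):
        base = null_design(atlas)
        with pytest.raises(ValueError, match="SD"):
            CohortDesign(
                regions=["A"],
                region_network={"A": "visual"},
                baseline_means={"A": 1.0},
                baseline_sds={"A": 0.0},
            )
        with pytest.raises(ValueError, match="unknown region"):
            CohortDesign(
                regions=base.regions,
                region_network=base.region_network,
                baseline_means=base.baseline_means,
                baseline_sds=base.baseline_sds,
                point_effects=[("nope", "CSVD", 0.1)],
            )

    def test_design_dict_roundtrip(self, study_design):
        rebuilt = CohortDesign.from_dict(study_design.to_dict())
        assert rebuilt == study_design


class TestRenderVolumes:
    def test_noiseless_rendering_roundtrips_exactly(self, atlas, cohort):
        sub = cohort.subjects[:3]
        small = cohort.suv.loc[sub]
        vols = render_volumes(_subset(cohort, sub), atlas, voxel_noise_sd=0.0, fwhm_mm=0.0)
        for s in sub:
            got = roi_suvmean(vols[s], atlas)
            np.testing.assert_allclose(got.to_numpy(), small.loc[s].to_numpy(), atol=1e-12)

    def test_noisy_rendering_is_unbiased(self, atlas, cohort):
        """ROI re-extraction error is bounded by the voxel-noise standard
        error 3 * sd / sqrt(voxels in region)."""
        sub = cohort.subjects[:5]
        vols = render_volumes(_subset(cohort, sub), atlas, voxel_noise_sd=0.05, fwhm_mm=0.0, seed=3)
        for s in sub:
            got = roi_suvmean(vols[s], atlas)
            for r in atlas.regions:
                bound = 3 * 0.05 / np.sqrt(atlas.voxel_counts[r.id])
                assert abs(got[r.abbreviation] - cohort.suv.at[s, r.abbreviation]) < bound

    def test_smoothing_gives_gaussian_profile(self):
        """A 10 mm FWHM kernel on a delta image produces a Gaussian with
        sigma = 10/2.3548 mm along each axis."""
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        out = smooth_volume(vol, 10.0, np.eye(4))  # 1 mm voxels
        sigma = 10.0 / (2 * np.sqrt(2 * np.log(2)))
        profile = out[20:, 20, 20]
        expected = profile[0] * np.exp(-np.arange(len(profile)) ** 2 / (2 * sigma**2))
        np.testing.assert_allclose(profile[:12], expected[:12], rtol=1e-3)

    def test_unknown_region_errors(self, atlas, cohort):
        c = _subset(cohort, cohort.subjects[:2])
        c.suv = c.suv.rename(columns={c.suv.columns[0]: "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            render_volumes(c, atlas)


def _subset(cohort, subjects):
    import copy

    c = copy.copy(cohort)
    c.subjects = list(subjects)
    c.group = cohort.group.loc[subjects]
    c.covariates = cohort.covariates.loc[subjects]
    c.suv = cohort.suv.loc[subjects]
    return c
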