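import itertools

import numpy as np
import pytest
from scipy import stats

from falff.inference import (
    GroupDesign,
    StatMap,
    binarize_map,
    cohens_d_from_summary,
    dice,
    extract_clusters,
    fwe_threshold,
    required_sample_size,
    summary_ci,
    voxelwise_group_ttest,
)


def make_design(rng, n_per_group=10, n_vox=500, shift=0.0, shift_slice=None,
                covariates=None, voxelwise=None):
    n = 2 * n_per_group
    maps = rng.normal(size=(n, n_vox))
    group = np.repeat([0, 1], n_per_group)
    if shift:
        sl = shift_slice if shift_slice is not None else slice(None)
        maps[group == 1, sl] += shift
    mask = np.ones((n_vox, 1, 1), dtype=bool)
    return GroupDesign(maps=maps, group=group, mask=mask, covariates=covariates,
                       voxelwise_covariates=voxelwise or {})


class TestVoxelwiseTtest:
    def test_null_calibration_matches_student_t(self, rng):
        design = make_design(rng, n_per_group=10, n_vox=10_000)
        stat = voxelwise_group_ttest(design, "two-sided")
        t_crit = stats.t.ppf(0.975, stat.df)
        frac = (np.abs(stat.t[design.mask]) > t_crit).mean()
        assert frac == pytest.approx(0.05, abs=0.01)
        assert stat.df == 20 - 2

    def test_planted_block_contains_peak(self, rng):
        design = make_design(rng, n_per_group=15, n_vox=2000, shift=1.0,
                             shift_slice=slice(100, 150))
        stat = voxelwise_group_ttest(design, "group2>group1")
        peak = np.nanargmax(stat.t[design.mask])
        assert 100 <= peak < 150

    def test_direction_flips_sign(self, rng):
        design = make_design(rng, n_vox=50)
        t_fwd = voxelwise_group_ttest(design, "group2>group1").t
        t_rev = voxelwise_group_ttest(design, "group1>group2").t
        np.testing.assert_allclose(t_rev, -t_fwd)

    def test_covariate_equal_to_group_raises_collinearity(self, rng):
        cov = np.repeat([0.0, 1.0], 10)[:, None]
        design = make_design(rng, covariates=cov)
        with pytest.raises(ValueError, match="collinear.*cov0"):
            voxelwise_group_ttest(design)

    def test_voxelwise_covariates_match_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n, n_vox = 24, 10
        vc = rng.normal(size=(n, n_vox))
        design = make_design(rng, n_per_group=12, n_vox=n_vox,
                             covariates=rng.normal(size=(n, 1)),
                             voxelwise={"gm": vc})
        stat = voxelwise_group_ttest(design, "two-sided")
        flat_t = stat.t[design.mask]
        for v in range(n_vox):
            x = sm.add_constant(np.column_stack([
                design.group, design.covariates[:, 0], vc[:, v]
            ]))
            fit = sm.OLS(design.maps[:, v], x).fit()
            assert flat_t[v] == pytest.approx(fit.tvalues[1], rel=1e-8)

    def test_covariate_absorbs_planted_confound(self, rng):
        # group 2 differs only through a confound; adjusting for it removes
        # every would-be detection
        n_per, n_vox = 15, 800
        confound = np.concatenate([rng.normal(0, 1, n_per), rng.normal(4, 1, n_per)])
        maps = rng.normal(size=(2 * n_per, n_vox)) + confound[:, None]
        group = np.repeat([0, 1], n_per)
        mask = np.ones((n_vox, 1, 1), bool)
        raw = voxelwise_group_ttest(
            GroupDesign(maps=maps, group=group, mask=mask), "two-sided"
        )
        adj = voxelwise_group_ttest(
            GroupDesign(maps=maps, group=group, mask=mask,
                        covariates=confound[:, None]), "two-sided"
        )
        t_crit = stats.t.ppf(0.9975, raw.df)
        assert (np.abs(raw.t[mask]) > t_crit).mean() > 0.5
        assert (np.abs(adj.t[mask]) > t_crit).mean() < 0.05

    def test_one_sided_directions_mutually_exclusive(self, rng):
        design = make_design(rng, n_vox=300)
        fwd = voxelwise_group_ttest(design, "group2>group1")
        rev = voxelwise_group_ttest(design, "group1>group2")
        both = binarize_map(fwd, 0.05) & binarize_map(rev, 0.05)
        assert not both.any()


class TestFweThreshold:
    def test_threshold_monotone_decreasing_in_alpha(self, rng):
        design = make_design(rng, n_per_group=8, n_vox=200)
        thresholds = [
            fwe_threshold(design, alpha, n_perm=300, seed=1)[0]
            for alpha in (0.01, 0.05, 0.1, 0.2)
        ]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_exhaustive_enumeration_for_small_groups(self, rng, caplog):
        design = make_design(rng, n_per_group=4, n_vox=100)
        with caplog.at_level("WARNING"):
            thr, null = fwe_threshold(design, 0.05, n_perm=1000, seed=0)
        assert len(null) == 70  # C(8, 4)
        assert any("exhaustive" in r.message for r in caplog.records)
        # independent enumeration oracle over all relabelings
        oracle = []
        y = design.maps
        for ones in itertools.combinations(range(8), 4):
            g = np.zeros(8)
            g[list(ones)] = 1
            m1, m0 = y[g == 1].mean(axis=0), y[g == 0].mean(axis=0)
            v1 = y[g == 1].var(axis=0, ddof=1)
            v0 = y[g == 0].var(axis=0, ddof=1)
            sp = np.sqrt(((3 * v1 + 3 * v0) / 6) * (1 / 4 + 1 / 4))
            oracle.append(np.abs((m1 - m0) / sp).max())
        assert thr == pytest.approx(np.quantile(oracle, 0.95, method="higher"), rel=1e-10)

    def test_null_distribution_seed_reproducible(self, rng):
        design = make_design(rng, n_per_group=10, n_vox=100)
        _, null1 = fwe_threshold(design, 0.05, n_perm=200, seed=42)
        _, null2 = fwe_threshold(design, 0.05, n_perm=200, seed=42)
        np.testing.assert_array_equal(null1, null2)


class TestClusters:
    def _stat(self, tmap, df=20):
        mask = np.isfinite(tmap)
        return StatMap(t=tmap, df=df, direction="group2>group1", mask=mask)

    def test_minimum_extent_filter(self):
        tmap = np.zeros((10, 10, 10))
        tmap[1:4, 1:4, 1] = 5.0    # 9 voxels < 10: discarded... make 12
        tmap[1:4, 1:4, 1:2] = 5.0  # 9 voxels
        tmap[1:4, 1:5, 1] = 5.0    # 12 voxels
        tmap[8, 8, 6:10] = 5.0     # 4 voxels, separate
        clusters = extract_clusters(self._stat(tmap), height=2.0, min_extent=10)
        assert clusters.sizes == [12]

    def test_connectivity_semantics_for_diagonal_voxels(self):
        tmap = np.zeros((5, 5, 5))
        tmap[1, 1, 1] = 5.0
        tmap[2, 2, 1] = 5.0  # in-plane diagonal touch
        c26 = extract_clusters(self._stat(tmap), 2.0, min_extent=1, connectivity=26)
        c6 = extract_clusters(self._stat(tmap), 2.0, min_extent=1, connectivity=6)
        assert c26.n_clusters == 1
        assert c6.n_clusters == 2

    def test_empty_suprathreshold_set_allowed(self):
        clusters = extract_clusters(self._stat(np.zeros((4, 4, 4))), 3.0)
        assert clusters.n_clusters == 0
        with pytest.raises(ValueError):
            clusters.largest_mask()

    def test_peak_reported_inside_cluster(self):
        tmap = np.zeros((8, 8, 8))
        tmap[2:5, 2:5, 2:5] = 3.0
        tmap[3, 3, 3] = 9.0
        clusters = extract_clusters(self._stat(tmap), 2.0, min_extent=10)
        assert clusters.peak_coord == [(3, 3, 3)]
        assert clusters.peak_t == [9.0]


class TestSummaryStatistics:
    def test_cohens_d_reproduces_published_cluster_value(self):
        d = cohens_d_from_summary(1.920, 0.829, 61, 1.527, 0.613, 59)
        assert round(d, 2) == 0.54

    def test_cohens_d_trivial_cases(self):
        assert cohens_d_from_summary(1.0, 1.0, 10, 1.0, 1.0, 10) == 0.0
        assert cohens_d_from_summary(1.0, 1.0, 10, 0.0, 1.0, 10) == pytest.approx(1.0)

    def test_ci_zero_sd_and_closed_form(self):
        assert summary_ci(5.0, 0.0, 9) == (5.0, 5.0)
        lo, hi = summary_ci(0.0, 1.0, 4, 0.95)
        assert lo == pytest.approx(-1.959964 / 2, abs=1e-6)
        assert hi == pytest.approx(1.959964 / 2, abs=1e-6)


class TestBinarizeAndDice:
    def test_boundary_exactly_at_critical_value_excluded(self):
        df = 30
        t_crit = stats.t.ppf(0.95, df)
        tmap = np.full((3, 3, 3), t_crit)
        stat = StatMap(t=tmap, df=df, direction="group2>group1",
                       mask=np.ones((3, 3, 3), bool))
        assert not binarize_map(stat, 0.05).any()
        tmap2 = tmap + 1e-9
        stat2 = StatMap(t=tmap2, df=df, direction="group2>group1",
                        mask=np.ones((3, 3, 3), bool))
        assert binarize_map(stat2, 0.05).all()

    def test_zero_map_empty_and_monotone_in_p(self, rng):
        tmap = rng.normal(size=(6, 6, 6))
        stat = StatMap(t=tmap, df=20, direction="group2>group1",
                       mask=np.ones((6, 6, 6), bool))
        zero = StatMap(t=np.zeros((3, 3, 3)), df=20, direction="group2>group1",
                       mask=np.ones((3, 3, 3), bool))
        assert not binarize_map(zero, 0.05).any()
        m1 = binarize_map(stat, 0.01)
        m2 = binarize_map(stat, 0.05)
        assert (m1 <= m2).all()

    def test_dice_values(self):
        a = np.zeros(20, bool)
        b = np.zeros(20, bool)
        a[:10] = True
        b[6:16] = True  # overlap 4, sizes 10 and 10
        assert dice(a, b) == pytest.approx(0.4)
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0

    def test_dice_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.zeros(4, bool), np.zeros(5, bool))


class TestRequiredSampleSize:
    def test_exact_t_search_reference_values(self):
        assert required_sample_size(0.5, 0.8, 0.05, tails=2) == 64
        assert required_sample_size(1.0, 0.8, 0.05, tails=2) == 17

    def test_nonincreasing_in_effect_size(self):
        sizes = [required_sample_size(d) for d in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0)
        with pytest.raises(ValueError):
            required_sample_size(0.5, power=1.5)
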