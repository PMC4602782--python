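"""Group inference: ANOVA/t oracles, smoothness, Monte-Carlo cluster
correction, cluster extraction, ROI summaries."""

import numpy as np
import pytest
from scipy import ndimage, stats

from dmnfc.errors import (
    EmptyRoiError,
    InsufficientSubjectsError,
)
from dmnfc.inference import (
    Cluster,
    ClusterCorrection,
    DesignInfo,
    alphasim_min_extent,
    estimate_smoothness,
    extract_clusters,
    posthoc_t,
    roi_mean,
    voxelwise_anova,
)
from dmnfc.types import BinaryMask, VolumeMap


def _maps(stack):
    """One 1x1xK map per subject row."""
    return [VolumeMap(row.reshape(1, 1, -1), np.eye(4), "z") for row in stack]


def _full_mask(k):
    return BinaryMask(np.ones((1, 1, k), bool), np.eye(4))


def _design(groups, rng=None, age=None, gender=None):
    n = len(groups)
    rng = rng or np.random.default_rng(0)
    return DesignInfo(
        groups=list(groups),
        age_years=age if age is not None else rng.normal(48, 10, n),
        gender=gender if gender is not None else rng.integers(0, 2, n).astype(float),
    )


def brute_force_f(y, groups, age, gender):
    """Independent RSS-based covariate-adjusted ANOVA for one voxel."""
    levels = sorted(set(groups), key=lambda g: (g != "HC", g))
    n = len(y)
    dummies = np.column_stack(
        [[1.0 if g == lev else 0.0 for g in groups] for lev in levels[1:]]
    )
    X_full = np.column_stack([np.ones(n), dummies, age, gender])
    X_red = np.column_stack([np.ones(n), age, gender])
    rss = lambda X: np.sum(
        (y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2
    )
    df1 = len(levels) - 1
    df2 = n - X_full.shape[1]
    f = ((rss(X_red) - rss(X_full)) / df1) / (rss(X_full) / df2)
    return f, stats.f.sf(f, df1, df2)


class TestVoxelwiseAnova:
    def test_identical_values_f_zero_p_one(self):
        stack = np.full((9, 4), 2.5)
        groups = ["HC"] * 3 + ["nonHE"] * 3 + ["MHE"] * 3
        f_map, p_map = voxelwise_anova(_maps(stack), _design(groups), _full_mask(4))
        np.testing.assert_allclose(f_map.data, 0.0)
        np.testing.assert_allclose(p_map.data, 1.0)

    def test_matches_rss_oracle(self):
        rng = np.random.default_rng(0)
        groups = ["HC"] * 4 + ["nonHE"] * 4 + ["MHE"] * 4
        stack = rng.standard_normal((12, 6))
        design = _design(groups, rng)
        f_map, p_map = voxelwise_anova(_maps(stack), design, _full_mask(6))
        for v in range(6):
            f, p = brute_force_f(
                stack[:, v], groups, design.age_years, design.gender
            )
            assert f_map.data[0, 0, v] == pytest.approx(f, abs=1e-8)
            assert p_map.data[0, 0, v] == pytest.approx(p, abs=1e-8)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        groups = ["HC"] * 6 + ["MHE"] * 6
        stack = rng.standard_normal((12, 8))
        design = _design(groups, rng)
        f_map, _ = voxelwise_anova(_maps(stack), design, _full_mask(8))
        t_map, _ = posthoc_t(_maps(stack), design, _full_mask(8))
        np.testing.assert_allclose(f_map.data, t_map.data**2, atol=1e-8)

    def test_missing_voxel_propagates(self):
        rng = np.random.default_rng(2)
        groups = ["HC"] * 3 + ["nonHE"] * 3 + ["MHE"] * 3
        stack = rng.standard_normal((9, 3))
        stack[4, 1] = np.nan
        f_map, _ = voxelwise_anova(_maps(stack), _design(groups), _full_mask(3))
        assert np.isnan(f_map.data[0, 0, 1])
        assert np.isfinite(f_map.data[0, 0, 0])

    def test_small_group_rejected(self):
        groups = ["HC"] * 4 + ["nonHE"] * 4 + ["MHE"]
        stack = np.random.default_rng(3).standard_normal((9, 2))
        with pytest.raises(InsufficientSubjectsError):
            voxelwise_anova(_maps(stack), _design(groups), _full_mask(2))


class TestPosthocT:
    def test_identical_groups_t_zero(self):
        stack = np.tile(np.linspace(0, 1, 5), (8, 1))
        groups = ["HC"] * 4 + ["MHE"] * 4
        design = _design(groups)
        t_map, _ = posthoc_t(_maps(stack), design, _full_mask(5))
        np.testing.assert_allclose(t_map.data, 0.0, atol=1e-10)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        groups = ["HC"] * 10 + ["MHE"] * 10
        stack = rng.standard_normal((20, 4))
        stack[10:] += 0.5
        design = _design(groups, rng)
        t_map, p_map = posthoc_t(_maps(stack), design, _full_mask(4))
        indicator = np.array([0.0] * 10 + [1.0] * 10)
        X = sm.add_constant(
            np.column_stack([indicator, design.age_years, design.gender])
        )
        for v in range(4):
            fit = sm.OLS(stack[:, v], X).fit()
            assert t_map.data[0, 0, v] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert p_map.data[0, 0, v] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_group_swap_flips_sign(self):
        rng = np.random.default_rng(5)
        stack = rng.standard_normal((10, 3))
        age = rng.normal(48, 10, 10)
        gender = rng.integers(0, 2, 10).astype(float)
        g1 = ["HC"] * 5 + ["MHE"] * 5
        g2 = ["MHE"] * 5 + ["HC"] * 5
        t1, _ = posthoc_t(_maps(stack), _design(g1, age=age, gender=gender), _full_mask(3))
        t2, _ = posthoc_t(_maps(stack), _design(g2, age=age, gender=gender), _full_mask(3))
        np.testing.assert_allclose(t1.data, -t2.data, atol=1e-10)


class TestEstimateSmoothness:
    def _residual_maps(self, fields, affine=None):
        return [VolumeMap(f, affine if affine is not None else np.diag([3.0, 3.0, 3.0, 1.0]), "z") for f in fields]

    def test_white_noise_fwhm_near_voxel_size(self):
        rng = np.random.default_rng(6)
        fields = rng.standard_normal((10, 16, 16, 16))
        mask = BinaryMask(np.ones((16, 16, 16), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        fwhm = estimate_smoothness(self._residual_maps(fields), mask, (3.0, 3.0, 3.0))
        # white fields: the estimator floors at the voxel size
        assert all(3.0 <= f < 3.0 * 1.15 for f in fwhm)

    def test_known_kernel_recovered(self):
        rng = np.random.default_rng(7)
        sigma_vox = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        fields = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((20, 20, 20)), sigma_vox)
                for _ in range(10)
            ]
        )
        mask = BinaryMask(np.ones((20, 20, 20), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        fwhm = estimate_smoothness(self._residual_maps(fields), mask, (3.0, 3.0, 3.0))
        for f in fwhm:
            assert f == pytest.approx(8.0, rel=0.2)

    def test_constant_residuals_rejected(self):
        from dmnfc.errors import DegenerateDataError

        fields = np.ones((3, 8, 8, 8))
        mask = BinaryMask(np.ones((8, 8, 8), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        with pytest.raises(DegenerateDataError):
            estimate_smoothness(self._residual_maps(fields), mask, (3.0, 3.0, 3.0))


def independent_alphasim(mask, fwhm_mm, voxel_mm, forming_p, alpha, n_iter, seed):
    """Second implementation of the Monte-Carlo extent threshold, written
    directly from its definition."""
    rng = np.random.default_rng(seed)
    sigma = [f / (2 * np.sqrt(2 * np.log(2))) / v for f, v in zip(fwhm_mm, voxel_mm)]
    zc = stats.norm.isf(forming_p / 2)
    struct = ndimage.generate_binary_structure(3, 3)
    maxima = []
    for _ in range(n_iter):
        f = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma, mode="constant")
        v = f[mask]
        f = (f - v.mean()) / v.std()
        lab, nl = ndimage.label((np.abs(f) > zc) & mask, structure=struct)
        maxima.append(max((np.bincount(lab.ravel())[1:]).max() if nl else 0, 0))
    maxima = np.array(maxima)
    k = 1
    while (maxima >= k).mean() > alpha:
        k += 1
    return k


class TestAlphasim:
    def test_alpha_one_gives_k_one(self):
        mask = BinaryMask(np.ones((8, 8, 8), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        corr = ClusterCorrection(alpha=1.0, n_iterations=100)
        out = alphasim_min_extent(corr, mask, rng_seed=0)
        assert out.min_extent_k == 1

    def test_matches_independent_implementation(self):
        mask = BinaryMask(np.ones((8, 8, 8), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        corr = ClusterCorrection(
            cluster_forming_p=0.05,
            alpha=0.05,
            n_iterations=2000,
            smoothness_fwhm_mm=(3.0, 3.0, 3.0),
        )
        out = alphasim_min_extent(corr, mask, rng_seed=101)
        k_oracle = independent_alphasim(
            mask.data, (3.0, 3.0, 3.0), (3.0, 3.0, 3.0), 0.05, 0.05, 2000, seed=999
        )
        assert abs(out.min_extent_k - k_oracle) <= 1

    def test_k_monotone_in_forming_p(self):
        mask = BinaryMask(np.ones((10, 10, 10), bool), np.diag([3.0, 3.0, 3.0, 1.0]))
        ks = []
        for p in (0.05, 0.01, 0.001):
            corr = ClusterCorrection(
                cluster_forming_p=p,
                n_iterations=400,
                smoothness_fwhm_mm=(6.0, 6.0, 6.0),
            )
            ks.append(alphasim_min_extent(corr, mask, rng_seed=3).min_extent_k)
        assert ks[0] >= ks[1] >= ks[2]


def flood_fill_components(field, connectivity):
    """Brute-force BFS connected components of a boolean field."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(field, bool)
    comps = []
    for idx in np.argwhere(field):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = []
        queue = [idx]
        seen[idx] = True
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(np.add(cur, off))
                if all(0 <= nb[i] < field.shape[i] for i in range(3)):
                    if field[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        comps.append(sorted(comp))
    return sorted(comps)


class TestExtractClusters:
    def _make_maps(self, p_field, stat_field=None):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        stat = stat_field if stat_field is not None else np.ones_like(p_field)
        return (
            VolumeMap(stat, affine, "F"),
            VolumeMap(p_field, affine, "p"),
        )

    def test_empty_suprathreshold(self):
        stat, p = self._make_maps(np.ones((5, 5, 5)))
        assert extract_clusters(stat, p, 0.05, 1) == []

    def test_extent_filter(self):
        p = np.ones((10, 10, 10))
        p[1:5, 1:5, 1:3] = 0.001  # 32-voxel blob... sized below
        p[7:9, 7:9, 7:9] = 0.001  # 8-voxel blob
        stat, pm = self._make_maps(p)
        clusters = extract_clusters(stat, pm, 0.05, 20)
        assert len(clusters) == 1
        assert clusters[0].size == 32

    def test_peak_location_in_mm(self):
        p = np.ones((6, 6, 6))
        p[2, 3, 4] = 0.001
        stat = np.zeros((6, 6, 6))
        stat[2, 3, 4] = 9.0
        smap, pmap = self._make_maps(p, stat)
        (cl,) = extract_clusters(smap, pmap, 0.05, 1)
        assert cl.peak_stat == 9.0
        assert cl.peak_mni_mm == (6.0, 9.0, 12.0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(13)
        for _ in range(5):
            field = rng.random((12, 12, 12)) < 0.3
            p = np.where(field, 0.001, 0.9)
            stat, pmap = self._make_maps(p)
            clusters = extract_clusters(stat, pmap, 0.05, 1, connectivity)
            got = sorted(
                sorted(map(tuple, c.voxel_indices.tolist())) for c in clusters
            )
            expected = flood_fill_components(field, connectivity)
            assert got == expected


class TestRoiMean:
    def _map(self, data):
        return VolumeMap(np.asarray(data, float), np.eye(4), "z")

    def test_uniform(self):
        roi = BinaryMask(np.ones((2, 2, 2), bool), np.eye(4))
        assert roi_mean(self._map(np.full((2, 2, 2), 0.52)), roi) == pytest.approx(0.52)

    def test_two_voxel_mean(self):
        data = np.zeros((1, 1, 3))
        data[0, 0, :2] = [0.4, 0.6]
        roi = BinaryMask(np.array([[[True, True, False]]]), np.eye(4))
        assert roi_mean(self._map(data), roi) == pytest.approx(0.5)

    def test_missing_ignored(self):
        data = np.array([[[0.4, np.nan, 0.8]]])
        roi = BinaryMask(np.ones((1, 1, 3), bool), np.eye(4))
        assert roi_mean(self._map(data), roi) == pytest.approx(0.6)

    def test_all_missing_rejected(self):
        data = np.full((1, 1, 2), np.nan)
        roi = BinaryMask(np.ones((1, 1, 2), bool), np.eye(4))
        with pytest.raises(EmptyRoiError):
            roi_mean(self._map(data), roi)

    def test_cluster_roi(self):
        cl = Cluster(
            voxel_indices=np.array([[0, 0, 0], [0, 0, 1]]),
            size=2,
            peak_stat=1.0,
            peak_mni_mm=(0.0, 0.0, 0.0),
        )
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.2, 0.4, 9.9]
        assert roi_mean(self._map(data), cl) == pytest.approx(0.3)
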