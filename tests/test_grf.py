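import numpy as np
import pytest
from scipy import ndimage

from alffpipe.core import SmoothnessEstimate, TStatResult, VoxelMap
from alffpipe.glm import paired_t, two_sample_t
from alffpipe.grf import (
    cluster_p_grf,
    estimate_smoothness,
    expected_clusters,
    label_clusters,
    make_cluster_table,
    resel_counts,
    z_threshold_from_p,
)
from alffpipe.preprocess import FWHM_TO_SIGMA
from tests.conftest import make_map


def smoothed_noise_map(rng, dims=(24, 24, 24), fwhm_mm=6.0, voxel_mm=3.0):
    sigma_vox = fwhm_mm / (voxel_mm * FWHM_TO_SIGMA)
    f = ndimage.gaussian_filter(rng.standard_normal(dims), sigma_vox, mode="nearest")
    return make_map(f, voxel_size_mm=voxel_mm)


class TestEstimateSmoothness:
    def test_recovers_6mm_fwhm(self):
        # mean estimate over 20 seeds must land in [5.4, 6.6] mm per axis
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            maps = [smoothed_noise_map(rng) for _ in range(4)]
            ests.append(estimate_smoothness(maps).fwhm_mm)
        mean_fwhm = np.mean(ests, axis=0)
        assert np.all(mean_fwhm > 5.4) and np.all(mean_fwhm < 6.6)

    def test_unsmoothed_noise_smaller_than_smoothed(self, rng):
        rough = [make_map(np.random.default_rng(s).standard_normal((16, 16, 16))) for s in range(3)]
        smooth = [smoothed_noise_map(np.random.default_rng(s + 100), (16, 16, 16)) for s in range(3)]
        f_rough = estimate_smoothness(rough).fwhm_mm
        f_smooth = estimate_smoothness(smooth).fwhm_mm
        assert all(r < s for r, s in zip(f_rough, f_smooth))
        # unsmoothed white noise: FWHM on the scale of one voxel (3 mm)
        assert all(1.0 < r < 6.0 for r in f_rough)

    def test_voxel_size_doubling_doubles_fwhm_mm(self, rng):
        vals = [np.random.default_rng(s).standard_normal((12, 12, 12)) for s in range(3)]
        m3 = [make_map(v, voxel_size_mm=3.0) for v in vals]
        m6 = [make_map(v, voxel_size_mm=6.0) for v in vals]
        f3 = estimate_smoothness(m3).fwhm_mm
        f6 = estimate_smoothness(m6).fwhm_mm
        np.testing.assert_allclose(f6, 2.0 * np.asarray(f3), rtol=1e-12)

    def test_flat_residuals_raise(self):
        flat = [make_map(np.full((6, 6, 6), 2.0)) for _ in range(3)]
        with pytest.raises(ValueError):
            estimate_smoothness(flat)

    def test_r3_is_volume_over_fwhm_product(self, rng):
        maps = [smoothed_noise_map(np.random.default_rng(s), (16, 16, 16)) for s in range(3)]
        est = estimate_smoothness(maps)
        # for a full box, the cube count is (n-1)^3
        expected_r3 = 15**3 / np.prod(est.fwhm_vox)
        assert est.resels[3] == pytest.approx(expected_r3, rel=1e-10)
        assert est.resels[3] > 0


class TestReselCounts:
    def test_full_box_counts(self):
        mask = np.ones((4, 4, 4), bool)
        r0, r1, r2, r3 = resel_counts(mask, (2.0, 2.0, 2.0))
        # Euler characteristic of a solid box is 1
        assert r0 == 1
        # R3 = number of 2x2x2 cubes / prod(fwhm) = 27 / 8
        assert r3 == pytest.approx(27 / 8)
        # R1 = 3 * (n-1) / fwhm for a box: edges-faces+cubes telescopes to 3 per axis
        assert r1 == pytest.approx(3 * 3 / 2.0)
        assert r2 == pytest.approx(3 * 9 / 4.0)

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        r = resel_counts(mask, (2.0, 2.0, 2.0))
        assert r == (1.0, 0.0, 0.0, 0.0)

    def test_two_disjoint_voxels_euler_2(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = mask[4, 4, 4] = True
        assert resel_counts(mask, (1.0, 1.0, 1.0))[0] == 2.0


def brute_force_components(binary, connectivity):
    """Flood-fill oracle for connected components."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                dist = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and dist > 1:
                    continue
                if connectivity == 18 and dist > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(binary, bool)
    comps = []
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[i] < dims[i] for i in range(3)) and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def z_map_from(vals, mask=None):
    return make_map(vals, mask=mask, kind="zstat")


class TestLabelClusters:
    def test_all_zero_no_clusters(self):
        z = z_map_from(np.zeros((6, 6, 6)))
        assert label_clusters(z, 0.05, "+") == []

    def test_corner_touch_connectivity(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 1, 1] = vals[2, 2, 2] = 10.0
        z = z_map_from(vals)
        assert len(label_clusters(z, 0.001, "+", connectivity=26)) == 1
        assert len(label_clusters(z, 0.001, "+", connectivity=6)) == 2

    def test_planted_block(self):
        vals = np.zeros((9, 9, 9))
        vals[2:7, 2:7, 2:7] = 10.0
        clusters = label_clusters(z_map_from(vals), 0.001, "+")
        assert len(clusters) == 1
        assert len(clusters[0]) == 125

    def test_negative_sign(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = -10.0
        assert len(label_clusters(z_map_from(vals), 0.001, "-")) == 1
        assert label_clusters(z_map_from(vals), 0.001, "+") == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        u = z_threshold_from_p(0.05, True)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            binary = rng.uniform(size=(12, 12, 12)) < 0.25
            vals = np.where(binary, u + 1.0, 0.0)
            got = {
                frozenset(map(tuple, c))
                for c in label_clusters(z_map_from(vals), 0.05, "+", connectivity)
            }
            assert got == brute_force_components(binary, connectivity)

    def test_mask_respected(self):
        vals = np.full((4, 4, 4), 10.0)
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        clusters = label_clusters(z_map_from(vals, mask=mask), 0.001, "+")
        assert sum(len(c) for c in clusters) == mask.sum()


class TestClusterPGrf:
    est = SmoothnessEstimate(
        fwhm_mm=(6.0, 6.0, 6.0),
        resels=resel_counts(np.ones((20, 20, 20), bool), (2.0, 2.0, 2.0)),
        voxel_size_mm=(3.0, 3.0, 3.0),
    )

    def test_monotone_nonincreasing_in_size(self):
        u = z_threshold_from_p(0.001, True)
        ps = [cluster_p_grf(k, self.est, u, 8000) for k in (1, 5, 20, 80, 320)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_minimal_cluster_near_expected_count_bound(self):
        # very smooth field: a single voxel is far below the typical cluster
        # extent, so P(N >= 1 voxel) ~ 1 and p approaches 1 - exp(-E[m])
        smooth = SmoothnessEstimate(
            fwhm_mm=(18.0, 18.0, 18.0),
            resels=resel_counts(np.ones((20, 20, 20), bool), (6.0, 6.0, 6.0)),
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        u = 3.3
        em = expected_clusters(smooth, u)
        p1 = cluster_p_grf(1, smooth, u, 8000)
        bound = 1 - np.exp(-em)
        assert p1 <= bound + 1e-12
        assert p1 > 0.7 * bound

    def test_increasing_in_smoothness_for_fixed_k(self):
        u = z_threshold_from_p(0.001, True)
        rough = SmoothnessEstimate(
            fwhm_mm=(3.0, 3.0, 3.0),
            resels=resel_counts(np.ones((20, 20, 20), bool), (1.0, 1.0, 1.0)),
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        assert cluster_p_grf(30, self.est, u, 8000) > cluster_p_grf(30, rough, u, 8000)

    def test_bounds_and_errors(self):
        u = 3.0
        p = cluster_p_grf(10, self.est, u, 8000)
        assert 0 < p <= 1
        with pytest.raises(ValueError):
            cluster_p_grf(0, self.est, u, 8000)
        with pytest.raises(ValueError):
            cluster_p_grf(10, self.est, -1.0, 8000)


class TestMakeClusterTable:
    def _null_result(self, rng, n=8, dims=(10, 10, 10)):
        maps_a = [make_map(rng.standard_normal(dims)) for _ in range(n)]
        maps_b = [make_map(rng.standard_normal(dims)) for _ in range(n)]
        return two_sample_t(maps_a, maps_b)

    def test_null_map_empty_table(self, rng):
        res = self._null_result(rng)
        res.t_map.values[:] = 0.0
        sm = estimate_smoothness(res.residual_maps)
        assert make_cluster_table(res, sm) == []

    def test_planted_effect_recovered(self):
        # strong planted effect: one surviving record with peak inside the ROI
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            dims = (14, 14, 10)
            roi = np.zeros(dims, bool)
            roi[5:9, 5:9, 4:7] = True
            pre, post = [], []
            for _ in range(12):
                base = ndimage.gaussian_filter(rng.standard_normal(dims), 0.85, mode="nearest")
                post_v = base + roi * 1.5 + 0.3 * rng.standard_normal(dims)
                pre.append(make_map(base))
                post.append(make_map(post_v))
            res = paired_t(pre, post)
            sm = estimate_smoothness(res.residual_maps)
            records = make_cluster_table(res, sm, voxel_p=0.001, cluster_p=0.05)
            pos = [r for r in records if r.sign == "+"]
            if pos and roi[pos[0].peak_grid_index]:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_peak_mm_is_affine_times_index(self, rng):
        res = self._null_result(rng, dims=(16, 24, 12))
        res.t_map.values[:] = 0.0
        res.t_map.values[12, 20, 8] = 30.0
        sm = SmoothnessEstimate(
            fwhm_mm=(6.0, 6.0, 6.0),
            resels=resel_counts(res.t_map.mask, (2.0, 2.0, 2.0)),
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        records = make_cluster_table(res, sm, voxel_p=0.001, cluster_p=1.0)
        assert len(records) == 1
        expected = res.t_map.affine @ np.array([12, 20, 8, 1.0])
        assert records[0].peak_coord_mm == tuple(expected[:3])
        assert records[0].peak_stat == 30.0

    def test_atlas_labeling(self, rng):
        res = self._null_result(rng)
        res.t_map.values[:] = 0.0
        res.t_map.values[3:5, 3:5, 3:5] = 20.0
        sm = SmoothnessEstimate(
            fwhm_mm=(6.0, 6.0, 6.0),
            resels=resel_counts(res.t_map.mask, (2.0, 2.0, 2.0)),
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        atlas = np.zeros((10, 10, 10), int)
        atlas[2:6, 2:6, 2:6] = 7
        records = make_cluster_table(
            res, sm, voxel_p=0.001, atlas=atlas, atlas_labels={7: "toy region"}
        )
        assert records[0].atlas_label == "toy region"

    def test_sorted_by_corrected_p(self, rng):
        res = self._null_result(rng, n=10, dims=(16, 16, 12))
        res.t_map.values[:] = 0.0
        res.t_map.values[2:4, 2:4, 2:4] = 15.0
        res.t_map.values[9:14, 9:14, 4:9] = -15.0
        sm = SmoothnessEstimate(
            fwhm_mm=(6.0, 6.0, 6.0),
            resels=resel_counts(res.t_map.mask, (2.0, 2.0, 2.0)),
            voxel_size_mm=(3.0, 3.0, 3.0),
        )
        records = make_cluster_table(res, sm, voxel_p=0.001)
        ps = [r.cluster_p_corrected for r in records]
        assert ps == sorted(ps)
        assert {r.sign for r in records} == {"+", "-"}
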