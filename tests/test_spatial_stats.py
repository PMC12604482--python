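import itertools

import numpy as np
import pandas as pd
import pytest

from craterscope import spatial_stats as ss
from craterscope.core_io import RegionMaskSet


def _toy_masks():
    """16^3 volume: tumor slab z<8, one 4x4x2 crater pocket at the top."""
    tumor = np.zeros((16, 16, 16), bool)
    tumor[:8] = True
    craters = np.zeros((16, 16, 16), np.int32)
    craters[6:8, 6:10, 6:10] = 2
    tumor &= craters == 0
    return RegionMaskSet(tumor=tumor, craters=craters, spacing=(1, 1, 1))


class TestAssignRegions:
    def test_cell_inside_crater(self):
        masks = _toy_masks()
        cells = pd.DataFrame({"z": [7.0], "y": [7.0], "x": [7.0]})
        out = ss.assign_cell_regions(cells, masks)
        assert out.loc[0, "region"] == "crater"
        assert out.loc[0, "dist_to_crater"] == 0.0

    def test_contact_distance_follows_5um_convention(self):
        masks = _toy_masks()
        # cell 4 um above the tumor surface (z = 7.5 boundary; voxel 11 -> 4 voxels up)
        cells = pd.DataFrame({"z": [11.0], "y": [2.0], "x": [2.0]})
        near = ss.assign_cell_regions(cells.copy(), masks, contact_dist=5.0)
        far = ss.assign_cell_regions(cells.copy(), masks, contact_dist=0.0)
        assert near.loc[0, "region"] == "tumor"
        assert far.loc[0, "region"] == "outside"
        assert near.loc[0, "near_tumor_5um"]

    def test_distances_match_brute_force(self):
        masks = _toy_masks()
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 15, size=(20, 3))
        cells = pd.DataFrame(pts, columns=["z", "y", "x"])
        out = ss.assign_cell_regions(cells, masks)
        tumor_vox = np.argwhere(masks.tumor)
        for i, p in enumerate(pts):
            idx = np.round(p).astype(int)
            bf = np.sqrt(((tumor_vox - idx) ** 2).sum(axis=1)).min()
            assert out.loc[i, "dist_to_tumor"] == pytest.approx(bf, abs=1e-9)

    def test_partition_property(self, segmented_phantom):
        _, masks, manifest = segmented_phantom
        out = ss.assign_cell_regions(manifest.cells.copy(), masks)
        assert out["region"].isin(["crater", "tumor", "outside"]).all()
        assert out["region"].value_counts().sum() == len(out)


class TestDensities:
    def test_arithmetic(self):
        masks = _toy_masks()
        a_crater, a_tumor = ss.surface_areas(masks)
        n = 5
        cells = pd.DataFrame({"z": [7.0] * n, "y": [7.0] * n, "x": [7.0] * n})
        out = ss.assign_cell_regions(cells, masks)
        rep = ss.region_densities(out, masks)
        assert rep.density_crater == pytest.approx(n / a_crater)
        assert rep.counts["crater"] == n

    def test_no_cells_gives_zero_density_null_affinity(self):
        masks = _toy_masks()
        cells = pd.DataFrame(columns=["z", "y", "x"])
        out = ss.assign_cell_regions(cells, masks)
        rep = ss.region_densities(out, masks)
        assert rep.density_crater == 0.0 and rep.density_tumor == 0.0
        assert rep.affinity_ratio is None

    def test_density_conservation(self, segmented_phantom):
        _, masks, manifest = segmented_phantom
        out = ss.assign_cell_regions(manifest.cells.copy(), masks)
        rep = ss.region_densities(out, masks)
        reconstructed = (rep.density_crater * rep.crater_area_mm2
                         + rep.density_tumor * rep.tumor_area_mm2)
        assert reconstructed == pytest.approx(rep.counts["crater"] + rep.counts["tumor"])


class TestCoverage:
    def test_no_craters(self):
        tumor = np.zeros((8, 8, 8), bool)
        tumor[:4] = True
        masks = RegionMaskSet(tumor=tumor, craters=np.zeros((8, 8, 8), np.int32),
                              spacing=(1, 1, 1))
        cov, diam = ss.coverage_and_sizes(masks)
        assert cov == 0.0 and diam == []

    def test_circular_footprint_diameter(self):
        # pocket with a circular footprint of radius 10 um -> diameter ~20 um
        tumor = np.zeros((20, 64, 64), bool)
        tumor[:10] = True
        craters = np.zeros_like(tumor, dtype=np.int32)
        yy, xx = np.mgrid[:64, :64].astype(float)
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
        craters[8:10, disk] = 1
        tumor &= craters == 0
        masks = RegionMaskSet(tumor=tumor, craters=craters, spacing=(1, 1, 1))
        _, diam = ss.coverage_and_sizes(masks)
        assert diam[0] == pytest.approx(20.0, rel=0.05)

    def test_invariant_to_rotation_and_translation(self, segmented_phantom):
        _, masks, _ = segmented_phantom
        cov0, _ = ss.coverage_and_sizes(masks)
        rot = RegionMaskSet(tumor=np.rot90(masks.tumor, axes=(1, 2)),
                            craters=np.rot90(masks.craters, axes=(1, 2)),
                            spacing=masks.spacing)
        cov1, _ = ss.coverage_and_sizes(rot)
        shifted = RegionMaskSet(tumor=np.roll(masks.tumor, 5, axis=1),
                                craters=np.roll(masks.craters, 5, axis=1),
                                spacing=masks.spacing)
        cov2, _ = ss.coverage_and_sizes(shifted)
        assert cov0 == pytest.approx(cov1) == pytest.approx(cov2)


class TestDistanceProfile:
    def test_planted_distances(self):
        ref = np.zeros((4, 64, 64), bool)
        ref[:, :, 0:2] = True  # wall voxels at x in {0, 1}
        pts = np.array([[2.0, 10.0, 9.0], [2.0, 10.0, 41.0]])  # 8 um and 40 um away
        prof = ss.distance_profile(pts, ref, (1, 1, 1), bins=[0, 10, 25, 50, 100])
        assert prof["counts"][0] == 1 and prof["counts"][2] == 1
        prof2 = ss.distance_profile(np.array([[1.0, 5.0, 0.0]]), ref, (1, 1, 1),
                                    bins=[0, 10, 25])
        assert prof2["counts"][0] == 1 and prof2["distances_um"][0] == 0.0

    def test_overflow_bin(self):
        ref = np.zeros((4, 32, 32), bool)
        ref[:, :, 0] = True
        pts = np.array([[0.0, 5.0, 30.0]])
        prof = ss.distance_profile(pts, ref, (1, 1, 1), bins=[0, 5, 10])
        assert prof["overflow"] == 1

    def test_empty_reference(self):
        with pytest.raises(ValueError, match="empty"):
            ss.distance_profile(np.zeros((1, 3)), np.zeros((4, 4, 4), bool),
                                (1, 1, 1), bins=[0, 5])


class TestFoldChange:
    def test_values(self):
        assert ss.tumor_area_foldchange(4.0, 6.0) == pytest.approx(1.5)
        assert ss.tumor_area_foldchange(2.0, 2.0) == 1.0

    def test_nonpositive_area(self):
        with pytest.raises(ValueError):
            ss.tumor_area_foldchange(0.0, 5.0)


def exact_mwu_two_sided_p(a, b):
    """Enumeration oracle: two-sided exact MWU p over all rank arrangements."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    def u_stat(idx_a):
        r = ranks[list(idx_a)].sum()
        return r - n_a * (n_a + 1) / 2
    u_obs = u_stat(range(n_a))
    n = len(pooled)
    mean_u = n_a * (n - n_a) / 2
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_stat(combo) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestGroupTest:
    def test_exact_mwu_small_sample(self):
        res = ss.group_test([1, 2], [3, 4], kind="mwu")
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1 / 3)
        assert res["p"] == pytest.approx(exact_mwu_two_sided_p(np.array([1., 2.]),
                                                               np.array([3., 4.])))

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            res = ss.group_test(a, b, kind="mwu")
            assert res["method"] == "mwu-exact"
            assert res["p"] == pytest.approx(exact_mwu_two_sided_p(a, b), abs=1e-12)

    def test_paired_identical_samples(self):
        res = ss.group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], kind="t_paired")
        assert res["statistic"] == 0.0 and res["p"] == 1.0

    def test_zero_variance_separation_flagged(self):
        res = ss.group_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], kind="t_unpaired")
        assert res["p"] == 0.0
        assert "exact_separation" in res["flags"]

    def test_all_tied_mwu(self):
        with pytest.warns(UserWarning, match="tied"):
            res = ss.group_test([2.0, 2.0], [2.0, 2.0], kind="mwu")
        assert res["p"] == 1.0

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            ss.group_test([1.0], [2.0, 3.0], kind="mwu")
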