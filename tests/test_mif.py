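import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from craterscope import mif
from craterscope import synthetic as syn
from craterscope.core_io import CalibratedImage


class TestPreprocess:
    def _img(self, arrays, names):
        return CalibratedImage(np.stack(arrays), (1, 1), channels=names)

    def test_constant_channel_normalizes_to_ones(self):
        img = self._img([np.full((32, 32), 7.0), np.full((32, 32), 3.0)], ["m", "n"])
        out = mif.preprocess_channels(img, ["m"], "n")
        np.testing.assert_allclose(out.channel("membrane_composite"), 1.0)
        np.testing.assert_allclose(out.channel("nucleus"), 1.0)

    def test_composite_bounded_by_channel_count(self):
        rng = np.random.default_rng(0)
        img = self._img([rng.random((40, 40)), rng.random((40, 40)),
                         rng.random((40, 40))], ["a", "b", "n"])
        out = mif.preprocess_channels(img, ["a", "b"], "n")
        assert out.channel("membrane_composite").max() <= 2.0 + 1e-12

    def test_pixelwise_percentile_normalization(self):
        rng = np.random.default_rng(1)
        ch = rng.random((60, 60)) * 50
        img = self._img([ch, np.ones((60, 60))], ["m", "n"])
        out = mif.preprocess_channels(img, ["m"], "n")
        v = np.percentile(ch, 99, method="lower")
        np.testing.assert_allclose(out.channel("membrane_composite"),
                                   np.clip(ch / v, 0, 1), atol=1e-12)

    def test_idempotence_within_float_eps(self):
        rng = np.random.default_rng(2)
        ch = rng.random((50, 50))
        img = self._img([ch, ch], ["m", "n"])
        once = mif.preprocess_channels(img, ["m"], "n")
        img2 = self._img([once.channel("membrane_composite"),
                          once.channel("nucleus")], ["m", "n"])
        twice = mif.preprocess_channels(img2, ["m"], "n")
        np.testing.assert_allclose(twice.channel("membrane_composite"),
                                   once.channel("membrane_composite"), atol=1e-9)

    def test_zero_percentile_channel_rejected(self):
        img = self._img([np.zeros((32, 32)), np.ones((32, 32))], ["m", "n"])
        with pytest.raises(ValueError, match="m"):
            mif.preprocess_channels(img, ["m"], "n")


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        out = mif.subtract_background(np.full((80, 80), 9.0), radius=10)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_narrow_peak_preserved(self):
        img = np.full((100, 100), 20.0)
        img[50:53, 50:53] += 100.0
        out = mif.subtract_background(img, radius=15)
        assert out[51, 51] == pytest.approx(100.0, rel=0.05)
        assert out[10, 10] == pytest.approx(0.0, abs=1.0)

    def test_output_bounds(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64)) * 30
        out = mif.subtract_background(img, radius=8)
        assert (out >= 0).all() and (out <= img + 1e-9).all()

    def test_radius_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            mif.subtract_background(np.zeros((20, 20)), radius=20)


class TestCellFeatures:
    def test_means_match_per_label_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.random((2, 30, 30)) * 10
        labels = np.zeros((30, 30), np.int32)
        labels[2:8, 2:8] = 1
        labels[15:25, 10:20] = 2
        img = CalibratedImage(data, (1, 1), channels=["a", "b"])
        df = mif.extract_cell_features(img, labels)
        for _, row in df.iterrows():
            m = labels == row["id"]
            for ch in ("a", "b"):
                assert row[ch] == pytest.approx(data[img.channels.index(ch)][m].mean())

    def test_split_value_cell(self):
        data = np.zeros((1, 10, 10))
        data[0, 0:2, 0] = [0.0, 20.0]
        labels = np.zeros((10, 10), np.int32)
        labels[0:2, 0] = 1
        img = CalibratedImage(data, (1, 1), channels=["c"])
        df = mif.extract_cell_features(img, labels)
        assert df.loc[0, "c"] == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        img = CalibratedImage(np.zeros((1, 8, 8)), (1, 1), channels=["c"])
        with pytest.raises(ValueError):
            mif.extract_cell_features(img, np.zeros((8, 8), np.int32))


class TestGating:
    def _cells(self, **markers):
        base = {"id": [1], "y": [0.0], "x": [0.0],
                "CD8a": [0.0], "CD4": [0.0], "FOXP3": [0.0],
                "CD163": [0.0], "CD11c": [0.0], "SOX10": [0.0]}
        base.update({k: [v] for k, v in markers.items()})
        return pd.DataFrame(base)

    def test_treg_priority_over_cd4(self):
        out = mif.classify_cells(self._cells(CD4=100.0, FOXP3=100.0))
        assert out.loc[0, "cell_type"] == "Treg"
        assert out.loc[0, "multi_gate"]  # also matches the CD4 T gate

    def test_all_zero_is_other(self):
        out = mif.classify_cells(self._cells())
        assert out.loc[0, "cell_type"] == "other"

    def test_external_labels_passthrough(self):
        out = mif.classify_cells(self._cells(), labels=["CD8 T"])
        assert out.loc[0, "cell_type"] == "CD8 T"

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError):
            mif.classify_cells(self._cells(), gates=[("x", {"nope": 1.0})])


class TestRegions:
    def _disc_phantom(self, with_cd31=True):
        """Tumor disc with one enclosed 100 um-diameter hole."""
        ny = nx = 300
        px = 2.0
        yy, xx = (np.mgrid[:ny, :nx] * px).astype(float)
        c = ny * px / 2
        tumor = (yy - c) ** 2 + (xx - c) ** 2 <= 240.0**2
        hole = (yy - c) ** 2 + (xx - c) ** 2 <= 50.0**2
        s100 = np.where(tumor & ~hole, 150.0, 2.0)
        cd31 = np.where((yy - c) ** 2 + (xx - c) ** 2 <= 15.0**2,
                        150.0 if with_cd31 else 0.0, 2.0)
        img = CalibratedImage(np.stack([s100, cd31]), (px, px),
                              channels=["S100", "CD31"])
        return img

    def test_perivascular_hole_and_pmb_length(self):
        img = self._disc_phantom()
        regions = mif.segment_tumor_regions(img, "S100", "CD31")
        assert regions.perivascular.max() == 1
        assert regions.pmb_length_cm * 1e4 == pytest.approx(2 * math.pi * 50.0,
                                                            rel=0.03)
        assert not (regions.margin & regions.tumor).any()

    def test_hole_without_cd31_not_perivascular(self):
        img = self._disc_phantom(with_cd31=False)
        regions = mif.segment_tumor_regions(img, "S100", "CD31")
        assert regions.perivascular.max() == 0

    def test_constant_channel_rejected(self):
        img = CalibratedImage(np.zeros((2, 40, 40)), (1, 1),
                              channels=["S100", "CD31"])
        with pytest.raises(ValueError):
            mif.segment_tumor_regions(img, "S100", "CD31")


class TestRuleClassifier:
    def _candidate(self, **kw):
        base = dict(polygon=Point(0, 0).buffer(15.0), equivalent_diameter=30.0,
                    on_boundary=True, collagen_fiber_count=1,
                    nuclear_density=0.0005, vessel_overlap=False,
                    asma_overlap=False)
        base.update(kw)
        return mif.CraterCandidate(**base)

    def test_conforming_candidate_accepted(self):
        acc, rej = mif.classify_crater_candidates([self._candidate()],
                                                  perivascular_density=0.004)
        assert len(acc) == 1 and rej == {}

    @pytest.mark.parametrize("kw,rule", [
        (dict(equivalent_diameter=80.0), "size"),
        (dict(equivalent_diameter=10.0), "size"),
        (dict(vessel_overlap=True), "vessel_overlap"),
        (dict(asma_overlap=True), "asma_overlap"),
        (dict(collagen_fiber_count=4), "collagen_fibers"),
        (dict(nuclear_density=0.01), "nuclear_density"),
        (dict(on_boundary=False), "on_boundary"),
    ])
    def test_each_rule_rejects(self, kw, rule):
        acc, rej = mif.classify_crater_candidates([self._candidate(**kw)],
                                                  perivascular_density=0.004)
        assert len(acc) == 0 and rule in rej[0]

    def test_monotone_in_thresholds(self):
        # relaxing any single threshold never shrinks the accepted set
        rng = np.random.default_rng(0)
        cands = [self._candidate(equivalent_diameter=rng.uniform(10, 90),
                                 collagen_fiber_count=int(rng.integers(0, 6)),
                                 nuclear_density=rng.uniform(0, 0.01))
                 for _ in range(30)]
        tight = mif.MifParams()
        loose_size = mif.MifParams(crater_size_range=(10.0, 90.0))
        loose_fib = mif.MifParams(max_collagen_fibers=5)
        loose_nd = mif.MifParams(nuclear_density_quantile=3.0)
        base, _ = mif.classify_crater_candidates(cands, tight, 0.004)
        for relaxed in (loose_size, loose_fib, loose_nd):
            more, _ = mif.classify_crater_candidates(cands, relaxed, 0.004)
            assert set(id(c) for c in base) <= set(id(c) for c in more)


class TestRegionAssignment:
    def _regions(self):
        tumor = np.zeros((60, 60), bool)
        tumor[10:50, 10:50] = True
        margin = np.zeros_like(tumor)
        margin[5:10, 10:50] = True
        craters = np.zeros((60, 60), np.int32)
        craters[8:15, 20:30] = 1  # straddles margin and tumor
        tumor &= craters == 0
        return mif.MifRegions(tumor=tumor, margin=margin & ~(craters > 0),
                              perivascular=np.zeros((60, 60), np.int32),
                              spacing=(1, 1), craters=craters)

    def test_priority_crater_over_border_over_tumor(self):
        regions = self._regions()
        cells = pd.DataFrame({"id": [1, 2, 3, 4],
                              "y": [9.0, 7.0, 30.0, 2.0],
                              "x": [25.0, 12.0, 30.0, 2.0]})
        out = mif.assign_cells_to_regions(cells, regions)
        assert list(out["region"]) == ["crater", "border", "tumor", "outside"]

    def test_matches_direct_set_algebra(self):
        regions = self._regions()
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 59, size=(200, 2))
        cells = pd.DataFrame({"id": range(200), "y": pts[:, 0], "x": pts[:, 1]})
        out = mif.assign_cells_to_regions(cells, regions)
        for _, row in out.iterrows():
            iy, ix = int(round(row["y"])), int(round(row["x"]))
            if regions.craters[iy, ix] > 0:
                want = "crater"
            elif regions.margin[iy, ix]:
                want = "border"
            elif regions.tumor[iy, ix]:
                want = "tumor"
            else:
                want = "outside"
            assert row["region"] == want

    def test_counts_partition(self):
        regions = self._regions()
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 59, size=(100, 2))
        cells = pd.DataFrame({"id": range(100), "y": pts[:, 0], "x": pts[:, 1]})
        out = mif.assign_cells_to_regions(cells, regions)
        assert out["region"].value_counts().sum() == 100


class TestLinearDensity:
    def test_arithmetic(self):
        assert mif.crater_linear_density(4, 0.2) == pytest.approx(20.0)
        assert mif.crater_linear_density(0, 0.5) == 0.0

    def test_fibrotic_exclusion(self):
        assert mif.crater_linear_density(4, 0.3, excluded_length_cm=0.1) == \
            pytest.approx(20.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mif.crater_linear_density(1, 0.0)


class TestMarkerComparison:
    def test_shifted_distribution_significant(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame({"HLA": np.concatenate([rng.normal(10, 1, 100),
                                                     rng.normal(5, 1, 100)])})
        res = mif.marker_region_comparison(cells, "HLA",
                                           [True] * 100 + [False] * 100)
        assert res["p"] < 0.001

    def test_identical_groups_nonsignificant(self):
        vals = np.tile(np.arange(50, dtype=float), 2)
        cells = pd.DataFrame({"m": vals})
        res = mif.marker_region_comparison(cells, "m", [True] * 50 + [False] * 50)
        assert res["p"] > 0.9

    def test_singleton_group_warns_null(self):
        cells = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            res = mif.marker_region_comparison(cells, "m", [True, False, False])
        assert res["p"] is None


class TestEndToEndPhantom:
    def test_classifier_and_linear_density(self, mif_phantom):
        img, _, man = mif_phantom
        params = mif.MifParams()
        regions = mif.segment_tumor_regions(img, "S100", "CD31", params)
        polys = [Point(c["cy"], c["cx"]).buffer(c["diameter_um"] / 2, quad_segs=64)
                 for c in man.extras["candidates"]]
        nuclei = np.asarray(man.extras["nuclei"])
        cands = mif.build_crater_candidates(polys, img, regions, nuclei,
                                            params=params)
        pv = mif.perivascular_nuclear_density(regions, nuclei)
        accepted, _ = mif.classify_crater_candidates(cands, params, pv)
        truth = [i for i, c in enumerate(man.extras["candidates"])
                 if not c["violations"]]
        got = [i for i, c in enumerate(cands) if c in accepted]
        assert got == truth
        ld = mif.crater_linear_density(len(accepted), regions.pmb_length_cm)
        assert ld == pytest.approx(man.extras["linear_density_per_cm"], rel=0.05)
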