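"""Shuffle-transform subtraction, Otsu thresholding, VEP mask, medians."""

import numpy as np
import pytest

from synodce.pk import PKMaps
from synodce.segmentation import (REGION_NAMES, ROILabelMap, ShuffleDifference,
                                  build_vep_mask, extract_median_biomarkers,
                                  otsu_threshold, shuffle_subtract)


def shuffle_bruteforce_2d(pre, post):
    """Exhaustive neighbourhood search on a 2-D grid (independent oracle)."""
    out = np.zeros_like(post, dtype=float)
    n, m = post.shape
    offs = sorted([(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)],
                  key=lambda o: (o[0] ** 2 + o[1] ** 2, o))
    for i in range(n):
        for j in range(m):
            best = None
            for di, dj in offs:
                u, v = i + di, j + dj
                if 0 <= u < n and 0 <= v < m:
                    d = post[i, j] - pre[u, v]
                    if best is None or abs(d) < abs(best):
                        best = d
            out[i, j] = best
    return out


class TestShuffleSubtract:
    # worked 5x5 integer example, checked against the brute-force oracle
    PRE = np.array([[10, 12, 11, 9, 8],
                    [13, 50, 52, 10, 7],
                    [12, 51, 49, 11, 9],
                    [11, 10, 12, 13, 10],
                    [9, 8, 11, 12, 14]], dtype=float)
    POST = np.array([[11, 13, 55, 10, 9],
                     [12, 52, 54, 12, 8],
                     [60, 53, 50, 10, 11],
                     [12, 11, 58, 14, 9],
                     [10, 9, 12, 13, 15]], dtype=float)

    def test_worked_example_matches_bruteforce(self):
        got = shuffle_subtract(self.PRE, self.POST).diff
        want = shuffle_bruteforce_2d(self.PRE, self.POST)
        assert np.array_equal(got, want)

    def test_identity_pair_gives_zero(self):
        assert np.all(shuffle_subtract(self.PRE, self.PRE).diff == 0)

    def test_one_voxel_translation_is_zero_in_interior(self, rng):
        pre = rng.uniform(0, 100, (12, 12, 4))
        post = np.roll(pre, 1, axis=0)
        d = shuffle_subtract(pre, post).diff
        assert np.all(d[1:-1, 1:-1, :] == 0)
        # simple subtraction is generically nonzero there
        assert np.abs(post - pre)[1:-1, 1:-1, :].max() > 0

    def test_magnitude_never_exceeds_simple_subtraction(self, rng):
        pre = rng.normal(50, 20, (10, 11, 3))
        post = rng.normal(55, 20, (10, 11, 3))
        d = shuffle_subtract(pre, post).diff
        assert np.all(np.abs(d) <= np.abs(post - pre) + 1e-12)

    def test_zero_wherever_post_equals_a_neighbour(self):
        pre = np.arange(25, dtype=float).reshape(5, 5)
        post = pre + 100.0
        post[2, 2] = pre[2, 3]  # equals an in-plane neighbour
        d = shuffle_subtract(pre, post).diff
        assert d[2, 2] == 0

    def test_3d_neighbourhood_covers_through_plane_shift(self, rng):
        pre = rng.uniform(0, 100, (8, 8, 4))
        post = np.roll(pre, 1, axis=2)
        d2 = shuffle_subtract(pre, post, "3x3").diff
        d3 = shuffle_subtract(pre, post, "3x3x3").diff
        assert np.all(d3[1:-1, 1:-1, 1:-1] == 0)
        assert np.abs(d2).max() > 0

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            shuffle_subtract(np.zeros((4, 4)), np.zeros((5, 4)))


class TestOtsu:
    def test_two_point_sample(self):
        thr = otsu_threshold(np.array([0, 0, 0, 10, 10, 10]))
        assert 0 < thr < 10

    def test_matches_bruteforce_between_class_variance(self, rng):
        sample = np.concatenate([rng.normal(10, 2, 4000),
                                 rng.normal(40, 3, 2000)])
        thr = otsu_threshold(sample)
        # exhaustive search over the same 256-bin histogram
        counts, edges = np.histogram(sample, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        w = counts.cumsum()
        mu = (counts * centers).cumsum()
        tot_w, tot_mu = w[-1], mu[-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            var_b = (tot_mu * w - mu * tot_w) ** 2 / (
                w * (tot_w - w) * tot_w**2 * 1.0)
        best = np.nanargmax(var_b[:-1])
        bin_width = edges[1] - edges[0]
        assert abs(thr - centers[best]) <= bin_width

    def test_scale_equivariance(self, rng):
        sample = np.concatenate([rng.normal(5, 1, 500), rng.normal(20, 2, 500)])
        t1 = otsu_threshold(sample)
        t2 = otsu_threshold(sample * 3.0)
        assert t2 == pytest.approx(3.0 * t1, rel=1e-9)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(100, 7.0))


def _roi_two_regions(shape=(10, 10, 4)):
    labels = np.zeros(shape, dtype=np.int16)
    labels[1:4, 1:4, :] = 1
    labels[6:9, 6:9, :] = 2
    names = {1: REGION_NAMES[1], 2: REGION_NAMES[2]}
    return ROILabelMap(labels=labels, label_names=names,
                       voxel_size=(2.0, 2.0, 2.0))


class TestVEPMask:
    def test_bright_blob_intersected_with_roi(self, rng):
        roi = _roi_two_regions()
        diff = rng.normal(0, 0.5, roi.labels.shape)
        blob = np.zeros_like(diff, dtype=bool)
        blob[2:6, 2:6, :2] = True           # overlaps region 1 partially
        diff[blob] += 100.0
        res = build_vep_mask(ShuffleDifference(diff, "3x3"), roi)
        assert np.array_equal(res.mask, blob & roi.union_mask())

    def test_enhancement_outside_roi_gives_zero_volume(self, rng):
        # whole-image Otsu sample: the bright background blob sets the
        # threshold, the disjoint ROI contributes no enhancing voxels
        roi = _roi_two_regions()
        diff = rng.normal(0, 0.5, roi.labels.shape)
        diff[0, 0, :] = 100.0               # background blob only
        res = build_vep_mask(ShuffleDifference(diff, "3x3"), roi,
                             otsu_within_roi=False)
        assert res.volume_ml["whole_joint"] == 0.0

    def test_volumes_additive_over_regions(self, rng):
        roi = _roi_two_regions()
        diff = rng.normal(0, 0.5, roi.labels.shape)
        diff[roi.labels > 0] += 50.0
        res = build_vep_mask(ShuffleDifference(diff, "3x3"), roi)
        parts = sum(v for k, v in res.volume_ml.items() if k != "whole_joint")
        assert parts == pytest.approx(res.volume_ml["whole_joint"])
        # volume = count * voxel volume
        assert res.volume_ml["whole_joint"] == pytest.approx(
            res.mask.sum() * 8.0 / 1000.0)

    def test_empty_roi_errors(self):
        roi = _roi_two_regions()
        roi.labels[:] = 0
        with pytest.raises(ValueError, match="ROI"):
            build_vep_mask(ShuffleDifference(np.zeros(roi.labels.shape), "3x3"),
                           roi)


def _const_maps(shape, ktrans=0.039):
    nan = np.full(shape, np.nan)
    k = np.full(shape, ktrans)
    return PKMaps(ktrans=k, ve=nan.copy(), vp=nan.copy(), iauc60=nan.copy(),
                  rss=nan.copy(), plausible=np.ones(shape, bool),
                  mask=np.ones(shape, bool))


class TestMedianExtraction:
    def test_constant_field_recovered(self):
        roi = _roi_two_regions()
        maps = _const_maps(roi.labels.shape)
        vep = build_vep_mask(
            ShuffleDifference(np.where(roi.labels > 0, 10.0, 0.0)
                              + np.linspace(0, 1e-3, roi.labels.size
                                            ).reshape(roi.labels.shape),
                              "3x3"), roi)
        tab = extract_median_biomarkers(maps, vep, roi)
        wj = tab[(tab.region == "whole_joint") & (tab.biomarker == "ktrans")]
        assert wj["value"].iloc[0] == pytest.approx(0.039)

    def test_whole_joint_median_between_region_medians(self):
        roi = _roi_two_regions()
        maps = _const_maps(roi.labels.shape)
        maps.ktrans[roi.labels == 1] = 0.02
        maps.ktrans[roi.labels == 2] = 0.06
        tab = extract_median_biomarkers(maps, None, roi, use_manual_mask=True)
        k = tab[tab.biomarker == "ktrans"].set_index("region")["value"]
        assert k["suprapatellar"] == pytest.approx(0.02)
        assert k["hoffa_fat_pad"] == pytest.approx(0.06)
        assert 0.02 <= k["whole_joint"] <= 0.06

    def test_region_without_vep_voxels_is_missing_not_zero(self, rng):
        roi = _roi_two_regions()
        maps = _const_maps(roi.labels.shape)
        diff = rng.normal(0, 0.1, roi.labels.shape)
        diff[roi.labels == 1] += 50.0      # only region 1 enhances
        vep = build_vep_mask(ShuffleDifference(diff, "3x3"), roi)
        tab = extract_median_biomarkers(maps, vep, roi)
        r2 = tab[(tab.region == "hoffa_fat_pad") & (tab.biomarker == "ktrans")]
        assert np.isnan(r2["value"].iloc[0])
        assert r2["n_voxels"].iloc[0] == 0

    def test_phantom_ground_truth_medians(self, phantom_demo):
        # noiseless phantom: per-region medians of the true map equal truth
        roi = ROILabelMap(labels=np.where(phantom_demo.synovial_mask(),
                                          phantom_demo.labels, 0),
                          voxel_size=phantom_demo.voxel_size)
        maps = _const_maps(phantom_demo.labels.shape)
        maps.ktrans = phantom_demo.ktrans
        vep = ShuffleDifference(np.where(phantom_demo.enhancing, 100.0, 0.0)
                                + 1e-6 * np.arange(phantom_demo.labels.size
                                                   ).reshape(
                                                       phantom_demo.labels.shape),
                                "3x3")
        res = build_vep_mask(vep, roi)
        tab = extract_median_biomarkers(maps, res, roi)
        k = tab[tab.biomarker == "ktrans"].set_index("region")["value"]
        region_kt = {1: 0.050, 2: 0.030, 3: 0.045, 4: 0.040, 5: 0.055,
                     6: 0.035, 7: 0.039}
        for lab, kt in region_kt.items():
            assert k[REGION_NAMES[lab]] == pytest.approx(kt, rel=1e-9)
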