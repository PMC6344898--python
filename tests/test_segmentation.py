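"""Otsu thresholding, nucleus segmentation, vesicle detection, measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oligoquant as oq
from oligoquant.errors import DegenerateHistogramError, InvalidParameterError


def brute_force_three_class(image):
    """Exhaustive oracle: minimize within-class variance over all pairs."""
    vals = np.unique(image)
    flat = np.asarray(image, dtype=float).ravel()
    best, best_pair = np.inf, None
    for i in range(len(vals) - 2):
        for j in range(i + 1, len(vals) - 1):
            t1, t2 = vals[i], vals[j]
            total = 0.0
            for m in (flat <= t1, (flat > t1) & (flat <= t2), flat > t2):
                if m.any():
                    total += ((flat[m] - flat[m].mean()) ** 2).sum()
            if total < best:
                best, best_pair = total, (float(t1), float(t2))
    return best_pair, best


def within_class_variance(image, t1, t2):
    flat = np.asarray(image, dtype=float).ravel()
    total = 0.0
    for m in (flat <= t1, (flat > t1) & (flat <= t2), flat > t2):
        if m.any():
            total += ((flat[m] - flat[m].mean()) ** 2).sum()
    return total


class TestOtsuThreeClass:
    def test_separated_modes(self, rng):
        img = np.concatenate([rng.poisson(10, 500), rng.poisson(100, 400),
                              rng.poisson(200, 300)]).astype(np.uint8)
        lo, hi = oq.otsu_three_class(img)
        assert 10 < lo < 100
        assert 100 < hi < 200

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            img = r.choice([3, 8, 15, 40, 90, 200], size=400,
                           p=[.3, .2, .1, .15, .15, .1]).astype(np.uint8)
            (t1o, t2o), best = brute_force_three_class(img)
            t1, t2 = oq.otsu_three_class(img)
            assert within_class_variance(img, t1, t2) == pytest.approx(best)

    def test_matches_skimage_multiotsu(self, rng):
        from skimage.filters import threshold_multiotsu
        img = np.concatenate([rng.poisson(8, 2000), rng.poisson(60, 1500),
                              rng.poisson(180, 800)]).astype(np.uint8)
        mine = oq.otsu_three_class(img)
        theirs = threshold_multiotsu(img, classes=3)
        # identical partitions: same achieved within-class variance
        assert within_class_variance(img, *mine) == pytest.approx(
            within_class_variance(img, *theirs))

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            oq.otsu_three_class(np.full((8, 8), 7, dtype=np.uint8))

    @given(st.lists(st.integers(0, 255), min_size=20, max_size=60))
    @settings(max_examples=25, deadline=None)
    def test_property_exhaustive_minimizer(self, pixels):
        img = np.asarray(pixels, dtype=np.uint8)
        if np.unique(img).size < 3:
            return
        (t1o, t2o), best = brute_force_three_class(img)
        t1, t2 = oq.otsu_three_class(img)
        assert within_class_variance(img, t1, t2) <= best + 1e-9


class TestSegmentNuclei:
    def test_five_disjoint_nuclei_found_with_centroids(self, small_scene):
        lm = oq.segment_nuclei(small_scene.images["dapi"])
        assert lm.n_objects == 5
        from skimage.measure import regionprops
        found = sorted((p.centroid for p in regionprops(lm.labels)))
        true = sorted((row.centroid_row, row.centroid_col)
                      for row in small_scene.truth.itertuples())
        for (fr, fc), (tr, tc) in zip(found, true):
            assert abs(fr - tr) < 2 and abs(fc - tc) < 2

    def test_small_object_rejected_by_size_gate(self):
        spec = oq.SceneSpec(image_shape=(128, 128),
                            nuclei=[((64, 64), (5, 5), 0.0)],
                            compartment_concentrations={"dapi": {"nucleus": 4e-7}},
                            seed=1)
        lm = oq.segment_nuclei(oq.generate_scene(spec).images["dapi"],
                               min_diameter=20)
        assert lm.n_objects == 0

    def test_touching_pair_split_by_watershed(self):
        img = np.zeros((120, 160), dtype=np.uint8)
        rr, cc = np.mgrid[0:120, 0:160]
        img[((rr - 60) ** 2 + (cc - 60) ** 2) <= 20 ** 2] = 200
        img[((rr - 60) ** 2 + (cc - 95) ** 2) <= 20 ** 2] = 200
        img[0, 0], img[0, 1] = 50, 100  # three grey levels for thresholding
        lm = oq.segment_nuclei(img, min_diameter=20, max_diameter=80)
        assert lm.n_objects == 2

    def test_blank_image_gives_empty_map(self):
        lm = oq.segment_nuclei(np.zeros((32, 32), dtype=np.uint8))
        assert lm.n_objects == 0

    def test_labels_consecutive(self, small_scene):
        lm = oq.segment_nuclei(small_scene.images["dapi"])
        labs = np.unique(lm.labels)
        assert labs.tolist() == list(range(lm.n_objects + 1))


class TestDetectVesicles:
    def test_blank_image_no_detections(self):
        lm, counts = oq.detect_vesicles(np.zeros((64, 64)))
        assert lm.n_objects == 0 and counts == {}

    def test_offset_invariance(self, rng):
        img = np.zeros((96, 96))
        for r, c in [(20, 20), (50, 70), (75, 30)]:
            rr, cc = np.mgrid[0:96, 0:96]
            img += 10.0 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / 8.0)
        a, _ = oq.detect_vesicles(img, diameter_range=(3, 8))
        b, _ = oq.detect_vesicles(img + 100.0, diameter_range=(3, 8))
        assert np.array_equal(a.labels > 0, b.labels > 0)

    def test_planted_vesicle_count_recovered(self, gymnosis_field):
        sc = gymnosis_field
        curve = oq.CalibrationCurve("lna", slope=sc.spec.counts_per_molar,
                                    intercept=sc.spec.background_counts,
                                    concentration_range=(0, 2e-5), fit_r2=1.0)
        cmap = oq.counts_to_concentration(sc.images["lna"], curve)
        lm, per_cell = oq.detect_vesicles(cmap.values, diameter_range=(3, 7),
                                          sensitivity=8.0,
                                          cell_labels=sc.cell_labels)
        true = len(sc.spec.vesicles)
        assert abs(lm.n_objects - true) <= 0.1 * true
        for n in per_cell.values():
            assert abs(n - 52) <= 0.1 * 52

    def test_invalid_diameter_range(self):
        with pytest.raises(InvalidParameterError):
            oq.detect_vesicles(np.zeros((8, 8)), diameter_range=(0, 5))


class TestMeasureObjects:
    def test_percentage_of_maximal_grey(self):
        labels = oq.LabelMap(np.array([[1, 1], [0, 0]]))
        rec255 = oq.measure_objects(labels, {"ch": np.full((2, 2), 255)},
                                    bit_max=255)[0]
        rec51 = oq.measure_objects(labels, {"ch": np.full((2, 2), 51)},
                                   bit_max=255)[0]
        assert rec255.mean_intensity["ch"] == pytest.approx(100.0)
        assert rec51.mean_intensity["ch"] == pytest.approx(20.0)

    def test_shape_mismatch_rejected(self):
        labels = oq.LabelMap(np.zeros((4, 4), dtype=int))
        with pytest.raises(InvalidParameterError):
            oq.measure_objects(labels, {"ch": np.zeros((5, 5))})

    def test_totals_conserved(self, small_scene):
        """Sum over objects of mean x area equals the summed foreground signal."""
        lm = oq.LabelMap(small_scene.nucleus_labels)
        img = small_scene.images["target"].astype(float)
        recs = oq.measure_objects(lm, {"target": img}, bit_max=None)
        total_from_records = sum(r.mean_intensity["target"] * r.area for r in recs)
        assert total_from_records == pytest.approx(
            img[small_scene.nucleus_labels > 0].sum(), rel=1e-9)

    def test_planted_nuclear_concentration_recovered(self, gymnosis_field):
        sc = gymnosis_field
        curve = oq.CalibrationCurve("lna", slope=sc.spec.counts_per_molar,
                                    intercept=sc.spec.background_counts,
                                    concentration_range=(0, 2e-5), fit_r2=1.0)
        cmap = oq.counts_to_concentration(sc.images["lna"], curve)
        recs = oq.measure_objects(oq.LabelMap(sc.nucleus_labels),
                                  {"lna": cmap.values}, bit_max=None)
        for r in recs:
            n_px = r.area
            se = 296e-9 / np.sqrt(50 * n_px)  # generous Poisson-scale SE
            assert r.mean_intensity["lna"] == pytest.approx(296e-9, abs=5 * se)


def test_segmentation_intensity_scale_covariant():
    """Doubling all grey values (within range) leaves the label map
    unchanged: the Otsu thresholds scale with the histogram."""
    img = np.zeros((120, 160), dtype=np.uint8)
    rr, cc = np.mgrid[0:120, 0:160]
    img[((rr - 60) ** 2 + (cc - 60) ** 2) <= 18 ** 2] = 110
    img[((rr - 60) ** 2 + (cc - 110) ** 2) <= 15 ** 2] = 110
    img[0, 0], img[0, 1] = 25, 55
    a = oq.segment_nuclei(img, min_diameter=20, max_diameter=80)
    b = oq.segment_nuclei((img * 2).astype(np.uint8), min_diameter=20,
                          max_diameter=80)
    assert np.array_equal(a.labels, b.labels)
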