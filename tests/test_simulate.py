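"""Synthetic-data generators: Poisson statistics, determinism, ground truth."""

import numpy as np
import pytest

import oligoquant as oq
from oligoquant.errors import InvalidParameterError, OverlappingNucleiError


class TestSceneGenerator:
    def test_zero_concentration_zero_background_gives_blank_image(self):
        spec = oq.SceneSpec(image_shape=(64, 64),
                            nuclei=[((32, 32), (10, 8), 0.0)],
                            compartment_concentrations={"dapi": {"nucleus": 0.0}},
                            background_counts=0.0, seed=0)
        scene = oq.generate_scene(spec)
        assert np.all(scene.images["dapi"] == 0)

    def test_same_seed_bit_identical(self):
        def build():
            spec = oq.SceneSpec(image_shape=(64, 64),
                                nuclei=[((32, 32), (10, 8), 0.3)],
                                compartment_concentrations={"dapi": {"nucleus": 2e-7}},
                                seed=7)
            return oq.generate_scene(spec)
        a, b = build(), build()
        assert np.array_equal(a.images["dapi"], b.images["dapi"])
        assert np.array_equal(a.nucleus_labels, b.nucleus_labels)

    def test_nuclear_pixel_mean_matches_poisson_expectation(self):
        # 100 nM at gain 5e8 counts.L/mol -> mean 50 counts per nuclear pixel
        spec = oq.SceneSpec(image_shape=(128, 128),
                            nuclei=[((64, 64), (30, 25), 0.0)],
                            compartment_concentrations={"dapi": {"nucleus": 1e-7}},
                            counts_per_molar=5e8, background_counts=0.0, seed=3)
        scene = oq.generate_scene(spec)
        m = scene.nucleus_labels == 1
        vals = scene.images["dapi"][m].astype(float)
        se = np.sqrt(50.0 / vals.size)  # Poisson SE of the mean
        assert abs(vals.mean() - 50.0) < 3 * se

    def test_poisson_index_of_dispersion_near_one(self):
        spec = oq.SceneSpec(image_shape=(200, 200), nuclei=[],
                            compartment_concentrations={},
                            background_counts=20.0, seed=9)
        scene = oq.generate_scene(spec)
        # no channels configured -> nothing rendered; use a uniform channel
        spec = oq.SceneSpec(image_shape=(200, 200),
                            nuclei=[((100, 100), (90, 90), 0.0)],
                            compartment_concentrations={"ch": {"nucleus": 1e-7}},
                            counts_per_molar=5e8, background_counts=0.0, seed=9)
        scene = oq.generate_scene(spec)
        vals = scene.images["ch"][scene.nucleus_labels == 1].astype(float)
        assert vals.mean() / vals.var() == pytest.approx(1.0, abs=0.05)

    def test_overlapping_nuclei_rejected(self):
        spec_kwargs = dict(
            image_shape=(128, 128),
            compartment_concentrations={"dapi": {"nucleus": 1e-7}},
            overlap_tolerance=0.1, seed=0)
        with pytest.raises(OverlappingNucleiError):
            oq.generate_scene(oq.SceneSpec(
                nuclei=[((50, 50), (20, 20), 0.0), ((55, 55), (20, 20), 0.0)],
                **spec_kwargs))

    def test_out_of_bounds_nucleus_rejected(self):
        with pytest.raises(InvalidParameterError):
            oq.SceneSpec(image_shape=(64, 64), nuclei=[((5, 5), (10, 10), 0.0)])

    def test_knockdown_factor_applied_to_injected_cells_only(self):
        nuclei = [((40, 40), (14, 12), 0.0), ((40, 110), (14, 12), 0.0)]
        spec = oq.SceneSpec(image_shape=(150, 150), nuclei=nuclei,
                            compartment_concentrations={"target": {"nucleus": 2e-7}},
                            injected_cell_ids=frozenset({1}),
                            knockdown_factor=0.25, counts_per_molar=5e8,
                            background_counts=0.0, seed=5)
        scene = oq.generate_scene(spec)
        t = scene.truth.set_index("object_id")
        assert t.loc[1, "conc_target"] == pytest.approx(0.25 * 2e-7)
        assert t.loc[2, "conc_target"] == pytest.approx(2e-7)


class TestFrapGenerator:
    def test_noise_free_trace_matches_closed_form(self):
        gt = oq.FrapGroundTruth(noise_sd=0.0, acquisition_bleach_rate=0.0,
                                background_level=0.0)
        tr = oq.generate_frap_trace(gt)
        t = tr.time[gt.n_prebleach:] - tr.time[gt.n_prebleach]
        f0 = 1 - gt.bleach_depth
        model = f0 + gt.mobile_fraction * gt.bleach_depth * (1 - np.exp(-t / gt.tau))
        assert np.allclose(tr.roi_bleach[gt.n_prebleach:],
                           gt.prebleach_level * model)
        assert np.allclose(tr.roi_bleach[:gt.n_prebleach], gt.prebleach_level)

    def test_full_recovery_returns_to_prebleach(self):
        gt = oq.FrapGroundTruth(mobile_fraction=1.0, tau=0.3, noise_sd=0.0)
        fit = oq.analyze_trace(oq.generate_frap_trace(gt))
        assert fit.immobile_fraction == pytest.approx(0.0, abs=1e-6)

    def test_immobile_fraction_recovered_noise_free(self):
        gt = oq.FrapGroundTruth(mobile_fraction=0.71, noise_sd=0.0)
        fit = oq.analyze_trace(oq.generate_frap_trace(gt))
        assert fit.immobile_fraction == pytest.approx(0.29, abs=1e-3)

    def test_negative_noise_rejected(self):
        with pytest.raises(InvalidParameterError):
            oq.FrapGroundTruth(noise_sd=-1.0)

    def test_seed_determinism(self):
        gt = oq.FrapGroundTruth(noise_sd=5.0, seed=11)
        a = oq.generate_frap_trace(gt)
        b = oq.generate_frap_trace(oq.FrapGroundTruth(noise_sd=5.0, seed=11))
        assert np.array_equal(a.roi_bleach, b.roi_bleach)


class TestFcsGenerator:
    def test_zero_brightness_gives_silent_trace(self):
        gt = oq.FcsGroundTruth(brightness=0.0, duration=0.05, seed=2)
        tr = oq.generate_fcs_trace(gt)
        assert np.all(tr.counts == 0)

    def test_mean_count_rate_matches_gaussian_overlap_integral(self):
        """Mean counts/bin = brightness x density x integral of the Gaussian
        profile over the box (numerical integration oracle)."""
        gt = oq.FcsGroundTruth(duration=2.0, seed=8, triplet_fraction=0.0)
        tr = oq.generate_fcs_trace(gt)
        # numerically integrate exp(-2 r^2 / w0^2) over the box
        box, w0 = gt.box_size, gt.w0
        x = np.linspace(0, box, 501) - box / 2
        xx, yy = np.meshgrid(x, x)
        integral = np.trapezoid(np.trapezoid(
            np.exp(-2 * (xx ** 2 + yy ** 2) / w0 ** 2), x), x)
        density = gt.n_particles_box / box ** 2
        expected = gt.brightness * density * integral
        assert tr.counts.mean() == pytest.approx(expected, rel=0.05)

    def test_step_sd_guard(self):
        with pytest.raises(InvalidParameterError):
            gt = oq.FcsGroundTruth(D_true=1e5, bin_time=1e-4, duration=0.05,
                                   dynamics_stride=1)
            oq.generate_fcs_trace(gt)

    def test_seed_determinism(self):
        a = oq.generate_fcs_trace(oq.FcsGroundTruth(duration=0.05, seed=4))
        b = oq.generate_fcs_trace(oq.FcsGroundTruth(duration=0.05, seed=4))
        assert np.array_equal(a.counts, b.counts)

    def test_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            oq.FcsGroundTruth(D_true=-1.0)
        with pytest.raises(InvalidParameterError):
            oq.FcsGroundTruth(w0=1.0, box_size=2.0)
        with pytest.raises(InvalidParameterError):
            oq.FcsGroundTruth(triplet_fraction=1.0)
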