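"""FRAP preprocessing, exponential fitting and derived mobility quantities."""

import math

import numpy as np
import pytest

import oligoquant as oq
from oligoquant.errors import (CorrectionUnderflowError, DegenerateBleachError,
                               InvalidParameterError)
from oligoquant.frap import FrapFit


class TestPreprocess:
    def test_reduces_to_simple_ratio_without_bleaching_or_background(self):
        gt = oq.FrapGroundTruth(noise_sd=0.0, acquisition_bleach_rate=0.0,
                                background_level=0.0)
        tr = oq.generate_frap_trace(gt)
        norm = oq.preprocess_recovery(tr)
        expected = tr.roi_bleach / tr.roi_bleach[:gt.n_prebleach].mean()
        assert np.allclose(norm.values, expected)

    def test_prebleach_level_is_unity(self):
        tr = oq.generate_frap_trace(oq.FrapGroundTruth(noise_sd=0.0))
        norm = oq.preprocess_recovery(tr)
        assert norm.values[:10].mean() == pytest.approx(1.0)

    def test_acquisition_bleaching_cancelled(self):
        """The plateau after double normalization is independent of the
        acquisition bleach rate."""
        plateaus = []
        for beta in (0.0, 0.03, 0.05):
            gt = oq.FrapGroundTruth(noise_sd=0.0, acquisition_bleach_rate=beta)
            norm = oq.preprocess_recovery(oq.generate_frap_trace(gt))
            plateaus.append(norm.values[-5:].mean())
        assert np.ptp(plateaus) < 1e-6

    def test_reference_underflow_detected(self):
        tr = oq.generate_frap_trace(oq.FrapGroundTruth(noise_sd=0.0))
        tr.roi_reference[:] = tr.roi_background
        with pytest.raises(CorrectionUnderflowError):
            oq.preprocess_recovery(tr)

    def test_unknown_mode_rejected(self):
        tr = oq.generate_frap_trace(oq.FrapGroundTruth(noise_sd=0.0))
        with pytest.raises(InvalidParameterError):
            oq.preprocess_recovery(tr, mode="fancy")


class TestFitRecovery:
    def test_noise_free_parameters_to_six_digits(self):
        gt = oq.FrapGroundTruth(mobile_fraction=0.875, tau=1.8, bleach_depth=0.8,
                                noise_sd=0.0)
        norm = oq.preprocess_recovery(oq.generate_frap_trace(gt))
        fit = oq.fit_recovery(norm)
        assert fit.a == pytest.approx(0.7, rel=1e-6)
        assert fit.tau == pytest.approx(1.8, rel=1e-6)
        assert fit.c == pytest.approx(0.2, rel=1e-6)

    def test_half_time_relation(self):
        gt = oq.FrapGroundTruth(tau=1.8, noise_sd=0.0)
        fit = oq.fit_recovery(oq.preprocess_recovery(oq.generate_frap_trace(gt)))
        assert fit.t_half == pytest.approx(1.8 * math.log(2), rel=1e-6)
        assert fit.t_half == pytest.approx(1.2477, abs=2e-4)

    def test_plateau_mode_normalizes_asymptote_to_one(self):
        gt = oq.FrapGroundTruth(mobile_fraction=0.71, noise_sd=0.0)
        norm = oq.preprocess_recovery(oq.generate_frap_trace(gt), mode="plateau")
        fit = oq.fit_recovery(norm)
        assert fit.a + fit.c == pytest.approx(1.0, rel=1e-9)

    def test_too_few_postbleach_frames(self):
        gt = oq.FrapGroundTruth(n_postbleach=5, noise_sd=0.0)
        norm = oq.preprocess_recovery(oq.generate_frap_trace(gt))
        with pytest.raises(InvalidParameterError):
            oq.fit_recovery(norm)

    def test_noisy_replicates_recover_tau(self):
        """Median tau over replicates at the study's acquisition geometry
        (70 frames x 97 ms) lands within 10% of truth."""
        taus = []
        for seed in range(100):
            gt = oq.FrapGroundTruth(noise_sd=10.0, seed=seed)
            norm = oq.preprocess_recovery(oq.generate_frap_trace(gt))
            taus.append(oq.fit_recovery(norm).tau)
        assert np.median(taus) == pytest.approx(1.8137, rel=0.10)


class TestDerivedQuantities:
    def test_diffusion_coefficient_formula(self):
        # D = 0.88 r^2 / (4 t_half): r = 2 um, t_half = 1.2477 s
        assert oq.diffusion_coefficient(1.2477, 2.0) == pytest.approx(0.7053, abs=2e-4)

    def test_quadratic_radius_scaling(self):
        assert oq.diffusion_coefficient(1.0, 4.0) == \
            pytest.approx(4 * oq.diffusion_coefficient(1.0, 2.0))

    def test_inverse_halftime_scaling(self):
        assert oq.diffusion_coefficient(2.0, 2.0) == \
            pytest.approx(oq.diffusion_coefficient(1.0, 2.0) / 2)

    def test_nonpositive_inputs(self):
        with pytest.raises(InvalidParameterError):
            oq.diffusion_coefficient(0.0, 2.0)

    @pytest.mark.parametrize("a,c,expected", [
        (0.8, 0.2, 0.0),        # full recovery: plateau = 1
        (0.568, 0.2, 0.29),     # the study's nuclear immobile fraction
        (0.0, 0.2, 1.0),        # no recovery at all
    ])
    def test_immobile_fraction_values(self, a, c, expected):
        fit = FrapFit(a=a, tau=1.0, c=c, t_half=math.log(2), r2=1.0,
                      normalization_mode="prebleach", bleach_radius=2.0)
        out = oq.immobile_fraction(fit)
        assert out.immobile_fraction == pytest.approx(expected, abs=1e-12)

    def test_no_bleach_depth_degenerate(self):
        fit = FrapFit(a=0.1, tau=1.0, c=1.05, t_half=math.log(2), r2=1.0,
                      normalization_mode="prebleach", bleach_radius=2.0)
        with pytest.raises(DegenerateBleachError):
            oq.immobile_fraction(fit)

    def test_immobile_requires_prebleach_mode(self):
        fit = FrapFit(a=0.8, tau=1.0, c=0.2, t_half=math.log(2), r2=1.0,
                      normalization_mode="plateau", bleach_radius=2.0)
        with pytest.raises(InvalidParameterError):
            oq.immobile_fraction(fit)


class TestRoundTrip:
    @pytest.mark.parametrize("beta", [0.0, 0.02, 0.05])
    def test_generator_fit_round_trip_under_acquisition_bleaching(self, beta):
        """Noise-free generate -> preprocess -> fit recovers tau and the
        mobile fraction within 2% for bleach rates up to 0.05/s."""
        gt = oq.FrapGroundTruth(mobile_fraction=0.71, tau=1.8137,
                                acquisition_bleach_rate=beta, noise_sd=0.0)
        fit = oq.analyze_trace(oq.generate_frap_trace(gt))
        assert fit.tau == pytest.approx(gt.tau, rel=0.02)
        assert 1 - fit.immobile_fraction == pytest.approx(0.71, rel=0.02)


class TestParameterRecovery:
    def test_diffusion_bias_small_across_snr(self):
        """Median D-hat bias stays below 5% at SNR 5, 10 and 20."""
        import oligoquant as oq
        for snr in (5.0, 10.0, 20.0):
            Ds = []
            for i in range(100):
                gt = oq.FrapGroundTruth(mobile_fraction=0.71, tau=1.8137,
                                        noise_sd=100.0 / snr, seed=9000 + i)
                Ds.append(oq.analyze_trace(oq.generate_frap_trace(gt)).D)
            assert abs(np.median(Ds) / 0.7 - 1.0) < 0.05, f"SNR {snr}"

    def test_bootstrap_interval_covers_truth(self):
        """A residual-bootstrap 95% interval for D covers the true value in
        at least 90% of noisy traces."""
        import oligoquant as oq
        from oligoquant.frap import _exp_model

        rng = np.random.default_rng(77)
        covered = 0
        n_traces = 60
        for i in range(n_traces):
            gt = oq.FrapGroundTruth(mobile_fraction=0.71, tau=1.8137,
                                    noise_sd=10.0, seed=30_000 + i)
            norm = oq.preprocess_recovery(oq.generate_frap_trace(gt))
            fit = oq.fit_recovery(norm)
            t = norm.time[norm.n_prebleach:] - norm.time[norm.n_prebleach]
            y = norm.values[norm.n_prebleach:]
            resid = y - _exp_model(t, fit.a, fit.tau, fit.c)
            boots = []
            for _ in range(60):
                y_b = _exp_model(t, fit.a, fit.tau, fit.c) + rng.choice(
                    resid, size=resid.size, replace=True)
                nb = oq.NormalizedTrace(norm.time.copy(),
                                        np.concatenate([norm.values[:norm.n_prebleach], y_b]),
                                        norm.n_prebleach, norm.bleach_radius,
                                        norm.mode)
                try:
                    fb = oq.fit_recovery(nb)
                except Exception:
                    continue
                boots.append(oq.diffusion_coefficient(fb.t_half, 2.0))
            lo, hi = np.percentile(boots, [2.5, 97.5])
            if lo <= 0.7 <= hi:
                covered += 1
        assert covered / n_traces >= 0.90
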