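"""Spectral estimation, normalization, attenuation and line-fit contracts."""

import numpy as np
import pytest

from qusmap.spectra import (PowerSpectrum, RFBlock, compensate_attenuation,
                            fit_spectral_line, windowed_power_spectrum)


def _block(samples, acq, depth=2.0):
    return RFBlock(samples, depth, 0.0, acq)


class TestWindowedPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self, acq):
        t = np.arange(104) / acq.sampling_rate
        x = np.sin(2 * np.pi * 5.0 * t)
        ps = windowed_power_spectrum(_block(np.tile(x[:, None], (1, 17)), acq))
        peak = ps.frequencies[np.argmax(ps.values)]
        assert abs(peak - 5.0) <= ps.frequencies[1] - ps.frequencies[0]

    def test_white_noise_flat_in_band(self, acq):
        rng = np.random.default_rng(0)
        # average over many 17-line blocks to beat periodogram variance
        specs = []
        for _ in range(60):
            ps = windowed_power_spectrum(_block(rng.standard_normal((104, 17)), acq))
            specs.append(10 ** (ps.values / 10))
        mean_db = 10 * np.log10(np.mean(specs, axis=0))
        sel = (ps.frequencies >= 4) & (ps.frequencies <= 8)
        assert mean_db[sel].max() - mean_db[sel].min() < 3.0

    def test_doubling_amplitude_adds_6dB(self, acq):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((104, 17))
        a = windowed_power_spectrum(_block(x, acq))
        b = windowed_power_spectrum(_block(2 * x, acq))
        np.testing.assert_allclose(b.values - a.values,
                                   20 * np.log10(2), atol=1e-9)

    def test_all_zero_block_flagged_invalid(self, acq):
        ps = windowed_power_spectrum(_block(np.zeros((104, 17)), acq))
        assert not ps.valid


class TestCompensation:
    def _flat(self, acq, value=0.0, depth=1.0):
        f = np.linspace(0, 20, 129)[1:]
        return PowerSpectrum(f, np.full_like(f, value), "phantom-normalized", depth)

    def test_zero_thickness_is_identity(self, acq):
        ps = self._flat(acq)
        out = compensate_attenuation(ps, [(0.0, 1.0), (0.0, 0.5)], 0.576)
        np.testing.assert_allclose(out.values, ps.values)

    def test_single_layer_formula(self, acq):
        # 1 cm at 1 dB/MHz/cm over reference 0: +4 dB/MHz of frequency
        ps = self._flat(acq)
        out = compensate_attenuation(ps, [(1.0, 1.0)], reference_attenuation=0.0)
        f = ps.frequencies
        np.testing.assert_allclose(out.values, 4.0 * f, atol=1e-12)
        assert out.values[np.argmin(np.abs(f - 6.0))] == pytest.approx(24.0, abs=0.4)

    def test_negative_thickness_rejected(self, acq):
        with pytest.raises(ValueError, match="negative"):
            compensate_attenuation(self._flat(acq), [(-0.5, 1.0)])

    def test_raw_spectrum_rejected(self, acq):
        ps = self._flat(acq)
        ps.kind = "raw"
        with pytest.raises(ValueError):
            compensate_attenuation(ps, [(1.0, 1.0)])


class TestSpectralLineFit:
    def test_flat_zero_spectrum_gives_zero_parameters(self):
        f = np.linspace(3, 8, 64)
        fit = fit_spectral_line(PowerSpectrum(f, np.zeros_like(f),
                                              "phantom-normalized"), (3, 8))
        assert fit.MBF == fit.SS == fit.SI == 0.0

    def test_exact_line_recovered(self):
        f = np.linspace(3, 8, 64)
        fit = fit_spectral_line(PowerSpectrum(f, 2 * f - 5, "phantom-normalized"),
                                (3, 8))
        assert fit.SS == pytest.approx(2.0, abs=1e-12)
        assert fit.SI == pytest.approx(-5.0, abs=1e-12)
        assert fit.MBF == pytest.approx(6.0, abs=1e-12)  # centre 5.5 MHz

    def test_mbf_identity_holds_for_noisy_spectra(self):
        rng = np.random.default_rng(3)
        f = np.linspace(4, 8, 80)
        for _ in range(25):
            y = rng.normal(-1.0, 2.0) * f + rng.normal(0, 5) \
                + rng.standard_normal(len(f))
            fit = fit_spectral_line(PowerSpectrum(f, y, "phantom-normalized"), (4, 8))
            assert fit.MBF == pytest.approx(fit.SI + fit.SS * fit.f_centre,
                                            abs=1e-10)

    def test_monte_carlo_slope_unbiased(self):
        rng = np.random.default_rng(4)
        f = np.linspace(4, 8, 40)
        slopes = []
        for _ in range(1000):
            y = 2.0 * f - 5.0 + rng.standard_normal(len(f))
            slopes.append(fit_spectral_line(
                PowerSpectrum(f, y, "phantom-normalized"), (4, 8)).SS)
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 2 * se

    def test_band_outside_support_rejected(self):
        f = np.linspace(3, 8, 64)
        with pytest.raises(ValueError):
            fit_spectral_line(PowerSpectrum(f, np.zeros_like(f),
                                            "phantom-normalized"), (10, 14))


class TestNormalizationProperties:
    def test_gain_cancels_in_slope_and_shifts_mbf(self, speckle_frame, refset, acq,
                                                  lesion_roi):
        """A frame-wide gain leaves SS unchanged and shifts MBF and SI by
        20*log10(g) after normalization and compensation."""
        from dataclasses import replace

        from qusmap.maps import AnalysisConfig, build_parametric_maps

        cfg = AnalysisConfig(overlap=0.5)  # coarse grid: speed
        small_roi = np.zeros_like(lesion_roi)
        small_roi[800:1200, 200:300] = True
        ms1 = build_parametric_maps(speckle_frame, small_roi, refset, cfg)
        gained = replace(speckle_frame)
        gained.samples = 2.0 * speckle_frame.samples
        ms2 = build_parametric_maps(gained, small_roi, refset, cfg)
        gain_db = 20 * np.log10(2)
        v = ms1.validity
        np.testing.assert_allclose(ms2.maps["SS"][v], ms1.maps["SS"][v], atol=1e-6)
        np.testing.assert_allclose(ms2.maps["MBF"][v] - ms1.maps["MBF"][v],
                                   gain_db, atol=1e-6)
        np.testing.assert_allclose(ms2.maps["SI"][v] - ms1.maps["SI"][v],
                                   gain_db, atol=1e-6)
        np.testing.assert_allclose(ms2.maps["ESD"][v], ms1.maps["ESD"][v], atol=1e-6)
        np.testing.assert_allclose(ms2.maps["EAC"][v] - ms1.maps["EAC"][v],
                                   gain_db, atol=1e-6)


class TestNormalizeToPhantom:
    def test_self_medium_near_zero_dbr(self, speckle_frame, refset, acq):
        from qusmap.spectra import normalize_to_phantom

        block = RFBlock(speckle_frame.samples[948:1052, 200:217],
                        1000 * acq.dz_mm / 10.0, 0.0, acq)
        ps = windowed_power_spectrum(block)
        out = normalize_to_phantom(ps, refset, 104, 17, 6)
        assert out.kind == "phantom-normalized"
        sel = (out.frequencies >= 4.2) & (out.frequencies <= 7.6)
        # single window: speckle noise of a 17-line periodogram in dB
        assert abs(out.values[sel].mean()) < 3.0

    def test_depth_mismatch_rejected(self, speckle_frame, refset, acq):
        from qusmap.spectra import normalize_to_phantom

        block = RFBlock(speckle_frame.samples[948:1052, 200:217], 9.9, 0.0, acq)
        ps = windowed_power_spectrum(block)
        with pytest.raises(ValueError, match="reference"):
            normalize_to_phantom(ps, refset, 104, 17, 6)
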