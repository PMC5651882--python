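"""Forward-simulator contracts: pulse, speckle, lattice, cohorts."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import hilbert

from qusmap.synthetic_rf import (AcquisitionSpec, PhantomSpec, CohortSpec,
                                 default_cohort_spec, generate_cohort,
                                 make_pulse, simulate_frame,
                                 simulate_reference_set)


class TestPulse:
    def test_spectral_peak_at_centre_frequency(self, acq):
        p = make_pulse(acq)
        peak = p.freqs_mhz[np.argmax(p.spectrum)]
        bin_width = p.freqs_mhz[1] - p.freqs_mhz[0]
        assert abs(peak - acq.centre_frequency) <= bin_width

    def test_minus6db_band_edges_match_fractional_bandwidth(self, acq):
        lo, hi = make_pulse(acq).band_edges_mhz(-6.0)
        f0, bw = acq.centre_frequency, acq.pulse_bandwidth_frac
        assert lo == pytest.approx(f0 * (1 - bw / 2), abs=0.25)
        assert hi == pytest.approx(f0 * (1 + bw / 2), abs=0.25)

    def test_unit_peak_amplitude(self, acq):
        assert make_pulse(acq).waveform.max() == pytest.approx(1.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            AcquisitionSpec(centre_frequency=25.0, sampling_rate=40.0)


class TestSimulateFrame:
    def test_same_seed_bit_identical(self, speckle_phantom, acq):
        a = simulate_frame(speckle_phantom, acq, seed=7)
        b = simulate_frame(speckle_phantom, acq, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_zero_attenuation_balances_depth_power(self, acq):
        ph = PhantomSpec(scatterer_radius_mean=12.5, number_density=60,
                         impedance_contrast=0.5, attenuation_coeff=0.0,
                         radius_cv=0.1)
        fr = simulate_frame(ph, acq, seed=2)
        n = fr.samples.shape[0]
        top = np.mean(fr.samples[100:n // 2] ** 2)
        bottom = np.mean(fr.samples[n // 2:-100] ** 2)
        assert top / bottom == pytest.approx(1.0, rel=0.1)

    def test_envelope_is_rayleigh_in_developed_speckle(self, acq):
        # attenuation-free so the envelope scale is depth-stationary;
        # >= 5 scatterers per resolution cell at this density
        ph = PhantomSpec(scatterer_radius_mean=12.5, number_density=60,
                         impedance_contrast=0.5, attenuation_coeff=0.0,
                         radius_cv=0.1)
        fr = simulate_frame(ph, acq, seed=2)
        env = np.abs(hilbert(fr.samples[200:1800, ::8], axis=0)).ravel()[:5000]
        scale = np.sqrt(np.mean(env**2) / 2.0)
        assert stats.kstest(env, "rayleigh", args=(0, scale)).pvalue > 0.01

    def test_lattice_imprints_spectral_comb(self, acq):
        # 1 mm pitch -> spectral comb period c/(2 mm) = 0.77 MHz, visible as
        # a peak in the autocorrelation of the average in-band power spectrum
        ph = PhantomSpec(scatterer_radius_mean=50, number_density=30,
                         impedance_contrast=0.5, attenuation_coeff=0.5,
                         periodic_fraction=1.0, lattice_spacing=1.0,
                         radius_cv=0.0)
        fr = simulate_frame(ph, acq, seed=11)
        nfft = 4096
        seg = fr.samples[400:1712, :]
        P = np.abs(np.fft.rfft(seg * np.hanning(seg.shape[0])[:, None], nfft, axis=0))**2
        f = np.fft.rfftfreq(nfft, 1.0 / acq.sampling_rate)
        sel = (f >= 4.2) & (f <= 7.6)
        s = 10 * np.log10(P.mean(axis=1))[sel]
        s = s - np.polyval(np.polyfit(f[sel], s, 2), f[sel])
        s = (s - s.mean()) / s.std()
        r = np.correlate(s, s, "full")[len(s) - 1:] / len(s)
        df = f[1] - f[0]
        expected = acq.speed_of_sound / (2 * 1.0e-3) / 1e6  # 0.77 MHz
        lag = np.arange(len(r)) * df
        window = (lag > 0.5) & (lag < 1.1)
        peak_lag = lag[window][np.argmax(r[window])]
        assert peak_lag == pytest.approx(expected, rel=0.08)

    def test_empty_phantom_yields_flagged_silent_frame(self, acq):
        ph = PhantomSpec(number_density=0.0)
        with pytest.warns(UserWarning, match="empty"):
            fr = simulate_frame(ph, acq, seed=1)
        assert fr.warning == "empty-phantom"
        assert np.all(fr.samples == 0)


class TestReferenceSet:
    def test_reflector_echo_centred_at_two_way_delay(self, refset, acq):
        depth, frame = refset.reflector_frames[3]  # 2.0 cm
        assert depth == 2.0
        idx = np.argmax(np.abs(frame.samples[:, 0]))
        expected = 2.0 * depth * 1e-2 / acq.speed_of_sound * acq.sampling_rate * 1e6
        assert abs(idx - expected) <= 1

    def test_reference_phantom_attenuation_default(self, refset):
        assert refset.phantom_attenuation == pytest.approx(0.576)
        assert refset.phantom_sos == pytest.approx(1488.0)

    def test_bsc_model_positive_and_rising_then_rolling(self, refset):
        f = np.linspace(2, 10, 50)
        bsc = refset.phantom_bsc_model(f)
        assert np.all(bsc > 0)


class TestCohort:
    def test_counting_patients_frames_labels(self):
        spec = default_cohort_spec(n_patients_per_class=3, planes_per_patient=2,
                                   seed=5)
        cohort = generate_cohort(spec)
        assert len(cohort.patients) == 6
        assert sum(len(p.planes) for p in cohort.patients) == 12
        labels = {p.label for p in cohort.patients}
        assert labels == {"benign", "malignant"}
        gt = cohort.ground_truth
        assert len(gt) == 6
        assert {"esd_um", "eac_db", "lattice_spacing", "attenuation_coeff"} <= set(gt.columns)

    def test_cohort_reproducible_under_seed(self):
        spec = default_cohort_spec(n_patients_per_class=1, planes_per_patient=1,
                                   seed=21)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert np.array_equal(a.patients[0].planes[0][0].samples,
                              b.patients[0].planes[0][0].samples)
        assert np.array_equal(a.patients[0].planes[0][1], b.patients[0].planes[0][1])

    def test_roi_masks_are_nonempty_ellipses_inside_frame(self):
        spec = default_cohort_spec(n_patients_per_class=1, planes_per_patient=2,
                                   seed=3)
        cohort = generate_cohort(spec)
        for frame, roi in cohort.patients[0].planes:
            assert roi.any()
            assert roi.shape == frame.samples.shape

    def test_oversized_lesion_rejected(self):
        spec = default_cohort_spec(n_patients_per_class=1, seed=0)
        from dataclasses import replace

        bad = replace(spec, lesion_diameter_cm=(7.5, 0.0))
        with pytest.raises(ValueError, match="field of view"):
            generate_cohort(bad)
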