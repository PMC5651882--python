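"""Forward simulation of beamformed ultrasound RF data.

The simulator emulates a linear-array acquisition (SonixTouch-like geometry:
~6 MHz centre frequency, 40 MHz sampling, 512 lines over a 6 cm lateral field
of view, 4 cm depth) insonifying a random medium of discrete point scatterers.
Each scan line is the superposition, over the scatterers inside the lateral
beam, of a Gaussian-enveloped pulse delayed by the two-way travel time and
filtered by

* a per-scatterer backscatter amplitude response ``f^2 * sqrt(F(f))`` with the
  spherical Gaussian form factor ``F(f) = exp(-0.827 k^2 a_eff^2)``, so the
  ensemble backscatter coefficient scales as ``f^4 F(f)`` — the same model the
  estimators invert;
* frequency-dependent attenuation. Convention used throughout the package:
  an attenuation coefficient ``alpha`` in dB/MHz/cm removes ``2*alpha*f*z`` dB
  from the one-way power spectrum at depth ``z`` (``4*alpha*f*z`` dB two-way).

Scatterer positions are drawn uniformly at random except for an optional
coherent component placed on a jittered axial lattice, which is what the
scatterer-spacing (SAS) estimator detects.

The simulation is 2-D (single imaging plane) with a Gaussian lateral beam
profile; there is no diffraction, focusing, nonlinearity or elevational
physics. That is deliberate: it provides a forward model that the spectral
estimators can invert exactly in expectation, which is what the recovery
tests exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionSpec",
    "PhantomSpec",
    "RFFrame",
    "ReferenceSet",
    "ClassDistribution",
    "CohortSpec",
    "Patient",
    "Cohort",
    "Pulse",
    "make_pulse",
    "simulate_frame",
    "simulate_reference_set",
    "generate_cohort",
    "default_cohort_spec",
    "gaussian_form_factor",
]

#: 0.827 constant of the spherical Gaussian form factor exp(-0.827 k^2 a^2).
_GAUSS_FF_CONST = 0.827

#: Jitter of the coherent axial lattice: 5% of the pitch, capped at 12 µm so
#: the round-trip phase error stays well under a wavelength at 6 MHz
#: (uncapped large-pitch jitter would fully decohere the comb).
LATTICE_JITTER_FRAC = 0.05
LATTICE_JITTER_CAP_MM = 0.012


def _lattice_jitter_mm(pitch_mm: float) -> float:
    return min(LATTICE_JITTER_FRAC * pitch_mm, LATTICE_JITTER_CAP_MM)

#: Elevational slab thickness (mm) mapping volumetric scatterer density to
#: the areal density actually simulated.  Common to sample and reference, so
#: it cancels in the reference-phantom normalization.
SLAB_THICKNESS_MM = 1.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and transducer description.

    Frequencies are in MHz, lateral/axial extents in cm, speed of sound in
    m/s and beam width in mm (-6 dB two-way lateral width, modelled as the
    FWHM of a Gaussian beam profile).
    """

    centre_frequency: float = 6.0
    sampling_rate: float = 40.0
    num_lines: int = 512
    lateral_fov: float = 6.0
    depth: float = 4.0
    speed_of_sound: float = 1540.0
    pulse_bandwidth_frac: float = 0.6
    beam_width: float = 0.7

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2.0 * self.centre_frequency * (1.0 + self.pulse_bandwidth_frac):
            raise ValueError(
                "Nyquist violation: sampling_rate must exceed "
                "2 * centre_frequency * (1 + pulse_bandwidth_frac) "
                f"({self.sampling_rate} MHz <= "
                f"{2 * self.centre_frequency * (1 + self.pulse_bandwidth_frac)} MHz)"
            )
        if self.num_lines < 2:
            raise ValueError("num_lines must be >= 2")
        if self.depth <= 0 or self.lateral_fov <= 0:
            raise ValueError("depth and lateral_fov must be positive")

    # -- derived geometry ---------------------------------------------------
    @property
    def dz_mm(self) -> float:
        """Axial sample spacing in mm (c / (2 fs))."""
        return self.speed_of_sound / (2.0 * self.sampling_rate * 1e6) * 1e3

    @property
    def n_samples(self) -> int:
        """Axial samples per line covering the imaging depth."""
        return int(round(self.depth * 10.0 / self.dz_mm))

    @property
    def line_pitch_mm(self) -> float:
        return self.lateral_fov * 10.0 / self.num_lines

    @property
    def line_x_mm(self) -> np.ndarray:
        """Lateral line positions, centred on 0."""
        j = np.arange(self.num_lines)
        return (j - (self.num_lines - 1) / 2.0) * self.line_pitch_mm


@dataclass(frozen=True)
class PhantomSpec:
    """Tissue/phantom micro-structure description (ground truth).

    ``scatterer_radius_mean`` is the effective scatterer radius a_eff in µm
    (ESD = 2 a_eff); ``number_density`` in scatterers/mm³;
    ``impedance_contrast`` the relative acoustic-impedance factor (with
    number density it fixes the acoustic concentration EAC);
    ``lattice_spacing`` the coherent axial pitch in mm (ground-truth SAS);
    ``attenuation_coeff`` in dB/MHz/cm (ground-truth ACE);
    ``heterogeneity`` scales patch-wise multiplicative variation of contrast
    and radius on a ``patch_size``-mm grid.
    """

    scatterer_radius_mean: float = 50.0
    radius_cv: float = 0.15
    number_density: float = 30.0
    impedance_contrast: float = 0.5
    periodic_fraction: float = 0.0
    lattice_spacing: float = 1.0
    attenuation_coeff: float = 0.576
    heterogeneity: float = 0.0
    patch_size: float = 2.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.periodic_fraction <= 1.0):
            raise ValueError("periodic_fraction must lie in [0, 1]")
        if self.periodic_fraction > 0 and self.lattice_spacing <= 0:
            raise ValueError("lattice_spacing must be positive when periodic_fraction > 0")
        if self.number_density < 0:
            raise ValueError("number_density must be non-negative")

    @property
    def eac_db(self) -> float:
        """Ground-truth effective acoustic concentration in dB/cm³."""
        n_cm3 = self.number_density * 1e3
        return 10.0 * np.log10(n_cm3 * self.impedance_contrast**2)

    @property
    def esd_um(self) -> float:
        return 2.0 * self.scatterer_radius_mean


@dataclass
class RFFrame:
    """One plane of beamformed RF samples (axial x lateral) plus metadata."""

    samples: np.ndarray
    acquisition: AcquisitionSpec
    plane_offset_mm: float = 0.0
    warning: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (axial x lateral)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def depths_cm(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.acquisition.dz_mm / 10.0


@dataclass
class Pulse:
    """Sampled transmit/receive pulse and its one-sided amplitude spectrum."""

    t_us: np.ndarray
    waveform: np.ndarray
    freqs_mhz: np.ndarray
    spectrum: np.ndarray
    centre_frequency: float
    sigma_f_mhz: float

    def band_edges_mhz(self, level_db: float = -6.0) -> tuple[float, float]:
        """Frequency band where the amplitude spectrum exceeds ``level_db``."""
        thresh = self.spectrum.max() * 10.0 ** (level_db / 20.0)
        inside = np.flatnonzero(self.spectrum >= thresh)
        return float(self.freqs_mhz[inside[0]]), float(self.freqs_mhz[inside[-1]])


def make_pulse(acq: AcquisitionSpec) -> Pulse:
    """Gaussian-modulated sinusoid at the acquisition's centre frequency.

    The fractional bandwidth is the full -6 dB width of the amplitude
    spectrum divided by the centre frequency; the time-domain peak amplitude
    is 1.  Raises on Nyquist violation via AcquisitionSpec validation.
    """
    f0 = acq.centre_frequency
    width = acq.pulse_bandwidth_frac * f0  # full -6 dB width, MHz
    sigma_f = (width / 2.0) / np.sqrt(2.0 * np.log(10.0 ** (6.0 / 20.0)))
    sigma_t_us = 1.0 / (2.0 * np.pi * sigma_f)  # MHz <-> µs
    dt_us = 1.0 / acq.sampling_rate
    half = int(np.ceil(5.0 * sigma_t_us / dt_us))
    t = np.arange(-half, half + 1) * dt_us
    wave = np.cos(2.0 * np.pi * f0 * t) * np.exp(-(t**2) / (2.0 * sigma_t_us**2))
    nfft = int(2 ** np.ceil(np.log2(4 * len(wave))))
    freqs = np.fft.rfftfreq(nfft, dt_us)
    spec = np.abs(np.fft.rfft(wave, nfft))
    spec = spec / spec.max()
    return Pulse(t, wave, freqs, spec, f0, float(sigma_f))


def gaussian_form_factor(f_mhz: np.ndarray | float, a_um: np.ndarray | float,
                         c_mps: float = 1540.0) -> np.ndarray:
    """Spherical Gaussian form factor F(f) = exp(-0.827 k² a_eff²)."""
    k = 2.0 * np.pi * np.asarray(f_mhz, dtype=float) * 1e6 / c_mps  # 1/m
    a_m = np.asarray(a_um, dtype=float) * 1e-6
    return np.exp(-_GAUSS_FF_CONST * (k * a_m) ** 2)


# --------------------------------------------------------------------------
# scatterer sampling
# --------------------------------------------------------------------------

def _sample_scatterers(phantom: PhantomSpec, rng: np.random.Generator,
                       x_lo: float, x_hi: float, z_lo: float, z_hi: float):
    """Draw scatterer positions/amplitudes/radii for one homogeneous region.

    Returns arrays (x_mm, z_mm, amplitude, a_um).  The coherent component is
    placed on axial lattice planes shared across the lateral extent so that
    every scan line sees the same periodicity.
    """
    area = max(0.0, (x_hi - x_lo)) * max(0.0, (z_hi - z_lo))
    rho_a = phantom.number_density * SLAB_THICKNESS_MM  # per mm²
    n_expected = rho_a * area
    if n_expected <= 0:
        e = np.empty(0)
        return e, e.copy(), e.copy(), e.copy()

    p = phantom.periodic_fraction
    n_diffuse = rng.poisson((1.0 - p) * n_expected)
    xd = rng.uniform(x_lo, x_hi, n_diffuse)
    zd = rng.uniform(z_lo, z_hi, n_diffuse)

    if p > 0:
        d = phantom.lattice_spacing
        phase = rng.uniform(0.0, d)
        planes = np.arange(z_lo + phase, z_hi, d)
        per_plane = p * rho_a * (x_hi - x_lo) * d
        counts = rng.poisson(per_plane, len(planes))
        zp = np.repeat(planes, counts)
        zp = zp + rng.normal(0.0, _lattice_jitter_mm(d), len(zp))
        xp = rng.uniform(x_lo, x_hi, len(zp))
        x = np.concatenate([xd, xp])
        z = np.concatenate([zd, zp])
        coherent = np.concatenate([np.zeros(n_diffuse, bool),
                                   np.ones(len(zp), bool)])
    else:
        x, z = xd, zd
        coherent = np.zeros(len(x), bool)

    keep = (z >= z_lo) & (z < z_hi)
    x, z, coherent = x[keep], z[keep], coherent[keep]

    amp = np.full(len(x), phantom.impedance_contrast)
    a_um = np.full(len(x), phantom.scatterer_radius_mean)

    if phantom.heterogeneity > 0:
        ps = phantom.patch_size
        gx = np.floor((x - x_lo) / ps).astype(int)
        gz = np.floor((z - z_lo) / ps).astype(int)
        nx, nz = gx.max() + 1, gz.max() + 1
        amp_fac = np.clip(1.0 + phantom.heterogeneity * rng.standard_normal((nz, nx)), 0.05, None)
        rad_fac = np.clip(1.0 + phantom.heterogeneity * rng.standard_normal((nz, nx)), 0.2, None)
        amp = amp * amp_fac[gz, gx]
        a_um = a_um * rad_fac[gz, gx]

    if phantom.radius_cv > 0:
        a_um = np.clip(a_um * (1.0 + phantom.radius_cv * rng.standard_normal(len(a_um))), 1.0, None)

    # diffuse scatterers get a random scattering sign (zero-mean speckle);
    # the lattice component keeps a consistent sign — randomly-modulated
    # periodic trains carry no spectral comb, coherent ones do
    sign = rng.choice([-1.0, 1.0], len(amp))
    sign[coherent] = 1.0
    amp = amp * sign
    return x, z, amp, a_um


# --------------------------------------------------------------------------
# RF synthesis engine
# --------------------------------------------------------------------------

def _synthesize(acq: AcquisitionSpec,
                x_mm: np.ndarray, z_mm: np.ndarray,
                amp: np.ndarray, a_um: np.ndarray,
                atten_path: Callable[[np.ndarray, np.ndarray], np.ndarray],
                seg_len: int = 104, guard: int = 76) -> np.ndarray:
    """Superpose the pulse echoes of all scatterers onto the line grid.

    ``atten_path(x_mm, z_mm)`` returns the cumulative one-way attenuation
    path integral ∫ alpha dz in dB/MHz (alpha in dB/MHz/cm, depth in cm).

    Depth-dependent filtering uses segmented overlap-add: each scatterer is
    deposited (with linear sub-sample interpolation) as an impulse scaled by
    its exact centre-frequency response, and per-(line, segment) zero-phase
    filters supply the frequency *shape* of the pulse, the f² sqrt(F)
    backscatter response and the attenuation relative to the centre
    frequency evaluated at the segment centre.  The shape error within a
    segment is bounded by a fraction of a dB in-band.
    """
    n_samp = acq.n_samples
    n_lines = acq.num_lines
    out = np.zeros((n_samp, n_lines))
    if len(x_mm) == 0:
        return out

    f0 = acq.centre_frequency
    c = acq.speed_of_sound
    dz = acq.dz_mm
    dt_us = 1.0 / acq.sampling_rate

    nfft = int(2 ** np.ceil(np.log2(seg_len + 2 * guard)))
    freqs = np.fft.rfftfreq(nfft, dt_us)  # MHz
    k = 2.0 * np.pi * freqs * 1e6 / c

    pulse_sigma_f = make_pulse(acq).sigma_f_mhz
    pulse_shape = np.exp(-((freqs - f0) ** 2) / (2.0 * pulse_sigma_f**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        freq_pow = np.where(freqs > 0, (freqs / f0) ** 2, 0.0)

    sigma_beam = acq.beam_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sigma
    support = 3.5 * sigma_beam

    order = np.argsort(x_mm, kind="stable")
    xs, zs, amps, aums = x_mm[order], z_mm[order], amp[order], a_um[order]
    tau = zs / dz  # fractional sample index of the echo
    A_s = atten_path(xs, zs)  # dB/MHz one-way path integral
    k0 = 2.0 * np.pi * f0 * 1e6 / c
    # exact per-scatterer scalar response at f0
    scal = amps * np.exp(-0.5 * _GAUSS_FF_CONST * (k0 * aums * 1e-6) ** 2)
    scal = scal * 10.0 ** (-2.0 * f0 * A_s / 10.0)

    line_x = acq.line_x_mm
    n_seg = int(np.ceil(n_samp / seg_len))

    for j in range(n_lines):
        lo = np.searchsorted(xs, line_x[j] - support)
        hi = np.searchsorted(xs, line_x[j] + support)
        if hi <= lo:
            continue
        w = np.exp(-((xs[lo:hi] - line_x[j]) ** 2) / (2.0 * sigma_beam**2))
        s_line = scal[lo:hi] * w
        tau_line = tau[lo:hi]
        A_line = A_s[lo:hi]
        a2_line = (aums[lo:hi] * 1e-6) ** 2
        w2 = s_line**2

        seg_idx = np.clip((tau_line // seg_len).astype(int), 0, n_seg - 1)
        for seg in np.unique(seg_idx):
            m = seg_idx == seg
            start = seg * seg_len
            # segment-representative attenuation path and radius (power-weighted)
            wsum = w2[m].sum()
            if wsum <= 0:
                continue
            A_c = float(np.average(A_line[m], weights=w2[m]))
            a2_c = float(np.average(a2_line[m], weights=w2[m]))

            buf = np.zeros(nfft)
            rel = tau_line[m] - start + guard
            i0 = np.floor(rel).astype(int)
            frac = rel - i0
            # residual attenuation at f0 relative to the segment filter
            resid = 10.0 ** (-2.0 * f0 * (A_line[m] - A_c) / 10.0)
            dep = s_line[m] * resid
            np.add.at(buf, i0, dep * (1.0 - frac))
            np.add.at(buf, i0 + 1, dep * frac)

            H = pulse_shape * freq_pow
            H = H * np.exp(-0.5 * _GAUSS_FF_CONST * k**2 * a2_c
                           + 0.5 * _GAUSS_FF_CONST * k0**2 * a2_c)
            H = H * 10.0 ** (-2.0 * (freqs - f0) * A_c / 10.0)
            chunk = np.fft.irfft(np.fft.rfft(buf) * H, nfft)

            o_lo = start - guard
            c_lo = max(0, -o_lo)
            c_hi = min(nfft, n_samp - o_lo)
            if c_hi > c_lo:
                out[o_lo + c_lo: o_lo + c_hi, j] += chunk[c_lo:c_hi]
    return out


def _const_atten(alpha: float) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    def path(x_mm: np.ndarray, z_mm: np.ndarray) -> np.ndarray:
        return alpha * np.asarray(z_mm) / 10.0  # dB/MHz

    return path


def simulate_frame(phantom: PhantomSpec, acq: AcquisitionSpec, seed: int,
                   plane_offset_mm: float = 0.0) -> RFFrame:
    """Simulate one RF frame of a homogeneous medium.

    The medium fills the whole field of view (with a lateral margin equal to
    the beam support so edge lines see full speckle) and has the phantom's
    constant attenuation.  Reproducible: the same seed gives bit-identical
    frames.
    """
    rng = np.random.default_rng(seed)
    margin = 3.5 * acq.beam_width
    half_fov = acq.lateral_fov * 10.0 / 2.0
    x, z, amp, a_um = _sample_scatterers(
        phantom, rng, -half_fov - margin, half_fov + margin, 0.0, acq.depth * 10.0
    )
    samples = _synthesize(acq, x, z, amp, a_um, _const_atten(phantom.attenuation_coeff))
    frame = RFFrame(samples, acq, plane_offset_mm)
    if len(x) == 0:
        warnings.warn("empty phantom: simulated frame is silent", stacklevel=2)
        frame.warning = "empty-phantom"
    return frame


# --------------------------------------------------------------------------
# reference set
# --------------------------------------------------------------------------

#: Reference phantom micro-structure mirroring a glass-bead calibration
#: phantom: small beads (weak form-factor roll-off), dense enough for fully
#: developed speckle.
REFERENCE_PHANTOM = PhantomSpec(
    scatterer_radius_mean=12.5,
    radius_cv=0.1,
    number_density=60.0,
    impedance_contrast=0.5,
    periodic_fraction=0.0,
    attenuation_coeff=0.576,
    heterogeneity=0.0,
)

#: Attenuation assumed for intervening (non-lesion) breast tissue, dB/MHz/cm.
INTERVENING_ATTENUATION = 1.0


@dataclass
class ReferenceSet:
    """Calibration data: reference-phantom frames and planar-reflector echoes.

    ``phantom_bsc_model(f_mhz)`` returns the phantom's backscatter
    coefficient on a linear scale (nominal 1/(sr·cm)), defined consistently
    with the simulator as n[cm⁻³]·γ²·f⁴·F(f; a_ref).
    """

    phantom_frames: list[RFFrame]
    phantom_attenuation: float
    phantom_sos: float
    phantom_spec: PhantomSpec
    reflector_frames: list[tuple[float, RFFrame]]  # (depth_cm, frame)
    _spectrum_cache: dict = field(default_factory=dict, repr=False)

    def phantom_bsc_model(self, f_mhz: np.ndarray) -> np.ndarray:
        ph = self.phantom_spec
        n_cm3 = ph.number_density * 1e3
        f = np.asarray(f_mhz, dtype=float)
        return n_cm3 * ph.impedance_contrast**2 * f**4 * gaussian_form_factor(
            f, ph.scatterer_radius_mean, self.phantom_frames[0].acquisition.speed_of_sound
        )

    # mean window spectra are computed lazily per analysis configuration by
    # qusmap.spectra (cached here keyed on the window/nfft settings).


def simulate_reference_set(acq: AcquisitionSpec, seed: int,
                           phantom_attenuation: float = 0.576,
                           n_phantom_frames: int = 8,
                           reflector_depths_cm: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
                           ) -> ReferenceSet:
    """Simulate the calibration data used for normalization.

    Phantom frames come from a homogeneous random phantom with the stated
    attenuation (default 0.576 dB/MHz/cm — a tissue-mimicking calibration
    medium).  Reflector frames each contain a single specular pulse echo at
    the stated depth with a negligible water attenuation path.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_phantom_frames)
    phantom = replace(REFERENCE_PHANTOM, attenuation_coeff=phantom_attenuation)
    frames = [
        simulate_frame(phantom, acq, int(s.generate_state(1)[0] % (2**31)))
        for s in seeds
    ]

    pulse = make_pulse(acq)
    reflector = []
    for depth in reflector_depths_cm:
        samples = np.zeros((acq.n_samples, acq.num_lines))
        centre = depth * 10.0 / acq.dz_mm
        i0 = int(round(centre))
        half = len(pulse.waveform) // 2
        lo = max(0, i0 - half)
        hi = min(acq.n_samples, i0 + half + 1)
        samples[lo:hi, :] = pulse.waveform[lo - (i0 - half): hi - (i0 - half), None]
        reflector.append((depth, RFFrame(samples, acq)))

    return ReferenceSet(frames, phantom_attenuation, 1488.0, phantom, reflector)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassDistribution:
    """Between-patient distribution of a PhantomSpec: per-field mean and SD."""

    mean: PhantomSpec
    sd: PhantomSpec

    def sample(self, rng: np.random.Generator) -> PhantomSpec:
        values = {}
        for f in fields(PhantomSpec):
            mu = getattr(self.mean, f.name)
            sigma = getattr(self.sd, f.name)
            values[f.name] = mu + sigma * rng.standard_normal() if sigma > 0 else mu
        values["periodic_fraction"] = float(np.clip(values["periodic_fraction"], 0.0, 1.0))
        values["scatterer_radius_mean"] = max(values["scatterer_radius_mean"], 5.0)
        values["number_density"] = max(values["number_density"], 1.0)
        values["impedance_contrast"] = max(values["impedance_contrast"], 0.01)
        values["lattice_spacing"] = max(values["lattice_spacing"], 0.1)
        values["attenuation_coeff"] = float(np.clip(values["attenuation_coeff"], 0.0, 3.0))
        values["heterogeneity"] = max(values["heterogeneity"], 0.0)
        values["radius_cv"] = max(values["radius_cv"], 0.0)
        return PhantomSpec(**values)


@dataclass(frozen=True)
class CohortSpec:
    """Two-class synthetic patient cohort description."""

    benign: ClassDistribution
    malignant: ClassDistribution
    n_patients_per_class: int = 10
    planes_per_patient: int = 2
    lesion_diameter_cm: tuple[float, float] = (1.2, 0.25)  # mean, sd
    lesion_depth_cm: tuple[float, float] = (2.0, 0.2)
    plane_spacing_mm: float = 5.0
    acquisition: AcquisitionSpec = AcquisitionSpec()
    background: PhantomSpec = PhantomSpec(
        scatterer_radius_mean=40.0,
        number_density=25.0,
        impedance_contrast=0.35,
        attenuation_coeff=INTERVENING_ATTENUATION,
        heterogeneity=0.1,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planes_per_patient < 1:
            raise ValueError("planes_per_patient must be >= 1")
        if self.benign == self.malignant:
            warnings.warn("benign and malignant class distributions are identical", stacklevel=2)


@dataclass
class Patient:
    patient_id: str
    label: str  # benign | malignant
    phantom: PhantomSpec
    lesion_diameter_cm: float
    lesion_depth_cm: float
    planes: list[tuple[RFFrame, np.ndarray]] = field(default_factory=list)  # (frame, roi mask)


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[Patient]

    @property
    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "label": p.label,
                   "lesion_diameter_cm": p.lesion_diameter_cm,
                   "lesion_depth_cm": p.lesion_depth_cm,
                   "esd_um": p.phantom.esd_um, "eac_db": p.phantom.eac_db}
            for f in fields(PhantomSpec):
                row[f.name] = getattr(p.phantom, f.name)
            rows.append(row)
        return pd.DataFrame(rows)


def _lesion_frame(patient_phantom: PhantomSpec, background: PhantomSpec,
                  acq: AcquisitionSpec, centre_z_mm: float, rx_mm: float, rz_mm: float,
                  rng: np.random.Generator) -> tuple[RFFrame, np.ndarray]:
    """Simulate a frame with an elliptical lesion embedded in background tissue."""
    margin = 3.5 * acq.beam_width
    half_fov = acq.lateral_fov * 10.0 / 2.0
    depth_mm = acq.depth * 10.0

    bx, bz, bamp, ba = _sample_scatterers(background, rng,
                                          -half_fov - margin, half_fov + margin,
                                          0.0, depth_mm)
    inside_b = ((bx / rx_mm) ** 2 + ((bz - centre_z_mm) / rz_mm) ** 2) <= 1.0
    bx, bz, bamp, ba = bx[~inside_b], bz[~inside_b], bamp[~inside_b], ba[~inside_b]

    lx, lz, lamp, la = _sample_scatterers(patient_phantom, rng,
                                          -rx_mm, rx_mm,
                                          centre_z_mm - rz_mm, centre_z_mm + rz_mm)
    inside_l = ((lx / rx_mm) ** 2 + ((lz - centre_z_mm) / rz_mm) ** 2) <= 1.0
    lx, lz, lamp, la = lx[inside_l], lz[inside_l], lamp[inside_l], la[inside_l]

    x = np.concatenate([bx, lx])
    z = np.concatenate([bz, lz])
    amp = np.concatenate([bamp, lamp])
    a_um = np.concatenate([ba, la])

    a_bg = background.attenuation_coeff
    a_les = patient_phantom.attenuation_coeff

    def atten_path(xq: np.ndarray, zq: np.ndarray) -> np.ndarray:
        xq = np.asarray(xq, dtype=float)
        zq = np.asarray(zq, dtype=float)
        u = np.clip(1.0 - (xq / rx_mm) ** 2, 0.0, None)
        half_chord = rz_mm * np.sqrt(u)
        z_top = centre_z_mm - half_chord
        z_bot = centre_z_mm + half_chord
        in_lesion_len = np.clip(np.minimum(zq, z_bot) - z_top, 0.0, None)
        return (a_bg * (zq - in_lesion_len) + a_les * in_lesion_len) / 10.0

    samples = _synthesize(acq, x, z, amp, a_um, atten_path)
    frame = RFFrame(samples, acq)

    zz = np.arange(acq.n_samples) * acq.dz_mm
    xx = acq.line_x_mm
    roi = ((xx[None, :] / rx_mm) ** 2 + ((zz[:, None] - centre_z_mm) / rz_mm) ** 2) <= 1.0
    return frame, roi


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a reproducible two-class cohort with known ground truth.

    Per patient a lesion phantom is drawn from the class distribution and an
    ellipse of the sampled diameter is embedded at the sampled depth in
    background tissue; each imaging plane intersects the (spherical)
    elevational extent of the lesion at ``plane_spacing_mm`` offsets, so
    off-centre planes see a smaller cross-section.  Everything is derived
    from per-patient substreams of the root seed, so the cohort is
    bit-reproducible and individual patients can be regenerated in isolation.
    """
    acq = spec.acquisition
    root = np.random.SeedSequence(spec.seed)
    patient_seeds = root.spawn(2 * spec.n_patients_per_class)
    patients: list[Patient] = []
    idx = 0
    for label, dist in (("benign", spec.benign), ("malignant", spec.malignant)):
        for i in range(spec.n_patients_per_class):
            rng = np.random.default_rng(patient_seeds[idx])
            phantom = dist.sample(rng)
            diam = max(0.6, rng.normal(*spec.lesion_diameter_cm))
            depth = float(np.clip(rng.normal(*spec.lesion_depth_cm), 1.0, acq.depth - 1.0))
            r_mm = diam * 10.0 / 2.0
            if 2 * r_mm > acq.lateral_fov * 10.0 or 2 * r_mm > acq.depth * 10.0:
                raise ValueError(
                    f"lesion diameter {diam:.2f} cm exceeds the field of view"
                )
            n_planes = spec.planes_per_patient
            offsets = (np.arange(n_planes) - (n_planes - 1) / 2.0) * spec.plane_spacing_mm
            patient = Patient(f"{label[0].upper()}{i + 1:03d}", label, phantom, diam, depth)
            for off in offsets:
                u = 1.0 - (off / r_mm) ** 2 if r_mm > 0 else 0.0
                if u <= 0.05:
                    u = 0.05  # grazing plane still intersects a sliver
                r_cross = r_mm * np.sqrt(u)
                frame, roi = _lesion_frame(phantom, spec.background, acq,
                                           depth * 10.0, r_cross, 0.85 * r_cross, rng)
                frame.plane_offset_mm = float(off)
                patient.planes.append((frame, roi))
            patients.append(patient)
            idx += 1
    return Cohort(spec, patients)


def default_cohort_spec(n_patients_per_class: int = 16, planes_per_patient: int = 2,
                        seed: int = 0) -> CohortSpec:
    """Default two-class study conditions.

    Class contrasts follow the directions reported for benign vs malignant
    breast lesions: malignant lesions have larger effective scatterer
    diameter, lower acoustic concentration, larger and more regular scatterer
    spacing, lower attenuation, and less intra-lesion heterogeneity.
    Magnitudes are chosen to exercise the pipeline at desk scale, not as a
    histology-calibrated model.
    """
    # Texture-dominant class contrast: the heterogeneity gap is the main
    # discriminator (benign lesions patchier in these conditions), while the
    # mean-level gaps (radius, concentration, spacing) are individually weak
    # — mirroring cohorts where almost no mean-value biomarker separates the
    # classes but several texture biomarkers do.
    benign = ClassDistribution(
        mean=PhantomSpec(scatterer_radius_mean=51.0, radius_cv=0.15,
                         number_density=28.0, impedance_contrast=0.50,
                         periodic_fraction=0.50, lattice_spacing=0.72,
                         attenuation_coeff=1.3, heterogeneity=0.30, patch_size=2.5),
        sd=PhantomSpec(scatterer_radius_mean=2.5, radius_cv=0.0,
                       number_density=3.0, impedance_contrast=0.05,
                       periodic_fraction=0.08, lattice_spacing=0.06,
                       attenuation_coeff=0.2, heterogeneity=0.05, patch_size=0.0),
    )
    malignant = ClassDistribution(
        mean=PhantomSpec(scatterer_radius_mean=53.5, radius_cv=0.15,
                         number_density=24.0, impedance_contrast=0.46,
                         periodic_fraction=0.62, lattice_spacing=0.78,
                         attenuation_coeff=0.8, heterogeneity=0.12, patch_size=2.5),
        sd=PhantomSpec(scatterer_radius_mean=2.5, radius_cv=0.0,
                       number_density=2.5, impedance_contrast=0.04,
                       periodic_fraction=0.08, lattice_spacing=0.06,
                       attenuation_coeff=0.1, heterogeneity=0.03, patch_size=0.0),
    )
    return CohortSpec(benign=benign, malignant=malignant,
                      n_patients_per_class=n_patients_per_class,
                      planes_per_patient=planes_per_patient, seed=seed)
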