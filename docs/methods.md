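# Methods

This note records the models, conventions and design choices behind
`qusmap`, in the spirit of a methods appendix: what is simulated, what each
estimator assumes, which defaults matter, and what the passing tests do and
do not demonstrate.

## Forward model

The simulator is two-dimensional (one imaging plane). A scan line at
lateral position `x_j` is the superposition over point scatterers of a
zero-phase Gaussian-enveloped pulse delayed by the two-way travel time
`2 z / c`, weighted by a Gaussian lateral beam profile (FWHM =
`beam_width`, default 0.7 mm), and filtered per scatterer by

* the backscatter amplitude response `f² √F(f)` with the spherical Gaussian
  form factor `F(f) = exp(−0.827 k² a_eff²)`, `k = 2πf/c` — so the ensemble
  backscatter coefficient scales as `f⁴ F(f)`, exactly the model the ESD/EAC
  estimator inverts;
* frequency-dependent attenuation (below).

Synthesis uses segmented overlap-add: scatterer impulses are deposited with
linear sub-sample interpolation and scaled by their exact centre-frequency
response; per-(line, 2 mm-segment) zero-phase filters supply the frequency
shape (pulse, `f²√F`, attenuation relative to the centre frequency at the
segment centre). The within-segment shape error is a fraction of a dB
in-band; the centre-frequency term is exact per scatterer.

**Attenuation convention.** A coefficient `α` in dB/MHz/cm removes
`2·α·f·z` dB from the one-way power spectrum at depth `z` (amplitude filter
`10^(−2αfz/10)`), hence `4·α·f·z` dB two-way. Simulator, spectral-difference
ACE estimator (`depth-slope = −4·Δα·f`) and point compensation
(`+4·f·Σ αᵢtᵢ` dB) all share this convention, which is what the
attenuate-then-compensate round-trip and ACE-recovery tests verify. Quoted
coefficients are therefore internally consistent labels, not calibrated
against any particular instrument's convention.

**Scatterer populations.** `number_density` is volumetric (mm⁻³); the 2-D
simulation uses the areal density of a 1-mm elevational slab. The factor is
common to sample and reference phantom, so it cancels in the
reference-phantom BSC ratio. Diffuse scatterers get random scattering signs
(zero-mean speckle; Rayleigh envelope at ≥ 5 scatterers per resolution
cell, verified by a Kolmogorov–Smirnov test). The coherent component sits
on axial lattice planes of pitch `lattice_spacing` with Gaussian jitter of
5% of the pitch capped at 12 µm — the cap keeps the round-trip phase error
well below a wavelength at 6 MHz; without it, millimetre pitches fully
decohere and carry no spectral comb. Lattice scatterers keep a consistent
sign: a randomly-modulated periodic train has a flat expected spectrum, so
an i.i.d.-sign "lattice" would be undetectable by construction.

**Heterogeneity.** Patch-wise multiplicative perturbations (scale
`heterogeneity`, grid `patch_size`) on impedance contrast and scatterer
radius, plus per-scatterer radius dispersion `radius_cv`. Patch variation is
what drives the texture contrast between lesion classes.

## Estimators

* **Windowed spectra.** Per-line Hann taper, FFT of length
  `next_pow2(4 × samples)`, power averaged over the 17 lines of a window.
* **Normalization.** Reference-phantom spectra are averaged over all
  lateral positions of several phantom frames per depth row (hundreds of
  independent blocks), then subtracted in dB. The phantom BSC model is
  tabulated as `n[cm⁻³]·γ²·f⁴·F(f; a_ref)`, consistent with the simulator,
  so `EAC_dB = 10·log₁₀(n·γ²)` and the noise-free inversion is exact.
* **ACE.** Linear depth-slope of the normalized dB power per in-band
  frequency over the ROI's window rows, `Δα(f) = −slope/4`, regression
  `Δα = a·f` through the origin, `ACE = a + α_phantom`, clamped to
  [0, 3] dB/MHz/cm. Estimated once per frame (a 2 mm window is too small
  for a stable per-window estimate) and applied to all windows via the
  two-layer compensation (intervening tissue at 1 dB/MHz/cm above the
  lesion top, ACE inside).
* **ESD/EAC.** Linearized fit: `ln BSC − 4 ln f` against `k²`; the slope
  gives `a_eff` (ESD = 2a_eff, search range 10–250 µm, edge hits flagged),
  the level gives EAC. Positive slopes are non-physical and pin to the
  range edge.
* **SAS.** Per-line Burg AR spectra averaged across the block's lines,
  normalized (dB subtraction) by the echo-centred spectrum of the
  nearest-depth planar-reflector frame (0.5 cm depth bins). The in-band
  spectrum is quadratically detrended, unit-variance scaled, and its
  autocorrelation over frequency lag is searched within the lag window
  mapped from the SAS range (default 0.25–3 mm). A comb peaks at every
  multiple of the fundamental lag, so the *first* peak within 80% of the
  tallest is taken; windows with no peak above the prominence floor
  (default 0.1) are excluded pixels. The default AR order is adaptive,
  ≈ `samples/3` (capped below `samples/2`): an order-10 spectrum cannot
  represent the 3–7 in-band comb lines of sub-millimetre spacings and
  locks onto an order artifact instead.

## Analysis defaults

| parameter | default | note |
| --- | --- | --- |
| window | 2 mm × 2 mm, Hann | 17 lines × 104 samples at the default geometry |
| overlap | 94% | 0.12 mm nominal isotropic pixel pitch; true integer-stride pitches recorded |
| analysis band | pulse −10 dB band (≈3.7–8.3 MHz) | −6 dB band roughly doubles ESD fit variance; configurable |
| intervening attenuation | 1 dB/MHz/cm | breast-tissue assumption above the lesion |
| reference phantom | α = 0.576 dB/MHz/cm, c = 1488 m/s, 12.5 µm beads | calibration medium |
| gray levels / distances / angles | 16 / 1–5 px / 0°,45°,90°,135° | per-image min–max quantization |
| k-NN | k = 5, Euclidean on z-scored features | distance ties broken by patient order |
| stepwise thresholds | F_enter 3.84, F_remove 2.71 | classic defaults |

ROI gating uses window *centres* (full containment available by flag).
Map validity is shared by construction across MBF/SS/SI/ESD/EAC; SAS can
additionally be missing inside the support where no spectral peak passed
the prominence floor — texture extraction treats missing pixels by
excluding any co-occurrence pair that touches one. Degenerate GLCM
correlation (zero marginal variance) is recorded as missing and excluded
from the 20-GLCM average rather than forced to 1.

Feature selection for the hybrid biomarker is a single global stepwise fit
by default, mirroring the reported-coefficient style of discriminant
tables; at the cohort sizes simulated here a leak-free per-fold refit
(available as `select_per_fold=True`) is noticeably less stable and
typically costs the hybrid a few accuracy points. Cross-validated
accuracies under the global default are therefore mildly optimistic, which
is a property of that design, not of the implementation.

## Synthetic cohort

The default study conditions are two classes of 16 patients, two imaging
planes each at 5 mm elevational spacing, elliptical lesions of diameter
1.2 ± 0.25 cm centred at 2.0 ± 0.2 cm depth in background tissue of
1 dB/MHz/cm. Class contrasts follow the directions reported for benign vs
malignant breast lesions — malignant: larger scatterers (ESD ~110 vs
~102 µm), lower acoustic concentration, larger and more regular scatterer
spacing (0.80 vs 0.72 mm), lower attenuation (0.8 vs 1.3 dB/MHz/cm), less
intra-lesion heterogeneity — with between-patient spreads chosen so that
single biomarkers are informative but imperfect. Cohort size and lesion
scale are the package's own desk-scale choices; they are an order of
magnitude below a clinical study and the absolute classification metrics
should be read accordingly.

What the synthetic cohort does *not* emulate: diffraction and focusing,
elevational beam physics, nonlinear propagation, phase aberration,
electronic noise, vendor-specific gain curves, and any calibrated mapping
from histology to acoustic micro-structure. Passing recovery tests show
the estimators invert this forward model correctly under realistic speckle
statistics — not that the class separations are biologically faithful.

## Numerical notes and limitations

* Determinism: one root seed fans out to per-patient substreams
  (`SeedSequence.spawn`), so identical config + seed reproduce cohorts and
  all downstream numbers bit-for-bit, and patients regenerate independently
  of cohort size.
* A 2 mm window cannot resolve spacings much beyond ~1 mm (a 1.5 mm pitch
  gives 1.3 periods per window, below the window's spectral resolution);
  SAS recovery at 1.5 mm is demonstrated on 6 mm blocks. In-map SAS values
  are trustworthy for the sub-millimetre spacings the cohort uses.
* Per-scatterer radius dispersion flattens the ensemble form factor, so ESD
  estimates on polydisperse media (radius_cv > 0) are biased a few percent
  low relative to the mean radius — a property of the Gaussian-form-factor
  model, visible in the cohort's absolute ESD levels.
* Leave-one-out k-NN is a few accuracy points *pessimistic* at the
  permutation null (removing the held-out patient tilts the training class
  balance against it); the chance-level test asserts a band around 50%
  rather than an exact match.
* The Mann–Whitney tests are reported uncorrected across the 30 biomarkers
  (a Holm option exists in `scipy` one line away); with 30 tests, one or
  two nominal p < 0.05 hits are expected under the null.
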