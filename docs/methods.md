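# Methods

`uvholo` implements the computational chain of a lensless on-chip
holographic microscope operating at a 266 nm (deep-UV) illumination
wavelength: forward simulation of sub-pixel-shifted in-line holograms,
pixel super-resolution with circular averaging, angular-spectrum
reconstruction with digital object peeling, background-compensated
multi-height nanoparticle detection with parabola focus validation, and
a Mie-based detection-limit calculator.

## Imaging model

The sample sits directly on a CMOS sensor (1.12 um pixel pitch, RGGB
Bayer mosaic), 300–500 um above the active area, illuminated by a
coherent collimated beam.  Light scattered by sample-plane objects
interferes with the undiffracted background, and the sensor records the
in-line hologram of the scene at unit magnification.  Steering the beam
by a small angle θ displaces the hologram of a plane at height z by
z·tan θ, which is how sub-pixel shift diversity is generated without
moving any parts.

All propagation uses the scalar angular-spectrum method on a uniform
medium (n = 1): the field's 2-D spectrum is multiplied by
`exp(i·2π·dz·(sqrt((n/λ)² − fx² − fy²) − n/λ))`.  Two conventions are
deliberate:

* **Carrier removal.** The constant plane-wave phase `exp(i2πdz·n/λ)`
  is factored out, referencing phase to the co-propagating
  illumination.  Without this, the background phase of a reconstruction
  rotates (and wraps) with height, which breaks any comparison of phase
  images across heights — in particular max-phase autofocus and the
  background-compensated phase division.  `keep_carrier=True` restores
  the absolute convention (used when validating against the
  Rayleigh–Sommerfeld integral, which contains the carrier).
* **Evanescent handling.** Components outside the propagating circle
  are attenuated with the corresponding real exponential in |dz|, never
  amplified, regardless of propagation direction.  This avoids both
  ringing (hard zeroing) and blow-up (literal inversion) on back-
  propagation.

The FFT implies periodic boundaries; `propagate` exposes an optional
zero-padding factor for cases where wrap-around matters (it is used in
the diffraction-integral validation).  Pipeline-scale holograms are
processed unpadded; border cells are excluded from candidate search
(`edge_margin`, default 16 high-res cells).

## Forward simulator

A scene is a list of scatterers on a single sample plane.  The sample
transmission is `t(x,y) = 1 − Σ strength·gain·disk(diameter)`, rendered
on a grid 4× finer than the sensor pitch.  Objects smaller than a fine
cell are deposited bilinearly with their area-integrated perturbation,
so deep sub-wavelength beads are represented without aliasing.
`strength` is a complex transmission perturbation (magnitude ≈
absorption/scattering, phase ≈ optical path delay); `nanolens_gain ≥ 1`
phenomenologically represents the signal boost of a self-assembled
nanolens around a particle.  Gains well above 1 are routinely needed to
make sub-300 nm beads rise above the residual coherent background —
mirroring why the physical instrument uses nanolenses at all.

Coherent background noise comes from parasitic planes at heights far
from the sample: oblique plane-wave reflections (fringes) and a frozen
complex-Gaussian speckle field with a configurable correlation length.
Under a beam tilt each plane's contribution displaces by its own
`h·tan θ` — the differential motion that circular averaging exploits.
A negative height models a virtual reflection below the sensor, whose
fringes move opposite to the sample holograms.  Default amplitudes
(fringes 0.02/0.015 of the background field, speckle contrast 0.05)
were chosen so the background structure is clearly visible in a
rectangular-only super-resolved image yet does not overwhelm
sample-plane registration; they are configuration, not a claim about
any particular instrument.

Each frame is synthesized by shifting every plane's precomputed
sensor-plane field by `z_plane·tan θ` via a spectral phase ramp,
summing coherently, taking the intensity, integrating over the 4×4
fine-cell pixel aperture, applying the Bayer mask (red/blue response to
266 nm defaults to 0), and digitizing with gain, Poisson shot noise,
Gaussian read noise and quantization.  The per-plane shift is the exact
paraxial equivalent of re-illuminating with a tilted plane wave; at the
tilts involved (≤ 0.5°) the difference is far below the sensor noise,
and it makes 556-frame stacks cheap.  Seeds deterministically expand to
per-frame noise streams; identical inputs give bit-identical frames.

## Pixel super-resolution with circular averaging

The acquisition pattern is the platform's: a 14×14 rectangular grid of
~0.16 um target shifts (196 frames, resolution diversity) plus 12
concentric circles of 0.3 um radial spacing with 30 positions each (360
frames, noise averaging) — 556 frames total.

Processing per frame: the green Bayer channel (the only one responsive
at 266 nm) is kept and red/blue positions are filled with the mean of
their 4-connected green neighbours; the frame is then divided by its
own Gaussian low-pass (σ = 0.05 /um) to flatten the illumination
envelope.

Shift estimation registers each frame to frame 0 by upsampled
cross-correlation on a window containing a visible sample-plane mark
(dust).  Three practical details matter:

* the window is mean-subtracted and apodized (Tukey, taper 0.5) before
  correlation — cropping without apodization biases sub-pixel peaks by
  ~0.1 pixel;
* estimates are anchored to the nominal shift table's mean
  (`anchor="nominal"`): registration relative to frame 0 carries an
  arbitrary global offset equal to frame 0's own displacement, which
  would otherwise translate the whole reconstruction;
* an optional `max_shift_px` restricts the peak search to physically
  plausible displacements, guarding against locking onto strong
  periodic background fringes (whose correlation peaks lie at their own
  `h/z2`-scaled displacements).

With the default noise levels and a few-micron dust mark, shifts are
recovered to ≈0.1 um RMS on noisy Bayer stacks and ≈0.01 um on clean
ones.  Accumulation is nearest-cell shift-and-add onto the 4×-upsampled
grid (0.28 um effective pitch) with per-cell coverage normalization;
all 556 frames enter the same accumulator.  Structure co-moving with
the sample plane adds coherently; everything else smears.  Cells never
covered (sparse patterns) are filled by normalized-convolution
interpolation and flagged with coverage 0.

## Reconstruction, autofocus and peeling

The intensity hologram is lifted to a complex field as
`sqrt(max(I,0))` with zero phase — the standard single-shot treatment;
no iterative phase retrieval is attempted.  Back-propagation by −z2
yields amplitude and phase images.  The zero-phase lift halves the
object term and adds a conjugate (twin) term focused at −z2.

Autofocus scans a height range and optimizes a windowed criterion:
minimum amplitude or maximum phase, ties toward smaller z2, with a
degenerate-flat guard.  Two systematic effects are worth knowing:
the pixel-aperture blur of the recorded hologram biases the
minimum-amplitude optimum a few micrometres high, while the twin-image
halo biases the maximum-phase optimum slightly low; for point-like
beads both land within a few micrometres of truth, but large
(several-um) objects at this wavelength have Fresnel numbers well below
1 and no sharp amplitude focus at all — their defocus ripples undershoot
the in-focus minimum.  Hence the pipeline focuses on bead signatures,
not on the large registration marks.

Digital object peeling removes strong objects: the hologram field is
propagated to the twin plane (+z2 in this package's sign convention)
and/or the object plane (−z2); cells whose phase deviates from the
background median by more than a threshold (mask dilated by 3 cells)
are replaced by the median amplitude/phase of a 10-cell annulus around
the mask; the field returns to the sensor plane as a complex hologram.
Deviation-from-median thresholding (rather than absolute phase) makes
the threshold insensitive to any residual global phase.

## Detection

1. **Background compensation.**  For each height z, the phase of the
   reconstructed hologram is divided element-wise by the phase of the
   reconstruction of its own low-pass (σ = 0.1 /um) version, after
   adding 2π to both.  The offset bounds the denominator below by +π
   for wrapped phase, and background cells come out near 1.
2. **Multi-height averaging.**  Compensated phase images over
   z2* ± 20 um at 1 um steps (41 planes) are averaged.  Physical
   particles stay laterally fixed across heights; noise grains wander
   and attenuate.  The half-range reading of the neighbourhood brackets
   the focus symmetrically and is configurable.
3. **Thresholding.**  Candidates are connected components (≥ 2 cells)
   above median + k·1.4826·MAD with k = 6 (strict inequality), located
   by intensity-weighted centroid.
4. **Focus validation.**  For each candidate the peak compensated phase
   is traced over z2* ± 40 um at 2 um steps (41 samples) and an
   ordinary least-squares parabola `y = a z² + b z + c` is fitted.  A
   candidate passes iff a < −9·10⁻⁶ (compensated-phase units per um²),
   R² > 0.42, and |−b/2a − z2*| ≤ 15 um, where z2* is the candidate's
   own curve maximum.  The unit convention behind the curvature
   threshold is this pipeline's own (compensated-phase units, z in um);
   the thresholds are configuration.
5. **Contrast.**  For extended aggregates, contrast is
   (mean background − min target)/mean background on the amplitude
   image, clipped at zero.

## Mie detection-limit analysis

The forward-scattering radar cross section of a perfect-electric-
conductor sphere is computed from the Mie series with
index-free coefficients `aₙ = jₙ(x)/hₙ(x)`,
`bₙ = [x jₙ(x)]′/[x hₙ(x)]′`, forward amplitude
`S(0) = ½Σ(2n+1)(aₙ+bₙ)` and `σ = λ²/π·|S(0)|²`, truncated at
`⌈x + 4x^{1/3} + 2⌉` terms.  Spherical Bessel functions come from
scipy.  `equivalent_diameter` inverts the RCS-vs-diameter curve by
bisection (0.01 nm tolerance) to translate a detection limit across
wavelengths; a 250 nm limit at 532 nm maps to ≈177 nm at 266 nm, the
quantitative basis for the UV platform's sensitivity advantage.  A
dielectric-sphere mode (real index) is included for realism checks; the
PEC idealization is the one used for the wavelength-scaling argument.

## What the synthetic data does and does not show

The simulator reproduces the features the processing chain depends on:
coherent in-line holograms with correct fringe geometry, sub-pixel
shift diversity with differential motion of out-of-plane noise, Bayer
sampling, pixel-aperture integration, shot/read noise, and nanolens-
like signal gains.  It does not model the real optic stack (the
parasitic planes are a two-reflection caricature), vectorial effects,
laser pulse structure, galvo dynamics, sample-substrate reflections, or
the chemistry of nanolens formation.  Passing tests therefore
demonstrate that the algorithms recover what this forward model
encodes at realistic SNR — not that the instrument achieves a specific
physical detection limit.  Noise amplitudes and nanolens gains are
stated per scene and are the package's own calibration of "clearly
detectable" versus "buried".

## Problem sizes and numerical defaults

Validation workloads are sized for a laptop-class single core: the
circular-averaging comparison uses 556 frames of 512×512 pixels (one
bead plus full coherent noise); the end-to-end recovery uses 556 frames
of 256×256 pixels with 20 beads, a 4-speck dust mark for registration,
and a particle-free twin acquisition for the false-positive test.
Fixed seeds make every figure in the test suite reproducible
bit-for-bit.  Key defaults: λ = 0.266 um, pitch 1.12 um, SR factor 4
(0.28 um), z2 = 400 um, autofocus scan 300–500 um, averaging ±20 um @
1 um, focus curves ±40 um @ 2 um, k = 6, a_max = −9·10⁻⁶, R²_min =
0.42, z_tol = 15 um.  All are overridable via `PipelineConfig` (YAML
round-trip) or CLI flags.

## Known limitations

* Registration precision degrades if coherent background fringes are
  much stronger than the sample-plane mark; the constrained search and
  apodization mitigate but do not eliminate this.
* Min-amplitude autofocus is unreliable for objects larger than the
  first Fresnel zone (≈ 20 um at 266 nm / 400 um); use the phase
  criterion or a sharpness metric for such objects.
* The intensity lift keeps the twin image; peeling suppresses the twins
  of strong objects but weak-object twins remain as low-level ripple.
* Periodic FFT boundaries wrap diffracted energy at small fields of
  view; border exclusion handles detection, but quantitative work near
  edges should pad.
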