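# Methods

This note documents the models implemented in `elastowave`, the defaults
and why they were chosen, the numerical details, and what the synthetic
validation does and does not demonstrate about real acquisitions.

## Wave-field simulator

The simulator produces the separable axial displacement field

    u(z, x, t) = A · w(z) · exp(−α|x−x₀|) · g(t − t₀ − |x−x₀|/c)

for a transient wave launched at the excitation position x₀ and
propagating bilaterally at group velocity c. The temporal pulse
g(τ) = exp(−τ²/2σ_t²)·cos(2πf₀τ) is a Gaussian-enveloped cosine; the
bandwidth parameter is the FWHM of its Gaussian amplitude spectrum, so
σ_t = 2√(2 ln 2)/(2πB). A Gaussian-windowed tone was chosen because it is
the simplest transient with an analytic spectrum; real air-puff and
radiation-force excitations are not pure Gaussians, but only arrival
structure and bandwidth matter to time-of-flight velocimetry. The onset
delay t₀ = 3.5σ_t keeps the pulse inside the time axis, which is sized by
default so the tail clears the farthest lateral position.

No dispersion is modeled: all frequency components travel at c, so the
group velocity is exact by construction. This is the main idealization —
real gelatin and tissue are mildly dispersive, and the two modalities'
different excitation bandwidths can therefore produce genuinely different
speeds in real data. Passing recovery tests here demonstrates correctness
of the processing chain, not immunity to dispersion.

### Depth profiles

Surface-launched waves (OCE) decay exponentially from the surface,
w(z) = e^{−z/ζ} with ζ = 1 mm by default; the depth dependence of real
surface waves is not characterized here beyond "smooth and decaying",
which suffices because the analysis averages over a 400 µm window.
Radiation-force pushes displace most strongly around the focal depth, so
USE geometries get a Gaussian bump centered on the 4 mm push focus
(σ = 1 mm). Beam profiles of the push itself are not simulated.

### Acquisition geometries (defaults, SI units internally)

| parameter | OCE | USE | rationale |
|---|---|---|---|
| lateral line | 251 pts / 7.83 mm | 128 pts / 25.2 mm | OCE: M-B-mode line scan; USE: field of view spanning most of a 128-element linear array |
| frame rate | 30 kHz | 10 kHz | swept-source A-scan rate; typical shear-wave tracking PRF |
| depth axis | 32 pts / 1.5 mm | 160 pts / 6 mm | OCT imaging depth; imaging down past the 4 mm push focus |
| optics/acoustics | λ₀ = 1310 nm, n = 1.4 | f_c = 7.8 MHz, c_sound = 1540 m/s | standard OCT source; linear-array imaging/push frequency |
| pulse | 573 Hz, 0.5 µm peak | 1073 Hz, 10 µm peak | transient excitation bandwidths typical of air-puff vs radiation-force pushes; push displacements are ~20× air-puff ones |

The USE lateral span deserves a note: truncating a still-propagating wave
at the edge of the tracked region smears its frequency-wavenumber
signature across quadrants and biases directional filtering (we measured
~2 % at 5 m/s with a 12.6 mm window). Real systems track across the full
beamformed field of view, so the wide window is the physically faithful
choice, not a tuning.

Default phantom materials are four stiffness levels (10/17/27/40 kPa, two
phantoms each) spanning the soft-tissue gelatin range; ground-truth shear
speeds follow from E = 3ρc² (≈1.8–3.7 m/s). Removal/replacement jitter is
modeled as Gaussian on speed only (SD 1.5 % of the speed), not on
geometry — repositioning a homogeneous sample changes the interrogated
material only marginally, and there is no repositioning model to draw on.

### Encodings and noise

* **OCE**: frames a(z)·exp(iφ) with φ = (4π/λ₀)·[n·u(z) − (n−1)·u_surf],
  the double-pass optical path for a sample imaged in air (light to depth z
  crosses the moved surface, hence the (n−1) air-gap term). Backscatter
  intensity decays exponentially with depth so the surface is the
  brightest return. Noise: additive circular Gaussian phase noise per
  pixel/frame (default 0.1 rad in the experiments — conservative for
  phase-sensitive OCT).
* **USE**: baseband IQ exp(i·4πf_c·u/c_sound) plus complex white Gaussian
  noise at a relative SD (default 0.1 of the signal amplitude, i.e. 20 dB).
  Speckle texture and depth-dependent gain are *not* modeled; complex
  white noise is the stated scope.

Both encodings are exactly invertible at zero noise, which the test suite
uses as round-trip identities.

## Displacement estimation

**OCE.** Inter-frame phase differences from conjugate products, unwrapped
along time (1-D, branch cuts at π; transient single pulses rarely wrap
more than once — unwrapping can be disabled). The surface is the first
depth bin above a configurable fraction (default 0.5) of each A-scan's
peak intensity. The corrected per-frame displacement is
dz = [λ₀Δφ/4π + (n−1)ds]/n with ds from the surface bin; rigid motion
(dz = ds) passes through exactly for any n, which pins the correction
algebraically. A result whose phase increments have mean resultant length
< 0.2 is flagged low-SNR rather than silently returned.

**USE.** The Loupas 2-D autocorrelator: mean slow-time Doppler phase over
a depth × ensemble window (default 5 × 2 samples), scaled by c/(4πf_c) and
divided by the ratio of the locally estimated center frequency to the
nominal one. The local frequency comes from the fast-time lag-one
autocorrelation; because it is a property of the medium and not of the
motion it is estimated from the whole ensemble, which averages out the
oscillating strain contribution of the transient itself. With a 1-sample
depth kernel no local estimate exists and the estimator reduces exactly to
the Kasai lag-one autocorrelator (pinned by an oracle test). Estimates
approaching the λ/4 unambiguous range trigger an aliasing warning. Note
the estimator returns the kernel-averaged motion — tests compare against
the equivalently smoothed field.

## Spatiotemporal reduction

Depth averaging is an unweighted mean over a 400 µm window — from the
surface for OCE, centered on the push focus for USE (the anchoring is a
documented default, not a claim about any particular instrument).
Directional filtering is a quadrant mask in the 2-D Fourier (f-k) domain:
a rightward wave occupies sign(ξ)·sign(f) = −1. The map mean is removed
up front (DC belongs to neither direction), both axes are zero-padded by
half their length to suppress periodic wrap-around, and the mask edges are
smoothed with a short raised-cosine kernel (2 bins) to limit ringing; the
left+right outputs partition the DC-free input up to that roll-off.
Bilateral splitting re-indexes each side by distance from the excitation
and drops positions within a 0.5 mm near-field exclusion zone, where
time-of-flight is biased by source effects. The OCE chain splits sides
without directional filtering (the two differ only near the source, which
the exclusion zone removes); the USE chain filters first, then fits the
matching side — both chains accept either configuration.

## Velocimetry

Arrival times: normalized cross-correlation of each position's trace
against the reference (the first position outside the exclusion zone —
nearest the source, hence highest SNR before attenuation), integer-lag
maximum (ties toward the smaller lag) refined by three-point parabolic
interpolation, clamped to ±0.5 samples. Traces are correlated without
per-trace mean removal: transient displacement traces are zero-baseline by
construction, and subtracting a mean introduces a pedestal that biases the
sub-sample refinement. Positions whose correlation peak falls below 0.3
are excluded (decorrelated traces carry no timing information).

The slowness fit is iteratively reweighted least squares with weights
w_i = 1/(|r_i| + 0.1·MAD(r)), iterated to a relative slope change < 1e-6
(max 50 iterations); an exactly linear series short-circuits to equal
weights, and a Tukey bisquare weighting is available as an alternative.
Inverse-absolute-residual weighting is one reasonable reading of
"residual-weighted"; it is robust to the gross single-point outliers that
decorrelation produces, and the tests assert outlier insensitivity against
an outlier-free OLS reference rather than any particular weight formula.
Side speed is the inverse slope (non-positive slopes are invalid); the
reported speed is the mean of the valid sides.

## Elasticity

E = 2ρ(1+ν)³/(0.87+1.12ν)²·C_g² for surface-wave speeds and E = 3ρc² for
shear speeds (ν = 0.5, ρ = 1000 kg/m³ defaults). The Rayleigh-to-shear
ratio is computed by default from the secular cubic
η³ − 8η² + 8(3−2ξ)η − 16(1−ξ) = 0, ξ = (1−2ν)/(2(1−ν)), solved by Brent's
method to 1e-12 for the root in (0,1); at ν = 0.5 this gives
√η = 0.95531 (≈95.5 %), versus 0.95333 from the rational approximation
(0.87+1.12ν)/(1+ν), which is also exposed. The two moduli models agree to
< 1 % when speeds are corrected with the exact ratio; the residual is the
rational approximation baked into the surface-wave formula.

## Repeatability statistics

Bland–Altman: per sample, each trial's difference from the sample mean
(x-coordinate: the sample mean); bias = grand mean of differences,
LOA = bias ± 1.96·SD (sample SD, n−1). Differences from a sample's own
mean sum to zero, so under this literal definition the bias is identically
0; a leave-one-out variant (difference from the mean of the remaining
trials, = (n/(n−1))·the centered difference) is provided because it breaks
that degeneracy, but neither variant is claimed to reproduce any
particular nonzero bias. Normalization divides each difference by its
sample mean (×100). ICC is the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1) computed from the two-way ANOVA mean
squares; a zero-variance matrix is degenerate perfect agreement (ICC 1
with a warning). The trend fit is plain OLS of differences on means with
the two-sided t-test on the slope; no multiple-testing correction is
applied (slope tests are reported raw). MAPE is the mean of
|measured − reference|/reference × 100.

## Experiment pipeline

`run_phantom_experiment` simulates every material × trial × modality:
ground-truth shear speed from the modulus, per-trial jitter, modality
encoding and decoding, map, velocity, Rayleigh correction (OCE only, since
OCE tracks the surface wave — the simulator accordingly launches the OCE
wave at 0.9553·c), modulus, then BA/ICC/MAPE summaries.
`run_anisotropy_experiment` does the same with angles as samples, the
ground-truth speed following the elliptical profile
c(θ) = √((c_∥cosθ)² + (c_⊥sinθ)²) between the fiber-parallel and
perpendicular speeds. Per-stage seeds derive from the configured seed via
`numpy.random.SeedSequence`, so reports are bit-reproducible; every
summary is recomputable from the report's own per-trial table (audited by
a test). Failed trials are recorded per row and the report is still
produced while at least one trial per sample succeeds.

The test and example configurations run reduced grids (e.g. 101 lateral ×
12 depth points for OCE, 64 × 60 for USE) — enough for sub-percent
recovery while keeping the full suite to about a minute; the acceptance
recovery checks use the full default geometries.

## Known limitations

* No dispersion, viscoelasticity, or phase-velocity analysis; group
  velocity only.
* No speckle statistics, beam profiles, reflections, or mode conversion in
  the simulator; noise is additive (circular Gaussian phase for OCE,
  complex white for USE).
* Axial displacement only; line-scan (2-D + time) only.
* The exact residual-weighting scheme used by practitioners varies;
  recovery is validated against ground truth, not against a specific
  historical estimator.
* MAPE against ground truth in the synthetic experiments reflects chain
  accuracy only; real-data MAPE against mechanical testing additionally
  contains model error (boundary conditions, dispersion, sample
  preparation) that the simulator deliberately omits.
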