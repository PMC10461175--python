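# Methods

`fmpi` simulates and analyzes a functional magnetic particle imaging (fMPI)
experiment: a rotating field-free-line (FFL) scanner watches the
superparamagnetic iron oxide (SPION) content of a rodent brain slice while
alternating hyper-/hypocapnia modulates cerebral blood volume (CBV).  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic tests do and do not demonstrate.

## Scanner physics

The selection field is modelled as the divergence-consistent FFL form
`B_sel = G (s n̂ − z ẑ)`, where `s` is the signed in-plane distance from the
line (direction set by the gantry angle), plus a uniform axial drive field
`B_d sin(2π f₀ t)`.  Defaults: `G = 2.83 T/m`, `f₀ = 25 kHz`, `B_d = 8 mT`
peak.  Tracer magnetization follows the Langevin curve
`L(ξ) = coth ξ − 1/ξ` with a series branch (`ξ/3 − ξ³/45`) below
`|ξ| < 1e−4` to avoid cancellation; the field scale at which `ξ = 1`
defaults to 2.5 mT, which puts the native in-plane point-spread FWHM near
3 mm at this gradient.  The receive signal is the time derivative of the
axial magnetization over one drive period (256 time steps), decomposed into
drive-frequency harmonics; the fundamental is excluded (drive
feed-through is filtered in hardware).

This field model reproduces the defining through-plane symmetry of an FFL
imager: for a source at `z = 0` the axial field is half-wave antisymmetric
over the drive period, so even harmonics vanish identically; out-of-plane
sources break the symmetry and leak into even orders.  Real scanners have
measured field maps; side-lobe amplitudes of the through-plane PSF are
therefore only qualitatively meaningful here, the even/odd structure is
exact.

A frame is 27 projection angles x 66 shift samples (0.45 mm) across a 30 mm
field of view, one frame per 5 s half rotation, acquired in sets of 5 with
a 5 s re-triggering gap (83% duty cycle).  Frames are stamped with their
completion time, so a 30 min run yields 300 frames, the last at `t = 1795 s`.
Projections within a frame are treated as simultaneous: the 184.8 ms
per-projection stagger is negligible against hemodynamic time scales.

Because the harmonic response of a point source depends only on
`(|s|, z)`, responses are evaluated on a fixed 8192-point distance table
per distinct `z` and linearly interpolated (the table oversamples the
Langevin transition scale ~100-fold; interpolation error is ~1e−5
relative).  The fixed table span makes superposition exact, which the
linearity tests exploit.  `simulate_voxel_signal` retains the direct
time-domain path.

## Reconstruction

The system matrix has one column per reconstruction-grid voxel: the
simulated sinogram of a unit-mass source there.  2D mode uses odd
harmonics (3, 5, 7, 9)·f₀ and one z slice (valid for objects confined to
the central plane); 3D mode uses (2, 3)·f₀ over 5 z slices spanning 7 mm,
and only the center slice of the solution is kept — the outer slices
absorb out-of-plane interference, which the tests verify (an identical
source at `z = 2 mm` reconstructs with strictly lower center-slice peak
than at `z = 0`).

Complex measurement rows are split into real/imaginary parts and the
matrix SVD'd.  A right singular vector is retained when more than 10% of
its center-slice 2D spectral energy lies inside the low-frequency radial
band; the pseudoinverse is assembled from the retained triplets.  This is
directly analogous to Tikhonov regularization — fewer vectors, more
smoothing.  **Band definition:** the band edge is a fraction (default
0.15) of the *acquisition's* Nyquist frequency, `1/(2 · 0.45 mm)`, i.e.
0.167 cycles/mm, converted to each grid's units.  Defining it against the
reconstruction grid's own Nyquist would make the physical selection rule
depend on the analysis grid and, on desk-scale grids, collapse the
retained set to a handful of near-DC vectors (measured: 6 of 289 on a
17×17 grid, PSF ≈ 10 mm).  With the physical definition the same grid
retains 85 vectors and reconstructs a point source at ≈ 3.7 mm FWHM,
consistent with the instrument's ~3 mm native / 2.55 mm reconstructed
resolution.  A fixed retained-vector count can be forced via
`retained_count` for matching an externally calibrated operator.  Whether
the energy rule should be evaluated per z slice or on the full 3D vector
is open; the center slice is used.

Images are smoothed to 3 mm FWHM (σ = FWHM/2.3548, reflect padding).
Resolution is measured by least-squares matching the image of a point
source to its ground truth convolved with a Gaussian of candidate width,
profiling the amplitude out analytically.

**Unit calibration.** Simulated signal units are arbitrary; the anchor is
the instrument's characterized sensitivity.  `calibrate_signal_gain` sets
the tracer gain so a processed (reconstructed + 3 mm smoothed) point
source peaks at `0.86 · √(2π²/3) · 0.0133` A.U. per ng, which makes the
static ROI SNR of a mass-`m` source equal `0.86·m` under the 0.0133 A.U.
noise floor and the Rician-corrected SNR convention below.  The dilution
round-trip test recovers a slope of 0.854 SNR/ng.

## Synthetic study generator

The generator emulates the *instrument*, not biology:

* **Phantoms** — single-voxel wells in a dilution series (default halving
  from 250 ng: 250/125/62.5/31.25/15.625), and an elliptical brain
  blood-pool map at 210 ng per 3 mm voxel (the resting value implied by a
  10 mg/kg dose, 64 ml/kg blood and 5% blood volume) with optional 20×
  large-vessel hotspots.
* **Physiology** — 5 min alternating capnic states, 3 cycles, starting
  hypocapnic.  Voxel Fe mass is
  `baseline · (1 + δ · (block ⊛ CO₂RF)) · e^{−t/τ₂}` with the CO₂
  response kernel `t e^{−t/τ₁}` normalized to unit steady-state gain, so
  `δ` (default 0.25) reads directly as the fractional CBV modulation and a
  210 ng voxel swings by 52.5 ng.  Convolution runs on an internal 2.5 s
  grid with the kernel truncated at 10 τ₁ and renormalized to unit sum,
  keeping the plateau gain exact.
* **Noise** — per frame value `v` at sample index `i`, wall time `t`:
  `g_i v (1 + ε_gain) + drift(t) + transient(t) + ε_thermal`, with
  `ε_thermal ~ N(0, σ₀ = 0.0133)`, `ε_gain ~ N(0, λ = 0.017)` per frame,
  and `g_i` alternating `1 ± δ_q/2` within each set (δ_q = 1%, motivated
  by the 1% drive-current stability; the true quadrant imbalance is not
  characterized).  The empirical frame-to-frame SD then follows
  `σ_tot = √(σ₀² + (λS)²)`, and the quadrant pattern alone puts all its
  spectral power at 0.2 and 0.4 cycles per sample.  Drifts and the
  `e^{−t/τ_d}` warm-up transient default to zero.  Seeds are mandatory;
  there is no hidden RNG state.  Noise can be injected at sinogram or
  image level; the image level is the default and the level at which σ₀ is
  defined (after smoothing), so the SNR calibration is self-consistent.

Absent from the generator: physiological (cardiac/respiratory) noise,
motion, spatially correlated noise, batch-to-batch tracer variation.
Passing tests therefore demonstrate correctness of the analysis chain
under the instrument noise model, not robustness to in-vivo confounds —
the gap between the phantom-style CNR (~45) and in-vivo-style CNR is
expected to be dominated by exactly those confounds.

## Preprocessing

The alternating-quadrant artifact is excised with a zero-phase hard
frequency-domain notch: per voxel, subtract the mean, zero all DFT bins
within 0.0375 cycles/sample of 0.2 and 0.4, invert, restore the mean.
The hard mask makes the filter exactly idempotent; it operates on the
acquired-sample index (the artifact is periodic in samples, not seconds),
while wall-clock timestamps are kept for the GLM.  The hypercapnia band
(1/120 ≈ 0.008 cycles/sample) is untouched to < 1%.

Static SNR = ROI peak / (√(2π²/3) · SD of the same ROI in an empty-bore
image), central 10×10 ROI.  The Rician factor compensates the non-zero
mean of magnitude-image noise; whether it belongs on the noise estimate
or the SNR is a convention — here it multiplies the noise SD and is a
configurable constant.

## GLM

Five regressors: activation (block ⊛ CO₂RF, times `e^{−t/τ₂}`), constant,
linear and quadratic drifts (centered, unit range), and a warm-up
transient `e^{−t/τ_d}` with τ_d = 100 s (one third of the first 5 min
half period).  BOLD mode drops the clearance term; phantom mode drops
both kernel and clearance and appends a conditional linear drift zeroed
while the phantom is out.  The activation regressor is rescaled to unit
peak-to-peak, so the fitted coefficient is the peak-to-peak signal change
and CNR = β/residual-SD with residual SD = √(SSR/(n−p)).  p-values come
from the two-sided OLS t statistic with n−p degrees of freedom; the
activation threshold (default 1e−12) is interpreted as the
already-corrected family-wise survival level and is not corrected again.

τ₁ ∈ [5, 300] s and τ₂ ∈ [600, 30000] s are found by Nelder–Mead
minimization (SS tolerance 1e−8) of the in-mask mean time course from a
4×4 log-spaced multistart, inside a grid search over the onset delay
Δt ∈ {−20, …, +20} s in 5 s steps; ties prefer the smallest |Δt|, then the
earlier delay.  A single global hemodynamic model is assumed — the chosen
(τ₁, τ₂, Δt) are applied voxelwise; per-voxel time constants are out of
scope.  On noiseless data the optimum recovers the generator values to
<1%, Δt exactly; at CNR ≈ 17 the median recovered τ₁ over 20 seeds is
within a few percent of the 51 s truth.

Percent signal change references both numerator and denominator to
`t = 0`: the activation amplitude is rescaled by the undecayed/decayed
peak-to-peak ratio of the convolved block, and the baseline is the fitted
drift polynomial extrapolated to `t = 0` (transient excluded); voxels
with non-positive baseline are flagged invalid.  A 25% generator
modulation reads back as ≈ 24–25%.

Degenerate fits (vanishing residual) cap CNR at a 1e6 sentinel with a
warning rather than emitting infinities.

## Metrics

The dilution line is ordinary least squares through (mass, SNR), with the
detection limit `(SNR_ref − intercept)/slope` at SNR_ref = 5, reported to
2 significant figures (5.8 ng at slope 0.86, zero intercept).  The noise
model is fitted in variance space, where it is linear
(`σ² = σ₀² + λ²S²`) and closed-form; negative fitted variances are
clamped to zero with a warning.  Equal thermal/gain contribution occurs
at SNR = 1/λ (≈ 59 at λ = 0.017), i.e. a ≈ 68 ng source on the dilution
line.  Iron accounting: `(dose/blood volume) · edge³ · blood fraction`,
giving 210.9 ng for the defaults (reported as 210).

## Problem sizes

The packaged tests run desk-scale systems chosen to exercise every code
path within a few minutes: a 17×17 grid at 1.75 mm for the 2D operator
(85 retained vectors), an 11×11×5 system for 3D-mode properties, ≤ 8×8
grids for the SVD oracle equivalences, and an 11×11 / 600 s end-to-end
smoke run.  The default configuration (33×33 at 0.9 mm, 1800 s) builds
and inverts in well under a minute and was used to confirm that retention
counts and PSF estimates carry over.  Statistical tolerances follow the
simulation sizes: 10⁴-frame noise checks at 3–5%, 20-seed medians at
10–15%.

## Known limitations

* The selection/drive field geometry is idealized; absolute side-lobe
  shapes and the exact retained-vector counts of a measured system matrix
  cannot be reproduced, only their symmetry and selection behavior.
* The shift sweep is abstracted to uniformly spaced FFL offsets; the
  42 A / 2.7 Hz triangular drive is recorded as descriptive metadata.
* No autocorrelation-aware (prewhitened) GLM; residuals are treated as
  white within each voxel.
* Vessel hotspots in the brain phantom clear with τ₂ but do not modulate
  with capnia (their CBV response is smaller and of opposite sign in
  vivo; modelling it is out of scope).
* The x-space reconstruction route and measured-matrix calibration are
  out of scope.
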