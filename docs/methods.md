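# Methods

This note documents the models, numerical choices and known limitations of
the `ecamri` simulation-and-reconstruction framework.

## The phantom model

A phantom is a function of continuous time: a static background volume plus
additive enhancement at masked voxels, so that before the earliest bolus
arrival the image equals the background exactly.

**Lesion voxels** carry the truncated-exponential uptake model
C(t) = A (1 − e^(−α(t−t₀))) for t ≥ t₀ and zero before, with per-voxel
parameters drawn independently from normal distributions truncated at zero.
The default distributions (A = 1.56 ± 0.45 mM, α = 0.14 ± 0.13 s⁻¹,
t₀ = 15 ± 2.2 s) describe a fast-enhancing invasive carcinoma; four other
presets spanning slower and later enhancement are provided in
`LESION_CASES`.

**Vessel voxels** enhance with the Parker population arterial input
function — two Gaussians (first and second bolus pass) plus a
sigmoid-gated exponential washout, standard published coefficients with
time in minutes — shifted by a per-voxel arrival offset and clamped to zero
before arrival.  Arrival offsets vary linearly along the vessel axis
(12 → 18 s by default), a stand-in for bolus propagation through the
vasculature; a constant offset is a configuration away.  Note the clamp
leaves a ~0.06 mM step at onset (the Parker form is not exactly zero at its
origin); this matters only to estimators that differentiate across the
onset.

**Signal model.** Concentration maps to signal through the steady-state
spoiled gradient-echo equation S = M₀ sin θ (1 − E₁)/(1 − E₁ cos θ),
E₁ = exp(−TR·R1), R1 = 1/T1₀ + r₁C, with θ = 10°, TR = 3.2 ms, relaxivity
r₁ = 4.5 s⁻¹mM⁻¹ and baseline T1 of 0.5 / 1.6 / 1.4 s for background /
blood / lesion tissue.  All are configurable.  T2* decay is not modeled
(TE is metadata only), phantom values are real and nonnegative, and
complex phase enters only through the Fourier transform.  A consequence
worth noting: at the Parker peak (~6 mM) blood is deeply T1-saturated at
these sequence parameters, so the *signal* peak of a vessel voxel is much
flatter than the concentration peak.  This is physically expected and is
why arterial peak-time estimation is noise-sensitive (see Limitations).

**Geometry.** The default grid is 32 × 28 × 7 voxels of 1 mm³: the
28 × 7 = 196-line phase-encode plane divides evenly into 14 sections of 14
sheaves, and the procedural geometry (one ellipsoidal lesion, two tubes
along the readout axis) yields 245 lesion and 576 vessel voxels — enough
for stable median statistics.  User-supplied masks (e.g. from NIfTI) are
accepted and must be disjoint.

## Sampling and the virtual scanner

A trajectory is an ordered list of k-grid indices with one timestamp per
sample, uniformly spaced across each 3.5 s Nyquist-complete sweep.  The
UnWRAP ordering splits the linearized phase-encode lines into f contiguous
sections, each into f sheaves, and acquires sheaf j of every section before
sheaf j+1 of any; with f = 14 and dt = 0.25 s every reconstruction interval
receives exactly one sheaf from every section.  When f does not divide the
line count the last section/sheaf absorbs the remainder, preserving
Nyquist completeness.  DC sits at the grid center (`fftshift` convention)
and all transforms are unitary, so Parseval identities are exact.

The scanner re-evaluates the phantom every 50 ms and linearly interpolates
between updates; because the FFT is linear, interpolating the two
bracketing volumes' Fourier coefficients equals transforming the
interpolated image.  The 50 ms chord error of the enhancement models is
below 0.1% of their amplitude away from onsets (and bounded by
slope·h/4 ≈ 0.18% of A in the window containing the lesion onset kink).

Noise is independent complex Gaussian per k-space sample (per-component SD
σ, scalar or per-k-point map).  The default scalar σ is calibrated so the
sweep-averaged image-domain PSNR — 20 log₁₀(peak of the clean sweep-IFFT
volume / rms of the image-domain noise), averaged over sweeps — equals
37 dB, the documented operating point of the acquisitions this framework
emulates.  Calibration uses the geometric mean of the clean sweep peaks,
which makes the *expected* average PSNR hit the target exactly;
realizations scatter by well under 0.1 dB.

## The ECA reconstruction

Measured samples are grouped by (k-frequency, interval); duplicates within
one interval (possible when dt spans sweep boundaries) are averaged.  The
solver minimizes

  Σ_v w_v Σ_t |Δ X_v(t)|²  +  λ′ ‖X − X_init‖²

over the *unmeasured* Fourier entries, with every measured entry
substituted as a constant — data fidelity therefore holds bit-exactly by
construction rather than through a penalty weight.  Choices:

- **Difference order.** Δ defaults to the second difference: the discrete
  curvature penalty whose interpolants are natural cubic splines.  This is
  the spline-like behavior the method is known for (excellent
  interpolation, linear extrapolation beyond the measured range) and it
  halves the noiseless reconstruction error on the demo phantom relative
  to first differences (rms 5.1 × 10⁻⁴ vs 8.1 × 10⁻⁴).  First differences
  (`diff_order=1`) give piecewise-linear interpolation per frequency with
  constant extension — a useful closed form that the tests exploit.
- **Regularization.** λ′ = λ · 2·mean(w) with λ = 10⁻⁶ by default.  The
  Tikhonov term anchors the solution to the initialization (zero-fill by
  default, optionally a static pre-contrast volume), which keeps the
  eliminated system positive definite.  λ must stay small: the anchor pulls
  each frequency toward its anchor value between measured knots, and with
  first differences the mid-segment sag is ≈ λ·n²/8 for segments of n
  intervals — 5% at λ = 10⁻³ with n = 14, a sweep-periodic bias that
  dominates reconstruction error.  At λ ≤ 10⁻⁵ the error curve is flat.
  With the zero anchor the sparsely constrained first and last time points
  are pulled slightly toward zero — the characteristic end-point
  "undershoot"; anchoring to a pre-contrast volume removes it, which the
  tests verify.
- **Solver.** Conjugate gradients on the free entries, relative-residual
  tolerance 10⁻⁸, iteration cap 2000 (the curvature penalty needs ~1200
  iterations on the 56 s demo problem; the cap flags, never hides,
  non-convergence).  With uniform per-voxel weights Parseval diagonalizes
  the penalty over k-frequencies and the normal operator is applied with
  pure stencil arithmetic — no FFTs per iteration; spatially varying
  weights switch to a per-frame FFT path.  Both paths are verified
  self-adjoint, PSD, and equal to an independently assembled dense
  least-squares solve (`numpy.linalg.lstsq` on explicit difference and DFT
  matrices) to 10⁻⁸ relative error.

The IFFT baseline assembles each Nyquist-complete sweep and inverts it —
the idealized ultrafast reconstruction (equivalently: perfect parallel
imaging and partial Fourier are assumed, since the 3.5 s sweep is taken as
the already-accelerated temporal resolution).

## Kinetic analysis and statistics

Voxel time courses are magnitudes of the reconstructed complex series.
Vessel BAT is the time of peak enhancement (earliest sample on ties);
lesion BAT is the earliest time enhancement over the pre-contrast baseline
reaches 20% of its maximum.  Initial slope is the maximum derivative of a
modified-Akima ("makima") interpolant on a 10 ms grid for vessels, and
A·α from a nonlinear least-squares fit of the piecewise uptake model for
lesions.  The fitted functional form is pluggable; the default truncated
exponential PSE(t) = A(1 − e^(−α(t−t₀))) has right-derivative exactly A·α
at onset, which is the property that makes A·α "the initial slope".  The
fit multi-starts over candidate onset times and flags non-convergence.

Method comparison uses *estimator-on-truth* references: each method's BAT
estimate is compared against the same estimator applied to the densely
sampled (10 ms) ground-truth curve, so estimator bias cancels from the
comparison.  The first and last reconstructed time points are excluded
from ECA kinetic estimation by default (the end-point undershoot region).
Per-voxel error ratios (ECA error / IFFT error) exclude voxels whose
reference error is exactly zero (counted separately); the summary is the
median ratio with a 5σ interval — median ± 5 bootstrap standard errors,
the two-sided level corresponding to p < 10⁻⁶ — plus the median absolute
deviation.  A distribution-free order-statistic interval is provided as a
cross-check.  Voxel fidelity is |recon − truth| normalized per voxel by
the ground-truth time-mean magnitude, summarized by median and MAD per
tissue class.

Quantization floors: the peak estimator localizes a noiseless peak to
within dt/2; the 20%-crossing rule is one-sided (the first sampled
midpoint at or after the true crossing), so its noiseless errors are
distributed in [0, dt) with median ≈ dt/2.

## Problem sizes

The standard study condition reconstructs V = 6272 voxels × T = 224 time
points from N = 16·V samples (α = 14) — about 1.3 million free complex
unknowns, solved in ~2 minutes on one CPU.  The dense-oracle comparisons
use random instances with V·T ≤ 2048, where the full constrained
least-squares system is assembled explicitly.

## What the synthetic phantom does and does not show

The generator emulates the additive structure of early-enhancement breast
DCE-MRI — sparse enhancing structures over a static background — with
exactly known continuous-time ground truth, which is what permits
quantitative BAT/slope error statistics.  It does not model: motion,
cardiac or background parenchymal enhancement, T2* decay (significant in
arteries at peak concentration), coil sensitivities/parallel imaging,
partial-volume mixing at vessel boundaries, or anatomically realistic
morphology.  Passing tests therefore demonstrate the correctness and the
intrinsic resolution of the reconstruction and estimators under the stated
models, not clinical performance.

## Known limitations

- **Vessel peak-time localization is noise-limited at this scale.**  With
  noise calibrated to 37 dB and the SPGR-saturated arterial signal peak
  (curvature ~0.05% of signal per 0.25 s at the top), the per-voxel
  argmax wanders within the flat top: reconstructed temporal noise
  (~10⁻³ of signal, strongly correlated in time) exceeds the peak's
  curvature over ±1 s.  Noiselessly the pipeline localizes vessel peaks to
  the dt/2 quantization floor (11–12× better than the sweep-IFFT
  baseline); with calibrated noise the median improvement drops to ~4×.
  At two to three orders of magnitude more voxels per volume the
  incoherent aliasing contribution shrinks by ~√(V ratio), and vessel
  amplitudes fitted from measured patient data need not sit in the deep
  T1-saturation regime, so larger-scale studies can realize the full
  factor.  Lesion BAT improvement (~10×) is robust at desk scale.
- The solver is plain CG without preconditioning; a temporal-frequency
  preconditioner would cut the curvature-penalty iteration count
  substantially.
- The bootstrap SE of the median is computed at n_boot = 2000 by default;
  for very small masks the 5σ interval is accordingly approximate.
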