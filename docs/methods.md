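# Methods

This note documents the models, algorithms and numerical choices behind
`cstpm`, in the spirit of the methods documentation of packages such as
msprime or statsmodels: what is computed, under which assumptions, and
which knobs matter.

## Problem setting

Tissue phase mapping (TPM) is cine phase-contrast MRI of the myocardium:
every pixel of every cardiac frame carries a velocity measurement encoded
in the phase of the complex MR signal. Fully sampled TPM of a small-animal
heart takes 10–20 minutes per slice, which makes it sensitive to
physiological drift and limits throughput. `cstpm` implements the
compressed-sensing route to acceleration: acquire a pseudo-random subset
of Cartesian phase-encode lines, reconstruct by enforcing sparsity of the
dynamic image series in temporal frequency, and quantify how much the
derived functional read-outs (regional velocities, circumferential strain)
deviate from a fully sampled reference.

## Undersampling mask design

Only the phase-encode axis (ky) is undersampled; readout is always fully
sampled. A mask for one (frame, encoding) pair keeps
`n_acq = ceil(n_ky / us_factor)` lines:

* a deterministic **centre block** of `round(n_acq / 4)` lines, symmetric
  about the DC line at index `floor(n_ky / 2)`, is always acquired, so a
  quarter of the acquired lines sample the contrast-dominating centre of
  k-space by construction;
* the remaining lines are drawn without replacement from the periphery
  with weight `w(ky) = (1 − d/(d_max + 1))^p`, `d` the distance to DC and
  `p = 2` by default. The `+1` keeps the outermost line at nonzero weight
  so a nominal factor of 1 can (and does) select every line. Sampling uses
  `numpy.random.Generator.choice`, so a mask is fully determined by its
  seed.

Incoherence is screened by the **sidelobe-to-peak ratio** (SPR) of the
mask's 1-D point spread function: the largest off-peak modulus of the DFT
of the acquire/skip indicator divided by the zero-lag peak. A fully
sampled mask has SPR 0, a single line SPR 1. Candidates are redrawn (with
deterministic sub-seeds) until SPR falls at or below `spr_max`, up to
`max_attempts` (default 100); on exhaustion the lowest-SPR candidate is
returned flagged `accepted=False`.

With the default centre-weighted density the SPR of a realistic mask is
dominated by the coherent near-DC lobe of the contiguous centre block and
typically lands between 0.3 (2× on 128 lines) and 0.95 (16×). The default
`spr_max = 0.25` therefore acts as a *best-of-attempts* selector — every
mask in a default set is the most incoherent of its 100 candidates — and
users who want the screen to accept outright should raise `spr_max` to the
regime of their factor and grid. Both the threshold and the centre
fraction are explicit configuration because no principled single value
covers all (n_ky, us) combinations.

A different mask is generated per cardiac frame and per velocity encoding
(sub-seeded from `(seed, frame, encoding)`), which spreads aliasing
incoherently along the temporal-frequency axis that the reconstruction
exploits; the whole set is serializable (HDF5 or plain text) so one set
can be reused across datasets.

## Reconstruction

Per receiver coil and velocity encoding the reconstruction addresses

    min ‖T x‖₁   s.t.   ‖R x − k‖₂ ≤ ε,

with `T` a *pixelwise temporal Fourier transform* (cine data are
quasi-periodic, hence sparse in temporal frequency), `R` the partial
Fourier operator of the mask and `k` the measured samples. The iteration
is projection onto convex sets with shrinkage:

1. inverse 2-D FFT of the current k-space estimate, frame by frame;
2. forward temporal FFT per pixel;
3. soft-thresholding of the real and imaginary coefficient parts;
4. inverse temporal FFT; 5. forward 2-D FFT;
6. residual bookkeeping (below); 7. data consistency: measured samples
   overwrite the estimate at acquired locations.

All transforms are unitary and k-space is kept centered (fftshift layout,
DC at `n//2`), making energy identities exact and testable.

**Threshold.** `lam` is expressed relative to the maximum temporal
coefficient modulus of the zero-filled reconstruction, separately per
(coil, encoding). This makes the setting invariant to receive gain and
coil scaling; an absolute mode is available via `lam_absolute`. The
shipped selection procedure reconstructs a reference undersampled dataset
over an ordered candidate grid and returns the smallest candidate whose
run triggers the stopping rule strictly inside the iteration window — a
reproducible surrogate for manual tuning. A run stopping at exactly
`min_iter + 1` plateaued at the first permitted check (the `lam = 0`
degenerate behaviour) and is not considered a genuine in-window
convergence.

**Stopping rule.** Iteration `i` stops when
`|r_i − r_{i−1}| ≤ tol_frac · |r_1 − r_2|` with `tol_frac = 0.01`, subject
to `i > min_iter = 15` (guarding against signal loss from aggressive
denoising) and a hard cap `max_iter = 50`. The residual
`r_i = ‖R x_i − k‖₂` is evaluated on the thresholded estimate *before*
data consistency — after reinsertion it is identically zero and the rule
would be vacuous. Residuals below `1e-12 · ‖k‖₂` are snapped to exact
zero: they are zero in exact arithmetic (full sampling, or `lam = 0`) and
leaving FFT round-off in place would let machine noise decide the stop
iteration.

Coils and encodings are mathematically independent (per-channel threshold,
channelwise operators); the implementation vectorises them through one
shared loop and evaluates the stopping rule on the aggregate residual so
the run has a single iteration count. Results are independent of any
execution order by construction.

Observed regimes on the phantom: `lam = 0` is the identity and stops at
`min_iter + 1` with the zero-filled result; thresholds far below the
useful range denoise so little that the residual keeps creeping and the
cap at 50 engages; well-chosen thresholds converge in roughly 20–45
iterations, consistent with the intended operating window.

## Velocity decoding

Encoding `e` with normalized first-moment direction `M_e` yields pixel
phase `φ_e = φ₀ + (π/venc) M_e·v`. Coil images are combined by the
magnitude-weighted reference-encoding product
`Σ_c conj(img_c,ref)·img_c,e`, which cancels coil phase exactly while
preserving the inter-encoding differences; the unknown reference
projection is absorbed by the intercept `φ₀` of the per-pixel least-squares
solve (design matrix `[1 | (π/venc) M]`, required to have full column
rank 4). Two-encoding data are decoded as `v = venc·Δφ/π` along the
encoded direction. No phase unwrapping is performed: velocities are
assumed within ±venc per encoding difference, which the phantom respects
and which `render_kspace` asserts. Zero-magnitude pixels decode to
velocity 0 and are flagged rather than set to NaN, for the benefit of the
downstream integration.

Shipped schemes: two-point (per axis), balanced four-point (tetrahedral
±1 corners) and a symmetric nine-point (reference plus the eight
(±1,±1,±1) corners); any full-rank user matrix is accepted, so acquisition
designs from the literature can be supplied as data.

**Background phase.** Eddy-current-like offsets are removed by fitting a
2-D polynomial (order 0–2) per frame and component over user-supplied
static-tissue pixels and subtracting it everywhere; the static-region mean
is zero to numerical precision afterwards. This is a deliberately simple
surrogate for full eddy-current calibration and handles constant/linear/
quadratic spatial drifts only.

## Kinematics

The myocardial mask is partitioned into 6 contiguous angular sectors
about its centroid (`floor(n·θ/2π)` with configurable reference angle).
Radial velocity is the in-plane velocity projected on the unit vector
from pixel to centroid, **positive toward the centroid** so systolic
contraction reads positive; longitudinal velocity is the through-plane
component. Segment curves are transmural means over sector pixels, the
global curve the mean over the whole mask — hence exactly the pixel-count
weighted mean of the segments.

Circumferential strain comes from Lagrangian tracking: a closed midwall
contour (72 points by default) is integrated through the velocity field
with an explicit midpoint (RK2) step per frame interval and bilinear
interpolation; the midpoint-time velocity is the average of the bracketing
frames (periodic at the cycle end). Units are exact: 1 cm/s = 0.01 mm/ms,
positions in pixel coordinates via FOV/matrix spacing. Engineering strain
`100·(L(t) − L(0))/L(0)` is evaluated on the polyline arc length, per
segment (edges assigned by the frame-0 midpoint angle; at least 3 points
per segment enforced) and globally; strain at frame 0 is identically 0,
and the global curve is the initial-length-weighted mean of the segment
curves up to round-off. Trajectories leaving the grid are clamped to the
boundary and flagged. Because strain integrates velocity, per-frame errors
accumulate over the cycle — the noisy-phantom tests assert exactly this
growth pattern.

## Synthetic phantom

The generator emulates a short-axis slice of a contracting myocardial
ring with fully closed-form motion: radius scale `s(t) = 1 − a·sin²(πt/T)`
(so peak circumferential strain is exactly −100·a %strain), in-plane
velocity `(x − c)·s'(t)/s(t)` — linear in position, which bilinear
interpolation reproduces exactly inside the ring — and a uniform
longitudinal velocity `A·sin(2πt/T)`. Defaults, chosen once as realistic
for a rat heart on a small-bore system: 128×128 matrix over a 50 mm FOV,
24 frames over a 150 ms cycle, ring radii 3.0–5.5 mm, `a = 0.15`
(peak strain −15%), longitudinal amplitude 2 cm/s, venc 13.9 cm/s,
4 receive coils with smooth complex quadrant sensitivities, relative
complex Gaussian k-space noise 0.02 (k-space RMS–referenced), balanced
four-point encoding. Static Gaussian blobs outside the ring provide
reference tissue for background-phase tests, and an optional
`eddy_amplitude` injects a linear spurious velocity ramp that the
correction must remove.

What the phantom does **not** emulate: realistic fibre mechanics or wall
thickening, blood signal and flow artifacts, respiratory/cardiac gating
errors, B0/B1 inhomogeneity, or partial-volume effects at the endo- and
epicardial borders beyond the smooth sub-pixel edge of the ring. Passing
tests therefore demonstrate correctness of the numerics and of the
pipeline's contracts under ideal-to-moderately-noisy conditions, not
in-vivo performance.

## Agreement analysis

Velocity and strain samples are not normal, so agreement uses the
nonparametric Bland-Altman form: bias = median of paired differences,
95% limits of agreement = their 2.5th/97.5th percentiles, computed with
linear interpolation between order statistics (numpy's default "linear"
method) so results are reproducible to the last digit. Group contrasts
use the two-sided Wilcoxon rank-sum test — exact null distribution when
both groups are small and tie-free, tie-corrected normal approximation
otherwise — with Bonferroni correction `α = 0.05 / n_tests` (0.0125 for
the four undersampling factors).

`retrospective_experiment` pairs, per factor, the per-frame global curves
and the pooled (segment, frame) regional curves of the undersampled
reconstruction against the fully sampled reference analysed with the
*same* segmentation and contour, pooling all frames (and segments, for
regional scope) into one difference vector per table cell. A factor-1
control run goes through the identical code path and yields exactly zero
bias and limits, which doubles as a pipeline-determinism check.

## Problem sizes

Analysis-scale runs in the test suite and the acceptance script use a
64×64 matrix with 16 frames, 4 coils and 4 encodings; unit tests use
32×32 with 8 frames and 2 coils. These sizes preserve every regime of
interest (the 4× mask keeps 16 of 64 lines with a 4-line centre block;
16× keeps 4 lines) while keeping a full retrospective study across
factors {1, 2, 4, 8, 16} to well under a minute.

## Known limitations

* Single-slice 2-D only; no kt-coupled or 3-D reconstruction, no
  parallel-imaging (SENSE/GRAPPA) combination, no non-Cartesian
  trajectories.
* No phase unwrapping: velocities beyond ±venc alias.
* Strain is circumferential-only (no radial/longitudinal strain, torsion
  or strain tensors), and no automatic myocardial segmentation is
  provided — masks are inputs.
* The SPR screen measures 1-D mask incoherence only; it does not model
  the temporal dimension of the aliasing.
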