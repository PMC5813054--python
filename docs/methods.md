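# Methods

`carotidcs` simulates, end to end, how a compressed-sensing (CS)
accelerated 3-D black-blood multi-contrast carotid protocol is validated:
digital vessel phantoms stand in for volunteers and patients, a Fourier
forward model with variable-density undersampling stands in for the
scanner, an iterative sparsity-promoting reconstruction with hard data
consistency and an autocalibrated parallel-imaging fill stands in for the
vendor reconstructor, automated sub-pixel contouring stands in for the
human reader, and the repeatability statistics (ICC, CoV, Bland–Altman,
paired t) are computed exactly as in a scan–rescan study.

## Digital phantom

The phantom is a bifurcating vessel on a 3-D Cartesian grid: a parent
cylinder (common carotid analog, CCA) along the slice-encode axis that
splits at the bifurcation height into two straight daughter cylinders
(internal/external carotid analogs, ICA at 0.85 and ECA at 0.70 of the
parent lumen radius) offset symmetrically along the readout axis.  Only
slice-wise annular cross-sections matter downstream, so no attempt is made
to model a realistic flow divider.

Black-blood contrast is the intensity ordering *lumen < background <
wall*; per-contrast triples default to (0.05, 1.00, 0.30) for the
T1w-analog, (0.08, 0.90, 0.35) for the PDw-analog and (0.05, 0.80, 0.28)
for the T2w-analog.  The absolute levels are free parameters — tissue
signal values are protocol- and hardware-specific — and only the ordering
is enforced.

Rasterisation uses **exact analytic disk coverage per voxel**: the area of
each pixel covered by the lumen and outer disks is computed in closed form
(corner integrals of the circle), so partial-volume values are exact and
sub-voxel translations and half-max contouring behave continuously.  When
the wall thickness varies along the vessel (focal plaque bump), coverage
is additionally averaged through the slice thickness with 3-point
Gauss–Legendre quadrature.

Defaults represent a volunteer-analog: lumen radius 3 mm, wall thickness
1 mm, bifurcation at z = 7 mm, branch separation 9 mm, acquired voxel
0.625 × 0.625 × 1.4 mm on a 48 × 96 × 40 (readout × phase × slice) grid —
a deliberately scaled-down acquisition matrix (the in-plane FOV shrinks
with it) chosen so that a full five-replicate, twelve-subject scan–rescan
study reconstructs in minutes on one CPU; the phase-encode plane is kept
large enough that the fully sampled 32 × 32 calibration centre remains a
minority of the sampling budget at R = 2.  Patient-analogs draw a 2.2 ±
0.3 mm wall with a focal Gaussian plaque bump (amplitude 0.6 ± 0.3 mm,
clipped to [0, 1]) centred on the CCA measurement window, and a wider
branch separation (12 mm) so the thicker branches stay separated.

Coil sensitivities are four complex Gaussian lobes placed on the FOV rim
(a neck-array analog) with mild per-coil linear phase ramps.  The maps are
normalised so their sum-of-squares is exactly 1 at every voxel: the
combined image then carries no coil shading (as after bias-field
correction) while the coil-to-coil structure that autocalibrated parallel
imaging exploits is preserved.  Without this normalisation the local
half-max contour levels are corrupted for off-centre vessels.

The vessel axis lies along the slice-encode axis, so cross-sections live
in the isotropic 0.625 mm (readout × phase) plane.  This keeps the
measurement-plane resolution at the acquired in-plane value; with the
1.4 mm voxel across the 1 mm wall, wall-peak suppression would bias
half-max contours by roughly 0.2 mm and make the 0.1 mm thickness
round-trip unattainable.

## Acquisition model

The forward model is a centred orthonormal 3-D DFT per coil (Parseval
holds exactly) of sensitivity × image, plus i.i.d. complex Gaussian noise
of standard deviation `noise_sd` per real/imaginary component of every
k-space sample.  The default `noise_sd = 0.05` corresponds to SNR ≈ 20 on
the wall signal — a typical vessel-wall imaging regime.  Undersampling
lives only in the two phase-encode dimensions; the readout is always fully
sampled.

The CS pattern draws **exactly** `round(N/R)` samples: the fully sampled
32 × 32 centre block plus points drawn without replacement with
probability proportional to a centred 2-D Gaussian (sd 0.25 of the grid
extent per dimension, a free parameter).  Exact-budget sampling, rather
than Bernoulli thinning, makes the acceleration factor deterministic and
testable.  The parallel-imaging comb keeps every second phase line
(2 × 1) plus the same calibration block; combined acquisitions are the
elementwise AND.  The sampling mask is drawn once per (subject, contrast,
acceleration) and shared by both scan sessions ("fixed per protocol"):
with per-scan masks, two noiseless identical sessions would still differ
at R > 1, contradicting the identity limit the scan–rescan design should
satisfy.

## Reconstruction

The reconstruction minimises the L1 norm of the nearest-neighbour
finite differences of the complex image subject to data consistency.  It
is realised as a proximal-gradient/POCS hybrid, 15 iterations per coil:

1. gradient step on ½‖F_u m − y‖² (step 1 for the unitary masked DFT);
2. isotropic soft-thresholding of the 3-axis complex finite-difference
   vector with weight λ·step, reassembled through the divergence adjoint
   with contraction factor 1/12 (‖DᵀD‖ ≤ 12 in 3-D), applied `n_inner`
   times — the repeat tightens the approximation to the proximal operator
   of the non-orthonormal transform;
3. hard data consistency: acquired values are substituted back into the
   estimated k-space at every sampled location.

λ = 0.05 and `n_inner = 4` come from a coarse grid search on a single
held-out phantom at R ∈ {1.5, 2} with and without noise; step = 1.  The
data-consistency tolerance ε is exposed (ε > 0 projects onto the residual
ε-ball instead of substituting) but defaults to hard substitution, which
makes the final sampled-point residual exactly zero by construction.  A
divergence guard aborts if the L1 trace grows beyond 10× its initial
value.  The solver runs per coil; a GRAPPA-style kernel (4 taps along the
undersampled phase axis × 5 along slice, least-squares-calibrated on the
32 × 32 centre with a truncated pseudo-inverse) then replaces the values
at points skipped by the uniform comb; the coils are combined by
sum-of-squares.  Full sampling short-circuits to inverse DFT + SoS,
reproducing the phantom to ≤ 1e−10 NRMSE.

Study reconstructions run in complex64 (the acceptance identity test runs
the default complex128 path); each 48 × 96 × 40 four-coil CS
reconstruction takes ≈ 1.5 s on one CPU.

## Morphometry

Reconstructed magnitude volumes are reformatted to an axial stack
(permutation so the vessel axis becomes the stack axis) and resampled
trilinearly to 0.2 × 0.2 × 0.3 mm, optionally cropped to the vessel
neighbourhood.  Per measured cross-section the chain is:

* **Levels**: pooled over all measured window slices — lumen floor =
  median of the lumen-disk pixels, wall peak = 99th percentile of the
  wall-band pixels, background = median of the crop corners.  The lumen
  boundary is the marching-squares iso-contour at (floor + peak)/2, the
  outer boundary at (bg + peak)/2 — both scale-invariant under intensity
  rescaling.  Pooling matters: per-crop extrema are biased by several
  noise standard deviations of whichever image is being measured, which
  both breaks outer iso-contours of the small branches and makes the
  measured morphometry depend on each arm's effective SNR; pooled
  quantiles over tens of thousands of pixels are essentially
  noise-independent.  (A per-crop min/max fallback remains for ad-hoc
  single-slice use.)
* **Contour selection**: among closed iso-contours containing the seed
  centre, the smallest (lumen) or largest (outer) by area; if the
  half-way iso-line is broken by noise dips in the wall ridge, the level
  steps down (0.5 → 0.45 → 0.4 of the local range) before the slice is
  flagged and skipped.
* **Regularisation**: each polygon's radius-vs-angle profile is truncated
  to 8 Fourier harmonics and resampled to 64 vertices.  This emulates a
  reader's smooth stroke and removes high-frequency noise wiggle, whose
  rectified variance would otherwise inflate enclosed areas in proportion
  to the image noise level — a bias that differs between arms of
  different effective SNR (denoised CS vs plain zero-fill) and would
  masquerade as a CS-induced thickness shift.
* **Metrics**: shoelace areas; equivalent-circle radii √(area/π); wall
  thickness = outer − lumen radius; wall area = outer − lumen area
  (additive by construction).  Plaque is flagged at focal thickness
  ≥ 1.5 mm, inclusive.

Slice selection follows the standard windows: five contiguous 0.3 mm
slices centred 5 mm below the bifurcation (CCA) and 5 mm above it (each
branch).  Slices where no closed iso-contour exists are logged and
skipped, never fabricated.

Wall–lumen sharpness samples a radial profile (default ± 3 mm at 0.05 mm
steps, 8 averaged angles) through the lumen–wall edge, normalises min → 0
and max → 1 within the profile (the wording "lowest pixel in the blood …
highest in the wall" read as per-profile min/max), finds the 0.2 and 0.8
crossings by linear interpolation on the rising edge nearest the
boundary, and reports 1/d₂₀₋₈₀.  On an erf edge of width σ the measured
distance is 1.6832 σ to within sampling error.  The profile length, step
and angle count are free parameters with logged defaults.

## Statistics

CoV = 100 × sd(x₁ᵢ − x₂ᵢ) / (Σ(x₁ᵢ+x₂ᵢ)/2 / n), with the sample (n−1)
standard deviation — the dispersion convention is not universal, so it is
fixed and documented here.  The default ICC form is ICC(2,1) (two-way
random effects, absolute agreement, single measures), the standard choice
for scan–rescan agreement because a systematic session shift should count
against agreement; ICC(3,1) is switchable and every report labels the
form used.  Confidence intervals follow the Shrout–Fleiss / McGraw–Wong
F-distribution formulas (verified against pingouin).  Agreement above
0.75 is excellent, 0.40–0.75 inclusive good, below 0.40 poor — the 0.75
boundary itself falls in "good" since only values *above* 0.75 are
excellent.  Bland–Altman limits are mean ± 1.96 sd of the paired
differences; the paired t-test is scipy's two-tailed `ttest_rel`.
Pooling of paired measurements defaults to per-slice (each (subject,
segment, slice) a unit), switchable to per-artery means.

## Study designs

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning: one branch per subject, then
per-stage branches (geometry, masks, sessions, acquisitions, readings),
so every table regenerates bit-identically and no stage shares a stream.

* **Scan–rescan**: subject geometry is drawn from population ranges
  (lumen 3.0 ± 0.3 mm, wall 1.0 ± 0.12 mm, clipped) — without
  between-subject variance the ICC would be undefined.  Each session
  applies rigid in-plane repositioning (sd 0.5 mm) and a very small true
  geometry change (sd 0.02 mm; arterial walls are stable over a
  two-week scan–rescan interval, so session variance is dominated by
  acquisition, not biology).  Within a session every (contrast,
  acceleration) cell is its own acquisition: fresh noise and an
  additional translation-only repositioning (sd 0.3 mm), as when each
  sequence is run separately within one visit.
* **Sharpness sweep**: one session per subject, all accelerations of the
  same acquisition (paired comparison), mean sharpness over 8 radial
  profiles on the central CCA slice; medians with bootstrap IQR.
* **Observer study**: contours are drawn directly on the true geometry by
  the observer model — circular polygons at the true radii plus a
  per-reader constant radial bias (common to lumen and outer wall, so it
  cancels in thickness to first order) plus i.i.d. radial vertex noise
  (default 0.1 mm, 64 vertices).  Intra-observer pairs share the bias and
  differ in noise; the inter-observer pair adds a 0.1 mm bias.  This is
  the simplest model producing non-zero intra- and inter-observer
  variability; because the i.i.d. vertex noise averages out over the 64
  vertices of an area measurement, its CoVs land an order of magnitude
  below typical human-reader values — the model demonstrates the
  statistical machinery (including the common-mode cancellation of
  reader bias in wall thickness), not reader realism.
* **Thickness comparison**: per-subject mean wall thickness of each
  accelerated arm against the non-accelerated arm of the same session,
  two-tailed paired t.

## What the phantom does and does not show

Passing tests demonstrate the pipeline's internal consistency — exact
recovery in the fully sampled limit, exact data consistency and sampling
budgets, contour accuracy to a fraction of an interpolated voxel, and the
qualitative acceleration trends (repeatability degrades and edges blur
with increasing CS factor; no detectable systematic thickness shift at
CS 1.5 under the default conditions).  They do not certify performance on
real data: the phantom has piecewise-constant tissue (ideal for a
total-variation-style sparsifier), circular cross-sections, no plaque
component heterogeneity, no flow or motion artefacts, no B0/B1
inhomogeneity, and an observer model far simpler than a human reader.
Quantities that depend on these idealisations (absolute CoV levels,
absolute sharpness) should be read as internally consistent analogs, not
predictions of in-vivo values.

Two consequences of the idealisation deserve emphasis, because they run
against intuitions formed on human studies.  First, the automated
contouring is far more precise than a human reader (whose intra-observer
CoV on such measurements is typically 10-25%), so the paired
thickness comparison between accelerated and non-accelerated arms has
enough statistical power to resolve the small but real edge-widening
that acceleration causes — the same degradation the sharpness sweep
shows — whereas a manual-measurement study of a handful of subjects
cannot.  The package reports the comparison honestly rather than
injecting reader-scale noise to mask it.  Second, with a deterministic
per-protocol sampling pattern the undersampling artifact is nearly
common to both scan sessions and largely cancels in the session
difference; the scan-rescan CoV therefore grows only weakly with the
acceleration factor under these conditions.  Strong CoV growth in real
studies plausibly rides on mechanisms outside this phantom's scope:
tissue texture that the total-variation prior does not favour,
intra-scan motion, and reader variability that increases with image
blur.

## Numerical choices and degenerate inputs

Finite differences use periodic boundaries (the background is constant at
the FOV edge, so wrap-around interaction is negligible) with the exact
adjoint.  GRAPPA calibration solves least squares with rcond = 1e−8 and
raises only when the numerical rank drops below the coil count — smooth
noiseless phantoms legitimately produce ill-conditioned calibration
matrices, and strict rank erroring would reject valid inputs.  Boundary
gaps whose kernel support leaves the grid keep their CS-filled values.
Identical scan sessions (zero noise and jitter) yield zero-variance
differences; these are reported through the perfect-agreement sentinel
(ICC 1, CoV 0) rather than as errors.  Degenerate flat image crops are
flagged and skipped.  Observer noise large enough to cross the lumen and
outer contours triggers a bounded resampling retry, then an error.

## Problem sizes

Defaults used by the analysis scripts and the acceptance script: grid
48 × 96 × 40, 4 coils, 15 CS iterations; scan–rescan studies use 12
subjects × 2 sessions × R ∈ {1, 1.5, 2} on the T1w-analog, replicated
over 5 master seeds; the sharpness sweep uses 6–8 subjects; the observer
study 7 patient-analogs.  These sizes were chosen as the smallest at
which the between/within variance structure of a scan–rescan study is
well resolved.
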