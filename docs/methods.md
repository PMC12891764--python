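# Methods

This note documents the models, parameter choices, and numerical decisions
behind `csfquant`, and what the phantom-based validation does and does not
demonstrate.

## Aqueductal resistance

### Model

The cerebral aqueduct is treated as a sequence of short cylindrical ducts
in steady laminar (Hagen–Poiseuille) flow.  The centerline between the
user-defined start point (distal third ventricle) and end point (anterior
fourth ventricle) is divided into `n_segments` = 100 microchannels of
equal arc length; each contributes

    R_i = 128 * mu * L_i / (pi * D_i^4)    [mPa s / mm^3]

with L_i, D_i in mm and mu in mPa s.  Total resistance is the sum.
Because R_i scales with D^-4, the narrowest portion dominates, and the
wide distal outlet contributes almost nothing: the reported *effective*
resistance and length stop at the first microchannel where cumulative
resistance reaches `endpoint_fraction` (default 0.95) of the total.  Ties
are resolved by the first index attaining the bound (>=).

Assumptions: steady, fully developed, incompressible laminar flow in a
locally circular duct.  No pulsatile (Womersley) correction, no
Navier–Stokes solution, no 3D tubular segmentation — diameters are
in-plane chords of the 2D maximum-intensity projection, which matches the
projection-based measurement workflow this package implements.

### Parameters

| parameter            | default | unit | rationale                                   |
|----------------------|---------|------|---------------------------------------------|
| `mu_mPa_s`           | 0.71    | mPa s| viscosity of water at ~36 °C                |
| `n_segments`         | 100     | —    | resolves mm-scale diameter variation        |
| `endpoint_fraction`  | 0.95    | —    | suppresses operator-dependent distal endpoint |
| `target_spacing_mm`  | 0.03    | mm   | interpolation grid; sub-voxel boundary localization |
| `smooth_window`/`smooth_passes` | 5 / 8 | samples | see "Centerline" below        |

### Imaging steps

1. **MIP** across the slab of slices containing the aqueduct.
2. **Interpolation** of the projection to `target_spacing_mm` (bilinear,
   cell-centered, physical extent preserved).
3. **Thresholding** at the maximum intensity gradient along a line drawn
   across the narrowest point.  On images upsampled from coarse voxels the
   raw first difference peaks at an arbitrary position inside the
   one-source-voxel-wide edge ramp; the gradient is therefore smoothed
   with a Gaussian of half the upsampling factor so its maximum sits at
   the ramp center, i.e. the half-level intensity.  The largest connected
   bright component under the line is kept.
4. **Centerline**: morphological skeleton, shortest path on the
   8-connected skeleton graph between the projections of the start/end
   points, resampling to `n_segments + 1` uniform points, then an
   *iterated* (8x) 5-sample moving average with pinned endpoints.  A
   single smoothing pass at skeleton-pixel spacing leaves the tangent
   direction wobbling by ~10 degrees at the source-voxel scale, which
   tilts the diameter chords obliquely and biases every D_i (and hence R
   by >10%); iterating the window approximates a Gaussian of ~0.5 mm
   width, below the curvature scale of any real aqueduct.  Tangents are
   taken by central differences over +-0.75 mm for the same reason.
5. **Diameters**: full chord of the mask along the local normal at each
   segment midpoint, marching at the fine-grid spacing with linear
   sub-step refinement of the 0.5-level crossing.  Chords (rather than 2x
   distance transform) remain correct under bends, where the inscribed
   circle can touch the inner wall twice.

### Phantom fidelity and what validation shows

Tube phantoms voxelize the lumen by a **voxel-center test** (a voxel is
lumen iff its center lies inside the swept circle) with no partial-volume
averaging — deterministic and oracle-friendly, but it discards the
sub-voxel boundary information a real acquisition encodes in edge-voxel
intensities.  At the scanner's 0.35 mm reconstructed spacing this
quantization alone biases recovered resistance of a 1 mm channel by ~10%;
resistance-validation phantoms are therefore generated at 0.15 mm native
spacing, roughly the boundary-localization scale of a partial-volume
acquisition reconstructed at 0.35 mm.  With that choice the full pipeline
recovers closed-form cylinder resistance to <1% and a 1 -> 1.5 mm taper to
~2% of a 1e5-point quadrature oracle; the refinement-ladder property
(error decreasing over target spacings 0.12 -> 0.06 -> 0.03 mm) is
demonstrated at 0.12 mm native spacing, where the interpolation grid is
the binding resolution.  Validation tubes are tilted ~7 degrees against
the grid: a perfectly axis-aligned tube is a degenerate geometry whose
voxelization errors are perfectly correlated along the length instead of
averaging out, which no real acquisition exhibits.

Passing these tests shows the geometry -> resistance chain is unbiased at
realistic boundary information content; it does not validate against MR
artifacts (intensity inhomogeneity, flow voids, motion), which the
phantoms do not model.

## Ratio-Area morphometry

Per-slice protocol: bilinear interpolation to 0.1 x 0.1 mm^2; threshold
from the max-gradient line rule (or Otsu between-class variance inside the
brain ROI as the automatic fallback); within the ventricular ROI, dark
(label-0) pixels are ventricle and bright components *fully enclosed* by
the ROI are choroid plexus — bright components touching the ROI boundary
are surrounding tissue, not plexus.  Plexus pixels are excluded from both
Area-vent and Area-brain.  Area-brain counts bright pixels inside the
whole-brain ROI.  The analysis slice is chosen by exhaustively scanning
all candidate slices for the maximal ratio (ties -> lowest index),
replacing the only subjective step of the manual protocol with a superset
of it.  ROI polygons use 0-based pixel coordinates, even-odd inclusion of
pixel centers.

On brain phantoms with 0.5 mm native pixels the measured ratio is within
~1.5% (relative) of the analytic ellipse value.  The ground-truth ratio
uses the label-consistent denominator (brain tissue = ellipse minus
ventricles), matching what the measurement defines.

## Flow quantification

* **ROI segmentation** (the stand-in for velocity-spectrum methods whose
  exact operators are unpublished): hysteresis region growing from a seed
  pixel.  The seed must have peak-to-peak velocity amplitude >= `k_amp`
  (3) x the background amplitude (image-wide median, i.e. the noise
  floor); the ROI grows over connected pixels with amplitude >= `k_grow`
  (1) x background and waveform correlation >= `c_min` (0.5) with the
  seed.  A single high amplitude cut would truncate the slow near-wall
  rim of the parabolic profile and bias stroke volume low by up to ~30%
  at low amplitudes; the correlation gate is what rejects noise instead.
* **De-aliasing** precedes segmentation (wrapped waveforms decorrelate
  from their neighbours): temporal unwrapping with period 2*VENC, then
  re-centering each waveform by the multiple of 2*VENC nearest its mean,
  which anchors oscillatory CSF flow around zero even when frame 0 is
  aliased.  Single-wrap only; residual super-VENC jumps are QC-flagged.
* **Background correction**: static tissue = pixels in a 6-pixel annulus
  around the ROI with mean magnitude above half the in-ROI mean and
  temporal velocity SD <= 1 cm/s; their time-mean velocity becomes the
  zero reference.
* **Flow and stroke volume**: Q(t) = ROI area x mean in-ROI velocity
  (cm/s -> mm/s at this boundary); SV+ and SV- by trapezoid integration
  over the *closed* cycle (the last -> first segment included); SV is
  their mean.  At 32 samples the sinusoid worked example integrates to
  1 mm^3 within 0.4%.
* **Ratio-SV QC**: signed cycle mismatch = difference of the two series'
  cycles over their mean, x100; |mismatch| > 10% flags the subject for
  exclusion.

Phantom recovery: over amplitudes 1–5 cm/s, cycles 700–1000 ms, radii 1–3
mm, and velocity noise up to 0.3 cm/s, recovered SV stays within ~2% of
ground truth, and Ratio-SV varies by <0.2% when both sites' SVs are held
fixed while the cycle is varied +-20% — the designed null effect of heart
rate on the ratio.

## Cohort statistics

* Summaries: mean, sample SD (n-1), linear-interpolation quantiles
  (`numpy.quantile` default), CV% = SD/mean x 100 (missing when the mean
  is zero).  Rounding (integer CV%, 2-dp effect sizes) happens only at
  report time.
* Outliers: one screening pass; a subject is excluded when any core
  parameter (Ratio-Area, Ratio-SV, resistance) falls outside
  [Q1 - 3 IQR, Q3 + 3 IQR], with quartiles from the pre-exclusion table.
  When IQR = 0, any deviation is excluded.
* Wilcoxon rank-sum: midranks, tie-corrected variance, continuity
  correction, two-tailed normal p; effect size r = Z / sqrt(n), with n the
  number of *analyzed* subjects — the published effect sizes are
  reproduced by the analyzed count (34), not by the enrolled-after-QC
  count its footnote cites (36), a discrepancy the implementation
  resolves in favor of the numbers.  For group sizes <= 6 the
  approximation tracks an exact-enumeration oracle with mean |deviation|
  < 0.017 over all outcomes; single outcomes can deviate up to ~0.04 at
  the smallest sizes (3 vs 3), an intrinsic property of the
  approximation.  `wilcoxon_exact_p` provides the exact alternative.
* Spearman: Pearson correlation of midranks with the two-tailed
  t-approximation p (scipy); matrices are pairwise-complete with
  significance stars at 0.05/0.01/0.001 and entries with <4 complete
  pairs left missing.

## Cohort phantom

The cohort generator draws per-sex parameters through a Gaussian copula.
Strictly positive, high-CV parameters (resistance, both stroke volumes,
ventricular area) use moment-matched lognormal marginals: a normal with
the published SD cannot reproduce the published tight interquartile
ranges (resistance 72 +- 42 but Q1–Q3 only 43–77), and the right-skewed
lognormal restores both, which also makes the 3xIQR screening behavior
stable across seeds.  Ratio columns are derived from their
numerator/denominator draws so tables are internally consistent; default
correlation target: resistance vs aqueductal SV, rho = -0.6.  Injected
outlier rows (e.g. resistance 301 mPa s/mm^3) are appended at population
means except for the planted value.

## Exclusion cascade and determinism

Cohort runs exclude in a fixed order: stage failure -> cardiac-cycle
mismatch QC (>10%) -> 3xIQR screening; every exclusion is logged with its
reason, and quartiles are computed after QC exclusions, so the order is
observable.  All generators and pipelines are deterministic given spec +
seed; identical manifest/config/seed reproduce byte-identical reports.

## Problem sizes used in validation

Phantom tubes: 19 mm lumen, 15 mm measured section, 0.15 mm native / 0.03
mm interpolated grids.  Brain phantoms: 0.5 mm pixels, 5–9 slices.  Cine
phantoms: 32 frames, 48x48 to 96x96 pixels.  End-to-end cohorts in tests
and the acceptance script use 4–6 subjects; statistical properties
(power monotonicity, type-I rate) use a few hundred Monte-Carlo
replicates.  These sizes make the full suite run in a couple of minutes
while keeping every numerical claim at its stated tolerance.

## Known limitations

* No MR physics: no partial volume, bias fields, flow-related signal
  loss, or k-space effects; noise is additive Gaussian.
* Resistance is a steady-flow Poiseuille approximation on a 2D
  projection; oscillatory (Womersley) effects and out-of-plane curvature
  are ignored.
* The ROI/background-correction operators are explicit stand-ins for
  cited-but-unpublished semi-automatic methods; thresholds are surfaced
  in `FlowConfig`.
* Single-wrap de-aliasing only; double-wrapped acquisitions are rejected
  at generation and flagged at analysis.
* The brain-ROI convention (whether sulcal CSF is excluded from
  Area-brain) is a real-data question the phantoms sidestep; real-data
  use must document the ROI convention.
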