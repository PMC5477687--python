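# Methods

## The measurement model

Skin above an active brown-adipose-tissue (BAT) depot is warmer than
neighbouring skin, with a relatively sharp temperature-gradient boundary.
The package models one data point as a short thermal video sequence — a stack
of per-pixel temperature frames in °C at a fixed frame rate (default 30 Hz,
5 s, 150 frames) — and estimates the radiated power of the "hot" region of
interest (ROI) above each cervical–supraclavicular (C-SCV) depot.

Per frame, the ROI is detected by modified seeded region growing (SRG);
per sequence, the per-frame ROI pixel counts and mean ROI temperatures are
averaged arithmetically over frames (frame averaging suppresses both camera
noise and the ±1 % jitter that subpixel pose shifts induce in the discrete
ROI boundary). The averaged area `A` (m², via the fiducial calibration) and
temperature `T` (K) give the radiated power

    W = ε σ A T⁴

with skin emissivity ε = 0.98 and σ = 5.676 × 10⁻⁸ W m⁻² K⁻⁴ (the constant
as printed in the protocol this implements; CODATA's value differs in the
fourth digit and can be passed via `PhysConstants`). Left and right outputs
are summed; stimulation responses are reported as Δ and percent change
against baseline. Because T⁴ is nonlinear, applying the law to the
sequence-averaged (A, T) — the protocol's order and the default — differs
slightly from averaging per-frame powers; `measure_sequence` reports both
(`watts`, `watts_per_frame_mean`).

Radiated power is an underestimate of total BAT heat output: conduction,
convection, and the insulating subcutaneous layer are not modelled.

## Seeded region growing

The seed is the hottest valid pixel in a rectangular search window over the
left or right C-SCV area. The region `A_i` starts as the valid pixels within
Chebyshev radius `seed_region_radius` (default 1, a 3×3 block) of the seed,
so the starting mean is stable. Growth repeatedly admits the frontier pixel
(8-adjacent to the region) whose temperature deviates least from the current
region mean, while that deviation stays within the tolerance `T_t`
(non-strict), recomputing the mean after every admission. Termination:
smallest frontier deviation exceeds `T_t`, frontier exhausted, or the region
reaches `max_region_fraction` of the window (default 0.5 — a guard against
runaway growth on low-contrast frames).

Numerical and tie-break choices:

- **Tie-breaks.** Among equal-deviation frontier pixels, and among
  equal-temperature seed candidates, the smallest (row, col) in row-major
  order wins. This makes results bit-reproducible.
- **Exactly-rounded means.** The running mean is computed with `math.fsum`,
  whose result does not depend on summation order; equal-deviation ties are
  therefore resolved purely by the coordinate rule, and the grower agrees
  bit-for-bit with a from-scratch reference implementation.
- **Homogeneous seed block (optional).** `seed_tolerance` restricts the
  initial block to pixels within that many °C of the seed. When the hottest
  pixel happens to sit on the ROI edge, an unconditioned block mixes in
  cooler across-the-boundary pixels, biasing the starting mean; growth can
  then leak down the boundary gradient or stall. The condition is a separate
  parameter rather than `T_t` itself so that growth remains monotone in
  `T_t` (`T_t` only decides where the — otherwise fixed — admission sequence
  stops). The pipeline examples set `seed_tolerance = T_t`.
- **Invalid pixels.** Non-finite pixels (dead detector elements) are excluded
  from seeding, the seed block (which shrinks rather than aborts), growth,
  and all means.
- **Tolerance selection.** `T_t` is a per-subject tuning parameter in the
  original protocol. `select_tolerance` offers a reproducible surrogate: scan
  a tolerance grid and return the midpoint of the longest run of constant
  region size — the flattest segment of the size-vs-tolerance curve. This is
  an extension, not part of the protocol.
- **Baseline.** `threshold_segment` implements the top-quartile baseline
  (threshold = median of the hottest ⌈0.25 n⌉ window pixels, selection ≥
  threshold, connectivity deliberately not enforced) to demonstrate the
  scattered-cluster failure mode SRG avoids.
- Frames are segmented independently (no temporal smoothing); unsegmentable
  frames are excluded from sequence averages with a warning.
- Fiducial-band pixels are masked out of search windows before segmentation;
  their 28–31 °C values would otherwise distort the region mean.

## Calibration

Four foil disks (5 mm, rendered ~29.5 °C) mark the corners of an 18 cm × 8 cm
rectangle on the chest. Detection: threshold the frame to the fiducial band
(default 28–31 °C), label 8-connected blobs, drop blobs under `min_blob_px`
(default 4), require exactly four, take sub-pixel centroids, and order them
geometrically (upper-left, upper-right, lower-left, lower-right). The exact
four-point homography (8 degrees of freedom) mapping pixel (x, y, 1) to cm is
then determined; its residual at the four points is zero up to round-off.

ROI area integrates the per-pixel Jacobian determinant of the homography
(`det(H)/w³` at each member pixel centre, cm² per px²), which reduces to
`count × scale²` for a frontal view but stays correct under perspective.
Calibration is estimated once per sequence from a designated frame (default
the first) and held fixed; `per_frame_calibration=True` re-estimates it every
frame, which makes metric areas invariant to rigid pose drift.

## Quantification safeguards

Temperatures are stored in °C everywhere and converted to kelvin (offset
exactly 273.15) only inside the radiometric step. `RoiMeasurement` validates
that the mean ROI temperature lies in a plausible physiological band
(300–315 K) unless overridden — this catches the classic °C-for-K slip, which
would otherwise change the result by orders of magnitude through T⁴.

## Synthetic scenes: what they emulate, and what they do not

`generate_sequence` renders, deterministically per seed: a warm background
(default 33 °C, optional linear gradient), one or two elliptical hot plateaus,
four fiducial disks, i.i.d. Gaussian pixel noise (default sd 0.05 °C, the
noise-equivalent-temperature class of research thermal cameras; the protocol
does not state the camera's noise floor), and rigid per-frame translation for
pose drift. Default geometry matches the acquisition setup: a 320 × 240-pixel
camera about 1 m from the chest (~10 px/cm on the body plane), 30 Hz, 150
frames.

The hotspot profile is a flat plateau with a clipped-sigmoid edge: elevation
exactly `delta_t_c` (default 2 °C) inside the ellipse, and the sigmoid tail
`delta_t_c / (1 + exp(e / w))` of the pixel distance `e` past the boundary
(edge width `w`, default 1 px). The first exterior pixel thus sits at most
half the elevation above background — a sharp dermal-gradient boundary, which
is the feature the SRG stopping rule keys on; a pure Gaussian bump has no
natural boundary and would make "the true ROI" ill-defined. Ground truth
returned per scene: per-frame plateau masks, per-frame fiducial centres, the
exact pixel→cm transform, and analytic plateau areas. Note the rendered
(discrete) plateau mask is the scene's exact ground truth; its area differs
from the analytic ellipse area by boundary discretization (±1–2 % at the
default sizes), which is also why per-frame areas jitter under subpixel
drift.

These scenes deliberately idealise real thermograms: no anatomical texture or
curvature, no physiologic temperature fluctuation, no spatially correlated
noise, translation-only pose changes, and independent scenes instead of the
protocol's three head poses. Passing tests therefore demonstrate algorithmic
correctness (segmentation, calibration, radiometry, bookkeeping), not
clinical performance on human data.

`generate_cohort` emulates the study design at the subject level: default 24
subjects, responder fraction 0.25 (the 6-of-24 split), baseline total output
3.0 ± 0.5 W, percent change drawn from N(15, 8²) for non-responders and
N(45, 10²) for responders (chosen as a realistic separation; the study
reports group contrasts, not these distributions). The responder count is the
rounded fraction of n, assigned at random, so the planted design matches the
study's fixed group sizes.

## Study statistics

The low/high-BAT split uses cutoff = mean + 1 SE of the percent changes,
with SE = sample SD (n−1 denominator) / √n and a strict `>` at the cutoff
(values at the cutoff are low-BAT). Paired t tests (df = n−1) and Pearson
correlations use the standard scipy routines behind guards that reject
zero-variance inputs, where the statistics are undefined. No multiple-testing
correction is applied (α = 5 %). The original study's longitudinal
generalized-SEM analysis is out of scope (an off-the-shelf package fit, not
part of the imaging method); per-timepoint baseline-adjusted paired contrasts
are the provided alternative.

## Interchange formats

Sequences: multi-page 16-bit TIFF of counts with a JSON sidecar (linear
`temperature = scale × count + offset`, frame rate, invalid-pixel sentinel
65535; default scale 0.01 °C/count gives ≤ 0.005 °C quantization error), or a
directory of lossless per-frame CSV matrices for debugging. The vendor's
proprietary radiometric video format is deliberately not decoded. ROI masks:
8-bit PNG. Transforms and results: JSON.

## Problem sizes in the checks

The automated checks run on compact scenes (140 × 200 px, plateaus of
~600 px, 2–12 frames; 150 frames only for the bookkeeping check), 1,000
random ≤ 7×7 frames for oracle equivalence, 50 noisy scenes for recovery, 100
random homographies, and 100–200 seeded cohorts — sizes chosen so the whole
suite re-runs in minutes on one CPU while every property is still exercised
at meaningful scale.
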