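# Methods

## Overview

`ramanmargin` implements, at desk scale, an image-guided Raman spectroscopic
probe-tracking system for tumor margin delineation. A handheld fiber-optic
Raman probe carrying two colored fiducial markers is tracked in surgical
video; each recorded spectrum is preprocessed and classified with a PLS-DA
model; positive (diseased) diagnoses are accumulated at the tracked tip
locations, connected into a lesion boundary, and expanded by a
clinician-chosen safety margin. A fluorescence-imaging route (PPIX-style
widefield thresholding) is provided for head-to-head comparison. All inputs
are synthetic with exact ground truth, so every accuracy number the package
reports is computed against a known answer.

## Probe tracking

Each frame is converted to HSV and each marker is segmented by a window on
hue (circular distance on the 360° ring, so red markers straddling 0°
behave), saturation, and value; the binary mask is cleaned with a 3×3
morphological open/close and the largest connected component's unweighted
centroid is the marker position. The HSV windows are calibrated from one
seed pixel per marker: circular-median hue with a ±20° tolerance, and the
5th-percentile saturation/value of the seed neighborhood minus 0.1 slack.

The pose is ratiometric. With proximal and distal marker centroids **p** and
**d**, known marker separation `s` (mm) and tip offset `o` (mm):

- scale: `mm_per_px = s / ‖d − p‖` (re-estimated every frame, so changes in
  working distance degrade accuracy gracefully rather than silently),
- tip: `tip = d + (d − p) · o / s`,
- orientation: `atan2(d − p)`.

Tracking is stateless: every frame is processed independently, and a frame
where either marker is missed is flagged invalid with no pose carried over.
That is what makes recovery after occlusion trivial — the diagnosis store,
not the tracker, holds the history.

Default geometry: marker separation 20 mm, tip offset 30 mm, tip diameter
2.1 mm, scale 0.5 mm/px, frames 640×480, 180-frame sequences. All geometry
is configuration, never hard-coded in the tracker.

## Spectral preprocessing

Fixed chain, in order: crop to 600–1800 cm⁻¹ (the biological fingerprint
region) → background subtraction → normalization → Savitzky-Golay filter.

Background subtraction uses a Whittaker smoother with asymmetric weights
(asymmetric penalized least squares): minimize
`Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)²` with `w = p` above the running baseline and
`1−p` below, iterated. λ = 100,000; the asymmetry `p = 0.01`, 10
iterations, and 2nd-order differences are package defaults chosen as the
common practice for fluorescence-background estimation — they are exposed in
`PreprocessConfig` and covered by tests rather than claimed to be anyone
else's settings. The solver is sparse banded, O(n) in spectrum length; the
test suite checks it against a dense normal-equation solve to 1e-6.

Normalization defaults to unit area under the curve (trapezoidal integral
over the wavenumber axis); max and vector modes are switches for
sensitivity analysis. Savitzky-Golay uses polynomial order 1 and frame
width 7 with mirror padding at the edges (preserves length, avoids edge
transients at the crop boundaries). The whole chain is invariant to positive
rescaling of the raw counts.

## PLS-DA diagnostics

Class labels are one-hot encoded and regressed on mean-centered (not
variance-scaled — the spectra are already normalized) intensities via PLS2;
the fit is delegated to scikit-learn's `PLSRegression` and checked in tests
against an independent eigen-decomposition oracle (successive dominant
eigenvectors of XᵀYYᵀX with deflation). Default 2 latent variables — the
pair conventionally plotted for class separation — overridable up to the
rank limit. Prediction is the argmax of the per-class responses; the binary
positive/negative display thresholds the designated positive class's
response at 0.5 by default, adjustable per model.

Validation uses Venetian-blinds cross-validation: fold `f` holds the
samples with dataset index ≡ f (mod n_splits), a pure function of index —
reproducible without seeds. Default 10 splits, reduced automatically to the
smallest class size. PCA (mean-centered) supports unsupervised phantom
discrimination: a 20-µM-analog class with its dominant fluorescence
background separates from 0/2/4-µM analogs on PC1.

## Margin delineation

The lesion boundary is the convex hull of the positive tip locations —
the simplest geometry consistent with "connect the positives into an
outline" (an alpha-shape/concave variant is an explicit non-goal, and
spatially disjoint positive clusters are merged into one hull; both are
documented limitations). The hull is buffered outward by
`margin_mm + tip_diameter_mm/2` (a 2.1-mm-wide tip senses a disk, not a
point; the tip term can be disabled for pure-geometry work), converted to
pixels with the median per-acquisition mm/px across the store for
robustness to single-frame scale noise. Degenerate cases: one positive → a
disk, two → a capsule. Masks are rasterized with pixel-center coverage and
clipped to the frame. Masks are nested in the margin, never shrink when a
positive is added, and depend on the set (not order) of positives.

Suggested measurement locations are placed on the boundary offset outward
by the requested spacing, at arc-length intervals of that spacing,
excluding candidates within one spacing of any existing measurement (with a
0.1% tolerance absorbing the polygonal buffer approximation).

Fluorescence delineation thresholds a single-channel image at a fixed
intensity, or at Otsu's threshold in auto mode (an error on a flat image).

## Evaluation

Delineation accuracy: TP/FN/FP pixel areas relative to the ground-truth
lesion area, so TP + FN = 100% exactly and FP is unbounded above (the
denominator choice that makes the reported triples consistent; it is
switchable in principle by dividing by the delineated area instead).
Tracking accuracy: per-frame Euclidean tip error × true scale, mean ± SD
over valid frames.

## Synthetic data

Spectra are sums of Gaussian peaks on a low-order polynomial baseline, plus
a broad fluorescence background (single Gaussian centered mid-axis, σ =
400 cm⁻¹) scaled by a PPIX-analog concentration in µM, plus white Gaussian
noise (default SD 0.05 against peak heights of 4–10). Class recipes use
disjoint, tissue-plausible band sets (muscle: 855/936/1003/1250/1450/1655
cm⁻¹; fat: lipid bands; phantom analog: a disjoint set), giving controlled
separability: the default classes are fully separable, and shrinking the
between-class distance to zero drives CV accuracy to chance — both are
tested. The generators emulate band positions and background behavior, not
instrument response, shot-noise scaling, cosmic rays, or specimen
heterogeneity — so perfect synthetic CV accuracy demonstrates the
machinery, not clinical performance.

Videos render the scene plus two anti-aliased saturated disks (green 120°,
blue 240°) placed by inverting the tip formula, so exact centroids
reproduce the ground-truth trajectory by construction; occluded frames
render no markers. Ground truth is exact rather than annotated. The default
trajectory is a smooth Lissajous path with slowly varying orientation that
keeps both markers in frame.

Fluorescence images follow
`I = gain · concentration · exp(−attenuation_per_mm · occlusion) + noise`.
The composite phantom pairs a 4-µM region with an adjacent 2-µM region
under a ~1 mm occluding layer; at the default gain 10, attenuation 3/mm and
threshold 8, the occluded region's signal (10·2·e⁻³ ≈ 1) falls below
threshold, so fluorescence imaging misses it while the Raman route does not
— the mechanism behind the package's Raman-vs-fluorescence comparison.

Every generator is a pure function of (spec, seed); per-class and per-frame
seeds are fanned out of one master seed via `SeedSequence`.

## Problem sizes and numerics

Standard runs use 180-frame 640×480 videos, 25 spectra per class on a
2 cm⁻¹ grid over 400–2000 cm⁻¹ (601 points after cropping), measurement
grids at 8–10 mm spacing, and margins from the sets {0, 1.5, 3} and
{0, 3.5, 7} mm; smaller 320×240 scenes and 12-frame clips are used where a
property does not need the full size. Buffers use 64 quadrant segments;
rasterization tolerance in tests accounts for the half-pixel boundary
band. Whittaker ties (y exactly on the baseline) weight as below-baseline;
fold reduction in CV and the hull for degenerate collinear point sets
follow shapely's conventions.

## Known limitations

Single-camera 2D pose only (no depth); one convex hull regardless of lesion
multiplicity; no spike removal or wavenumber calibration; no real-time
throughput claims; synthetic realism limited as described above. Reported
tissue-level accuracies from physical experiments are specimen-dependent
and are not reproduced here — the package reproduces the algorithms and
their behavior under controlled, separable conditions.
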