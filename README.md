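# ramanmargin

Image-guided Raman spectroscopic probe tracking and tumor margin
delineation, as a tested, simulation-backed Python package.

During tumor resection a surgeon needs to know, point by point, whether the
tissue under a handheld Raman probe is diseased — and then to see those
diagnoses assembled into a resection boundary on the surgical video. This
package implements that whole loop for desk-scale study: visual tracking of
the probe via two colored fiducial markers, real-time-style spectral
diagnosis, geometric margin delineation with adjustable safety margins, and
a fluorescence-imaging comparison arm — exercised entirely on synthetic
video and spectra with exact ground truth.

## What it computes

**Probe tracking.** Markers are segmented per frame in HSV space (hue
treated circularly); with proximal/distal centroids **p**, **d**, known
marker separation *s* and tip offset *o* (mm), the pose is ratiometric:

    mm_per_px = s / ‖d − p‖
    tip       = d + (d − p) · o / s

Frames are processed independently, so tracking recovers immediately after
occlusion.

**Diagnosis.** Each spectrum passes a fixed chain — crop to 600–1800 cm⁻¹,
asymmetric-Whittaker background subtraction (λ = 10⁵), area normalization,
Savitzky–Golay filtering (order 1, frame 7) — then a PLS-DA model (PLS2 on
one-hot labels, 2 latent variables by default) assigns a class; an
adjustable threshold on the positive-class response drives the binary
display. Validation is Venetian-blinds cross-validation (fold = index mod
n_splits).

**Delineation.** Positive diagnoses at the tracked tip locations are
connected into a convex-hull boundary, buffered outward by
`margin_mm + tip_diameter/2` at the store's median mm/px scale, and
rasterized; TP/FN/FP areas are scored against the ground-truth lesion as
percentages of its area (TP + FN = 100). A fluorescence image of the same
scene can be thresholded for comparison.

## Worked example

```sh
ramanmargin run --out demo_run --seed 2 --n-frames 20
```

simulates a 640×480 scene with an elliptical lesion, tracks the probe over
20 frames, trains and cross-validates a muscle-vs-phantom PLS-DA model,
walks a measurement grid diagnosing a spectrum at each point, and
delineates at margins 0 / 1.5 / 3 mm. `demo_run/summary.json` from that
exact command:

```json
{
  "seed": 2,
  "tracking": {"mean_mm": 0.1517, "sd_mm": 0.0843},
  "cv_accuracy_pct": 100.0,
  "margins": [
    {"margin_mm": 0.0, "tp_pct": 88.54, "fn_pct": 11.46, "fp_pct": 0.12},
    {"margin_mm": 1.5, "tp_pct": 94.28, "fn_pct": 5.72,  "fp_pct": 1.47},
    {"margin_mm": 3.0, "tp_pct": 97.23, "fn_pct": 2.77,  "fp_pct": 5.31}
  ]
}
```

Read: the tracker localized the probe tip to 0.15 ± 0.08 mm of the known
trajectory; the two synthetic spectral classes (disjoint Raman band sets)
were classified perfectly under cross-validation; and widening the safety
margin trades false-negative area (missed lesion, 11.5% → 2.8%) against
false-positive area (healthy tissue inside the boundary, 0.1% → 5.3%) —
the clinical tradeoff the safety margin exists to control. The run
directory also holds the pose table, the per-acquisition diagnosis log, the
margin-metrics CSV, and a rendered overlay (numbered green/red squares plus
the red boundary) as PNG.

Individual steps are available as subcommands (`simulate`, `calibrate`,
`track`, `train`, `cv`, `delineate`, `evaluate`) and as library functions
(`ramanmargin.tracking`, `.preprocess`, `.plsda`, `.delineate`,
`.evaluate`, `.synthetic`, `.workflow`).

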