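# carpo

Quantification of dynamic wrist movement from 2D+time grayscale image
sequences, as produced by real-time radial FLASH MRI of the moving
wrist (~168x168 px at 1.0 mm/px, ~10 frames/s).

Carpal instability — pathologic malalignment of the carpal bones after
intercarpal ligament injury — is often *dynamic*: the scapholunate (SL)
or lunotriquetral (LT) gap widens only during motion, so static imaging
misses it. `carpo` implements a complete analysis chain that turns a
real-time image series of a wrist performing radial-ulnar abduction
("waving") into per-frame diagnostic measures:

1. **Preprocessing** — per-image percentile clipping (P10/P99), Z-score
   normalization, biquadratic 2x upsampling (336x336 at 0.5 mm/px);
   training-time augmentation (noise, mirror, shift, rotate, zoom).
2. **Segmentation** — a symmetric U-Net (two 3x3 conv + BN + ReLU per
   level, 2x2 max-pool down, mirrored up, 1x1 head) labelling eight
   structures: distal radius, distal ulna, scaphoid, lunate, triquetrum,
   hamate, capitate, trapezium+trapezoid. Trained with Adam under a
   multi-step schedule on a sum loss of soft Dice error and a
   distance-transform Hausdorff surrogate. The network runs on a
   compact, fully-tested numpy engine — no GPU or deep-learning
   framework required.
3. **Post-processing** — mean-field CRF refinement with bilateral
   appearance kernels; Gaussian-weighted temporal voting over a 5-frame
   window (cumulative allocation 0..5, mean thresholded at 0.6);
   opening/closing with a 5-px cross and largest-component selection.
4. **Quantification** — the scaphoid-lunate-triquetrum masks are fused
   and a centerline is routed along the carpal arcs (medial axis ->
   longest path -> spline); the SL gap is the distance between the
   centerline's crossings of the ulnar scaphoid cortex and the radial
   lunate cortex, LT analogously. The wrist angle is measured between
   the long axis of the forearm bounding box and the vector to the
   distal-row bounding-box center (radial negative / ulnar positive).
5. **Evaluation** — per-class Dice tables, Bland-Altman agreement,
   subject-level train/test splits, equal-interval movement-cycle frame
   selection, and 5-deg angle-binned gap-width curves.

A first-class **synthetic phantom** (`carpo.phantom`) renders an
articulated eight-bone wrist with known, angle-dependent gap widths
(healthy and SL-injury modes), pixel-perfect truth masks, and truth
metric curves, so the whole chain is testable end-to-end without MRI
data.

## Worked example

Measure a healthy phantom's truth masks at the 0.5 mm/px measurement
grid and summarize the gap-width curves:

```python
import numpy as np
from carpo import PhantomSpec, generate_sequence
from carpo.metrics import quantify_sequence, bin_by_angle

spec = PhantomSpec(duration_s=6.0, frame_interval_ms=100.0,
                   noise_sigma=0.0, seed=11)
seq, truth = generate_sequence(spec, supersample=2)

met = quantify_sequence(truth.masks, truth.pixel_spacing_mm,
                        spec.frame_interval_ms)
err_sl = np.abs(met.sl_gap_mm - truth.sl_gap_mm).max()
err_ang = np.abs(met.wrist_angle_deg - truth.angle_deg).max()
print(f"frames: {len(met)}  max |SL error|: {err_sl:.3f} mm  "
      f"max |angle error|: {err_ang:.3f} deg")
print(bin_by_angle(met, 5.0)[["bin_center_deg", "sl_mean_mm",
                              "lt_mean_mm"]].round(3).to_string(index=False))
```

Output:

```
frames: 60  max |SL error|: 0.405 mm  max |angle error|: 0.168 deg
 bin_center_deg  sl_mean_mm  lt_mean_mm
        -17.501       2.075       1.025
        -12.500       1.833       1.367
         -7.500       1.762       1.012
         -2.500       1.833       1.167
          2.500       1.750       1.512
          7.500       1.762       1.525
         12.500       1.550       1.025
         17.500       1.825       1.037
         22.500       1.675       1.258
         27.500       1.712       1.387
         32.500       1.746       1.196
```

The 60 frames of the 6 s sweep recover the analytic truth — SL ~1.7 mm
and LT ~1.3 mm with a slight (-0.002 mm/deg) narrowing towards ulnar
abduction — with every gap within half an interpolated pixel (0.5 mm)
and every angle within 2 deg of its true value (the bin-level scatter of
~0.2 mm is the quantization noise of single-frame measurements on the
0.5 mm grid; the outermost bins hold single frames at the sweep
extremes). Running the same pipeline on an
SL-injury phantom (`PhantomSpec(injury_mode=True, ...)`) shows the
pathologic pattern: SL ~4 mm over the radial half of the range of
motion, collapsing towards ~1 mm in deep ulnar abduction.

The `carpo` command line exposes each stage (`simulate`, `preprocess`,
`train`, `segment`, `postprocess`, `quantify`, `bins`, `evaluate`,
`agree`, `run`, `demo-injury`); `carpo run --config cfg.yaml --out dir/`
executes the full pipeline and writes a reproducibility manifest.

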