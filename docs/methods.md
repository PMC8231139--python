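# Methods

`carpo` quantifies dynamic wrist movement from 2D+time grayscale image
sequences of the kind produced by real-time radial FLASH MRI (~168x168 px
at 1.0 mm/px, ~10 frames/s). Eight osseous structures are segmented per
frame — distal radius, distal ulna, scaphoid, lunate, triquetrum, hamate,
capitate, and trapezium+trapezoid (one class) — and three diagnostic
measures are derived per frame: the scapholunate (SL) gap width, the
lunotriquetral (LT) gap width, and the wrist (radioulnar deviation)
angle, with radial deviation negative and ulnar deviation positive.

This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Synthetic phantom

No public dynamic wrist dataset with dense per-frame bone labels exists,
so every stage is validated against a parametric articulated phantom that
provides pixel-perfect truth for masks, gaps, and angle.

**Geometry.** Bones are convex superellipses laid out at realistic wrist
proportions for a 168 mm field of view and scaled linearly with the
field. The radius and ulna are fixed, emulating forearm fixation by
tourniquets in a movement device; the six carpal bones rotate rigidly
about a pivot on the forearm axis. The three proximal-row bones sit on a
common row line with cortex-to-cortex separations set to the analytic
gap-truth functions at the current pose, so rasterized separations match
truth to within one pixel of the rendering grid. Trapezium+trapezoid and
hamate are mirror images about the forearm axis so that the distal-row
bounding box is centered on the axis in the neutral pose.

**Pivot choice.** The carpal rotation pivot is placed at the center of
the forearm group's minimum bounding box. With this choice the
bounding-box angle measurement (below) recovers the pose angle exactly:
the distal-row box center orbits the forearm box center, so the angle
between the box-center vector and the forearm axis equals the pose. A
pivot distal to the radius would be anatomically closer to the true
center of carpal rotation but turns the box-center angle into a biased,
geometry-dependent proxy; since the package's angle definition *is* the
box-center construction, the phantom is built so that definition is
exact.

**Motion.** A cosine-eased sweep `a(t) = a_min + (a_max - a_min)(1 -
cos(2 pi t/T))/2` takes the wrist from the radial extreme (-15 deg
default) to the ulnar extreme (+35 deg) and back over the acquisition
(default 30 s, 100 ms/frame, 300 frames — one full "waving" cycle in
~15 s, i.e. at most ~1 deg of pose change per frame). The cosine easing
is a modeling choice; real per-subject motion profiles vary.

**Gap truth.** Healthy wrists: SL = 1.7 mm and LT = 1.3 mm at neutral,
both with a -0.002 mm/deg linear trend (a slight narrowing in ulnar
abduction). SL-ligament injury: SL ~4 mm from the radial extreme to
+10 deg, then closing linearly to ~1 mm at +35 deg; LT ~0.7 mm on the
radial side rising to ~1.2 mm in deep ulnar abduction. Both functions
are injectable per `PhantomSpec`.

**Rendering.** Polygons are rasterized by the pixel-center rule;
intensities are two-level (bone 0.8 / background 0.2) blurred by a
0.7 px Gaussian point-spread surrogate, with additive Gaussian noise
(default sigma 0.05 on normalized intensities; masks are noise-free).
Rician noise, coil-sensitivity profiles, undersampling artifacts,
out-of-plane motion, and soft tissue are deliberately absent — passing
tests demonstrate algorithmic correctness under known geometry, not
robustness to real MRI physics. A gap narrower than one pixel of the
rendering grid raises a degenerate-geometry error; the injured-wrist LT
gap therefore requires the supersampled (0.5 mm/px) grid.

## Preprocessing

Per frame: intensities are clipped to the image's own 10th/99th
percentiles (linear-interpolation percentile convention), Z-scored to
zero mean and unit SD, and upsampled 2x by biquadratic interpolation
after a small Gaussian anti-aliasing pre-filter (sigma 0.5 px), doubling
168x168 at 1.0 mm/px to 336x336 at 0.5 mm/px. Clipping precedes
Z-scoring; both are per-image. Polygon annotations are scaled by the
same factor of two. Note that percentile clipping necessarily pins ~10%
/ ~1% of continuous-valued pixels to the lower/upper bound.

Training-time augmentation draws, per sample: Gaussian noise sigma in
[0, 0.2], mirroring along x, shifts along x up to +/-10% of the width,
in-plane rotation up to +/-15 deg, and zoom of +/-10%. Rotation and zoom
use nearest-neighbour resampling for image and mask alike (labels stay
crisp); noise touches the image only. Out-of-frame regions are filled
with the frame median (the background mode of a normalized image) and
label 0.

## Segmentation network

A classic symmetric U-Net: per level two 3x3 convolutions each followed
by batch normalization and ReLU; 2x2 stride-2 max-pooling down,
nearest-neighbour upsampling with skip concatenation up; a final 1x1
convolution maps the first-level features (64 at default width) to the
class channels. Default depth 4 with channel progression 64-128-256-512.
Eight foreground classes plus an explicit background channel under a
per-pixel softmax, so every pixel carries a label; the losses run over
foreground classes only.

The engine is a compact hand-written numpy implementation (`carpo.nn`):
channels-last activations, convolutions as nine shifted-slice matrix
products, manual backward passes, verified against scipy correlation and
numeric differentiation. It supports exactly the operations this
architecture needs.

**Loss.** Unweighted sum of two terms, each averaged over the foreground
classes present in the target:

* soft Dice error `1 - (2|P.T| + eps)/(|P| + |T| + eps)`, eps = 1e-6;
* a distance-transform Hausdorff surrogate: per pixel, the squared
  soft error weighted by `d_T^2 + d_P^2`, the squared unsigned distance
  transforms of the target region and of the hard prediction (the latter
  held constant in the gradient). Mistakes far from the true cortex
  dominate; a lone misplaced pixel at distance d contributes
  proportionally to d^2.

**Protocol.** Adam with initial learning rate 0.1 and weight decay 1e-8,
500 epochs, batch size 4, multi-step schedule dropping the rate by 10x at
epochs 10, 50, 100, 150, 250. These reference defaults are aggressive
for small-batch CPU runs, so a desk-scale recipe is provided and used
throughout the tests: depth 2, base 16 channels, learning rate 1e-2 with
one 10x drop at 75% of a 16-epoch run, trained on 64 frames of a 96 px
phantom. That run reaches a held-out mean foreground Dice similarity
coefficient (DSC) of ~0.98 raw and ~0.99 after post-processing in a few
minutes on one CPU. The problem sizes (96 px field, 64 training frames,
16 epochs) were chosen as the smallest configuration that exercises
every mechanism of the full-scale protocol while leaving the network at
a realistic operating point — converged but not saturated, so the
refinement stages still have residual boundary errors to correct, as
they do on real data.

## Post-processing

Applied at inference, in order:

1. **CRF.** Fully-connected conditional random field solved by
   mean-field iteration (5 iterations) with a convolutional
   approximation of the pairwise term: a Gaussian smoothness kernel and
   a bilateral appearance kernel implemented on a (y, x, intensity)
   grid, Potts compatibility. Kernel widths are held at fixed physical
   sizes — appearance 4 mm spatial / 0.5 Z-units intensity, smoothness
   1.5 mm — i.e. 8 px and 3 px on the 0.5 mm/px measurement grid
   (`CRFConfig.for_spacing` converts). All CRF parameters are
   conventions exposed in config.
2. **Temporal stabilization.** Per pixel and class, hard label
   allocations in a 5-frame window (two before, two after) are weighted
   by a Gaussian over temporal offset (sigma_t = 1 frame) normalized to
   sum to the window length, so the cumulative allocation ranges from 0
   (never assigned) to 5 (always assigned). The mean allocation is
   thresholded at 0.6: pixels at or above keep the class, below fall
   back to background. Classes are processed independently; if several
   pass, the highest mean wins. At sequence ends the window is truncated
   and renormalized. This voting presumes slight inter-frame motion
   (about a degree per frame, as in the emulated acquisition); on
   sequences with much faster pose changes it erodes moving boundaries,
   which is the expected behaviour of the construction, not a defect of
   the implementation.
3. **Morphology.** Per class, binary opening then closing with a 5-pixel
   cross (center + 4-neighbours), then retention of the largest
   4-connected component only. "Five connected pixels" is read as the
   cross-shaped element; any 5-px element would be a plausible
   alternative. Opening with a cross necessarily rounds off right-angle
   corners (the element cannot fit into them) — on pixelated convex
   bones this costs a few boundary pixels per frame, the price of the
   speck/hole robustness the stage buys.

## Measurement algorithms

**Proximal-row fusion.** Union of scaphoid, lunate, triquetrum masks,
morphologically closed with a disk whose radius grows from 5 px (at
0.5 mm/px: bridges gaps to ~5 mm) until the union is one 4-connected
region; failure raises a fusion error and the frame's gaps are flagged
invalid.

**Centerline.** The fused region is skeletonized; the skeleton's longest
geodesic path (double breadth-first search over the 8-connected pixel
graph) is taken, end-spurs are trimmed where the distance transform
falls below 70% of the path median (skeleton branches running into
corners hug the boundary), and a smoothing spline is fitted over an
arc-length parameterization. The curve is oriented radial-to-ulnar
(scaphoid end first) and extended tangentially at both ends so it fully
traverses the flanking bones.

**Gap widths.** Walking the centerline at 0.05 px steps, the SL gap is
the Euclidean distance between the point where the curve exits the
scaphoid and the point where it enters the lunate (ulnar scaphoid cortex
to radial lunate cortex); LT analogously for lunate to triquetrum.
Cortex crossings are located to sub-pixel precision as the midpoint of
the last-inside/first-outside sample pair. Straight-line distance is
used, not arc length — over a 1-4 mm gap the two differ negligibly.
Gaps are measured on the 0.5 mm/px grid, so the worst-case quantization
of the two crossing points stays within half an interpolated pixel.

**Wrist angle.** Minimum-area rotated rectangles (convex hull of the
pixel-corner cloud) are fitted to the forearm group (radius + ulna) and
the distal carpal row (hamate + capitate + trapezium/trapezoid). The
angle is measured between the forearm box's long axis, directed towards
the carpus, and the vector joining the two box centers. The sign is
resolved anatomically from the radius-to-ulna centroid direction —
deviation towards the ulnar side is positive — which makes the measure
invariant under whole-image mirroring (a left wrist is not a negated
right wrist) while a pure pose mirror negates it. The forearm long axis
was chosen as the reference (rather than the image vertical) because the
forearm is mechanically fixed in the emulated setup.

**Binning.** Gap-versus-angle curves are summarized in 5-deg half-open
angle bins aligned to multiples of the bin width; empty bins are
omitted.

## Evaluation machinery

Dice similarity `2|A.B|/(|A|+|B|)` per class; a class absent from both
masks scores 1 (perfect agreement on absence). Sequence tables report
per-frame-per-class DSC averaged over frames (not pooled pixels).
Bland-Altman agreement uses the standard limits mean +/- 1.96 sample SD.
Subject-level splits keep both wrists of a subject on one side; the
emulated cohort (28 subjects x 2 wrists x 15 frames, 21 training
subjects) yields 630/210 images. Movement-cycle subsampling selects 15
equal-interval frames, `round_half_up(k (L-1)/(n-1))`, strictly
increasing for any cycle length >= 15. The per-frame acquisition time of
the emulated sequence is 21 radial spokes x TR 4.5 ms, rounded half-up
to 95 ms; the phantom's default 100 ms interval reconciles that
temporal resolution with the 300-frames-in-30-s count.

## Numerical and degenerate-input choices

* Constant images: percentile clipping returns them unchanged; Z-scoring
  raises (zero SD) rather than dividing.
* A constant-intensity CRF guide degenerates the bilateral kernel to its
  spatial factor; the intensity-axis blur is capped at the bin count.
* Dice smoothing constant 1e-6; both-empty DSC defined as 1.
* Max-pool gradient ties are split evenly (the conserved subgradient).
* Temporal threshold comparisons use >= (a pixel exactly at 0.6 keeps
  its class).
* Component ties in largest-component selection break to the
  first-labeled (lowest) component id.
* Rounding of frame indices and acquisition times is half-up, not
  banker's.

## Known limitations

* The phantom's straight proximal-row line makes the fused-row
  centerline nearly straight; curved-arc behaviour is exercised
  separately on annulus-sector fixtures.
* Training at desk scale covers one phantom geometry; nothing here
  demonstrates segmentation of real MRI contrast, coil shading, or
  pathology.
* The temporal stage assumes the acquisition's slight inter-frame
  motion; it is not suitable for sequences sampled much more coarsely in
  time.
* The linear-mixed-model analysis of gap widths reported for the real
  cohort is out of scope; only descriptive and agreement statistics are
  implemented.
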