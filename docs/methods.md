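# Methods

This note records the model behind `gridtag`, the conventions the package
freezes, the numerical choices inside the detector, what the synthetic
scenes do and do not emulate, and the known limitations.

## Tag code model

A tag is a 5×5 binary matrix (1 = white, 0 = black) surrounded by a
1-module white ring and a 1-module black ring, 9×9 modules in all.  The
white ring's outer edge — a 7×7-module square, the "white quad" — is what
the detector finds and fits corners to.

The 25 bits split into a 15-bit identity and a 10-bit error check:

* **Identity.**  An integer 1..32767, written MSB-first as bits b₁…b₁₅ and
  placed column-major into the 5×3 left block of the matrix (b₁ top-left,
  b₁₅ bottom-right).
* **Parity check.**  Five parity bits (1 = odd number of ones) over fixed
  cell groups of the identity block — its three columns and its
  first-3-rows / last-2-rows groups — in the fixed order
  [column 2, column 1, rows 1–3, column 3, rows 4–5].  The 5-bit check
  **c** is extended to **c** ‖ reverse(**c**) and placed column-major into
  the 5×2 right block, so the second check column is the first mirrored
  vertically ("repeated and reversed").

The exact fill orders, parity groups and check-bit order are
*conventions*: nothing about the detection method depends on which is
chosen, but the sizes of the enumerated code sets do.  The conventions
above were calibrated by searching the convention space (fill orders,
group definitions, check placement and ordering — several thousand
variants) for the one reproducing the published set sizes, and are then
frozen project-wide (saved codebooks carry a `layout_version` marker).
The frozen layout reproduces **both** published anchors exactly — 7,515
usable codes at Hamming ≥ 3 and 110 at Hamming ≥ 7 — and is the only
searched variant that does so while keeping all parity groups geometric;
alternatives miss one or both counts (values roughly 3,800–7,700 for the
first, 106–115 for the second).

Because every identity bit occurs in exactly one column group and one
split group, and every 5-bit check bit appears twice in the 10-bit check,
any single module misread changes at least three bits of a valid word —
the check *detects* single errors and most short error bursts, and never
attempts correction.

### Usable code sets

Tags are photographed at unknown orientation, so:

1. **Orientation uniqueness.**  A code is usable only if its parity check
   passes in exactly one of its four 90° rotations (32,674 of the 32,767
   identities qualify).
2. **Rotational Hamming distance.**  Identities are scanned in ascending
   order; a candidate is kept iff the Hamming distance between its
   canonical 25-bit word and *all four rotations* of every previously kept
   code is ≥ *h*.  Greedy ascending order makes the result well defined
   and reproducible.

With *h* = 3 the scan keeps 7,515 codes; with *h* = 7 it keeps 110.

## Detector

Pipeline: grayscale (Rec.601) → binarise → 8-connected white components →
area gate → quadrilateral fit → perspective grid sampling → decode.

* **Binarisation.**  Global: pixel ≥ threshold (default 0.5).  Adaptive
  (Bradley-style): pixel > local mean × (1 − sensitivity), local mean over
  an odd window (default 15 px, sensitivity 0.1); robust to smooth
  illumination gradients that defeat any global cutoff.
* **Area gate.**  White components with `min_area` ≤ area ≤ `max_area`
  (defaults 100 px² and a quarter of the image) are candidates.
* **Quadrilateral fit.**  The component's convex hull is reduced to the
  maximum-area 4-vertex subset (any 4 hull vertices in order are convex;
  the area-maximising choice hugs the true corners even when
  anti-aliasing rounds them).  Douglas–Peucker simplification is applied
  first only when a hull has more than 60 vertices, to bound the search.
  A fit is accepted iff (a) the quad covers ≥ 90% of the hull area — this
  rejects disks and other rounded blobs whose best inscribed quad is far
  smaller than their hull, (b) the *hole-filled* component area is ≥ 0.8 of
  the quad area (the white component of a tag is a ring plus attached
  modules, so the raw pixel count would be meaningless), and (c) all
  interior angles are within 90° ± 30° (perspective tolerance).
* **Grid sampling.**  The white quad spans 7×7 modules; a projective
  transform maps the quad to that grid and the centres of the central 5×5
  cells are read.  By default each sample is the *single pixel* under the
  grid point (nearest-neighbour read) — this matches how the method is
  classically implemented and is what makes detection degrade under heavy
  pixel noise in the characteristic way; setting
  `sample_neighborhood=3` averages a 3×3 patch per point and makes
  decoding markedly more noise-robust if that trade-off is preferred.
* **Decode.**  The sampled matrix is accepted iff the parity self-check
  passes and the decoded identity is a codebook member, in exactly one of
  the four rotations.  Parity alone is deliberately insufficient: codebook
  membership (with its Hamming filtering) is the false-positive defence.
* **Coordinates.**  Origin at the top-left pixel centre, x right, y down.
  Corners are listed clockwise (as displayed) starting at the tag's
  canonical top-left; orientation is the counter-clockwise angle of the
  canonical top edge, wrapped to (−180°, 180°].

## Tracker

Frames are decoded independently; nothing flows between frames.
Trajectories are detections grouped by identity and sorted by frame, gaps
preserved, no interpolation or smoothing, no identity inference across
gaps.  Duplicate (identity, frame) pairs — possible from reflections or
false positives — keep the detection whose sampled grid had the largest
mean margin from the binarisation threshold; conflicts are logged and
counted.  The per-identity summary reports frames detected, detection
rate, total path length, net displacement, bounding-box and convex-hull
areas.

## Synthetic scenes and sweeps

The scene factories define the package's reference study conditions:
12 tags per frame on a flat mid-gray field (emulating a printed test card
filmed from a moving viewpoint), per-frame jittered positions and uniform
random orientations, at 6 px/module (42 px white-quad edge) unless stated.
The gradient-lit variant renders intensity as
`albedo × 0.45 + ambient(x)` with ambient rising 0.10 → 0.50 across the
image, so black and white modules stay separable by a mid threshold
everywhere while thresholds near 0.2 or 0.9 misclassify one side.

Sweep scoring is always against ground truth: a tag counts as tracked in
a frame iff its identity is detected *and* the detected centroid lies
inside the true white-quad outline; any other detection is a false
positive.  The sweeps:

* **Resolution** — frames rendered at 12 px/module and bilinearly rescaled
  so the functional resolution (√ of mean quad area, px per tag edge)
  spans 5–45 px; detection is complete at ≥ 40 px/edge and collapses below
  ~20 px/edge.
* **Noise** — i.i.d. zero-mean Gaussian noise with variance 0–0.1 of the
  squared intensity range.  One standard-normal field is drawn per frame
  and scaled by √variance at every level (common random numbers), so the
  degradation curve is monotone rather than blurred by independent
  sampling noise between levels.
* **Threshold** — global threshold swept over 0.2–0.9 (30 levels by
  default); per frame the *recoverable* set is the union of tags tracked
  at any threshold, and each threshold's recovery fraction of that union
  is reported alongside the plain fraction.

What the synthetic scenes do **not** emulate: real sensor noise
statistics, lens distortion, motion blur, compression artefacts, cluttered
natural backgrounds, partial occlusions, specular reflections, or dirt on
tags.  Passing these sweeps therefore demonstrates the correctness and
the qualitative degradation behaviour of the implementation, not
field-ready performance on any particular camera setup.

## False-positive estimation

When only the set of identities known to be present is available (no
per-detection ground truth), detections decoding outside that set are
certain false positives.  With `V` valid codes and `K` known identities, a
spurious valid decode lands outside the known set with probability
`(V − K)/V`, so the estimated total false-positive count is
`n_out × V/(V − K)` and the rate divides by the total detection count.
With `K = 0` this reduces to the raw uncorrected rate.  The estimator
assumes spurious decodes are uniform over the codebook — adequate for
small rates, and by construction the corrected rate is never below the
raw one.

## Numerical choices and degenerate inputs

* Rendering uses inverse-mapped bilinear interpolation for rotation, with
  an alpha channel so the background shows through outside the black
  border; placement centres are rounded to whole pixels and the recorded
  ground-truth corners are exact for the rounded placement.
* Rescaling is bilinear with anti-aliasing prefilter on downscale.
* Tag placements may not overlap (bounding boxes are checked); scenes
  raise on overlap rather than modelling it.
* Degenerate regions (collinear hulls, < 4 hull vertices) are rejected,
  not errors; an image with no tags returns an empty list.
* All randomness flows through `numpy` generators seeded from explicit
  arguments; every render, sweep and CLI run is bit-reproducible given
  (config, seed).
* Test and acceptance problem sizes (6-frame sweeps, 2-frame resolution
  sweeps, 100-frame propagation sequences, 200-tag round trips) were
  chosen to exercise each behaviour at the package's reference conditions
  while keeping a full run in well under a minute.

## Known limitations

* No error *correction*: a single misread module invalidates a tag for
  that frame (by design — the next frame re-identifies it).
* No sub-pixel corner refinement beyond the hull fit; corner accuracy is
  ~1 px RMS axis-aligned and a few px at oblique angles.
* The detector assumes tags lie on (approximately) planar surfaces facing
  the camera; strong perspective beyond the ±30° interior-angle tolerance
  is rejected at the quad-fit stage.
* Video container decoding is out of scope: the tracker consumes ordered
  image sequences or an explicit frame manifest.
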