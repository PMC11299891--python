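# Methods

This note documents the models, parameters and design choices behind
`octtm`, and what the synthetic experiments do and do not establish.

## Scan model and conventions

A volume is `voxels[slice_y, depth_z, width_x]` with unsigned 8-bit
intensities; page order in the TIFF is slice order, row 0 of a page is the
shallowest depth. 16-bit stacks are rescaled to 8-bit on load by max-value
mapping because every threshold in the package is defined on the 0–255
scale. The default physical extents, (8, 8, 12.83) mm for a
417 × 669 × 417-voxel stack, are carried as metadata only; no operation in
scope consumes them numerically (they matter for future multi-volume
stitching, not for segmentation). All indices are 0-based.

## Detection stages

One detection stage is `binarize(t) → merge(r) → components(Amin, Amax)`:

* **binarize** — white iff intensity > *t* (strict, so *t* = 255 blanks any
  8-bit image).
* **merge** — conceptually a box blur of the binary image re-binarized at
  any-nonzero; implemented as morphological dilation with a
  (2*r*+1)×(2*r*+1) square, which is the same operator without float
  round-off. It exists purely to keep one physical structure from
  splitting into several objects: white regions closer than 2*r* px join.
  `r = 0` is the identity.
* **components** — 8-connected components of the merged image whose area
  lies in [*A*min, *A*max]; masks and areas are measured on the merged
  image. Objects are returned by descending area, ties broken by
  (corner_z, corner_x) so runs are reproducible. 8-connectivity was chosen
  because it matches contour-following behavior and absorbs diagonal
  speckle chains.

Defaults live in config, not code. For the full 417 × 669 geometry:
coarse *t* = 40, *r* = 3, *A*min = 500 px²; fine *t* = 25, *r* = 1,
*A*min = 550 px². For the small CI geometry (64 slices of 160 × 128):
coarse 40/2/120 and fine 25/1/60. At CI scale the fine-stage area floor
sits *below* the coarse one — sub-patch artifact fragments there are only
tens of pixels and a higher floor would exempt them from classification
entirely; the "slightly higher fine minimum" heuristic is a speed trade-off
that only makes sense at full scale. *A*max is supported but unset by
default: the benefit of a maximum size bound is ambiguous (removing large
objects trades recall for speed in a way that depends on the artifact
census), so nothing is guessed.

Raising *t* never adds white pixels and raising *A*min never adds objects;
both monotonicities are asserted in tests.

## Patch classifier

Both stages use the same architecture: input 64 × 64 grayscale in [0, 1] →
2 × [3×3 valid conv (16, then 32 filters), ReLU, 2×2 max-pool] → dense 64
ReLU → dropout 0.25 → single sigmoid output = TM probability. Variable-size
object crops are aspect-preserving resized (limiting edge) and centre
zero-padded. The loss is binary cross-entropy on the logit; the optimizer
is Adam at 1e-3; decision cutoff 0.5 with ties going to TM.

The network, backpropagation and optimizer are written in float32 NumPy
(im2col convolutions, argmax-routed pooling gradients, inverted dropout
from a seeded stream). This makes the entire training trajectory
bit-reproducible on one CPU given the seeds — a property the test suite
asserts directly and that framework-backed training does not guarantee.
Correctness of the gradients is checked against central differences in the
test suite.

### Sample-based accounting

Training is organized in *samples*: `sample_size` images per sample of
which `train_per_sample` train the model and the remainder enter a pooled
validation set fixed for the entire run (at full scale: 45 samples × 182
images, 150 trained, pool 45 × 32 = 1440). After each sample the model
records accuracy/loss on that sample and on the pool — four curves indexed
by sample. The desk-scale experiments keep the ratio but shrink the
sample to 91/75 and derive the sample count from the corpus size. When a
corpus cannot fill every sample, training ids are reused across samples
(never within one, never into the pool) and a warning is emitted.

Rotation augmentation ({0, ±15, ±30, 90, 180, 270}°; exact array rotations
at square multiples of 90°, bilinear otherwise) is applied to TM patches
before the split. Two consequences are accepted deliberately: rotated
copies of one source patch may land on both sides of the split, and
validation images share volumes with training images. Both make the pooled
validation accuracy an optimistic, within-corpus figure — a training
diagnostic, not a generalization estimate; the held-out-volume pipeline
experiment is the generalization measurement.

Loss is reported in raw cross-entropy units. Accuracy-style "loss
percentages" sometimes quoted for such curves have no standard definition
and are not reproduced.

## Phantom

The generator renders, in order of intensity compositing (pointwise max):

* **fixed-pattern lines** — `count` horizontal lines at fixed rows in the
  top 10 % of depth, identical across slices (that is what fixed-pattern
  noise is), intensity 160–220;
* **saturation lines** — `count` vertical full-depth lines, width 1–3 px,
  each persisting over a contiguous run of 20–50 % of the slices,
  intensity 235–255;
* **deep blobs** — `count` ellipsoids strictly below the membrane
  (clearance drawn from `gap_px`), intensity 120–190;
* **membrane** — a band of thickness `thickness_px` around the depth
  profile `z(x, y) = apex(y) + curvature·depth·u(x)²`, with the apex depth
  drifting linearly across slices and per-pixel Gaussian intensity jitter
  (mean 200, sd 15) over an X-range leaving 10 % margins;

then multiplies by log-normal speckle (σ = 0.25) and adds Gaussian
background noise (sd = 5). Labels follow precedence
TM > deep structure > artifact > background; every voxel has exactly one
label, and disabling a component (count or strength 0) removes its label
class entirely.

The blob clearance range (3–10 px at CI scale) is chosen so that a subset
of blobs sits within the coarse merging range (2*r* = 4 px) but outside the
fine one (2 px): exactly the population that motivates the two-stage
design, merged into the membrane object by the coarse pass and separated
again by the fine pass. The CI membrane thickness (12 px) keeps a coarse
membrane object majority-TM even with a merged blob (see labeling below).
What the phantom does *not* model: physically realistic speckle statistics,
refraction, beam profile, shadowing, real anatomical shape variation, or
pathology. Passing tests therefore demonstrate the correctness and
reproducibility of the machinery under the stated geometry, not clinical
performance.

## Auto-labeling and its consequences

An object's ground-truth class is TM iff ≥ 50 % of its (merged-mask) pixels
carry the TM label — one object, one majority label, as a human auditor
would assign. Two consequences:

* a membrane object that absorbed a small blob stays TM (the band
  dominates), so the fine stage gets to clean it — the intended two-stage
  behavior;
* a full-depth saturation line crossing the membrane welds membrane,
  fixed-pattern lines and itself into one giant component whose majority
  class is artifact; the object is non-TM, the classifier learns to reject
  it, and that slice's membrane is lost from the mask.

The second point is why object-level accuracy (the headline metric) can be
near-perfect while volume Dice on artifact-heavy phantoms is modest
(~0.4): the labels are *consistent*, and the pipeline reproduces them.
Recovering a membrane welded to an artifact requires an artifact-removal
model rather than threshold detection, which is out of scope. On
noise-free phantoms (lines and noise off, blobs kept), substituting the
ground-truth labeler for both CNNs yields Dice ≥ 0.99 — the residual is
detection-stage error alone, and that bound is an acceptance property.

The final slice mask is the union of accepted fine-stage object footprints
*intersected with the fine-threshold binarization*. The footprints carry
the merging halo (up to 2*r* px of background); keeping only genuinely
bright pixels inside them implements "use the object locations as a mask"
without smearing the mask, and is what makes the ≥ 0.99 oracle bound
attainable.

## Desk-scale experiment sizes

Chosen so the full suite and the acceptance script each finish in minutes
on one CPU: CI phantom geometry 64 × 160 × 128; pipeline experiment = train
on 4 volumes, score every object on 4 held-out volumes (≈ 550 objects);
classifier experiment = corpus from 6 volumes (≈ 1700 patches after
augmentation), samples of 91/75, training to the training-pool plateau
(early-stopped at accuracy 1.0 or after 3 stale epochs, max 25). All seeds
derive from one base seed.

## Known limitations

* Slices are processed independently; no 3D connectivity or inter-slice
  smoothing constrains the masks (a noted extension, not implemented).
* Multiple coarse TM objects per slice are allowed and their fine-stage
  results unioned; nothing enforces a single membrane per slice.
* The validation-accuracy figure is within-corpus (see above).
* Membrane recall drops on slices where saturation lines cross the
  membrane, by construction of the majority-label semantics.
* The classifier is trained and evaluated on phantom statistics only;
  nothing here claims clinical accuracy.
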