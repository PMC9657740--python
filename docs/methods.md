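# Methods

## Supervision softening

The package's central object is a three-tier per-pixel loss-weight map built
deterministically from instance annotations.

**Bounding boxes and the median diagonal.**  Box extents are the literal
coordinate ranges `max − min` (no `+1`), so a single-pixel instance has
width, height, and diagonal 0.  The diagonal median `ψ*` is pooled over
*every* instance in the training dataset; a per-image mode exists behind a
flag for experimentation but is not the default, because a single kernel pair
applied uniformly is what makes weight maps comparable across images.

**Kernel sizes.**  `κ_e = υ·⌊(φψ* + 1)/2⌋ + 1` and likewise `κ_d` with `τ`.
With the default multipliers (υ = 2, τ = 6) and the doubled preset (4, 12)
the result is always odd and `κ_d = 3κ_e − 2`.  The halved preset (υ = 1,
τ = 3) can produce an even side (e.g. ψ* = 100 → κ_e = 2); since a square
structuring element needs a centre pixel, an even result is bumped to the
next odd integer.  This ±1 adjustment affects only the non-default preset.

Note the rule's dead zone: for ψ* < 100 the floor term is 0 and both kernels
are 1 — the soft band vanishes and the construction degrades gracefully to
hard labels.  This is a real property of the published parameterisation, and
it matters at desk scale (below).

**Morphology and borders.**  Erosion and dilation use the all-ones κ×κ
square.  Outside-image pixels count as background: instances touching the
border erode from that side, and dilation is clipped to the frame.  An
instance that erodes to the empty set contributes no core; its own pixels
become pure soft band (forced by the region algebra, documented rather than
"fixed").  Where instances overlap, tier priority is core > band >
background, so a pixel in one instance's core and another's band gets Ψ.

**Hard targets.**  Only weights are softened.  Target classes stay hard, and
dilation-band pixels outside any annotation keep the background class; the
per-pixel loss needs a single target class, and nothing in the construction
supplies a graded one.  Overlapping instances of *different* classes are
rejected with an error naming the instances.

## Loss

Per-pixel softmax cross-entropy, each pixel scaled by its weight, averaged
over the pixel count M (not the weight total).  Softmax is stabilised by
subtracting the per-pixel maximum score — mathematically a no-op.  The
natural logarithm is used throughout.  A `sum` reduction switch exists
because the historical FCN recipe (learning rate 1e−10, momentum 0.99) pairs
with sum-reduced loss; switching reductions requires rescaling the learning
rate by roughly the pixel count.  Label value 255 marks ignored pixels
(padded tile borders): they contribute zero loss and gradient and are
excluded from M.

## Network

FCN-32s exactly: stages of 2/2/3/3/3 3×3 convolutions (64/128/256/512/512
channels), each stage closed by a 2×2 stride-2 max pool; then 7×7×4096 and
1×1×4096 fully-convolutional heads with dropout, a 1×1 score layer to N
classes, a 64×64 stride-32 deconvolution, and a crop.  Three conventions are
pinned by the published inference shape trace (512 → 710 → 355 → 178 → 89 →
45 → 23 → 17 → 576 → 512):

- the first convolution pads by 100 — the only padding that yields 710;
- all five pools are ceil-mode 2×2 stride 2 (355 → 178 requires ceil); the
  source table's "3×3 stride 1" entry for pool2 contradicts its own printed
  feature sizes, and the sizes win;
- the crop offset is 19, the canonical FCN-32s alignment (only the cropped
  size is published).  An empirical shift scan on trained desk models
  confirms offset 19 maximises agreement with ground truth.

The fc6 kernel is 7×7 (the architecture table and the 23 → 17 shape algebra
both say so; accompanying prose that says 3×3 is inconsistent with them).
The minimum supported input side is 26; smaller inputs are reflect-padded at
prediction time and cropped back.  A `width_multiplier` scales every channel
count (minimum 1) so the same topology trains at desk scale; the layer-shape
trace is exact at any width.

The implementation is plain numpy: im2col + matmul convolutions, explicit
backward passes, per-position patch scatter for the deconvolution (its input
grid is tiny at stride 32).  Gradients are verified against central finite
differences in the test suite.

**Initialization.**  `random` (N(0, 0.01)), `kaiming`, `xavier` apply the
named scheme everywhere.  `vgg16_transfer` copies shape-matched convolution
weights from a user-supplied `.npz` archive, zero-initialises the score
layer, and sets the deconvolution to exact bilinear upsampling; it requires
full width.  `kaiming_bilinear` (Kaiming convolutions + bilinear deconv +
zero score layer) is the desk-scale default: the bilinear deconvolution makes
the untrained network an interpolator rather than a noise generator, and the
zero score layer starts from uniform class probabilities.

**Optimizers.**  SGD with momentum (`v ← μv − ηg; θ ← θ + v`), NAG, Adam,
Adagrad, Adadelta, RMSprop; weight decay enters as L2 added to the gradient.
The published full-scale recipe is SGD momentum 0.99, lr 1e−10 (sum
reduction), weight decay 5e−4.

**Desk-scale training profile.**  Width 1/8, 128×128 fields, mean reduction,
lr 1e−3, momentum 0.99 (the published value), weight decay 5e−4, dropout
disabled, `kaiming_bilinear` init, 500 steps at batch size 1, no
augmentation.  Dropout and augmentation were evaluated at this scale and
rejected: with a 1/8-width head and a 500-step budget, dropout's noise
outweighs its regularisation, and spreading 500 steps over an 11× augmented
dataset under-trains each unique field.  Augmentation (the original + five
5°-step rotations + three right-angle rotations + two flips = 11 samples)
remains available and is the intended regulariser for full-scale runs.

## Tiling, stitching, augmentation

Inference tiles are 512×512 by default (any size ≥ 26 works); borders are
reflect-padded and tracked by validity masks, overlapping valid score
contributions are averaged at stitch time, and a coverage gap is an error.
At stride = tile side each source pixel belongs to exactly one valid region.
Geometric augmentation transforms image, label map, and weight map
identically: bilinear resampling for the image, nearest-neighbour for the
categorical planes, so label indices and the {Ψ, Π, ℵ} weight set are
preserved exactly; regions rotated in from outside the frame are filled with
black / background class / background weight.

## Synthetic fixtures

The clinical slides are not deposited, so the generator emulates only the
statistical structure the method targets: crisp ground truth under a blurred
appearance.  Each field contains non-overlapping elliptical nuclei with a
low-frequency radial wobble, and two classes of small disk signals rendered
strictly inside nuclei ("her2"-like dark, "cen17"-like red in the DISH
palette; a FISH palette is available).  Instance masks are taken from the
pre-blur geometry, then the image alone is Gaussian-blurred (the
`boundary_blur_sigma` difficulty dial) and noised.  Signal pixels are carved
out of their nucleus' pixel set so instances of different classes never
overlap.  Placement is seeded rejection sampling with a bounded retry budget;
an infeasible packing raises a generation error.

Defaults: 256×256 fields, 5 nuclei of radius 16–26 px, 4 dark + 2 red dots
of radius 1.5–3 px per nucleus, blur σ 1.5, background noise σ 0.02.

The *desk training family* uses 128×128 fields with 2 nuclei of radius
20–28 px.  The radii are chosen so a nucleus spans roughly 1.5–2 output-stride
cells of the stride-32 architecture — the closest a 128-px field can come to
the clinical regime, where annotated objects span several stride cells of a
512-px tile.  (With substantially smaller objects the fixture measures the
architecture's stride limit, not the supervision scheme: an ideal stride-32
block predictor tops out near F1 0.5 on 13–21 px nuclei.)

Because desk-scale diagonals sit far below the kernel rule's ψ* = 100
threshold, the desk pipeline pins the kernel pair at (3, 7) — the pair the
published parameters produce at clinical scale — instead of the degenerate
identity pair; the `softmap` CLI and library default keep the literal rule.

What passing desk-scale tests do **not** show: realism of colour and texture,
robustness to staining variation, uneven illumination, out-of-focus planes,
or touching/overlapping nuclei, none of which the generator models.

## Evaluation

Pixel confusion counts give accuracy, precision, recall, F1 = 2TP/(2TP+FP+FN)
and Jaccard = TP/(TP+FP+FN); F1 = 2J/(1+J) is asserted as a cross-check.
Multi-class predictions are scored one-vs-rest per foreground class plus a
"foreground = any class" roll-up.  Zero-denominator conventions: if
TP+FP+FN = 0 (both masks empty) the overlap metrics are 1, otherwise an
undefined ratio is 0; either case is flagged.  Aggregation reports the mean ±
sample standard deviation (ddof = 1; 0 for a single image) per image.

## Known limitations

- `vgg16_transfer` needs an external weight archive; no pretrained weights
  ship with the package.
- Batch size is fixed at 1; there is no GPU path.  A full-width 512×512
  training step is possible but slow in numpy — the desk profile exists
  precisely so the full pipeline stays testable on one CPU.
- The per-image-median softening mode is experimental and unvalidated.
- Weight maps are class-agnostic; per-class kernel sizes are out of scope.
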