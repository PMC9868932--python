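# Methods

`leafdet` implements the method side of an improved single-stage crop-disease
detector for the regime where lesions are small, numerous and frequently
overlapping. This note records the models and procedures, the parameters
that matter, what the synthetic data does and does not exercise, and the
design choices made where the design was genuinely open.

## Box losses

For a predicted box `b` and ground truth `b_gt` (pixel coordinates, y down),
`pair_geometry` derives IoU, union area `u`, minimal enclosing rectangle area
`A_c` and squared diagonal `c²`, squared centroid distance `ρ²(b, b_gt)` and
squared distance between the upper-left corners `ρ²(l, l_gt)`. On top of
these:

- **BCE** — mean binary cross-entropy over probabilities, clamped to
  `[1e-7, 1 − 1e-7]`.
- **GIoU loss** = `1 − IoU + (A_c − u)/A_c`, range [0, 2).
- **DIoU** = `IoU − ρ²(b, b_gt)/c²`; loss `1 − DIoU`.
- **Improved DIoU** = `IoU − ρ²(b, b_gt)/(ρ²(l, l_gt) + c²) ×
  ((w/w_gt − 1)² + 1)`; loss `1 − DIoU`.

The improved variant addresses a failure mode of DIoU on disjoint pairs:
inflating the predicted box grows `c²`, shrinking the penalty, so the
optimiser is rewarded for wrong growth. Adding the corner distance to the
denominator ties the penalty to box placement rather than extent alone, and
the width-ratio factor multiplies the penalty whenever the predicted width
deviates from the ground truth in either direction. On the canonical
configuration (equal squares of side `w`, centroids `2w` apart) DIoU is
−0.4 and the improved value is −2/7 ≈ −0.29; over a prediction-scale sweep
{0.25…2} the improved value is uniquely maximised at scale 1, while plain
DIoU keeps improving as the prediction inflates. The width-only (no height)
ratio factor is implemented exactly as specified by the method; the
asymmetry is deliberate fidelity, not an oversight of this package.

## Offset decoding

Head outputs `(tx, ty, tw, th)` decode against a grid cell `(cx, cy)` and an
anchor `(pw, ph)`:

- original: `bx = 2σ(tx) − 0.5 + cx` — the offset lives in the *open*
  interval (−0.5, 1.5), so a center on the far cell boundary needs an
  infinite logit;
- improved: `bx = clamp(2.2σ(tx) − 0.6, −0.5, 1.5) + cx` — both endpoints
  are attained at finite logits (±3.045); the clamp is a hard min/max with
  zero gradient outside the window;
- sizes (both schemes): `bw = pw·(2σ(tw))²`, range (0, 4pw).

`encode_center_improved` / `encode_size` invert these maps for target
construction; encoding is defined exactly on the attainable ranges.

## Positive-sample assignment

A ground-truth center selects its containing cell plus the axis neighbours
on the nearer half of the cell (3-cell rule); the extended rule adds the
diagonal neighbour completing that 2×2 quadrant — the only further adjacent
cell whose offset remains inside the decodable [−0.5, 1.5] window. Ties at
fractional part exactly 0.5 resolve to the right/above neighbour. Anchors
match a target iff `max(w/pw, pw/w, h/ph, ph/h) < 4` (threshold
configurable); each (matched anchor × selected cell) pair becomes one
positive sample, and duplicates claimed by different ground truths are all
kept. On interior, non-tied centers the extended rule yields exactly one
extra cell, hence ≥ 4/3 more positives — the point of the scheme on dense
small-object scenes.

## Anchor clustering

Anchors are k-means centroids of the dataset's (w, h) distribution under the
distance `d(box, centroid) = 1 − IoU(box, centroid)` with the boxes placed
concentrically. Initial centers are k distinct samples drawn by seeded index
(k-means++ seeding available); centroids update as the per-cluster
arithmetic mean of (w, h) — the convention of this detector family — and
iteration stops when assignments stabilise or after 300 rounds. Because a
single random start can merge near-by shape clusters, the implementation
runs 30 seeded restarts and keeps the solution with the smallest mean
distance; on well-separated synthetic clusters this recovers the generating
centers to within a few percent. Note the mean update's k = 1 fixed point is
the sample mean, which sits near but not exactly at the minimiser of the
mean 1 − IoU objective. The nine anchors are split into ascending-area
triples; the smallest triple serves the stride-8 head (highest resolution,
smallest objects), following the universal convention.

## Augmentation schedule

Mosaic stitches crops of four scenes around a pivot drawn uniformly in the
central 50% of the canvas; boxes are remapped, clipped to their crop, and
dropped below 2 px side length or 25% visible area. Because mosaic output
departs from the natural image distribution, it is applied only during the
first 40% of training epochs (`epoch < floor(0.4 × total)`, per-epoch
granularity); afterwards the standard set applies: horizontal flip,
isotropic scale, independent width/height distortion, and HSV jitter. A
separate one-shot offline expansion (Gaussian blur, horizontal flip, ±15°
rotation with mask-retightened boxes, brightness) multiplies an annotated
set before training, mirroring the usual split between offline dataset
enlargement and on-the-fly augmentation.

## Network blocks and assembly

All network code runs on a compact reverse-mode autograd engine over numpy
written for this package (float32, im2col convolutions, exact batch-norm
backward); gradients of every structured operation are verified against
finite differences in the test suite.

- **Ghost block**: dense 1×1 produces half the output channels; a cheap
  depthwise 3×3 on those produces the rest; concatenated.
- **Inverted residual**: 1×1 expand (×2 by default) → depthwise 3×3 → 1×1
  project, residual when shapes allow.
- **Improved CSP**: shortcut 1×1 branch beside a processed branch
  (1×1 → Ghost) that splits into an inverted-residual path and a
  global-average-pool context path broadcast back over the plane; the three
  equal-width outputs concatenate into a final 1×1 fuse. Branch widths are
  `cout/2` each (the original does not pin them; equal widths assumed).
- **EPSA**: channels split four ways, convolved with kernels 3/5/7/9 (grouped
  convolution sizes 1/4/8/16 keep large kernels cheap); per-split SE
  descriptors produce attention logits softmax-normalised across splits.
- **CAM**: fuses a shallow map with an upsampled deep map at the shallow
  resolution. Each side contributes a pooled sigmoid gate (average pooling
  on the deep side for global context, max pooling on the shallow side for
  texture detail) and an inverted-residual → EPSA branch; the four branch
  outputs plus both 1×1-aligned inputs are summed elementwise
  (concatenate-then-1×1 available behind a flag), preserving the original
  signals. The pooled "gate" reading of the pooling branches is an
  interpretation: the block's description fixes the pooling operators but
  not how the pooled vector re-enters the map.

The baseline detector is Focus + CSPDarknet + SPP with a PAN neck and three
heads at strides 8/16/32 (width/depth multiples 0.5/0.33 ≈ 7.08 M
parameters). The improved detector replaces every neck CSP with the improved
CSP and both post-upsample concatenations with CAM (read from the assembly
diagram as both junctions); its parameter count lands ≈ 12% above the
baseline — same direction and similar margin as the reference values
(7.08 M baseline, 7.62 M improved); exact equality is out of reach because
the original design's inner channel widths are not public.

## Evaluation

PASCAL-VOC protocol at IoU 0.5: per class, detections sorted by descending
confidence greedily consume their best unmatched ground truth; AP integrates
the monotone precision envelope over recall (all-point interpolation); mAP
averages per-class AP over classes present in the ground truth (a common
misprint writes recall as a second precision formula; TP/(TP+FN) is recall
and is implemented as such). P/R are reported at the operating point of all
detections above the confidence floor (0.001 default) and F1 at the
confidence maximising it, since no single operating point is canonical.
Frame-rate measurement is deliberately out of scope (hardware-dependent).

## Synthetic data

Scenes are green-textured canvases (low-frequency mottling over a leaf-green
base) with anti-aliased rotated elliptical lesions; each class has a fixed
hue, lesions carry mild multiplicative texture, and the label box is the
tight axis-aligned extent of the rendered blob (verified to ±1 px). Side
lengths draw log-uniformly from [4, 64] px at a 640 px canvas (rescaled with
image size), biasing mass toward the stride-8 head as in the motivating
regime; placements permit partial overlap up to a 40% cover allowance.
What this does *not* emulate: real lesion morphology and texture continuity
with the leaf, illumination and perspective variation, annotation noise, and
inter-class ambiguity beyond hue similarity. Passing tests therefore
demonstrate that the machinery is correct and trainable, not that the
accuracy figures transfer to field imagery.

## Desk-scale training

The full-scale defaults mirror the reference protocol: SGD momentum 0.937,
initial lr 0.01 with a 3-epoch linear warmup and ×0.1 steps at 70%/90% of
epochs, input 640, 400 epochs, batch 16, early stop after 20 non-improving
validation epochs, mosaic for the first 40% of epochs. Loss = BCE(class) +
BCE(objectness, balanced 4/1/0.4 across strides) + improved-DIoU(box),
combined 0.05/1.0/0.5 and scaled by batch size, evaluated at the 4-grid
positive samples. The objectness target at a positive cell is the detached
IoU of the decoded box with its ground truth rather than a constant 1 (the
family convention): confidence then ranks localization quality, which is
what the VOC AP integral rewards.

The test suite's smoke training necessarily shrinks the problem: 50 scenes
at 96 px with four lesion classes, width multiple 0.25, 30 epochs, batch 4,
no augmentation — a few hundred optimizer steps in total. Three desk-scale
adaptations matter at that budget: anchors are re-clustered on the
synthetic set (the package's own anchor workflow; 640-scale priors are
meaningless on 96 px inputs); the box/class loss weights are raised (box
4.0, class 2.0), because with the full-scale weights and only ~10² steps
the box branch receives gradients far too small to leave its
initialisation — a pathology of the step budget, not of the loss; and the
class inventory is halved because distinguishing eight hue-coded classes
from ~20 examples each is data-starved at this sample size, whereas
class-agnostic localization is already strong. Validation loss is computed
with batch statistics (running BN statistics lag the fast-moving weights
early on), and after training the BatchNorm running statistics are
recalibrated by cumulative averaging over plain forward passes of the
training set, so eval-mode inference matches the converged network.
Training is bit-deterministic given config + seed.

## Numerical choices

- float32 throughout the network; losses accumulated in float64 where scalar.
- Sigmoid logits clipped to ±60 before exponentiation; BCE probabilities
  clamped at 1e-7.
- BatchNorm ε = 1e-4, momentum 0.03 (cumulative averaging during the final
  recalibration pass).
- k-means ties and area-sort ties break by width then height; equality
  comparisons in tests use absolute tolerance 1e-6 unless a quantity is
  printed at 2 decimals, in which case values are compared after rounding.
- NMS is per class at threshold 0.45 (class-agnostic behind a flag);
  confidence floor 0.001 at evaluation (configurable).
- Empty clusters re-seed on the worst-covered sample; degenerate boxes
  (non-positive sides) are rejected at construction everywhere.

## Known limitations

- The autograd engine is single-threaded numpy; it is meant for desk-scale
  verification, not production training. Full-scale (640 px, width 0.5)
  training is out of reach on CPU, and benchmark accuracy on real
  plant-disease data is explicitly not reproduced here.
- Letterboxing is not implemented; images are square-resized.
- The improved model's exact internal channel widths are this package's own
  choices (the original design does not pin them); parameter counts are
  compared by direction and ratio, not equality.
- Transfer learning is supported only as warm-starting from a local
  checkpoint; no pretrained weights ship with the package.
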