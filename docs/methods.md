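# Methods

This package re-implements, at desk scale, a two-stage detector for bone
marrow oedema in lumbar MRI whose three distinctive ingredients are (i)
deformable convolution and deformable RoI pooling in the feature
extractor, (ii) a feature-pyramid neck assembled from six kinds of
"information paths", and (iii) a one-shot supernet over those paths whose
best sub-network is found by an evolutionary algorithm. Everything below
is the package's own account of what is computed, which knobs matter and
what the synthetic experiments do and do not show.

## Differentiation engine

No GPU autodiff framework is part of the dependency set; the package
ships a small reverse-mode engine over `numpy` float64 arrays
(`lesionnas.autodiff`). It supports exactly the operations the detector
needs: elementwise arithmetic, matrix products, "same"-padded convolution
written as a sum over integer sampling taps, its deformable variant with
gradients flowing into the learned offsets, bilinear gathering at
fractional positions, 2×2 max pooling, nearest upsampling and the two
detection losses. Every operator is validated by central finite
differences at tolerance 1e-4 on small inputs (bilinear interpolation is
piecewise linear, so gradient checks sample fractional positions away
from the integer lattice where the true derivative jumps).

## Deformable operators

A standard convolution samples the input `x` on a regular grid `R` of
taps around each output position `p0`; the deformable variant adds a
learned per-position, per-tap displacement `Δp_n` and resolves the
resulting fractional positions with the bilinear kernel

    g(a, b) = max(0, 1 − |a − b|),   G(q, p) = g(q_r, p_r) · g(q_c, p_c),

so at most four integer neighbours contribute to any sample. Conventions
fixed once and asserted in tests: (row, col) 0-based coordinates,
half-open boxes in continuous coordinates, offsets stored as (Δrow,
Δcol) pairs, and out-of-map reads contributing zero (consistent with
zero-padded convolution). The convolution weight is indexed by the tap,
`w(p_n)` — the only reading under which the operation is a convolution.

Offsets are produced by a plain convolution over the same input feature
map ("predict then deform"), zero-initialised so training starts from the
plain-convolution regime. A flag makes the offset predictor itself a
deformable convolution (carrying a fixed zero offset field) for
structural experiments; the default is the plain predictor.

Deformable RoI pooling divides an RoI into `bins_h × bins_w` equal
sub-rectangles, averages the integer-position samples inside each bin,
and shifts every bin's sample positions by a learned per-bin offset
before bilinear resolution. The defining sum is undefined for a bin that
contains no integer position; such bins fall back to a single bilinear
sample at the bin centre, which keeps the output finite and
differentiable. This matters in practice: small lesions pooled to 7×7
bins on a stride-4 map routinely produce empty bins.

## The six information paths

All paths map a 4-level pyramid (levels 2–5, strides 4/8/16/32, shared
width C) to a pyramid of identical shape:

* **top-down** `F_i = W_i ⊗ (U(F_{i+1}) + P_i)`, built 5→2, seeded with
  `F_5 = W_5 ⊗ P_5`;
* **bottom-up** the mirror image, built 2→5;
* **scale-balanced** `F_i = U(W_1 ⊗ P_{i+1}) + W_0 ⊗ P_i + D(W_{−1} ⊗
  P_{i−1})` with the three convolutions shared across levels; the
  lower-level term is downsampled so shapes agree, and missing
  neighbours at the boundary levels drop their term;
* **fuse-split** fuses the upper pair (`α_s = P_4 + U(P_5)`) and lower
  pair (`α_l = D(P_2) + P_3`), mixes them through channel concatenation
  and two 2C→C convolutions, then splits back to four levels by
  resampling;
* **null** — the zero pyramid, the additive identity that lets the
  search prune edges;
* **skip** — the identity, parameter-free.

`U` is nearest-neighbour ×2 and `D` is 2×2 max pooling; both are
parameter-free, so a path's parameter count equals its convolution
content (asserted in closed form in the tests). Per-level convolutions
are deformable on levels 3–5 and regular on level 2; the shared
convolutions of the scale-balanced and fuse-split paths are deformable.
The boundary seeds (`F_5` top-down, `F_2` bottom-up) use the
convolution-of-input only, since the defining recursions are silent
there.

## Supernet and search

The neck search space is a fully connected DAG over nodes `[P, X_1 … X_N,
O]` holding pyramids; every forward-ordered pair carries one edge, each
edge realises one of the six path kinds, and a node's value is the
element-wise **sum** of its incoming edge outputs. Sum-aggregation is a
design choice the source architecture leaves open; it makes the null path
a true identity and a sequential chain a special case. Each edge owns
private parameter bundles for the four parameterized kinds (standard
one-shot practice; no cross-edge sharing). Defaults: N = 5 intermediate
nodes (21 edges, 6^21 raw codes) and 112 channels, both configurable; the
desk-scale configuration uses N = 1 (3 edges, 216 codes — small enough to
enumerate exhaustively in tests).

A subnet code assigns one kind per edge. Codes with no non-null directed
route from P to O would feed the detection head zeros; sampling,
crossover and mutation all re-draw such codes (validity conditioning).
Supernet training follows Single Path One-Shot: each step samples one
uniform valid code and updates only the parameters that code touches.

The evolutionary search keeps S = 50 candidates, ranks them by AP50 on
validation data computed with the shared weights (no retraining), carries
the k = 10 fittest unchanged (elitism — the best-so-far fitness is
non-decreasing by construction), and refills with children =
`mutate(crossover(elite, elite), p)` at per-edge mutation probability
p = 0.1. The number of rounds is not pinned by the source description;
the default is n = 20. Mutation resamples each edge independently with
probability p over all six kinds — so the expected fraction of changed
edges is 5p/6, because a resample may repeat the old kind; the
alternative reading (exactly one random edge per child) is available via
a flag. Fitness values are cached per code; the evaluation is
deterministic given weights and data.

## Detector assembly

Forward order: backbone → 1×1 lateral projections to a C-channel pyramid
→ neck (the supernet with a fixed or sampled code) → element-wise
addition of the neck output back onto the projected backbone pyramid
(residual superposition; the 1×1 laterals are the channel projection) →
RPN → deformable RoI pooling to 7×7 → a fully connected head (1024-d at
full scale) producing class scores and class-agnostic box deltas.

Two backbones are provided. `tiny` is a 4-stage CNN (≤ 32 channels,
strided convs + one refining conv per stage, deformable in stages 3–5)
that trains end-to-end on one CPU in minutes and is used by every test.
`resnet50` reproduces the full-scale architecture's shape — bottleneck
counts 3/4/6/3, widths 256/512/1024/2048, deformable 3×3 convolutions in
stages 3–5 — with random initialisation; it is structural only (no
pretrained weights, no claim of full-scale accuracy).

The proposal machinery is the standard two-stage recipe, which the
source architecture inherits from its Faster-RCNN base without
specifying: 3 scales × 3 aspect ratios per level, IoU 0.7/0.3 anchor
assignment with each ground truth keeping its best anchor, proposal
decoding with log-delta clamping at ±4, NMS at 0.7 for proposals and at
0.5 (configurable) at inference, IoU ≥ 0.45 foreground assignment for
RoIs, and ground-truth boxes — plus two randomly jittered copies of each
(±15 % of the box size per coordinate) — appended to the training
proposals. The jittered copies matter: a head that only ever sees exact
ground-truth boxes as clean positives learns to reject the slightly-off
proposals the RPN actually produces for small lesions, and a lesion
whose best proposal hovers just below the foreground cutoff is never
recovered; jittered positives teach the head to accept and re-regress
near misses. RoIs
are routed to pyramid levels by `k = clip(2 + floor(log2(√area / 16)),
2, 5)`. Per-bin RoI offsets are predicted by a zero-initialised linear
layer from a plainly pooled copy of the RoI.

The loss is

    L = Σ(L_cls + L_loc) + μ · L1,

summed over both stages: cross-entropy for RPN objectness and head
classification, smooth-L1 on box deltas of positive matches, and an L1
penalty equal to the **mean absolute value** of the regularised weight
set, μ = 0.11 by default. The regularisation scope is the neck (laterals
plus the active path parameters) by default, switchable to all weights.
The decomposition `total = l_cls + l_loc + μ·l1` is computed once in a
fixed operation order and holds bitwise for every logged step.

## Synthetic data

The clinical dataset (521 lumbar MRI images from 72 patients) is private.
The generator emulates its geometry rather than its physics: a vertical
stack of rounded-rectangle vertebrae at medium intensity on a dark
background, bright elliptical/streak distractors outside the vertebral
column (the organ and fat tissue that makes oedema hard to spot), and
bright rotated-ellipse lesions centred inside vertebrae. Defaults follow
the study conditions where stated: 416 training and 105 test images,
single category "oedema", COCO-format annotations, horizontal flip with
probability 0.5 and random crop to 0.6–1.0 of the original size as
augmentations. Values the study does not state were chosen once:
256×256 images, lesion axes 4–30 px, lesion intensity at least 0.3 above
the vertebra level, additive Gaussian noise σ = 0.03, and boxes reduced
to below 25 % visible area by cropping are dropped. Crops are resampled
back to the input size so batch geometry is stable. Lesion placements
whose bounding box comes within 3 px of an existing lesion are re-drawn:
lesions are distinct foci separated by normal marrow, and abutting or
nested ellipses would merge into a single visual blob whose two
annotations no detector — and no reader — could separate.

What passing the synthetic tests shows: the operators are exact, the
pipeline's gradients are correct end-to-end, the search machinery finds
enumerable optima, and the full detector can drive its training loss to
a perfect training-set AP50. What it does not show: accuracy on real
MRI, robustness to scanner variation, or any clinical claim — real
oedema has diffuse borders, intensity texture and anatomy this generator
deliberately does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the detector in the tiny
configuration: 64×64 images, 16 channels everywhere, N = 1, 10 training
images, epoch-shuffled batches of 4, SGD with learning rate 0.08 (decayed
to 0.016 after 600 steps) and global gradient norm clipping at 10, up to
1000 steps. These sizes were chosen so a full
train-to-perfect-AP50 run takes a few minutes on one CPU; the default
(full-scale) configuration keeps the study's values — 112 channels,
N = 5, 1024-d head, lr 0.001, batch 4, 30 epochs — and is exercised
structurally (construction, parameter counts, shapes) rather than
trained. Momentum is available but off by default in the desk-scale
runs: with a working effective step of lr/(1−m), momentum 0.9 at these
learning rates oscillated rather than converged. Image sides must be
divisible by 32 so the four pyramid levels tile exactly.

Detector activations are leaky ReLU (slope 0.01): with plain ReLU and
the aggressive desk-scale learning rate, the head's single hidden layer
can die outright — every RoI then scores the bias-only constant and
classification stops learning. The leaky slope keeps a gradient path
open at negligible cost.

The desk-scale evaluation runs inference NMS at IoU 0.3 (the
configurable default is 0.5): synthetic lesions are distinct foci whose
ground-truth boxes overlap by at most IoU 0.1 by construction, so the
tighter threshold removes duplicate detections of one lesion without any
risk of suppressing a true neighbouring one. The localisation loss uses
smooth-L1 with transition β = 1/9 (the classic region-proposal setting);
with β = 1 the loss sits in its quadratic regime for ordinary box-delta
errors and the gradient is too weak to tighten boxes quickly.

Other numerical choices: box IoU uses exact interval arithmetic on
half-open boxes; AP50 uses the 101-point interpolated COCO convention
(pooled detections, greedy per-image matching in descending score);
ties in score sorting are broken stably. The reported F1 is the
harmonic mean of the AP50 and recall percentages, rounded half-up to one
decimal — the reading that reproduces the consistent rows of the source
tables exactly; a score-thresholded precision/recall report is also
available, since two table rows are inconsistent with any single
definition.

## Known limitations

* The engine is float64-on-CPU throughout; full-scale training (ResNet-50,
  112-channel neck, N = 5) is structurally supported but computationally
  impractical here.
* Modulated (v2) deformable convolution, dilation > 1 and pyramid depths
  other than 4 are out of scope.
* The evolutionary search at full scale would evaluate S × n = 1000
  subnet inferences; the tests exercise the machinery on enumerable
  spaces instead.
* The synthetic generator is a geometric stand-in; no claim about
  clinical MRI transfers from it.
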