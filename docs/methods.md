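# Methods

This note records the models implemented in `rdwkit`, the assumptions and
parameter choices behind them, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Box losses

### Gaussian box model and Wasserstein distance

A box (cx, cy, w, h) is modelled as a 2-D Gaussian with mean (cx, cy) and
covariance Σ = diag((w/2)², (h/2)²) — the half-extent convention of the
normalized-Wasserstein literature, under which the squared 2-Wasserstein
distance between two boxes reduces from the general matrix form

    W₂²(Na, Nb) = ‖μa − μb‖² + Tr(Σa + Σb − 2(Σb^{1/2} Σa Σb^{1/2})^{1/2})

to a plain squared Euclidean distance on the 4-vector (cx, cy, w/2, h/2).
Both forms are implemented: the matrix form (`wasserstein2_squared`,
evaluated through symmetric eigendecompositions) serves as the independent
cross-check of the closed form (`wasserstein2_squared_diag`), and the test
suite holds them to 1e-9 relative agreement over 1000 random pairs.

### NWD normalization

NWD = exp(−D/c). Two readings of the exponent are defensible: D = √W₂²
(a length, the convention of the published NWD constant c = 12.8 on pixel
scales) and D = W₂² (a squared length). The default is the square-root
reading — it makes NWD scale-invariant when boxes and c are scaled together,
which is the property that matters for multi-scale detection — and the
squared reading is available via `LossConfig(nwd_exponent="squared_distance")`.
`c_norm` should sit on the order of the typical object extent in the
caller's units: 12.8 for pixel-scale boxes (the published constant), ~0.2
for [0,1]-normalized boxes (the toy detector's default).

### CIoU

L_CIoU = 1 − IoU + ‖Δcenter‖²/d² + αv with v = (4/π²)(arctan(w_gt/h_gt) −
arctan(w_pred/h_pred))² and α = v/((1 − IoU) + v), the standard Complete-IoU
form. Each of the three terms is individually bounded by 1. An ε = 1e-9 in
the arctan denominators and in α's denominator keeps gradients finite for
near-degenerate boxes; at pred = gt the loss is exactly 0.

### WWIoU and differentiation

L_WWIoU = r·L_CIoU + (1−r)·(1−NWD). The NWD term is taken as a loss of the
same orientation as CIoU (0 at identity, increasing with mismatch) so the
mixture is a convex combination of losses. Defaults r = 0.5, c = 12.8, both
configurable — r trades local overlap accuracy against global geometric
robustness and there is no canonical value.

Gradients are exact forward-mode derivatives (dual numbers, one pass per
coordinate; `rdwkit._autodiff`). Piecewise primitives (the min/max of corner
arithmetic) use the active branch's derivative; √x at x = 0 — reached only
at pred = gt, the loss minimum — is assigned slope 0, the correct descent
choice. Finite-difference agreement is asserted at 1e-4 relative on random
non-degenerate pairs (pairs with IoU ≥ 0.05, keeping the probe off the
measure-zero kink at zero overlap where two-sided differences are
ill-defined).

### Box-fit descent (`fit_box`)

The demonstration harness descends the chosen loss with the *normalized*
gradient direction and a step size decaying linearly from `lr` (default
0.02) to zero. Raw fixed-step descent is unstable here: the CIoU center
term's gradient grows without bound as the enclosing box shrinks, so tiny
boxes oscillate. Normalization plus decay converges across box scales, and
a zero gradient (pure IoU loss on disjoint boxes) leaves the box exactly in
place — which is the point of the comparison: the Wasserstein-based loss
attains positive IoU from a disjoint start; pure IoU loss never moves.

## RDFBlock

Training forward: y = ReLU(BN(W_std ∗ x + Σᵢ W_dil,i ∗ᵣᵢ x)) — one batch
norm *after* the branch sum. This placement is what makes fusion a pure
weight identity: a k×k kernel at dilation rate d equals a dense
R×R kernel (R = k + (k−1)(d−1)) with the taps spread at stride d and zeros
between; center-embedding that into the K×K field (requires odd sizes and
R ≤ K) preserves the convolution at matching padding; summing with W_std
gives W_deploy with *bit-level* equality of the pre-BN response up to float
rounding. Branch convolutions carry no bias (BN absorbs shifts), stride is
fixed at 1.

Equivalence claims are stated for BN in running-statistics mode on both
paths: in batch-statistics mode the two paths see the same statistics too,
but training-time BN is not part of the deployment contract. The fusion
test sweeps 20 random configurations (K ∈ {5,7}, 1–3 branches, channels
∈ {4,8}, groups ∈ {1, channels}) × 5 inputs and bounds the relative
deviation by 1e-5; measured deviations are ~1e-15.

Default branch set K = 7 with branches (k=5, r=1), (k=3, r=2), (k=3, r=3) —
all receptive fields ≤ 7, mixing a dense mid-size view with two sparse
wide views. The block is exposed standalone (plus an optional residual
wrapper when channel counts match) rather than woven into any particular
backbone topology.

## DPDown

Pipeline: AvgPool(k=2, s=1) → channel split → [Conv3×3 s=2 p=1 |
MaxPool3×3 s=2 p=1 → Conv1×1] → concat. The leading average pool is a local
smoothing that shrinks each spatial dimension by one; the stride-2
padding-1 stages then map even H×W exactly to H/2×W/2. Each branch emits
out_channels/2 so concatenation restores the contract. Odd spatial inputs
are rejected rather than floored — this keeps the halving contract exactly
testable. No normalization or activation lives inside the block; callers
wrap it.

## Evaluation metrics

Greedy protocol: detections sorted by descending confidence (stable sort:
confidence ties keep input order); each matches the highest-IoU unconsumed
ground truth of the same class and image, counting TP iff IoU ≥ threshold;
IoU ties go to the earlier ground truth in list order. AP integrates the
monotone (right-to-left maximum) envelope of the P-R staircase with
all-point interpolation — the convention of modern detection toolkits; mAP
averages AP over classes that have at least one ground truth; classes
without ground truth are excluded rather than defaulted. mAP@0.5:0.95
averages over IoU thresholds 0.50, 0.55, …, 0.95. P and R are additionally
reported at an explicit confidence floor, since a "precision" without an
operating point is ambiguous.

## Synthetic scenes

The generator emulates the statistics that make pest detection hard:
value-noise (multi-octave smooth noise) backgrounds with a vegetation-like
base tone and pixel grain, controlled by `clutter_level`; per-class shape
families (ellipse, rectangle, triangle, diamond, cross) and base colors with
per-instance jitter; object sizes drawn from `object_scale_range` (default
0.1–0.4 of the image side — small-to-medium targets on a 64-px canvas);
1–3 objects per scene; and class frequencies proportional to
`per_class_counts`, by default a Zipf profile count ∝ (i+1)^−1.5, giving
the long-tail shape. Every label is the tight bounding box of the rendered
object mask, so label fidelity is exact by construction; determinism is
byte-level given (config, seed).

What it does **not** emulate: photographic texture, intra-class
morphological variation (larval vs. adult stages), occlusion by foliage,
lighting changes, camouflage. Tests passing on these scenes therefore
validate the *mechanisms* (losses, blocks, metrics, training plumbing), not
field performance on real imagery.

Augmentation: brightness, contrast, saturation, Gaussian blur, and unsharp
masking (the "detail enhancement" operator) are photometric and leave labels
untouched; rotation is restricted to 90° multiples (positive = clockwise;
a 90° turn maps (cx, cy, w, h) → (1−cy, cx, h, w)) so axis-aligned boxes
transform exactly — arbitrary angles would make box geometry lossy and are
excluded. Rebalancing lifts each class below a configured instance floor by
cycling the six operators over images containing that class, recording the
provenance of every synthetic copy in the manifest; a class with no
instances at all cannot be rebalanced and is reported.

The 70:20:10 split uses largest-remainder apportionment computed in exact
rational arithmetic (float quotas can corrupt remainder ties); remainder
ties go to the earlier split. 25158 images split as 17611 / 5031 / 2516.

## Toy detector

stem Conv3×3 → RDFBlock → DPDown → RDFBlock → DPDown → 1×1 head, grid
stride 4. Anchor-free: each ground truth claims the cell containing its
center (first-come on collisions); each cell predicts an objectness logit,
per-class logits, and (dx, dy, log w, log h) — sigmoid center offset within
the cell, exponential sizes, so decoded w, h > 0 always and
encode → decode is the identity to 1e-6.

Loss = BCE(objectness, all cells) + BCE(classes, positive cells) +
WWIoU(decoded boxes, positive cells), weights 1/1/2, WWIoU with c = 0.2 in
normalized units. Positives are ~1 % of cells, so the objectness term uses
a positive-class weight of 64 (≈ the cells-per-object ratio); without it
the objectness head barely moves from its low-prior initialization (bias
−4) in a short run. Box gradients are the exact forward-mode loss gradients
chained analytically through the decode map; everything else is
hand-written backprop through the NumPy layers.

Training: SGD with momentum 0.937 and learning rate 0.01 (standard YOLO-style
settings), batch size 8, deterministic given the seed. The toy
configuration uses K = 5 with branches (3,1), (3,2) and stem width 8 — a
deliberate desk-scale choice so that the full 200-image, 20-epoch smoke run
(including per-run dataset generation and evaluation) completes in about a
minute on one CPU; the library default K = 7 / three branches remains
available through `ToyDetectorConfig`. The network runs in float32 — the
NumPy layers are memory-bandwidth-bound, and single precision roughly
halves step time; fusion equivalence still holds to well below the 1e-4
mAP tolerance asserted after training.

Inference: confidence = objectness × best class score, per-class greedy NMS
at IoU 0.5, default confidence floor 0.25 for detection output and 0.1 for
validation mAP during training (a lower floor lets the P-R sweep see more
of the curve).

Typical desk-scale outcome (200 scenes, 5 classes, 20 epochs, one CPU):
validation mAP@0.5 rises from 0.0 (untrained, low-prior head) to ≈ 0.4–0.5,
and fusing both RDF blocks changes validation mAP by 0.0 — exactly the
reparameterization contract. Epoch-mean loss decreases sharply over the
first epochs; individual epochs can tick up by a few percent under plain
SGD, as usual.

## Known limitations

- The toy detector is single-scale and anchor-free with one positive cell
  per object; it is an exercise harness for the components, not a
  production detector. Two objects whose centers share a grid cell collide
  (first one wins).
- `wasserstein2_squared` accepts only diagonal covariances (the box model);
  full-covariance Gaussians and rotated boxes are out of scope.
- Rotation augmentation is exact only for 90° multiples, by design.
- The NumPy conv core targets desk-scale problems; it is bandwidth-bound
  and makes no attempt at large-scale performance.
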