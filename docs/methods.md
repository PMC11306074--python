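# Methods

`kiwidet` implements a lightweight four-class detector for kiwifruit-flower
pollination stages (Female, Bud, Male, Success) built from a nano-scale
single-stage anchor detector plus two architectural additions: a
frequency-domain feature-fusion block (FDFF) and bi-level routing attention
embedded in CSP containers (C3BiF). This note records the model, the
parameter-accounting convention, the training recipe, what the synthetic
data generator does and does not emulate, and the numerical choices.

## Base detector

The backbone/neck/head follow the YOLOv5n v6.0 graph: a CBS stem (6x6/2),
four downsampling CBS stages with C3 blocks (depth multiples rounded as
`max(round(n * 0.33), 1)`), SPPF, an FPN+PAN neck, and three anchor heads at
strides 8/16/32 predicting `3 * (n_classes + 5)` channels. Channel widths are
`make_divisible(c * 0.25, 8)`: 16/32/64/128/256. Convolutions inside CBS are
bias-free and followed by batch norm and SiLU. Anchor priors are the
standard small/medium/large pixel priors ((10,13),(16,30),(33,23) at stride
8, and so on); priors are fixed pixel sizes, independent of the training
resolution.

## Parameter accounting

All headline totals use the *deploy* convention: batch-norm parameters fold
into the preceding convolution (weights + one bias per output channel),
which is how model summaries are printed by the ecosystem's validation
tools. Under this convention the baseline audits to exactly 1,764,577
parameters with four classes; the raw trainable count (batch-norm affine
terms included) is 4,752 higher. Layer-norms and stand-alone batch-norms in
the custom blocks do not fold and are counted as-is. `audit_params` reports
both numbers; counts depend only on tensor shapes, never on seeds.

## FDFF

The block runs, shape-preserving, at one backbone position (default:
inserted directly after the P3 downsampling conv, where C = 64):

1. unnormalised 2-D DFT per (batch, channel) slice (`X_F`, complex,
   same extents; the transform is lossless and satisfies Parseval);
2. real part only by default (the amplitude-bearing component; imaginary
   and stacked real+imaginary modes are selectable);
3. 3x3 / stride-1 max-filter in the frequency domain with -inf border
   padding, so border outputs are true neighbourhood maxima and the extents
   are preserved — required because the next step is an elementwise product;
4. multiplicative fusion `X_MS = X_M * X_S` with the spatial input;
5. concat `[X_MS, X_S]` (2C channels) and a separable fusion conv:
   1x1 expand to `h = 2C - 2` (bias-free), 3x3 depthwise (bias-free),
   1x1 project to C (bias) + batch norm, SiLU between stages;
6. a CBAM-style spatial gate (channelwise max/mean -> 7x7 conv, bias-free,
   BN(1), sigmoid) multiplied into the fused map.

Design notes. The DFT uses the plain sum form (no normaliser) and no
centring shift; the max-filter is layout-insensitive so the spectrum is
consumed with DC at the origin. The expansion width `2C - 2` (126 at C=64)
is the one free bookkeeping choice; it is calibrated so that the default
block at C = 64 costs exactly 25,618 parameters, the published insertion
delta at P3. Only the P3 placement is calibrated: the published totals for
the other placements are mutually inconsistent with any single
quadratic-in-C block cost, so placements P1/P2/P4/P5 are functional but
their totals are not anchored to printed values. A replace-the-layer mode
is not shipped: the published numbers only reconcile with insertion.

## Bi-level routing attention and C3BiF

Tokens are the spatial positions of a head feature map. The map is split
into an S x S grid of square regions (adaptive default: the largest S <= 8
dividing both extents while keeping >= 4 tokens per region). Region
descriptors are mean-pooled Q and K; the affinity matrix `A = Q_r K_r^T` is
sparsified row-wise to the top-k regions (default k = 4, clamped to S^2;
ties break toward the lower region id for determinism). Fine multi-head
attention (heads: largest divisor of d that is <= 8) gathers keys/values
only from the routed regions; at k = S^2 the result is numerically
identical to dense global attention.

The BiFormer block is

    x = x + DWConv3x3(x)            # convolutional position encoding
    x = x + proj(BRA(LN(x)) + DWConv5x5(V))   # local-context enhancement
    x = x + MLP(LN(x))              # expansion ratio 4, SiLU

and costs exactly `12 d^2 + 49 d` trainable parameters (qkv `3d^2+3d`,
projection `d^2+d`, MLP `8d^2+5d`, two layer-norms `4d`, positional
depthwise `10d`, local-context depthwise `26d`). C3BiF reuses the C3
container (two parallel 1x1 reductions, concat, 1x1 expansion) with the
bottleneck stack replaced by one BiFormer block at the hidden width c2/2;
substituting it for head C3 positions keeps every shape contract and
changes the deploy total by block(d) - bottleneck(d): +3,552 at d = 32 and
+11,200 at d = 64, additive across positions. Routing is parameter-free
(mean pooling), which is what keeps the budget at 12d^2 + 49d.

## Loss and training

The objective is the standard composite of the detector lineage: CIoU box
loss on positive anchor cells, BCE objectness over all cells (positives
targeted with the detached CIoU, level balance 4.0/1.0/0.4), and per-class
BCE on positives; term gains 0.05/1.0/0.5, scaled by batch size. Ground
truth is assigned to any anchor with shape ratio `max(wh/a, a/wh) < 4` in
the centre cell plus the two nearest neighbour cells.

Optimisation is SGD (momentum 0.937, nesterov, weight decay 5e-4 on weight
matrices only), lr0 = 0.01 with one warmup epoch and cosine decay to
0.1 * lr0, batch 16. An exponential moving average of the weights
(decay 0.995 with a 100-step ramp) is what gets validated and returned.
Because desk-scale runs are short, the batch-norm running statistics lag
the weights badly; before every validation the statistics are recomputed
exactly over a few training batches ("precise BN": cumulative averages
over 4 batches per epoch, 8 at the end).

Mosaic and mixup run online (per epoch, dataset size unchanged): mosaic
with probability 0.3 (stitching around a random centre on a double canvas,
per-image scale 1.2-2.0 so the final 2x reduction roughly preserves object
scale, minimum surviving box side 2 px), mixup with probability 0.1 and
Beta(8, 8) weights.

Desk-scale problem sizes: the published recipe (300 epochs, 640 px, GPU) is
replaced by the package's own CPU recipe — 200 synthetic scenes (180/20
split), 30 epochs, batch 16, training resolution 128 px, single-threaded
numpy. Every random draw is seeded; two runs with the same seed produce
bitwise-identical loss histories.

## Synthetic scenes

The generator emulates bottom-up orchard photographs at 640x640: a mottled
green background with darker leaf ellipses, 10 objects per scene by default
(diameters 9-20% of the canvas, crowded placements with a bounded overlap
budget), class ratio 3:3:2:2 (Female:Bud:Male:Success) and three
illumination regimes (gain 0.55/1.0/1.45) cycled across a dataset. Class
identity is carried by contour cues, mirroring how the stages are told
apart in the field: Bud — near-circular filled disc; Female — lobed petal
rosette with bright radial stigma spokes; Male — rosette with a dark anther
ring and no stigma (an area cue, chosen over a dot pattern so it survives
downsampling); Success — shed petals around a darker young-fruit ellipse.
Boxes are the tight bounding boxes of the rendered masks.

What it does *not* emulate: photo-realistic texture, camera noise, bokeh,
perspective, true occlusion by foliage, or the intra-class variability of
real flowers. A detector score on these scenes therefore demonstrates that
the assembled architecture trains, localises and classifies end-to-end —
it says nothing quantitative about orchard imagery, and the published
orchard-dataset accuracies are not reproducible here (the dataset is not
deposited).

## Evaluation

Matching is greedy in descending confidence with a one-to-one constraint
per class at IoU >= 0.5. AP integrates the monotone (cumulative-maximum)
precision envelope over all operating points of the confidence sweep
(continuous AP, not 11-point); classes without ground truth are excluded
from the unweighted mAP mean. mAP@0.5:0.95 averages over IoU thresholds
0.50 to 0.95 in steps of 0.05. Because a single printed recall/F1 must
correspond to one operating point, the report emits the max-F1 point of the
confidence sweep and labels it as such. 0/0 ratios are defined as 0 and
logged; zero-area boxes have IoU 0 by convention.

## Numerical choices

float32 throughout the network; batch-norm statistics accumulate in
float64. Batch-norm eps 1e-3, momentum 0.03; layer-norm eps 1e-5. Max-pool
padding uses -1e30 (an effective -inf that cannot produce NaNs in untouched
borders). Softmax subtracts the row maximum; BCE uses the
`max(z,0) - z t + log1p(exp(-|z|))` form. Routing top-k uses stable argsort
(low region id wins ties). The gradient of `Re(DFT2(.))` is `Re(DFT2(.))`
itself (the cosine kernel is symmetric), and likewise for the imaginary
part. NMS is greedy per class at IoU 0.45 with confidence floor 0.25 for
deployment and 0.001 for validation sweeps.

## Known limitations

- Real-data performance is out of reach by construction (no deposited
  dataset); all learnability statements are about the synthetic task.
- The desk recipe's absolute mAP depends on the training resolution and
  the 30-epoch budget; the learning curves are still rising at epoch 30.
- Published totals for FDFF placements other than P3 cannot all be matched
  by one block-cost model; the audit matches the baseline, the P3 variant,
  the C3BiF subsets and the full model exactly.
- Grad-CAM uses total objectness evidence as the score, which highlights
  everything the detector considers object-like rather than a single class.
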