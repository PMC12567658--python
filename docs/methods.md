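# Methods

## What the package computes

`lmtb` assembles nano-scale one-stage detector graphs in two flavours — the
unmodified YOLO11-family baseline (C3k2 CSP stages, SPPF, C2PSA attention,
PAFPN neck, three decoupled DFL heads) and the lightweight YOLO-LMTB rework
(MERCA backbone stages, DHTST attention stage, P2-injected BiFPN neck) —
and audits them: exact trainable-parameter counts and FLOPs at a stated
input size. Around the graphs it provides detection metrics (P, R, mAP), a
synthetic tea-scene generator, and a trainability smoke harness. All
numerics run on the package's own reverse-mode autograd over numpy arrays;
every backward pass is tested against central finite differences on float64
inputs.

## Baseline reconstruction

The baseline follows the publicly documented nano layout (width multiplier
0.25, depth 0.5, max width 256): stem convs to 32 channels, four CSP stages
(64/128/128/256 channels, the deeper two using C3k sub-blocks), SPPF with a
5×5 max-pool cascade, one C2PSA block (two heads, attention ratio 0.5), the
PAFPN top-down/bottom-up neck, and decoupled heads with 16-bin
distribution-focal box regression over a single "tea bud" class. Bottleneck
expansion inside the plain C3k2 stages is 0.5; inside C3k sub-blocks the
3×3 pairs run at full width. Convolutions carry batch norm (affine, eps
1e-3) and SiLU unless stated otherwise. With one class this reconstruction
counts 2,590,019 trainable parameters; the fixed DFL projection is not
trainable and is excluded.

## The three replacement blocks

**MERCA.** Branch count N = 4 with pooled sizes g_k = 3k (3, 6, 9, 12):
adaptive average pooling to g_k×g_k, a 1×1 reduction to c₂/N channels, and
a grouped 3×3 conv. Each branch passes the edge refiner
`ER(X) = X + Conv(X − P_avg(X))` and is resized back to H×W by bilinear
interpolation (half-pixel centres, no corner alignment); concatenated with
a 1×1 local branch (total width 2·c₂) and fused by a 1×1 aggregation conv.
Choices at points the published description leaves open:

- *Grouped-conv groups = 16.* The group count is unstated; 16 was fixed by
  calibrating the block's parameter budget against the published ablation
  deltas (see "Width calibration" below).
- *Edge conv: depthwise 3×3, bias, linear.* A linear enhancement conv makes
  the refiner exactly the identity on constants and keeps the residual
  arithmetic exact; an activation after the conv would break both.
- *P_avg divides by the real-pixel count at borders,* so the low-pass is
  exactly mean-preserving and constant inputs give a zero high-frequency
  residual everywhere, not just in the interior.
- *Small inputs:* g_k is clamped to min(H, W). Branches whose clamped sizes
  coincide are retained, since dropping them would change the concatenation
  width the aggregation conv is built for. Below 12×12 the pyramid
  degenerates gracefully toward repeated global pooling.
- *Placement:* MERCA replaces the CSP stages in the backbone only; the
  neck-side and everywhere variants exist as explicit ablation builds.

**DHTST.** One block at the end of the backbone (256 channels), C2-style:
1×1 conv, 1:1 channel split; the auxiliary half passes a dynamic tanh
(per-channel α, β, γ; α initialised to 0.5, β to 1, γ to 0) and
token-statistics attention over the H·W spatial tokens; it rejoins its own
branch residually and is concatenated with the main half; a second dynamic
tanh and a two-conv FFN (hidden width = C) close the block residually.
The attention follows the token-statistics design: per head (h = 4), tokens
are linearly projected, weights Π are the softmax over tokens of
τ-scaled squared norms (τ learnable per head, initialised to 1), the
Π-weighted second moment per coordinate gives a variance estimate, and
tokens are rescaled by its inverse square root with an ε = 1e-6 floor,
gated by a learnable per-channel vector (initialised to 1), re-weighted by
Π and merged by a final linear layer. Dropout is 0 at inference. Cost is
linear in token count; Σ_n Π = 1 per head by construction, and the
operator is token-permutation equivariant (no positional term).

**BiFPN neck.** Levels P2–P5 (stride 4–32, backbone widths 64/128/128/256)
are compressed to a common 64-channel width by 1×1 convs. Top-down: P5 is
upsampled (nearest ×2) into the P4 node (2-input fusion, then a three-conv
enhancement stack); the result is upsampled into the P3 node, which also
receives P2 downsampled by a stride-2 3×3 conv (3-input fusion). Bottom-up:
stride-2 3×3 convs propagate P3′→P4′→P5′ (P4 node takes 3 inputs —
compressed P4, its top-down map, and the downsampled P3′; P5 node takes 2).
Fusion is fast normalized fusion with relu-clamped learnable scalars and
ε = 1e-4. One bidirectional sweep; no P6/P7; three heads unchanged.
Node-conv lightweighting (see calibration): the P3 node conv is grouped
(g = 2), the middle conv of the P4 enhancement stack and the P5 node conv
are depthwise-separable, all remaining convs are full 3×3 at width 64.

## Width calibration

The published YOLO-LMTB description fixes the architecture topology but not
every width (MERCA group count, DHTST FFN hidden width, the exact form of
the BiFPN node convs). These were chosen once so that the assembled
variants reproduce the published parameter/FLOP budget and its ablation
deltas, and are exposed as configuration for anyone who wants to move them:

| variant            | parameters | published |
|--------------------|-----------:|----------:|
| baseline           |  2,590,019 | 2.58 M    |
| + MERCA (backbone) |  2,538,035 | 2.53 M    |
| + DHTST            |  2,572,743 | 2.56 M    |
| + BiFPN            |  1,917,421 | 1.92 M    |
| full lightweight   |  1,848,161 | 1.85 M    |

FLOPs at 640×640 (2×MAC): baseline 6.31 G, lightweight 6.24 G. The audit
counts multiply–accumulates of convolution and linear layers only (each MAC
as two FLOPs), treats normalisation as fused, and ignores elementwise,
pooling and attention-matrix work — the reporting convention of the
lightweight-detector literature. Parameter counts are exact integers and
input-independent; FLOPs are measured by running a counted forward pass at
the stated size.

## Synthetic scenes

The generator emulates the study regime for field imagery of young tea
shoots — the features that matter to the architecture — rather than
photorealism:

- *Scale spread* (default 5): the ratio of the largest to smallest target's
  long side, anchoring ~3–5 mm bud tips against ~2 cm leaves; the two
  extremes are always realised so the configured spread is present in every
  scene. Smallest long side defaults to 12 px at 640 px frames.
- *Density and occlusion* (default 0.5): targets are drawn into a few
  Gaussian clusters; overlapping draws occlude earlier targets.
- *Low contrast* (default 22 lightness units on the 0–255 scale):
  bud colour is the background green shifted slightly lighter/yellower.
- *Illumination*: a random linear lighting ramp (default ±12.5%).
- Background is multi-octave value noise in a foliage-green band.

Annotations are tight boxes around each rendered ellipse in normalised
`cls cx cy w h` (YOLO TXT) form. Everything is a pure function of the seed.
Mosaic augmentation (2×2 collage around a random centre, labels translated,
clipped per quadrant, sub-2-px slivers dropped) and the seed-deterministic
7:2:1 split round out the data pipeline. Split counts use floor for the
train and validation partitions with the remainder to test, which
reproduces 3062 → 2143/613/306.

What passing tests on these scenes do **not** show: real-bud texture,
leaf-vein edges, specular highlights from the waxy cuticle, camera blur, or
any accuracy claim on field data. The generator's role is to exercise
shapes, label plumbing and gradients under the right scale/occlusion/
contrast statistics.

## Trainability smoke

Production training configuration (300 epochs, batch 32, SGD lr 0.01,
momentum 0.973, weight decay 1e-5, 640 px, mosaic) is recorded in
`lmtb.train.REFERENCE_TRAIN_CONFIG` but out of scope. The smoke harness instead
optimises a simplified dense loss — stable BCE pushing every cell's class
logit toward a centre-occupancy map, plus an MSE pull of the softmaxed DFL
bins toward the two-hot encoding of true box distances at positive cells —
with Adam (lr 2e-3), one scene per step. The shipped check runs 8 synthetic
scenes at 320×320 for 200 steps (about 3 minutes on one CPU core): the loss
must at least halve and every parameter tensor must receive finite,
non-zero gradients. This validates differentiability and optimisation
plumbing, not detection quality.

## Numerical choices and degenerate inputs

- Autograd accumulates with `+=`, so shared sub-expressions (residuals, CSP
  splits) are exact; softmax subtracts a detached max for stability.
- Convolution is computed as kernel-position-shifted grouped matmuls; its
  adjoint scatters through the same strided views (bit-reproducible, no
  atomics). Max-pool routes gradients to the argmax (first index on ties).
- Bilinear resizing uses half-pixel source centres and clamped borders;
  adaptive pooling uses floor/ceil window edges, tiling the input exactly.
- Metrics: greedy confidence-descending one-to-one matching (the community
  mAP convention, not Hungarian); AP uses the all-points interpolated
  envelope by default with a 101-point option; 0/0 is defined as 0; a class
  with detections but no ground truth scores AP 0.
- Degenerate inputs raise (`ValueError`) rather than silently adapting:
  channel/group mismatches, empty token axes, fewer than two fusion inputs,
  fewer than four mosaic tiles, ratios not summing to 1. Scene packing
  retries placement 60 times before raising a diagnostic.

## Known limitations

- The baseline is a reconstruction from the public nano layout; its count
  (2.59 M at one class) sits one rounding step above the commonly printed
  2.58 M, and per-stage deltas against any third-party implementation can
  be inspected via `lmtb build`/`lmtb audit` breakdowns.
- No checkpoint import, no export formats, no real-dataset accuracy claims;
  serialized model size is representation-dependent and not reported.
- The numpy backend targets correctness and desk-scale experiments, not
  GPU-scale training throughput.
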