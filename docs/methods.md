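# Methods

## The model

The package implements a dual-branch guided feature interaction network for
binary 2-D segmentation. Both branches are U-shaped encoder-decoders over
`num_stages` resolution levels (default 4, channel widths
`[32, 64, 128, 256]`, bottleneck 512), joined by two guidance mechanisms:

* **Encoding guidance.** At each stage *s* the auxiliary encoder's output is
  adapted by a 1×1 convolution and added elementwise to the main encoder's
  stage-*s* output, before both branches down-sample by 2×2 max pooling. The
  addition operator was chosen over concatenation because it preserves
  channel widths, letting the ablation flags compose without reshaping the
  rest of the graph.
* **Decoding guidance.** The auxiliary decoder is run to full resolution
  first; its output feature map is average-pooled by factors 2⁰, 2¹ and 2²
  and fused into the three shallowest main-decoder levels (1×1-adapted
  elementwise sum by default; a concat+1×1 variant is selectable with
  `fusion_mode`). The three factors are read as three *downsampling levels*
  starting at the identity scale; this is the only reading under which all
  fusion shapes are consistent.

The blocks:

* **ECRB** (main encoder stage): 1×1 conv → 3×3 dilated conv → 3×3 conv,
  each followed by batch normalization and ReLU. Dilation defaults to 2, the
  smallest rate that enlarges the receptive field without extra parameters.
* **AGFRB** (auxiliary encoder stage): three aligned paths — 3×3/stride-1
  max-pool saliency followed by a 1×1 conv; a 1×1 conv → 3×3 depthwise conv
  → ECA gate; and an identity path (1×1-projected only on a channel
  mismatch) — summed elementwise and refined by a 3×3 conv. Stride-1
  same-padded pooling is forced by the requirement that the three summands
  share spatial extent.
* **ECA**: global average pool → odd-length 1-D conv across the channel
  descriptor → sigmoid → per-channel multiply. The kernel extent adapts to
  the width as the nearest odd integer to `log2(C)/γ + b/γ` (γ=2, b=1,
  ties resolved downward; a fixed extent is configurable).
* **LRM** (bottleneck reinforcement): L cascaded layers (default 2), each
  computing `DW_k(x) + PW(x) + x` with a k×k depthwise and a 1×1 pointwise
  convolution (k default 3). These branch convolutions are deliberately
  bare — bias, no normalization, no activation — so the residual identity is
  exact: with zero weights each layer is the identity map, and the module
  never disturbs a converged bottleneck representation.

Everything else follows U-Net convention: double 3×3 conv+BN+ReLU stages in
the plain variants, bilinear 2× upsampling + 1×1 conv in the decoders
(2×2 transposed convolution selectable), skip connections by channel
concatenation, and a 1×1 conv + sigmoid head. Convolutions that feed a batch
norm carry no bias (the shift would be cancelled by normalization and its
gradient would be identically zero). Weights are Kaiming-uniform (fan-in,
ReLU gain) from a generator seeded per model build, so construction is
bit-reproducible.

Ablation flags (`use_ecrb`, `use_agfrb`, `use_dgfi`, `use_lrm`) span the
ladder: baseline U-Net → +ECRB → +AGFRB (swapped into the single-branch
encoder when no auxiliary branch exists) → +dual-branch interaction → full
model. Only the main head is supervised; the auxiliary branch receives its
learning signal through the guidance connections.

## Numerical engine

No autodiff framework is part of the runtime stack, so the package carries a
small reverse-mode engine on numpy (`dgfinet.autodiff`). All convolutions
are stride-1 with "same" zero padding (downsampling is pooling), which makes
every input-gradient itself a same-padded convolution with the flipped
kernel — backward is as cheap as forward, with no scatter-add. Forward
convolutions use `as_strided` patch views plus one batched matmul; grouped
and depthwise variants share the same path. Batch normalization uses biased
batch variance for normalization, unbiased updates for the running
statistics (momentum 0.1, eps 1e-5). Training runs in float32; the public
loss/metric functions compute in float64. Head logits are clamped to ±15
before the sigmoid so that predicted probabilities remain strictly inside
(0, 1) even in float32 (an unclamped float32 sigmoid rounds to exactly 0 or
1 beyond |z| ≈ 17, which kills the Dice gradient for those pixels). Every structured primitive is
checked against nested-loop oracles and central finite differences in the
test suite.

## Objectives and metrics

The training objective is the soft Dice loss with squared-sum denominator,
summed over the whole batch,

    L = 1 − (2·Σ y·p + ε) / (Σ y² + Σ p² + ε),

with ε = 1e-6 so an all-empty batch yields loss 0 (the bare formula is
0/0 there). The alternative family: mean binary cross-entropy (probabilities
clamped at 1e-7), soft IoU, Tversky (defaults α=0.7, β=0.3, the standard
false-negative-weighted setting), and a Hausdorff surrogate — squared error
weighted by the summed squared boundary distance transforms of the mask and
the thresholded prediction, with the distance maps held constant for
differentiation (a true Hausdorff distance has no useful gradient).
Tversky at α=β=0.5 coincides with the Dice loss on *binary* predictions
(where Σp² = Σp); for soft predictions the two denominators differ, which is
why the identity tests binarize first.

Evaluation binarizes at 0.5 with a ≥ tie rule (the natural threshold for a
sigmoid head) and counts TP/FP/FN/TN exactly:
Dice = 2TP/(2TP+FN+FP), Jaccard = TP/(TP+FN+FP), and the Matthews
correlation coefficient with integer-arithmetic radicand to avoid overflow.
Degenerate conventions: Dice/Jaccard are 1 when TP=FP=FN=0, Mcc is 0 when a
marginal vanishes. Both per-image-mean and globally-pooled aggregation are
implemented; per-image mean is the default reporting mode.

## Training protocol

Adam (betas 0.9/0.999, eps 1e-8, no weight decay), learning rate 1e-3,
batch size 16, 200 epochs, inputs at 256×256 — the reference regime, all
fields of `TrainConfig`. No learning-rate schedule and no augmentation are
applied. Shuffling is seeded per run; with seeded weight init and
single-threaded execution the whole loop is deterministic. The best
checkpoint is selected by validation Dice (the protocol itself names no
selection rule). Optional `max_steps` and `early_stop_train_dice` bound a
run; an in-loop NaN aborts with the offending epoch/step.

CPU-scale experiments in the tests and the acceptance script use widths
`[8, 16, 32, 64]` with bottleneck 128 on 64×64 phantoms (batch 8), the
problem size at which the full variant memorizes 16 phantoms to train Dice
≥ 0.95 within a few hundred optimizer steps.

## Synthetic phantoms

The generator emulates the qualitative axes of 2-D brain-tumor slice data:
an elliptical "brain" support (jittered center/axes) with a smooth radial
gradient plus low-frequency texture on a dark field; one to three elliptical
lesions placed wholly inside the support with random size, orientation and
polarity (bright with probability 0.7); lesion intensity blended toward a
near-white/near-black target so the gap scales linearly with `contrast` and
never saturates; Gaussian blur of the lesion indicator (`boundary_blur_sigma`,
default 1.5 px) applied to the image only — masks keep the crisp pre-blur
support, reproducing the ambiguous-boundary regime; additive Gaussian pixel
noise (default σ=0.03). Dataset generation jitters radius (×0.7–1.3),
contrast (×0.8–1.2) and blur (×0.5–1.5) per sample and assigns splits by
largest-remainder rounding of the requested fractions.

What the phantoms do *not* model: MRI bias fields, multi-sequence contrast,
anatomy beyond a single ellipse, 3-D structure, or inter-patient intensity
statistics (the source datasets are not characterized, so the phantom
parameters are calibration-free stand-ins). Passing tests therefore
demonstrate the correctness and trainability of the implementation, not
clinical-grade segmentation accuracy.

## Complexity accounting

`count_parameters` sums the named registry exactly;
`count_mult_adds` counts multiply-accumulates of every convolution
(2-D, 1-D and transposed) analytically during a batch-1 forward pass —
normalization, pooling and activations are excluded, per the usual
convention. At the default widths the full model has 15.3 M parameters and
25.6 G mult-adds at 256×256; the dual branch roughly doubles the cost of
the baseline (7.2 M / 12.0 G). The published network of this design reports
6.81 M parameters, implying narrower stage widths than the defaults here;
since the exact widths are not documented anywhere, the counts are exposed
as a reporting feature rather than asserted against any external total.

## Known limitations

* Single-class sigmoid head only; no 3-D or multi-modal inputs.
* The ECA gate makes the network only approximately translation-equivariant
  (its channel descriptor is a global statistic); the equivariance test
  allows a 5% pixel budget for this plus border effects.
* CPU throughput limits realistic training to small widths and image sizes;
  the defaults build and run but are not trained in the test suite.
* The Hausdorff surrogate treats its distance maps as constants between
  steps, the established trainable proxy but not a true Hausdorff distance,
  and no Hausdorff *metric* is provided.
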