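# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, what the synthetic data does and does not
emulate, and the numerical conventions the package commits to.

## Selective state-space core

The scan implements the recurrence

    h_t = Ābar_t ⊙ h_{t−1} + Δ_t B_t u_t,   y_t = C_t · h_t + D ⊙ u_t

with the Euler-simplified zero-order-hold discretisation
`Ābar = exp(Δ·A)`, `B̄ = Δ·B`. The transition matrix is parameterised as
negative reals, `A = −exp(A_log)`, with the S4D-real initialisation
`A_log = log(1..N)` per channel, so the dynamics decay and the hidden
state obeys a geometric-series bound. Δ is made positive by a softplus
applied to a low-rank projection of the token stream; the projection bias
is initialised so that softplus(bias) is log-uniform in [dt_min, dt_max]
= [0.001, 0.1]. Defaults: state dimension N = 16, inner expansion 2,
depthwise causal convolution of width 3, Δ-projection rank
max(1, ⌈d/16⌉).

The scan runs as a strictly sequential jitted kernel (the discretised
transition is precomputed vectorised; the recurrence itself is a
left-to-right loop, cost linear in L, with a hand-derived backward pass
verified against central finite differences). A deliberately slow dense
oracle unrolls the recurrence into the full L×L lower-triangular causal
operator and is used only in tests; the two paths agree to < 1e−5 on
random instances up to L = 64. The scan always runs in the input's full
precision.

## PV-Mamba

Eq-level reading implemented: per-spatial-position LayerNorm, four-way
channel split, a Mamba block of width C/4 applied to each group's
raster-scanned token sequence, α-scaled residual per group, concat,
LayerNorm, and a square per-token linear projection C → C. Two points
were open:

- **Weight sharing.** One Mamba block is shared by the four groups (the
  four streams are evaluated as a single batched scan). Sharing makes
  sequential and batched group evaluation exactly equivalent and keeps the
  parameter count near the published budget; a per-group-weights variant
  would quadruple the SSM parameters of every PV block.
- **α.** A learnable scalar per group, initialised to 1.0 — the learnable
  form subsumes a fixed factor.

Scan order is a single row-major raster; no reverse or column scans.

## Attention and edge blocks

- **EMA** follows the grouped cross-spatial design at contract level:
  g = 8 channel groups (g = 4 for the width-halved test model whose
  narrowest stage has 4 channels); directional average pooling along H
  and W, a shared 1×1 mix, sigmoid gates; per-channel group
  normalisation; a 3×3 local path; softmax-pooled descriptors matmul'd
  against the flattened maps in both directions; summed, sigmoided, and
  multiplied into the group map.
- **MCA** global-average-pools each skip stage, concatenates the
  descriptors, mixes locally with a single-channel 1-D convolution
  (kernel 3, padding 1 — unstated upstream, chosen minimal) and produces
  per-stage channel weights through one fully connected map per stage;
  the output keeps a residual floor `t_i + t_i ⊗ Att_i`.
- **MMSA**'s dilated convolution is implemented as a 2-D 7×7 convolution
  with dilation 3 and padding 9 on the 2-channel mean/max map: a literal
  1-D convolution cannot produce an H×W spatial attention map, and
  padding 9 is the unique choice that preserves spatial size.
- **EFE** consumes the stage-2 and stage-6 encoder outputs (after each
  stage's EMA), runs PV-Mamba on each, upsamples the deep branch
  bilinearly (parameter-free), concatenates, refines with two 3×3
  convolutions carrying 16 intermediate channels, a PV-Mamba, and a 1×1
  sigmoid head that emits the single-channel edge prior. The single
  output channel is a design commitment: the prior reads as an edge
  probability map and broadcasts over channels in the fusion product.
- **EFF** injects the prior with a residual floor (`F = f_i + f_i⊗U(f_e)`,
  exactly `f_i` when the prior is zero), then conv 3×3 (channel-
  preserving), PV-Mamba, and a channel gate from a 1-D convolution over
  the pooled descriptor.

## Network assembly

Six encoder stages per the printed dimension table; PV-Mamba in stages
4–6; EMA everywhere; skips for stages 2–6 go EFF → MCA (jointly, S = 5)
→ MMSA (per stage); the processed deepest skip feeds the decoder; the
stage-1 skip is a plain concatenation. The decoder upsamples bilinearly
(×2 + 3×3 conv) and mirrors the deep PV-Mamba placement *by channel
width*: PV acts on the 64-wide bottleneck entry and the 48- and 32-wide
decoder outputs, the same widths at which the encoder carries it. The
alternative (mirroring by stage index) is equally readable from the
architecture description; the width-mirror was chosen because it is
symmetric and lands the parameter count (478,489 = 0.478 M) closest to
the published budget used to validate under-specified internals. The
head is a 1×1 convolution to 1-channel logits; sigmoid + 0.5 thresholding
happens only at inference/metric time.

Ablation toggles (`use_ema`, `use_efe`, `use_eff`, `use_mmsc`) remove the
corresponding modules structurally; `use_eff` without `use_efe` is
rejected since the fusion consumes the extracted prior.

**Complexity accounting.** `count_parameters` enumerates trainable
scalars exactly. `count_flops` reports multiply-accumulates (MACs) from
an instrumented eval-mode forward at batch 1: convolutions contribute
k²·C_in·C_out·H_out·W_out, linear maps d_in·d_out per token, the scan
4·D·N + D per token (state decay, input write, read-out, skip);
parameter-free resampling and elementwise ops are not counted, matching
the dominant profiler convention. The default build measures 0.988 G
MACs at (3, 224, 224).

## Losses and metrics

BCE is evaluated in log-sum-exp form `softplus(z) − y·z`. The training
Dice uses the squared-denominator form with ε = 1e−6 smoothing (no
smoothing term is stated upstream; ε only regularises the empty-empty
case). Evaluation Dice uses the confusion-count form; both are exposed.
The combined loss is the unweighted sum.

Surface metrics: a mask's surface is its foreground pixels with at least
one background 4-neighbour, with out-of-image treated as background (so
a full-frame mask's surface is its border ring); directed Euclidean
nearest-surface distances are pooled over both directions; HD95 is the
95th percentile with linear interpolation between order statistics; ASSD
the pooled mean. Distances are in pixel units — physical voxel spacing
is not propagated through the 224×224 resize. Degenerate conventions:
both masks empty → DSC = IoU = 1 and zero distances; exactly one empty →
DSC = IoU = 0 and distances equal to the image diagonal (a finite
sentinel chosen so means over a case set remain defined).

## Preprocessing

Histogram equalisation maps intensities through the rounded cumulative
histogram (`round(cdf·255)`); a constant image is returned unchanged.
The crop box is the tight bounding rectangle of the patient's
largest-diameter mask (largest bounding-box diagonal) expanded by 5
pixels per side and clipped — the tight-box reading was chosen over a
center-anchored square because the box must fully enclose the lesion.
The same box is applied to every slice of the patient; images are
resized bilinearly to 224×224 and replicated to three channels, masks
nearest-neighbour and re-binarised.

## Synthetic phantoms

Each phantom is a randomly placed, rotated, radially deformed ellipse
(low-order sinusoidal boundary perturbation) whose mask is the pre-blur
binary region. The image adds a small foreground/background intensity
gap (default 35 on the 8-bit scale — low contrast), Gaussian boundary
blur (σ = 2 px — fuzzy margins), a low-frequency bias field (amplitude
10 — coil inhomogeneity), and pixel noise (σ = 8). The foreground
fraction is kept in (0.05, 0.25), the range a cropped prostate occupies
in a 224² frame. These defaults are the package's fixed study
conditions.

What the phantoms do **not** emulate: real anatomical texture,
inter-patient shape statistics, multi-centre scanner variation, slice
correlation within a patient, and ambiguous expert boundaries. A model
passing the phantom learnability check has demonstrated that the
pipeline can fit a coherent low-contrast shape-from-intensity signal —
it says nothing about clinical segmentation accuracy, which requires the
real dataset at full training scale.

The learnability check trains a width-halved model (channels 4–32,
EMA groups 4) on 200 phantoms at 96×96 for 30 epochs — sizes chosen so
the check runs on one CPU in minutes while leaving the architecture
topologically identical to the default.

## Training

AdamW (lr 1e−3, β = (0.9, 0.999), ε = 1e−8, weight decay 1e−2), batch
16, no learning-rate schedule, 5-fold patient-wise cross-validation with
best-model selection by validation DSC. All randomness — weight
initialisation, fold assignment, shuffling, phantom generation — derives
from explicit integer seeds; identical invocations are bit-reproducible.
The batch-norm layers use batch statistics in training and running
averages (momentum 0.1) in eval, so eval-mode forwards are
deterministic.

## The autograd core

The network runs on a package-internal reverse-mode autograd engine over
numpy: a tape of primitives (broadcast arithmetic, matmul, im2col
convolution, depthwise causal convolution, separable bilinear
resampling, reductions, activations, and the selective scan with a
hand-written backward kernel), float32 by default with float64 supported
throughout for verification. Every primitive's gradient is tested
against central finite differences. The engine exists to keep the
package self-contained and fully inspectable; it favours clarity over
peak throughput, with the two genuinely hot paths (the scan recurrence)
jitted via numba.

## Known limitations

- 2-D slices only; no volumetric context.
- CPU-oriented: full-scale (100-epoch, 224²) training is possible but
  slow; the package is intended for method study and desk-scale
  experiments.
- Pixel-unit surface distances (no mm scaling).
- The published FLOP figure for this architecture could not be
  reconciled with its published parameter count under standard MAC
  accounting; the package reports its measured count (see the README's
  reproduction section for how it is computed).
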