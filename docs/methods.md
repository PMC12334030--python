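# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, the numerical conventions, and what the
synthetic-data evidence does and does not show.

## Architecture

The network is a five-stage U-shaped encoder–decoder over rank-5
`(batch, channel, depth, height, width)` volumes.

**Encoder.** Stage 1 is a dense 7³ convolution with stride 2 and padding 3
(`in_channels → 48`): a large-kernel patch embedding that halves every
spatial axis. ("Depthwise" embedding is impossible for a 1-channel input;
a dense convolution is the only reading that type-checks.) Stages 2–5 each
apply a dense 2³ stride-2 convolution that doubles the width
(48 → 96 → 192 → 384 → 768), followed by a run of residual blocks.
Input dims must be divisible by 32 so the ladder bottoms out on an integer
grid. The stage-2 width (96) follows the doubling rule; it is the only
width the reference plan leaves implicit.

**Block.** Pre-norm residual form with layer normalisation taken
channel-wise at every voxel (the channels-last convention of
ConvNeXt-style convolutional blocks):

```
ẑ = z + LKDAttention.gated(LN(z))
z' = ẑ + DWCA(LN(ẑ))
```

The attention *contribution* added to the stream is the gated term
`w₃ ⊗ x` (with `x` the normalised input); the residual lives in the
stream. This is the only arrangement under which zeroing the final
projection and the channel-mixer weights makes the block exactly the
identity — the invariant the test suite asserts at machine precision. The
standalone `LKDAttention.forward` keeps the self-contained contract
`out = w₃ ⊗ x + x`.

**LKD attention.** `project C → C/2` (1×1×1) → depthwise k=5, d=1 →
depthwise k=7, d=3 (cascaded, so the second branch sees the first's
output) → concatenate both branches back to C channels → per-voxel channel
mean and max → dense 2→2 convolution, k=5 → sigmoid, giving spatial gates
w₁, w₂ ∈ (0,1) → branch blend `X₄ = w₁⊗X₁ + w₂⊗X₂` (element-wise sum
of the gated branches, keeping C/2 channels) → squeeze-and-excitation on
X₄ (global average pool, bottleneck C/2 → C/2r → C/2, ReLU then sigmoid,
r = 4 by default) → 1×1×1 projection C/2 → C producing the gate w₃.
Resolved ambiguities, all recorded here as the package's design:

- The gate w₃ has C channels and multiplies the block input (the residual
  `w₃⊗x + x` forces C channels; a C/2-channel gate cannot type-check
  against the residual).
- The statistics-mixing convolution is dense over its 2 channels: a
  depthwise map would prevent the average and max statistics from
  interacting, defeating its purpose.
- SE is the standard spatial-kernel-free block (a "5×5×5 SE" has no
  meaning; the spatial mixing already happened in the cascade).

**DWCA (channel mixer).** Grouped 1×1×1 convolutions with group count C:
expansion to m=4 copies per channel, GELU, compression back — per-channel
scalars only, (3m+1)·C = 13·C parameters. This deliberately removes all
cross-channel weights from the MLP position of the block; cross-channel
mixing happens only in the projections, the concatenation, and SE.

**Decoder.** From the deepest feature, four ×2 upsampling blocks
(trilinear interpolation with half-pixel alignment — the 3-D analogue of
bilinear — then conv 3³ → BatchNorm → ReLU), each followed by fusion with
the same-scale encoder feature: separate 3³ convolutions per path
(conv → GELU → BatchNorm, following the module's stated convention for
every convolution), concatenation to 2C, then a pointwise inverted
bottleneck 2C → 4C → C. A final ×2 upsampling block restores full
resolution and a pointwise head emits class logits. With deep supervision
on, an independent pointwise head per fused scale emits auxiliary logits
at 1/2 … 1/16 resolution.

**Depth schedule and the parameter budget.** The reference width plan
fixes everything except the number of blocks per stage. The reference
parameter budget (48.52 M for the full network with fusion modules) pins
it: with the closed-form count

```
params(depths) = 29 237 237 + Σᵢ depthᵢ·block(Cᵢ) − baseline
block(96) = 35 266,  block(192) = 90 766,
block(384) = 263 974, block(768) = 859 222
```

the shipped default `(2, 4, 6, 23)` gives 48 518 327 = 48.52 M to the
printed precision. The schedule is deep in the 1/32-resolution stage,
where blocks are cheapest per unit compute; any schedule is configurable
via `stage_depths`. The closed form and instantiated-model enumeration are
cross-checked in the tests and the acceptance script.

**Effective receptive field.** For a chain of unit-stride convolutions,
ERF = 1 + Σ(kᵢ−1)·dᵢ. The cascade [(5,1), (7,3)] gives 23 per axis; the
test suite confirms the closed form against a gradient-footprint probe for
every kernel/dilation chain of length ≤ 2 over kernels {1,3,5,7} and
dilations {1,2,3}.

## Objective and metrics

**Loss.** `L = L_dice + L_ce` with P the channel softmax, Z the one-hot
target: mean soft-Dice over classes, `1 − (1/K) Σⱼ 2ΣᵢZᵢⱼPᵢⱼ /
(ΣᵢZᵢⱼ² + ΣᵢPᵢⱼ² + ε)`, ε = 1e−5 (guarding 0/0 for absent classes),
plus mean voxel cross-entropy. This is the standard reading of the
compound objective; the literal printed formula (a single bracket summing
Dice fractions and the CE sum, subtracted from 1) is sign- and
scale-inconsistent and is not implemented.

**Deep supervision.** Auxiliary logits are trilinearly upsampled to full
resolution and scored against the full-resolution ground truth; the n
per-scale losses combine with weights αₖ = 2^(n−k)/(2ⁿ−1) — the unique
halving chain with exact unit sum, computed as rationals. For n = 5:
(16, 8, 4, 2, 1)/31.

**Metrics.** Per-class DSC = 2|z∧p|/(|z|+|p|), returning 1.0 when a class
is absent from both volumes (correctly predicted absence). HD95 extracts
boundary voxels (face-connectivity erosion), computes the two directed
surface-distance sets via an exact Euclidean distance transform honouring
anisotropic spacing, takes each set's 95th percentile
(linear-interpolation definition) and returns the max; undefined (None)
when either mask is empty. Class means exclude background by default, the
multi-organ reporting convention (flag to include it). Both metrics are
verified against brute-force oracles (all-pairs distances; direct counts).

## Synthetic data

`generate_phantom` places K non-overlapping random ellipsoids (rejection
sampling, seeded) on a zero-mean background; organ k gets label k and
intensity Normal(mean_k, σ), background Normal(0, σ). Default means are
evenly spread over [0.5, 1.5] — pairwise distinct and well separated from
background at the default σ = 0.1, so a two-class phantom is separable by
an intensity threshold at ≥ 99 % voxel accuracy (asserted as a
learnability guard).

What the phantom emulates: several compact foreground structures of
distinct intensities, additive noise, per-voxel integer labels, NIfTI I/O
with real voxel spacing. What it does not: organ shape complexity and
contact, intensity overlap between classes, partial-volume effects,
scanner artefacts, anisotropic acquisition. Passing the phantom tests
therefore establishes that the architecture, gradients, objective and
pipeline are correct and trainable — not that the network reaches clinical
accuracy; clinical-scale benchmarking is out of scope for this package.

**Augmentation** follows the stated suite — scaling (0.9–1.1), rotation
(±15° about a random axis pair), brightness, contrast, additive Gaussian
noise, Gaussian blur — with magnitudes and per-transform probabilities
chosen in the style of common 3-D segmentation pipelines (all exposed in
`AugmentConfig`). Spatial transforms resample the image trilinearly and
the labels nearest-neighbour; intensity transforms never touch labels.
Rotation is limited to the stated ±15° range; axis-aligned 90° rotations
are not part of the suite. Foreground-biased cropping (default bias 0.5)
is an addition the training loop needs for stable learning on sparse
foregrounds at small scale, and is documented as such.

## Training

AdamW (decoupled weight decay 0.01), constant learning rate by default
(initial 1e-4, the reference schedule; optional polynomial decay flag —
any decay/warmup beyond the stated initial rate is unspecified upstream,
so constant is the default), batch 2, 96³ patches, 40 000 iterations as
the reference schedule. A single master RNG drives sampling, cropping and
augmentation; its state, the weights, and the optimiser moments go into
the checkpoint, so a resumed run reproduces the uninterrupted loss
trajectory bitwise on the same platform.

**Scaled-down smoke profile.** The trainability check runs a
width-reduced network (stage channels 8…128, one block per stage) for 200
iterations on one seeded 24³ two-class phantom, zero-padded into 32³
patches (24 is not divisible by 32, the encoder's ladder requirement).
200 steps at the reference rate of 1e-4 cannot move AdamW-updated weights
materially (total step magnitude ~ lr·iters ≈ 0.02, the same order as the
initialisation scale), so the profile scales the rate to 3e-3. It reaches
foreground DSC ≥ 0.90 on the phantom; these problem sizes are the
package's chosen smoke scale, not a statement about clinical training.

## Numerical choices

- All computation in float64; weights initialised truncated-normal
  (std 0.02, cut at ±2σ), biases zero, from a per-model seeded generator —
  construction is bit-deterministic given (config, seed).
- The autodiff core records a backward closure only when an input requires
  gradients, so inference is tape-free. Convolution is evaluated as a loop
  over kernel taps (strided slices of the padded input), which keeps
  memory proportional to the activations and makes depthwise kernels
  broadcast multiplies; gradients of every operation are validated against
  central finite differences.
- Trilinear resizing uses half-pixel source alignment and is applied
  separably per axis (exact for linear interpolation under this mapping);
  its adjoint is a bincount-based scatter.
- LayerNorm ε = 1e−6, BatchNorm ε = 1e−5 with momentum 0.1 running stats
  (evaluation mode uses the running estimates).
- Channel-max pooling routes its gradient to the first argmax on ties.
- Sliding-window inference tiles with 50 % overlap and Gaussian importance
  weighting (σ = extent/8), zero-padding inputs smaller than the window
  and cropping the argmax labels back.

## Known limitations

- The tap-loop convolution is CPU-friendly at test scale but far from the
  throughput of a tuned GPU framework; the reference 96³/48.52 M training
  schedule is not practical in this implementation.
- BatchNorm statistics at batch 2 are noisy; the reference design retains
  BatchNorm in the decoder regardless.
- HD95 is None for empty masks rather than substituting a penalty
  distance; downstream averaging skips undefined entries.
- The phantom's limitations (above) bound what the smoke tests establish
  about real data.
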