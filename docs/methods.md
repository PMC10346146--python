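# Methods

## Problem setting

Multi-organ segmentation of 2-D abdominal CT slices: given a 3×H×W image,
predict a label map over eight organ classes (aorta, gallbladder, left and
right kidney, liver, pancreas, spleen, stomach) plus background.
Convolutional encoders model local detail well but mix information over long
spatial ranges only slowly, while organs of interest are small, clustered
patches that may lie far apart — the left and right kidney being the classic
example of two locally indistinguishable structures that only context can
separate. The remote feature exploration (RFE) layer addresses this at the
network bottleneck, where the feature map is small enough that explicit
all-to-quadrant mixing is affordable.

## The RFE layer

Let F be a C×H×W feature map with H, W even (512×14×14 at the bottleneck of
a 224×224 input). F is cut into four spatial quadrants A, B, C, D of size
C×h×w with h = H/2, w = W/2. From each quadrant all single-row strips (1×w)
and single-column strips (h×1) are extracted. With A as the *base* block and
row index k, the base block (row-major) and the k-th row strips of B, C and
D — in that fixed order — are flattened into a vector of length
h·w + 3·w (for 2×2 blocks: 4 + 3·2 = 10, the stacked 5×2 map T1). A fully
connected, bias-free correlation map W ∈ R^{(hw+3s)×(hw)} produces one
transformed block per strip index:

    M(i,j) = Σ_t w(t, i·w+j) · v_t ,

so every output element sees both the whole base block and the remote
strips. One variant exists per row index and per column index (h + w total;
the 2×2 case gives the four variants). The variants are averaged
element-wise, passed through a two-layer MLP, and added residually to the
base block; the four transformed quadrants are placed back in their original
positions, so the layer preserves shape. Spatial weights are shared across
channels (the layer acts purely in the spatial dimensions); each base block
and direction has its own correlation matrix, and each block its own MLP.

Design choices where the construction was genuinely open:

- **Variant aggregation** is an element-wise *mean* rather than a sum, so the
  output magnitude does not grow with block size.
- **MLP**: two affine maps with exact (erf) GELU between them, hidden width
  4× the block element count, biases allowed (the correlation map has none).
- **Initialization**: correlation and MLP weights are drawn from N(0, 0.02²),
  biases zero. With the residual connection the layer starts near the
  identity, which keeps early training stable; a layer with exactly zero
  weights *is* the identity.
- **Generalization beyond 2×2 blocks**: all h row indices and all w column
  indices are used as variants; the four-variant description is the h = w = 2
  special case.
- Odd spatial dimensions are an error, not padded: the encoder guarantees
  even bottleneck sizes for resolutions divisible by 32.
- The number of stacked RFE layers is configurable (default 2 at full scale,
  1 in the desk preset); with 0 layers the model reduces to a plain residual
  U-shaped network, which doubles as the ablation baseline.

A slicing-free per-element reference implementation
(`rfeunet.reference.rfe_layer_reference`) recomputes the layer with scalar
index arithmetic only and serves as an independent oracle in the tests
(agreement within 1e-6 up to 8×14×14 inputs).

## Network

- **Encoder**: stride-2 stem (3×3 conv, batch norm, ReLU) followed by three
  residual stages, each opening with a stride-2 unit; widths 64/128/256/512
  by default, two residual units per stage. A 3×224×224 input yields a
  512×14×14 bottleneck and skips at 1/2, 1/4 and 1/8 resolution. The
  published description fixes only the input and bottleneck shapes; stage
  depth and widths are configurable here.
- **Bottleneck**: N stacked RFE layers.
- **Decoder**: four stages of 2× bilinear upsampling + 3×3 conv + BN + ReLU;
  the matching encoder skip is concatenated before the convolution at the
  first three stages; a final 1×1 convolution emits n_classes+1 logit
  channels at input resolution. Upsample-then-convolve was chosen over
  transposed convolution to avoid checkerboard artifacts.
- **Initialization**: He-normal for convolutions, zeros for biases.

The whole network, including reverse-mode differentiation, 2-D convolution
(im2col), fused batch normalization and bilinear resizing, is implemented in
`rfeunet.nn` on NumPy.

## Loss and metrics

Training minimizes λ₁·L_dice + λ₂·L_CE with λ₁ = λ₂ = 0.5. Cross-entropy is
the pixel mean of −log q(true class) (log clamped at 1e-12); the dice term
is one minus the mean-over-classes soft dice computed from softmax
probabilities against one-hot labels, smoothing ε = 1e-5 in numerator and
denominator, all classes including background entering the mean. On hard 0/1
predictions the soft dice reduces exactly to the set form 2|X∩Y|/(|X|+|Y|).

Evaluation reports per-class and mean DSC (percent) and HD95 (mm). HD95 uses
the boundary-distance dialect: boundary = mask minus its erosion, directed
distances read off a Euclidean distance transform, symmetric HD95 = max of
the two directed 95th percentiles, scaled by pixel spacing. Degenerate
cases: a class absent from both masks is excluded from that class's average;
absent from exactly one scores DSC 0 and HD95 equal to the image diagonal in
mm (a finite worst case). The directed-vs-symmetric percentile order is not
uniquely fixed by the usual notation; the conventional
max-of-directed-percentiles is used.

## Synthetic phantoms

The generator emulates the statistical premise of abdominal CT slices:
eight foreground classes as boundary-perturbed ellipses (four Fourier
harmonics, |amplitude| ≤ 0.03 each) with class-specific intensity
distributions, placed by rejection sampling into anatomy-inspired regions of
the canvas under minimum-centroid-distance and non-overlap constraints, over
a textured background with additive Gaussian noise (σ = 0.03). The two
kidneys share one intensity distribution and are distinguishable only by
their mirrored positions, so some long-range context is required to label
them correctly. Area fractions per class (0.008–0.06 of the canvas) were
chosen so the smallest organ remains resolvable (~30 px) at a 64×64 desk
resolution while all eight organs still fit without overlap. Datasets are
split 7:3 by default with train count = floor(0.7·n) (430 → 301/129), and
every sample regenerates bit-for-bit from the child seed recorded in the
manifest.

What the phantoms do **not** model: true CT physics (Hounsfield calibration,
beam hardening, partial-volume effects), anatomically correct organ shapes
and contact between adjacent organs, inter-patient variability, or 3-D
structure. Passing the desk-scale tests therefore demonstrates that the
implementation trains, mixes remote information and evaluates correctly —
not that the architecture reaches any particular accuracy on clinical data.

## Training

SGD with momentum 0.9 and weight decay 1e-4; full-scale defaults are
learning rate 0.01, batch size 24, 20 000 iterations at 224×224. The desk
preset (`rfeunet.desk_preset`) uses 64×64 phantoms, widths 8/16/32/64, one
residual unit per stage, one RFE layer, batch size 4, 500 iterations and
learning rate 0.05 — at this tiny scale and short schedule the larger step
size is needed for convergence within the budget. The learning-rate schedule
is constant by default with an optional polynomial-decay flag; no data
augmentation is applied by default. All randomness (phantom generation,
weight init, shuffling) derives from single integer seeds, and repeated runs
on one device reproduce identical loss curves and reports.

Divergence (non-finite loss) aborts training with a diagnostic. Checkpoints
are NumPy archives with an embedded, versioned architecture config, so a
model is reconstructable from the file alone.

## Desk-scale evaluation protocol

The acceptance-level learning check trains the desk preset on 40 phantoms
(28 train / 12 held out, dataset seeds 1000+i, model seeds i for
i = 0..4), evaluates mean foreground DSC on the held-out split, and compares
against the 0-RFE ablation trained with the identical budget and seeds. The
tiny model reaches well above 85 % mean DSC, and the RFE variant wins the
majority of seed pairs; at this scale both models can saturate on easy
classes, so the margin comes mostly from the kidney pair and small organs.

## Known limitations

- Pure-NumPy training is single-device and desk-scale; the full 224×224,
  20 000-iteration recipe is supported by the code but not exercised by the
  tests.
- The correlation matrices grow as (hw)² per block; the layer is meant for
  bottleneck-sized maps, not high-resolution features.
- HD95 conventions for empty masks vary across the literature; numbers are
  comparable only under the dialect documented above.
- Phantom PNG fixtures quantize images to 8 bits; masks are lossless.
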