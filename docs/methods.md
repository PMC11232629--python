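# Methods

## Problem setting

Ultrasound nerve segmentation is a binary pixel-labelling task: given a
grayscale B-mode scan, mark the pixels belonging to a nerve (for the
brachial plexus, a hypoechoic structure with a brighter rim whose
position, size and shape vary widely between frames).  Speckle — the
multiplicative interference texture of coherent imaging — and the
resulting ambiguous boundaries make purely local convolutional features
unreliable, which motivates the two ingredients of this architecture:
dilated convolutions that widen the receptive field without extra
parameters, and a self-attention bottleneck that models long-range
spatial dependencies.

## Network

The model is a U-Net-lineage encoder–decoder (see the README for the
layer equations).  Design points that were genuinely open, and how this
package resolves them:

* **Padding.** Convolutions use zero "same" padding of `(K−1)·r/2` per
  side, so every stage preserves spatial size and skip-connection
  concatenation needs no cropping.  Out-of-range samples of the dilated
  sum contribute zero, consistently with the padding.
* **Where dilation applies.** By default every encoder conv block uses
  the encoder rate (default 3) and every decoder block rate 1.  A config
  switch (`dilate_first_level_only`) restricts dilation to the first
  level, since a reasonable reading of the architecture applies it only
  to the first two convolutional layers.
* **Normalise-then-convolve.** Batch normalisation precedes each
  convolution, including the very first layer on the raw [0, 1] image —
  normalising an already-bounded input is harmless and keeping the block
  uniform avoids a special case.
* **Activations.** ReLU in conv blocks (standard for this family); GELU
  only inside the transformer MLP.
* **Bottleneck tokens.** Patch size 1 (one token per spatial position of
  the deepest map), embedding dimension equal to the bottleneck width, a
  learned additive position embedding applied once at tokenisation, and
  exactly two pre-norm transformer blocks.  Layer-norm epsilon 1e-5, no
  dropout.
* **Relative position bias.** The attention logits receive a learned
  bias indexed by the (dy, dx) offset between token pairs; offsets along
  each axis of an M×M token grid span 2M−1 values, so the table has
  (2M−1)² rows per head.
* **Skip merge.** Concatenation, not addition.
* **Output head.** One logistic channel for the binary task (a softmax
  head is configurable via `num_classes`).

### Parameter budget and the reference configuration

The architecture family fixes a published computational-cost figure of
4,675,329 trainable scalars at 256×256 input but not the per-level
widths.  The reference configuration here was calibrated analytically
against an exact closed-form parameter count of this implementation:

```
channel_schedule = (20, 40, 88, 176, 336)   # encoder levels + bottleneck
heads = 6, mlp_hidden = 1237, patch_size = 1
```

which yields exactly 4,675,329 scalars (convolution and deconvolution
weights/biases, norm affine terms, ViT projections, position embeddings,
relative-bias tables).  The count is invariant across dilation rates
1–6, as dilation inserts zeros rather than weights.  The schedule is a
calibration to the published budget, not a reconstruction of any
particular released code; treat the widths as one valid member of the
family.

## Numerical core

No deep-learning framework is used: all layers implement explicit
forward and reverse-mode backward passes on numpy arrays (NHWC layout,
float32 by default, float64 available for verification).  The dilated
convolution is evaluated as K² shifted matrix products on the padded
input, its gradient by the transposed scatter of the same slices.
Softmax is computed with max-shifting; the logistic output with the
split-sign stable form.  Adam uses the standard bias-corrected moments
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8 — framework defaults, recorded in every
run's config snapshot).  Gradient correctness of every parameter group
is enforced by finite-difference tests in float64.

Max-pooling ties resolve to the first window position in row-major
order.  Metrics with vanishing denominators score 1.0 when the
complementary error counts are zero (a correctly empty prediction is
perfect) and 0.0 otherwise.  Metric aggregation is micro (pooled pixel
counts) by default, per-image macro averaging optional.  The soft-Dice
smoothing term defaults to ε = 1.0; the binarisation threshold for
evaluation is 0.5.

## Synthetic phantom test bed

Clinical benchmark images cannot be redistributed, so the test bed is a
seeded generator that emulates their statistical structure:

* dark background with a few smooth, undulating hyperechoic bands
  (tissue layers);
* with configurable probability (default 0.8), one target: a rotated
  ellipse whose boundary radius is perturbed by low-order harmonics,
  interior darkened (hypoechoic) with a brighter dilated rim;
* multiplicative speckle: the squared magnitude of a spatially smoothed
  complex Gaussian field (Rayleigh-type intensity, positive skew),
  blended at `speckle_scale`;
* Gaussian boundary blur, then clipping to [0, 1].  The ground-truth
  mask is the exact pre-blur target support.

Sample `index` under a spec is a pure function of `(seed, index)`, so
datasets are lazily enumerable and bit-reproducible.  Defaults: 128×128
images with semi-axes in [10, 22] px; the desk-scale runs use 64×64 with
axes [6, 14] (same target/image area ratio).

What the phantoms do **not** model: wave propagation, attenuation and
shadowing, depth-dependent resolution, probe-pressure deformation,
anatomical context, or operator variability.  Passing the learning tests
therefore shows that the implementation can fit and generalise on
speckle-limited imagery of this geometry — it does not certify clinical
benchmark performance, which additionally requires the external dataset
and GPU-scale training.

## Training protocol

The benchmark protocol — Adam, learning rate 1e-4, batch 8, 50 epochs,
soft-Dice loss, checkpoint from the epoch with the best validation Dice
— is the `TrainConfig` default.  "Best performance" is interpreted as
highest validation Dice, the main criterion metric.  No learning-rate
schedule, augmentation or early stopping (all deliberately absent).  The
benchmark's published two-way accounting (1,128 test / 4,512 validation
of 5,640 frames, training unenumerated) is mirrored by
`split_dataset(..., val_fraction=None)`; the harness itself uses an
explicit three-way split (default 0.6/0.2/0.2).

Desk-scale problem sizes, chosen so the whole suite runs on one CPU:
64×64 phantoms, a reduced-width model `(8, 16, 32, 64)` with 4 heads and
MLP width 128 (~141 k parameters), learning rate 1e-3 (the standard Adam
default suits these small-batch short runs; 1e-4 belongs to the
benchmark's 50-epoch GPU protocol).  The memorisation probe trains on 8
phantoms for 200 steps and evaluates its final-step parameters
(restoring an earlier best-validation epoch would defeat a capacity
probe); the generalisation run uses 266 phantoms split 200/16/50 for 20
epochs.

## Known limitations

* Batch statistics: validation/test use running batch-norm statistics
  (momentum 0.1), so very short runs evaluate with partially converged
  statistics.
* The ViT bottleneck's position embedding and bias table are built for
  one token-grid size; a model instance therefore accepts one input
  size (per-size construction, no embedding interpolation).
* CPU-only numpy execution: benchmark-scale (256×256, 4.7 M parameters,
  5,640 images × 50 epochs) training is out of reach by design; the
  harness exposes the epoch budget rather than fixing a surrogate.
* Speckle is modelled in intensity space, not through beam physics.
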