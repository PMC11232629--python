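# sonoseg

Binary semantic segmentation of ultrasound images with a hybrid
multi-scale CNN / Vision-Transformer encoder–decoder, plus everything
needed to exercise it end-to-end without clinical data: a seeded
speckle-phantom generator, pixel-level metrics, a training harness with
best-epoch checkpointing, a dilation-rate sensitivity sweep and a 2×2
ablation grid.

It is aimed at researchers who want a dependency-light, fully inspectable
implementation of this architecture family — every forward and backward
pass is written out on plain numpy arrays, so there is no framework
autodiff between you and the math.

## The model

The network maps a grayscale image `x` to a per-pixel foreground
probability `y_pred = f(x; θ)`:

* **Encoder** — per level, two blocks of *batch-norm → 3×3 atrous
  convolution → ReLU* followed by 2×2 max-pooling.  The atrous (dilated)
  convolution

  `y[i] = Σ_k x[i + r·k] · w[k]`

  samples its input on a grid with spacing `r` (encoder default `r = 3`),
  enlarging the receptive field to `K + (K−1)(r−1)` pixels per axis
  without adding parameters; `r = 1` is an ordinary convolution.
* **Bottleneck** — two pre-norm Vision-Transformer blocks on the deepest
  feature map (one token per spatial position):

  `ẑ = MSA(LN(z_in)) + z_in`,  `z_out = MLP(LN(ẑ)) + ẑ`

  with multi-head scaled dot-product attention
  `Attention(Q,K,V) = softmax(QKᵀ/√d + B)V` and a learned
  relative-position bias `B`.
* **Decoder** — per level, a 2×2 stride-2 transposed convolution that
  halves the channels, concatenation with the matching encoder map (skip
  connection), and two conv blocks at `r = 1`; a final 1×1 convolution
  and logistic output restore the input resolution.

Training uses Adam on the soft Dice loss
`1 − (2Σpg + ε)/(Σp + Σg + ε)`; evaluation reports Dice, accuracy,
precision, sensitivity and specificity from pooled pixel confusion
counts.  Both architecture innovations are config flags
(`use_multiscale_cnn`, `use_self_attention`), so the ablation grid and
the plain-UNet baseline are the same code path.

## Worked example

```python
import numpy as np
from sonoseg import (ModelConfig, PhantomSpec, TrainConfig, DatasetSplit,
                     build_model, make_dataset, train, evaluate)

spec = PhantomSpec(image_size=(64, 64), target_axes=(6.0, 14.0), seed=11)
samples = make_dataset(spec, 266)
perm = np.random.default_rng(0).permutation(266)
split = DatasetSplit(train=tuple(map(int, perm[:200])),
                     validation=tuple(map(int, perm[200:216])),
                     test=tuple(map(int, perm[216:266])))

config = ModelConfig(input_size=(64, 64, 1), channel_schedule=(8, 16, 32, 64),
                     heads=4, mlp_hidden=128)
model = build_model(config, np.random.default_rng(0))
record = train(model, samples, split,
               TrainConfig(learning_rate=1e-3, batch_size=8, epochs=20, seed=0))
result = evaluate(model, samples, split.test)
print(round(record.best_val_dice, 4), round(result.metrics.dice, 4))
```

prints

```
0.8523 0.8466
```

i.e. after 20 epochs the checkpoint from the best validation epoch
reaches a micro-averaged Dice of 0.85 on the 50 held-out phantoms —
the model finds the hypoechoic target despite speckle and deliberately
ambiguous boundaries.  (Exact third decimals depend on the BLAS build.)

The same workflow is available from a shell:

```bash
sonoseg generate --out data/ -n 266 --size 64 --seed 11
sonoseg train --data data/ --checkpoint best.npz --epochs 20 --learning-rate 1e-3
sonoseg evaluate --data data/ --checkpoint best.npz --split test
sonoseg sweep --data data/ --rates 1,2,3 --out sweep.tsv     # dilation sensitivity
sonoseg ablate --data data/ --out ablation.tsv               # 2x2 ablation grid
sonoseg params --reference                                   # parameter count
```

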