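# dgfi-net

Binary segmentation of brain-tumor-like lesions in 2-D grayscale images with
a **dual-branch guided feature interaction network**: two parallel U-shaped
encoder-decoders in which an auxiliary branch guides a main branch during
both encoding (1×1-adapted feature addition at every stage) and decoding
(the auxiliary decoder's full-resolution features, pooled at scales 1/2/4,
fused into the shallowest main-decoder levels). The main encoder uses
dilated-convolution context blocks (ECRB), the auxiliary encoder uses
attention-guided refinement blocks (AGFRB) with efficient channel attention
(ECA), and the main bottleneck is reinforced by a lightweight residual
module (LRM) of `L` layers computing `DW_k(x) + PW(x) + x`.

The package is aimed at researchers who want to study this architecture
family — ablate its components, swap losses, count parameters and
mult-adds — on a single CPU without access to clinical data: a synthetic
brain-phantom generator produces reproducible image/mask pairs with
controllable lesion size, contrast and boundary blur.

Training minimizes the soft Dice loss

    L = 1 − 2·Σᵢ yᵢŷᵢ / (Σᵢ yᵢ² + Σᵢ ŷᵢ²)

(with BCE, soft-IoU, Tversky and a distance-transform Hausdorff surrogate as
alternatives), and evaluation reports Dice = 2TP/(2TP+FN+FP),
Jaccard = TP/(TP+FN+FP) and the Matthews correlation coefficient.

Everything — model, autodiff, convolutions — runs on numpy; see
`docs/methods.md` for the model, the numerical engine and the design
decisions.

## Worked example

```python
import numpy as np
from dgfinet import (ModelConfig, PhantomSpec, TrainConfig, build_model,
                     evaluate, make_dataset, train)
from dgfinet.network import set_state

# 48 phantoms at 64x64, split 30/9/9
samples, split = make_dataset(48, PhantomSpec(image_size=64),
                              (0.625, 0.1875, 0.1875), seed=2)
by = {k: [s for s in samples if split[s.id] == k]
      for k in ("train", "val", "test")}

cfg = ModelConfig(stage_widths=[8, 16, 32, 64], bottleneck_width=128,
                  use_ecrb=True, use_agfrb=True, use_dgfi=True, use_lrm=True)
model = build_model(cfg, seed=1)
history, best = train(model, by["train"], by["val"],
                      TrainConfig(epochs=12, batch_size=8, image_size=64,
                                  seed=1))
set_state(model, best)
report = evaluate(model, by["test"])
print(f"test dice={report.dice:.3f} mcc={report.mcc:.3f} "
      f"jaccard={report.jaccard:.3f}")
```

prints (after about two minutes of CPU training)

```
test dice=0.722 mcc=0.709 jaccard=0.596
```

i.e. after only twelve short epochs the model already recovers ~72% overlap
(Dice) with the held-out phantom masks and a Matthews correlation of 0.71 —
far above the near-zero values of an untrained model. Longer training and
larger widths push this further; the deliberately ambiguous lesion
boundaries of the phantoms bound what any model can reach.

A command-line interface wraps the same pipeline:

```sh
dgfi synth --n 100 --image-size 64 --seed 0 --out-dir data/phantoms
dgfi train --data-dir data/phantoms --variant full --epochs 12
dgfi ablate --data-dir data/phantoms --out-tsv ablation.tsv
dgfi complexity --variant full --input-size 256
```

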