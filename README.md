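# replaysim

Simulations of memory consolidation by **generative replay** in a layered
convolutional classifier, for computational neuroscientists studying how
offline reactivation ("replay" during rest and sleep) turns daytime
category learning into knowledge that generalizes.

A VGG-style network — five convolutional blocks, each ending in a pooling
layer that serves as a named *cut point* (`pool_1` … `pool_5`) — learns
image categories across simulated **days** (one epoch of augmented real
images per day). Between days, **nights** consolidate: the activations the
training images induced at a chosen cut point are captured, one
multivariate normal 𝒩(μ_c, Σ_c) is fitted per class c over the spatially
downsampled, flattened maps, and novel "imagined" activation patterns are
sampled, upsampled, and trained through the truncated network with their
class labels. Variants replay the exact stored activations (*veridical*),
replay from a frozen day-1 snapshot with no further real images
(*continuous*), or let a small reinforcement-learning side network — a
hippocampus stand-in — pick which class to replay next, rewarded by the
reduction of the chi-square gap

    chi2 = sum_c (total_c - correct_c)^2 / total_c

between perfect and observed per-class validation predictions, with
classes drawn from a softmax over the learned values.

Everything runs from synthetic data: a procedural generator renders
texture-defined image categories (prototype + within-class variability,
tunable inter-class similarity and per-class difficulty), so all
experiments are reproducible on one CPU with no downloads. The network
itself is pure NumPy (im2col convolutions, hand-written backpropagation,
Adam), including a `vgg16` preset that reproduces the full-scale
architecture's exact parameter count (138,357,544 with 1,000 outputs).

## Worked example

```python
import numpy as np
import replaysim as rs

# 6 texture classes, 24 train / 4 val / 8 test images each, 64x64
protos = rs.generate_prototypes(6, seed=3)
data = rs.build_dataset(protos, n_train=24, n_val=4, n_test=8, seed=3)

cfg = rs.ProtocolConfig(condition="generative", cut_point="pool_4",
                        n_days=4, n_models=2, master_seed=7,
                        pretrain_epochs=4, pretrain_classes=8)
log = rs.run_condition(cfg, data)
print(np.round(log.accuracy_curve().to_numpy(), 3))
print("final replicate-mean accuracy:", round(log.final_accuracy(), 3))
```

prints

```
[0.135 0.24  0.281 0.312 0.406]
final replicate-mean accuracy: 0.406
```

— the day-0 entry is the untrained network near chance (1/6 ≈ 0.167);
each later entry is the replicate-mean test accuracy after one more
day-night cycle, rising as nightly generative replay consolidates the
day's learning. Running the same protocol with `condition="none"` gives
the slower no-replay baseline; `rs.summarize([...])` tabulates
mean ± s.e.m. per condition and day.

The command line mirrors the library for shell workflows:

```bash
replaysim generate-data --out data/            # PNG image-folder dataset
replaysim replay-experiment --condition generative --days 10 --seed 1 --out runs/
replaysim sweep --exemplars 20,40,60,80,100 --out runs/
replaysim report --runs runs/                  # summary.csv + curve plot
```

Each run writes a long-format CSV (condition, model, day, overall and
per-class accuracy, replay-selection counts) and a JSON manifest with the
fully resolved configuration and seeds; identical config + seed reproduce
the CSV byte for byte.

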