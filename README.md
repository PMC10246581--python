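# phegemil

Attention-based multiple-instance learning (MIL) for **grain-yield
prediction in plant breeding**, fusing variable-size bags of UAV plot
imagery (multispectral, thermal, elevation) with SNP genotypes.

Breeding programs want to rank candidate lines *before* harvest — ideally
before sowing, from genotypes alone. Classical genomic selection fits linear
models on SNP dosages and ignores the environment; remote-sensing models
predict well but need late-season images and cannot transfer to unseen
lines. This package implements a deep MIL architecture that treats every
observation of a field plot — each time-stamped image in each channel, plus
the line's SNP dosage vector — as one *instance* of a bag, and regresses the
plot yield (t/ha) on the pooled bag.

## Model

Each instance is encoded to a 256-dimensional embedding by a
channel-specific encoder (a small residual CNN for images; a fully connected
net with hidden sizes 1024 and 512 for SNP dosages). The embedding bag
H = {h_1, …, h_k} is pooled by gated attention:

    z = Σᵢ aᵢ hᵢ,   aᵢ = softmax_i( wᵀ tanh(V hᵢᵀ) ),   V ∈ R^{l×m}, w ∈ R^l

with several independent heads whose pooled vectors are concatenated and
passed to a fully connected regressor. Because pooling is a convex
combination over an unordered set, the prediction is permutation-invariant
in the instances (a valid set function), bags of any size — including
missing channels — are handled natively, and the weights aᵢ expose which
channels and flight dates the model relied on. Training minimises MSE with
Adam; oversized bags are uniformly subsampled per iteration (the *bag size*
hyperparameter), while inference uses full bags.

The package also ships:

* a **synthetic breeding-trial generator** (`phegemil.datagen`): additive
  SNP architecture with tunable heritability, trial/replicate structure,
  and imagery whose NDVI tracks a latent logistic canopy-health curve, most
  informatively at mid-season;
* **genotype QC** (`phegemil.io_core`): markers kept at <40% missing and
  <10% heterozygosity, lines dropped above 50% missing;
* the **baseline featurization** (`phegemil.baseline_features`): per-pixel
  NDVI/NDRE/GNDVI maps, mean + histogram-mode moments per band and index
  (16 features per date group, 64 over all four groups), and tuned
  Lasso / random-forest baselines;
* **evaluation protocols** (`phegemil.training_eval`): entry-grouped,
  trial-stratified 80/10/10 splits (5 repeats), random hyperparameter
  search, ensembling, marker harmonization across environments, and
  genotype-only fine-tuning for prediction on new environments;
* **interpretation** (`phegemil.interpret`): attention mass by channel and
  flight date, and selection-gain curves (mean realized yield of the top-f
  fraction of lines ranked by prediction).

The neural-network layer (`phegemil.nn`) is a compact, fully seeded
reverse-mode autodiff core on numpy arrays — no GPU or external deep
learning framework required.

## Worked example

```python
import numpy as np
from phegemil.datagen import SimConfig, simulate_dataset
from phegemil.interpret import attention_by_channel
from phegemil.mil_model import ModelConfig
from phegemil.training_eval import (TrainConfig, evaluate, make_splits,
                                    predictions_for, train_model)

cfg = SimConfig(n_lines=60, n_reps=2, n_trials=3, n_markers=80, n_causal=8, seed=42)
res = simulate_dataset(cfg)

plan = make_splits(res.samples, repeats=1, seed=42)
train = plan.partition(res.samples, 0, "train")
val = plan.partition(res.samples, 0, "val")
test = plan.partition(res.samples, 0, "test")

mc = ModelConfig(n_markers=cfg.n_markers, n_heads=4, bag_size=8,
                 temporal_encoding=True, channel_encoding=True,
                 date_vocabulary=cfg.flight_dates)
model, history = train_model(train, val, mc, TrainConfig(epochs=8, seed=42))

obs = np.array([s.yield_t_ha for s in test])
report = evaluate(predictions_for(model, test), obs)
print(f"test MAE  {report.mae:.3f} t/ha")
print(f"test r    {report.pearson:.3f}")
print(f"test R^2  {report.r2:.3f}")
print(attention_by_channel(model, test).head_mean().round(3))
```

Output (a 120-plot simulated trial, ~1 minute on one CPU):

```
test MAE  0.547 t/ha
test r    0.898
test R^2  0.770
multispectral    0.344
thermal          0.363
dem              0.292
genotype         0.000
```

The held-out Pearson correlation of 0.90 shows the bag pooling extracting
the yield signal the generator placed in the imagery; the attention table is
the mean share of pooling weight each data channel received (at this noise
setting all three image channels are informative, and a 1-instance genotype
bag competes against ~35 images per plot).

A command-line interface mirrors the library
(`phegemil simulate | qc-genotypes | featurize | train | predict | evaluate`).

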