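# mcpinn

Multi-channel pairwise-input neural networks (PINNs) for compound–protein
interaction (CPI) prediction, with a synthetic CPI benchmark generator for
desk-scale experiments.

## Who this is for

Computational chemists and ML researchers working on proteochemometrics:
predicting a binary bioactivity label for a *pair* (compound, protein), so
one model covers new compounds and new targets at once.  The package
provides the full experimental loop — featurization, architecture,
training, evaluation, model ranking, and a pretrain/finetune transfer
protocol — runnable end to end on a laptop CPU against generated data
with a known ground truth.

## The model

A PINN feeds each input side through its own *separated* dense stack
(no cross-connections), concatenates the per-channel representations, and
classifies through a *concatenated* stack and a sigmoid unit:

```
compound channels ──► separated stack ─┐
                                       ├─► concat ─► dense ─► σ ─► P(interaction)
protein  channels ──► separated stack ─┘
```

Channels per side: one-hot SMILES / amino-acid sequences consumed by
dilated-CNN (or LSTM/BLSTM) encoders, 1024-bit ECFP4 fingerprints, and
Mol2vec/ProtVec-style sentence embeddings (skip-gram over Morgan
substructures / amino-acid 3-grams, aggregated by sum, mean, or TF-IDF
weighted sum `S = Σ t_w · w_i`).  Single-channel (SC) models use one
channel per side; multi-channel (MC) models merge several.  All fifteen
standard feature-pair presets (SC_1…SC_6, MC_1…MC_9) are shipped.

Because every channel enters the merge at its last separated width, the
architecture balances features of very different raw dimensionality, and
it needs about half the parameters of a plain feed-forward network on the
concatenated input (the package computes both counts exactly).

Training: class-weighted binary cross-entropy, Adam (lr 5e-4, β₁ 0.9,
β₂ 0.999) with per-update learning-rate decay, ELU activations,
Lecun-uniform init, dropout 10%/50%, early stopping on validation MCC.
Evaluation: MCC, ROC AUC, PRC AUC; models are ranked by z-scores averaged
over metrics and replicates with paired-t and variance-ratio F tests.
The whole stack runs on a self-contained NumPy forward/backward kernel —
no deep-learning framework needed — and is bit-deterministic per seed.

## Worked example

```python
from mcpinn.synthetic_data import SyntheticSpec
from mcpinn.training import TrainConfig
from mcpinn.workflow import RunConfig, run_experiment
import json

config = RunConfig(
    preset="SC_6",                                # ECFP + ProtVec
    synthetic=SyntheticSpec(noise_sd=0.0, seed=1),
    output_dir="runs/sc6_demo",
    seed=1,
    train=TrainConfig(batch_size=128, max_epochs=50,
                      early_stopping_patience=15, seed=1),
)
rundir = run_experiment(config)
print(json.loads((rundir / "metrics.json").read_text()))
```

This generates the default balanced task (2,000 compounds × 200 proteins,
20,000 pairs, 54.7% positives), featurizes the ECFP and ProtVec channels,
trains the single-channel PINN and prints the held-out test metrics:

```
{'mcc': 0.697, 'roc_auc': 0.921, 'prc_auc': 0.934,
 'threshold': 0.5, 'best_val_mcc': 0.682}
```

Read: the model separates interacting from non-interacting pairs well
beyond chance (MCC 0 = random, 1 = perfect); ROC/PRC above 0.9 mean the
ranking of pairs is highly concordant with the hidden interaction rule.
The run directory holds the config snapshot, seed, per-epoch history
(`history.tsv`), layer manifest, and metrics — everything needed to
reproduce the run.

The same loop is scriptable from the shell:

```bash
mcpinn simulate --out data/task --seed 1
mcpinn train --preset SC_6 --dataset data/task --out runs/sc6 --seed 1
mcpinn compare --preset SC_6 --preset SC_4 --replicates 3 --out runs/cmp
```

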