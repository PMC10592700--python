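# sctab

Cross-tissue cell-type classification for single-cell RNA-seq.

Automated cell-type annotation across diverse tissues is a classification
problem with three awkward properties: labels live on the Cell Ontology (a
DAG of `is_a` relations) and datasets annotate at different granularity;
donor-to-donor batch effects dominate generalization error; and corpora are
bigger than memory. This package implements, end to end and testable on one
CPU, a method stack built around those properties:

- **A feature-attention tabular classifier** (TabNet-style, single decision
  step): normalized expression passes through a GLU feature transformer, an
  attentive transformer projects back to gene space, and an exact
  **1.5-entmax** turns the scores into a sparse feature mask on the simplex
  — the network attends to a small, per-cell subset of genes. Linear
  (multinomial logistic regression) and MLP reference models share the same
  training loop.
- **Donor-difference data augmentation**: differences between per-(cell
  type, donor) centroids are precomputed into a bank; during training each
  cell is shifted by a random bank vector with a random sign, simulating the
  same cell observed in another donor.
- **Ontology-corrected macro F1**: a prediction counts as correct when it
  equals the annotated label or is a strict subtype of it, and wrong when it
  is an ancestor or unrelated; per-class F1 = 2tp/(2tp+fp+fn), averaged
  without class weights.
- **Deep-ensemble uncertainty**: members differ only by seed; probabilities
  are averaged and `1 - max(mean probability)` is the uncertainty.
- **Corpus procedures**: the six-stage quality filter (primary data, 10x
  assays, strict subtype of "native cell", ≥ 5,000 cells and ≥ 30 donors per
  type, ≥ 7 ontology ancestors), donor-level 70/15/15 splitting, and
  incrementally nested donor/cell subsampling, plus a parquet shard store
  with block-shuffled streaming.
- **A synthetic-corpus generator** (cell-type gene programs, additive donor
  batch effects, Poisson counts, toy ontology with diamonds) so the whole
  stack runs without any download, including an XOR corpus on which no
  linear decision boundary exists.

The classifier trains under class-weighted cross-entropy
(`w_c = n_samples / (n_classes · count_c)`) plus a mask-entropy sparsity
penalty, with AdamW and per-epoch step decay. Model details, parameter
defaults and design rationale are in [docs/methods.md](docs/methods.md).
The networks run on a compact numpy reverse-mode autodiff core
(`sctab.autodiff`) whose gradients are finite-difference-checked in the
tests.

## Worked example

```python
import numpy as np
from sctab import (SimConfig, TrainConfig, simulate, split_by_donor, train,
                   normalize, corrected_macro_f1)

sim = simulate(SimConfig(seed=1))            # 8 types, 20 donors, ~10k cells
donors = sim.dataset.cell_meta["donor_id"].unique().tolist()
split = split_by_donor(donors, seed=1)       # 14 / 3 / 3 donors, no overlap

model = train(sim.dataset, split,
              tcfg=TrainConfig(seed=1, max_epochs=2, batch_size=1024, augment=False))
print("validation macro F1 per epoch:", [round(v, 4) for v in model.history["val_macro_f1"]])

test = split.cell_mask(sim.dataset.cell_meta, "test")
x_test = normalize(sim.dataset).values[test]
preds = model.predict(x_test)
truths = sim.dataset.cell_meta.loc[test, "cell_type"].tolist()
report = corrected_macro_f1(preds, truths, sim.ontology)
print(f"test macro F1 (ontology-corrected): {report.macro_f1:.4f}")
probs = model.predict_proba(x_test)
print(f"mean uncertainty (1 - max prob): {(1 - probs.max(axis=1)).mean():.4f}")
```

Output:

```
validation macro F1 per epoch: [1.0, 1.0]
test macro F1 (ontology-corrected): 1.0000
mean uncertainty (1 - max prob): 0.0052
```

The validation score is computed on held-out donors, so 1.0 means the
classifier generalizes across the synthetic donor batch effects; the mean
uncertainty near zero reflects confident (and here correct) predictions.
On the XOR corpus (`make_xor_corpus`) the same model reaches macro F1 1.0
while the linear baseline stays near 0.5 — class identity there is a
nonlinear function of two gene-module activations.

## Command line

```bash
sctab simulate --config run.yaml --out sim.h5ad --obo sim.obo
sctab prepare  --input sim.h5ad --ontology sim.obo --out prep/ \
               --min-cells 5000 --min-donors 30 --min-ancestors 7
sctab augment-bank --input prep/filtered.h5ad --out bank.npz
sctab train    --input prep/filtered.h5ad --split prep/split.tsv \
               --bank bank.npz --out model.pkl
sctab predict  --checkpoint model.pkl --input prep/filtered.h5ad --out pred.csv
sctab evaluate --pred pred.csv --truth truth.csv --ontology sim.obo \
               --group-by tissue --out report.json
```

Each command accepts `--config run.yaml` (section per module, unknown keys
rejected, flags override file values) and writes a JSON manifest with the
config hash and seed next to its artifacts.

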