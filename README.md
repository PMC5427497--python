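# subloc

Classify where a fluorescently tagged protein lives inside a yeast cell —
nucleus, vacuole, ER, one of twelve compartments — from two-channel 64×64
single-cell microscopy patches, and turn noisy per-cell predictions into
confident per-protein calls. The package is aimed at computational
biologists working with high-content screens who want a self-contained,
CPU-runnable reference implementation of the deep-learning localization
pipeline together with its classical baseline.

The pieces, in the order the pipeline runs them:

- **`subloc.synth`** — a synthetic microscopy generator. Red channel: a
  cytosolic marker filling the cell; green channel: the compartment
  archetype (nuclear disk, peripheral ring, puncta, tubules, …) plus a
  realistic intensity model (expression jitter, background gradients, read
  and shot noise). Twelve core compartments, four held-out transfer classes
  and non-cell artifacts, grouped into proteins with protein-disjoint
  train/validation/test folds.
- **`subloc.network`** — an 11-layer convolutional classifier (eight 3×3
  convolutions of widths 64…256 with batch norm and ReLU, three 2×2
  poolings, FC 512/512/K, dropout 0.5, softmax), trained by SGD with
  momentum 0.9, lr 0.1 halved every 16,250 iterations, weight decay 5·10⁻⁴
  — implemented in pure numpy, gradients verified against finite
  differences. A `small` preset (widths ÷8) trains in minutes on one CPU.
- **`subloc.features`** — the classical baseline: intensity, Otsu-mask
  geometry, 13 Haralick statistics, Gabor energies and Zernike moment
  magnitudes (242 features over 2 channels × 2 scales), a grid-searched
  random-forest compartment classifier, and a cross-validated cell/non-cell
  quality filter.
- **`subloc.aggregate`** — per-protein calls via a Dirichlet–multinomial
  posterior: concentration = prior + soft counts (summed per-cell
  probability vectors), MAP compartment, top-k mass fractions for
  dual-localized proteins, minimum-cell filtering.
- **`subloc.evaluate`** — confusion matrices, Cohen's κ, per-class
  precision/recall with 95% CIs from a class-stratified bootstrap (20,000
  replicates, class counts preserved exactly in every replicate).
- **`subloc.transfer`** — the trained network as a feature extractor for
  unseen compartments (learning curves vs classic features), plus
  interpretability: t-SNE layer embeddings, neuron–class mutual
  information, strongest correlations to classic features, maximally
  activating patches via receptive-field arithmetic.
- **`subloc.study`** — the desk-scale end-to-end experiment driver;
  **`subloc.cli`** — a `subloc` command-line tool wrapping the stages
  (`simulate`, `features`, `train`, `evaluate`, `aggregate`, `run`, …).

## Worked example

```python
import numpy as np
from subloc import (
    DatasetSpec, generate_dataset, NetworkConfig, TrainConfig,
    build_network, train, predict_proba, aggregate_proteins,
    map_compartment, confusion_and_metrics,
)

spec = DatasetSpec(cells_per_protein=18, proteins_per_class=7, seed=1)
ds = generate_dataset(spec)                 # 1,512 cells, 12 compartments
net = build_network(NetworkConfig.small(12), seed=1)
cfg = TrainConfig(epochs=16, batch_size=50, initial_lr=0.15,
                  lr_halving_interval=88, warmup_iterations=44, seed=1)
trained = train(net, ds, cfg)               # ~2.5 min on one CPU core

man = ds.manifest.set_index("cell_id")
test_ids = man.index[man["fold"] == "test"]
probs = predict_proba(trained, ds.pixel_array(test_ids))
pred = [trained.classes[i] for i in probs.argmax(axis=1)]
report = confusion_and_metrics(man.loc[test_ids, "label"], pred, trained.classes)
print(f"per-cell accuracy {report.accuracy:.3f}, kappa {report.kappa:.3f}")

posts = aggregate_proteins(probs, man.loc[test_ids, "protein_id"], trained.classes)
calls = {p: map_compartment(post, trained.classes)[0] for p, post in posts.items()}
truth = man.drop_duplicates("protein_id").set_index("protein_id")["label"]
correct = sum(calls[p] == truth[p] for p in calls)
print(f"per-protein accuracy {correct}/{len(calls)}")
```

Output:

```
per-cell accuracy 0.875, kappa 0.864
per-protein accuracy 12/12
```

Per-cell, the small network classifies 87.5% of held-out cells correctly
(κ = 0.86; chance would be 1/12). Aggregating the 18 cells of each held-out
protein into a Dirichlet posterior and taking the MAP compartment corrects
the residual single-cell errors: all 12 test proteins are called correctly.
On the same data a grid-searched random forest over the 242 classic
features reaches 81.9% per cell — the network wins, and the gap widens in
the transfer setting (see `docs/methods.md` for the study design and
`subloc.study` for the driver).

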