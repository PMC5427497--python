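"""Desk-scale replication study: the end-to-end experiment driver.

Runs the full pipeline on synthetic data at the package's standard
desk-scale study conditions — 12 compartments, 7 proteins per class with
protein-disjoint 72/14/14 folds, the small network preset — and measures
the quantities the method is judged by: single-cell accuracy of the network
and of the classic-feature random forest, Cohen's kappa, protein-level
accuracy before and after the minimum-cell filter, transfer-learning
accuracy of deep versus classic features on the four held-out classes, and
per-layer interpretability summaries (neuron-class mutual information,
strongest correlation to classic features).

Every quantity is recomputed from scratch for each seed; the same driver
backs both the test suite's ordering checks and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import aggregate as agg
from . import evaluate as ev
from . import features as feat
from . import network as net
from . import synth
from . import transfer as tr

#: Desk-scale study conditions (sample sizes chosen once; see docs/methods.md)
STUDY = dict(
    cells_per_protein=18,
    proteins_per_class=7,
    fold_fractions=(0.72, 0.14, 0.14),
    epochs=16,
    warmup_epochs=2,
    batch_size=50,
    initial_lr=0.15,
    transfer_per_class_folds=(30, 15, 30),
    transfer_cells_per_protein=15,
    transfer_sizes=(1, 3, 5, 10),
    transfer_reps=3,
    mi_layers=(1, 10),
    n_bins=16,
)


@dataclass
class SeedResult:
    """Everything one seed of the study measures."""

    seed: int
    rf_accuracy: float
    rf_kappa: float
    cnn_accuracy: float
    cnn_kappa: float
    protein_accuracy_all: float
    protein_accuracy_min10: float
    protein_accuracy_by_cells: dict[int, float]
    transfer_deep: dict[int, float]  # size -> mean test accuracy
    transfer_classic: dict[int, float]
    mi_median: dict[int, float]  # layer -> median MI (bits)
    maxcorr_median: dict[int, float]  # layer -> median max |r|
    rf_chosen: dict = field(default_factory=dict)
    trained: "net.TrainedNetwork | None" = None
    extras: dict = field(default_factory=dict)


def run_seed(seed: int, keep_model: bool = False) -> SeedResult:
    """One complete replicate of the desk-scale study."""
    spec = synth.DatasetSpec(
        classes=synth.CORE_CLASSES,
        cells_per_protein=STUDY["cells_per_protein"],
        proteins_per_class=STUDY["proteins_per_class"],
        fold_fractions=STUDY["fold_fractions"],
        seed=seed,
    )
    ds = synth.generate_dataset(spec)
    classes = tuple(sorted(set(ds.manifest["label"])))
    man = ds.manifest.set_index("cell_id")
    fold, labels = man["fold"], man["label"]

    table, _ = feat.extract_feature_table(ds)
    tr_ids = table.index[fold[table.index] == "train"]
    va_ids = table.index[fold[table.index] == "val"]
    te_ids = table.index[fold[table.index] == "test"]

    baseline = feat.train_rf_baseline(
        table.loc[tr_ids], labels[tr_ids], feat.RFGrid.small(),
        table.loc[va_ids], labels[va_ids], seed=seed,
    )
    rf_pred = baseline.predict(table.loc[te_ids])
    rf_report = ev.confusion_and_metrics(labels[te_ids], rf_pred, classes)

    network = net.build_network(net.NetworkConfig.small(len(classes)), seed=seed)
    per_epoch = net.iteration_schedule(len(tr_ids), STUDY["batch_size"], 1)
    tcfg = net.TrainConfig(
        epochs=STUDY["epochs"], batch_size=STUDY["batch_size"],
        initial_lr=STUDY["initial_lr"], seed=seed,
        lr_halving_interval=max(1, per_epoch * max(STUDY["epochs"] // 4, 1)),
        warmup_iterations=per_epoch * STUDY["warmup_epochs"],
    )
    trained = net.train(network, ds, tcfg)
    test_imgs = ds.pixel_array(te_ids)
    probs = net.predict_proba(trained, test_imgs)
    cnn_pred = np.array([trained.classes[i] for i in probs.argmax(axis=1)])
    cnn_report = ev.confusion_and_metrics(labels[te_ids], cnn_pred, classes)

    # protein-level aggregation on the test fold
    posteriors = agg.aggregate_proteins(probs, man.loc[te_ids, "protein_id"], classes)
    calls = {p: agg.map_compartment(post, classes)[0] for p, post in posteriors.items()}
    truth = man.drop_duplicates("protein_id").set_index("protein_id")["label"].to_dict()
    n_per = {p: post.n_cells for p, post in posteriors.items()}
    prot = ev.protein_level_report(calls, truth, n_per, min_cells=10)

    protein_by_cells = _protein_accuracy_by_cells(
        probs, man.loc[te_ids, "protein_id"].values, truth, classes, seed
    )

    # transfer learning on the four held-out classes
    tds = synth.generate_transfer_dataset(
        seed=seed, per_class_folds=STUDY["transfer_per_class_folds"],
        cells_per_protein=STUDY["transfer_cells_per_protein"],
    )
    t_man = tds.manifest
    t_imgs = tds.pixel_array()
    t_labels = t_man["label"].values
    deep = net.extract_activations(trained, t_imgs, 9)
    classic, _ = feat.extract_feature_table(tds)
    t_idx = {f: np.flatnonzero((t_man["fold"] == f).values) for f in ("train", "val", "test")}
    curve = tr.transfer_learning_curve(
        {"deep": deep, "classic": classic.values}, t_labels,
        t_idx["train"], t_idx["val"], t_idx["test"],
        sizes=STUDY["transfer_sizes"], n_reps=STUDY["transfer_reps"], seed=seed,
    )

    # interpretability summaries on the held-out test cells (one activation
    # extraction per layer, shared by the MI and correlation analyses)
    acts = {
        L: net.extract_activations(trained, test_imgs, L, pool="gap")
        for L in STUDY["mi_layers"]
    }
    mi = {
        L: tr.neuron_class_mutual_information(a, labels[te_ids], STUDY["n_bins"])
        for L, a in acts.items()
    }
    maxcorr = {
        L: tr.max_feature_correlation(a, table.loc[te_ids].values)
        for L, a in acts.items()
    }

    return SeedResult(
        seed=seed,
        rf_accuracy=rf_report.accuracy,
        rf_kappa=rf_report.kappa,
        cnn_accuracy=cnn_report.accuracy,
        cnn_kappa=cnn_report.kappa,
        protein_accuracy_all=prot.accuracy_all,
        protein_accuracy_min10=prot.accuracy_filtered,
        protein_accuracy_by_cells=protein_by_cells,
        transfer_deep=curve.accuracy["deep"].to_dict(),
        transfer_classic=curve.accuracy["classic"].to_dict(),
        mi_median={L: float(np.nanmedian(v)) for L, v in mi.items()},
        maxcorr_median={L: float(np.nanmedian(v)) for L, v in maxcorr.items()},
        rf_chosen=baseline.chosen,
        trained=trained if keep_model else None,
    )


def _protein_accuracy_by_cells(
    probs: np.ndarray,
    protein_ids: np.ndarray,
    truth: dict[str, str],
    classes: Sequence[str],
    seed: int,
    sizes: Sequence[int] = (1, 3, 10, 18),
    n_draws: int = 10,
) -> dict[int, float]:
    """Protein-level accuracy when only j cells per protein are observed
    (averaged over random subsets), tracing accuracy versus population size."""
    rng = np.random.default_rng((seed, 77))
    out = {}
    pids = np.asarray(protein_ids)
    unique = list(dict.fromkeys(pids))
    for j in sizes:
        correct = total = 0
        for pid in unique:
            rows = probs[pids == pid]
            take = min(j, len(rows))
            for _ in range(n_draws):
                sub = rows[rng.choice(len(rows), size=take, replace=False)]
                post = agg.dirichlet_posterior(
                    [agg.ClassProbabilities(r, protein_id=pid) for r in sub]
                )
                call, _ = agg.map_compartment(post, classes)
                correct += call == truth[pid]
                total += 1
        out[j] = correct / total
    return out


def run_study(seeds: Sequence[int] = (1, 2, 3, 4, 5), keep_first_model: bool = False):
    """Run the full study across seeds; returns the list of SeedResults."""
    return [
        run_seed(s, keep_model=(keep_first_model and i == 0))
        for i, s in enumerate(seeds)
    ]


def summarize(results: Sequence[SeedResult]) -> dict[str, float]:
    """Seed-mean summary of the study's headline quantities."""

    def mean(fn):
        return float(np.mean([fn(r) for r in results]))

    sizes = STUDY["transfer_sizes"]
    mi_layers = STUDY["mi_layers"]
    return {
        "rf_accuracy": mean(lambda r: r.rf_accuracy),
        "rf_kappa": mean(lambda r: r.rf_kappa),
        "cnn_accuracy": mean(lambda r: r.cnn_accuracy),
        "cnn_kappa": mean(lambda r: r.cnn_kappa),
        "protein_accuracy_all": mean(lambda r: r.protein_accuracy_all),
        "protein_accuracy_min10": mean(lambda r: r.protein_accuracy_min10),
        **{
            f"transfer_deep_n{s}": mean(lambda r, s=s: r.transfer_deep[s])
            for s in sizes
        },
        **{
            f"transfer_classic_n{s}": mean(lambda r, s=s: r.transfer_classic[s])
            for s in sizes
        },
        **{
            f"mi_median_layer{L}": mean(lambda r, L=L: r.mi_median[L])
            for L in mi_layers
        },
        **{
            f"maxcorr_median_layer{L}": mean(lambda r, L=L: r.maxcorr_median[L])
            for L in mi_layers
        },
    }
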