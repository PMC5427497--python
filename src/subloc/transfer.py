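"""Transfer learning and network interpretability.

The trained network doubles as a feature extractor: activations of its
intermediate layers feed random forests that classify compartments never
seen during training, traced out as learning curves against the classic
hand-crafted features. Interpretability tools quantify what each layer
encodes: 2-D stochastic neighbor embeddings of layer activations, mutual
information between discretized neuron outputs and the class label, the
strongest Pearson correlation of each neuron to a classic feature, and the
input patches that maximally activate a chosen neuron (via receptive-field
arithmetic).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE

from .network import TrainedNetwork, extract_activations

#: Training-set sizes (images per class) of the standard learning curve.
DEFAULT_CURVE_SIZES: tuple[int, ...] = (1, 3, 5, 10, 25, 50, 100, 250, 500)


@dataclass
class LearningCurve:
    """Mean held-out accuracy per training-set size per feature source."""

    train_sizes: tuple[int, ...]
    accuracy: pd.DataFrame  # index = sizes, columns = sources (mean over reps)
    replicates: pd.DataFrame  # long form: size, source, rep, accuracy
    n_reps: int
    seed: int

    def __post_init__(self):
        if list(self.train_sizes) != sorted(set(self.train_sizes)):
            raise ValueError("train_sizes must be strictly increasing")


def _stratified_subsample(
    labels: np.ndarray, per_class: int, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if per_class > len(members):
            raise ValueError(
                f"requested {per_class} training images per class but only "
                f"{len(members)} available for {cls!r}"
            )
        idx.append(rng.choice(members, size=per_class, replace=False))
    return np.concatenate(idx)


def transfer_learning_curve(
    features_by_source: Mapping[str, np.ndarray],
    labels: Sequence[str],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    sizes: Sequence[int] = DEFAULT_CURVE_SIZES,
    n_reps: int = 3,
    seed: int = 0,
    n_trees_grid: tuple[int, ...] = (100,),
) -> LearningCurve:
    """Learning curves of random forests on different feature sources.

    For every source and training size: subsample ``size`` images per class
    from the training fold (stratified), fit a forest for each entry of
    ``n_trees_grid``, pick the best on validation accuracy, and record its
    test accuracy. Repeated ``n_reps`` times with derived seeds.
    """
    labels = np.asarray(labels)
    rows = []
    for source, X in features_by_source.items():
        X = np.asarray(X)
        for size in sizes:
            for rep in range(n_reps):
                src_key = zlib.crc32(source.encode()) % (2**16)
                rng = np.random.default_rng((seed, src_key, size, rep))
                sub = train_idx[
                    _stratified_subsample(labels[train_idx], size, rng)
                ]
                best = (-1.0, None)
                for t in n_trees_grid:
                    clf = RandomForestClassifier(
                        n_estimators=t, random_state=int(rng.integers(2**31)), n_jobs=1
                    )
                    clf.fit(X[sub], labels[sub])
                    val_acc = float((clf.predict(X[val_idx]) == labels[val_idx]).mean())
                    if val_acc > best[0]:
                        best = (val_acc, clf)
                test_acc = float((best[1].predict(X[test_idx]) == labels[test_idx]).mean())
                rows.append(dict(size=size, source=source, rep=rep, accuracy=test_acc))
    reps = pd.DataFrame(rows)
    mean = reps.pivot_table(index="size", columns="source", values="accuracy", aggfunc="mean")
    return LearningCurve(
        train_sizes=tuple(sizes), accuracy=mean, replicates=reps, n_reps=n_reps, seed=seed
    )


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------


def embed_2d(
    feature_matrix: np.ndarray, seed: int = 0, sample_size: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """2-D t-SNE embedding of (a sample of) the rows.

    At most ``sample_size`` rows are embedded (sampled without replacement
    with the given seed, the conventional design being 1000 random cells).
    Returns (coordinates n x 2, row indices of the embedded sample).
    """
    X = np.asarray(feature_matrix, dtype=np.float64)
    if len(X) < 3:
        raise ValueError("need at least 3 rows to embed")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant feature matrix cannot be embedded")
    rng = np.random.default_rng(seed)
    if len(X) > sample_size:
        idx = np.sort(rng.choice(len(X), size=sample_size, replace=False))
    else:
        idx = np.arange(len(X))
    perplexity = min(30.0, (len(idx) - 1) / 3.0)
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return ts.fit_transform(X[idx]), idx


# ---------------------------------------------------------------------------
# Mutual information between neurons and the class label
# ---------------------------------------------------------------------------


def neuron_class_mutual_information(
    activations: np.ndarray, labels: Sequence[str], n_bins: int = 16
) -> np.ndarray:
    """MI (bits) between each neuron's discretized output and the label.

    Neuron outputs are discretized into ``n_bins`` equal-frequency bins
    (quantile edges; exactly constant neurons get MI 0 by convention) and
    the mutual information is computed from the empirical joint histogram.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    A = np.asarray(activations, dtype=np.float64)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    n, d = A.shape
    py = np.bincount(y) / n
    out = np.zeros(d)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(d):
        col = A[:, j]
        if col.max() == col.min():
            continue
        edges = np.unique(np.quantile(col, qs))
        bins = np.searchsorted(edges, col, side="right")
        nb = bins.max() + 1
        joint = np.zeros((nb, len(classes)))
        np.add.at(joint, (bins, y), 1.0)
        joint /= n
        px = joint.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = joint / (px[:, None] * py[None, :])
            terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
        out[j] = max(0.0, float(terms.sum()))
    return out


def mi_by_layer(
    trained: TrainedNetwork,
    images: np.ndarray,
    labels: Sequence[str],
    layers: Sequence[int],
    n_bins: int = 16,
) -> dict[int, np.ndarray]:
    """Per-neuron MI distributions for several layers (conv layers are
    global-average-pooled to one neuron per channel)."""
    return {
        L: neuron_class_mutual_information(
            extract_activations(trained, images, L, pool="gap"), labels, n_bins
        )
        for L in layers
    }


# ---------------------------------------------------------------------------
# Correlation of neurons to classic features
# ---------------------------------------------------------------------------


def max_feature_correlation(
    activations: np.ndarray, classic_feature_table: np.ndarray
) -> np.ndarray:
    """For each neuron, the strongest |Pearson r| to any classic feature.

    Zero-variance neurons yield NaN; zero-variance features are skipped.
    Rows of both matrices must refer to the same cells in the same order.
    """
    A = np.asarray(activations, dtype=np.float64)
    F = np.asarray(classic_feature_table, dtype=np.float64)
    if A.shape[0] != F.shape[0]:
        raise ValueError("activations and features must cover the same cells")
    sa = A.std(axis=0)
    sf = F.std(axis=0)
    keep_f = sf > 0
    Az = (A - A.mean(axis=0)) / np.where(sa > 0, sa, 1.0)
    Fz = (F[:, keep_f] - F[:, keep_f].mean(axis=0)) / sf[keep_f]
    r = np.abs(Az.T @ Fz) / A.shape[0]
    out = r.max(axis=1) if r.shape[1] else np.full(A.shape[1], np.nan)
    out = np.where(sa > 0, out, np.nan)
    return out


# ---------------------------------------------------------------------------
# Maximally activating patches
# ---------------------------------------------------------------------------


def receptive_field(config, layer_index: int) -> int:
    """Input-pixel extent of one neuron of a weight-bearing layer.

    Stacked 3x3 stride-1 convolutions grow the field by 2 x jump per layer;
    each 2x2 stride-2 pooling adds jump and doubles it. Fully connected
    layers see the whole input.
    """
    n_conv = len(config.conv_widths)
    if not (1 <= layer_index <= n_conv + len(config.fc_widths)):
        raise ValueError(f"invalid layer index {layer_index}")
    if layer_index > n_conv:
        return config.input_shape[1]
    rf, jump = 1, 1
    for i in range(1, layer_index + 1):
        rf += 2 * jump  # 3x3 conv
        if i in config.pool_positions and i < layer_index:
            rf += jump
            jump *= 2
    return rf


def _neuron_center(config, layer_index: int, pos: tuple[int, int]) -> tuple[int, int]:
    """Approximate input-space center of a conv neuron at spatial pos."""
    stride = 1
    for p in config.pool_positions:
        if p < layer_index:
            stride *= 2
    return (pos[0] * stride + stride // 2, pos[1] * stride + stride // 2)


@dataclass
class ActivatingPatch:
    cell_id: str
    activation: float
    patch: np.ndarray  # (2, rf, rf) crop, clipped at borders
    center: tuple[int, int]


def top_activating_patches(
    trained: TrainedNetwork,
    images: np.ndarray,
    cell_ids: Sequence[str],
    layer: int,
    neuron: int,
    k: int = 9,
) -> list[ActivatingPatch]:
    """The k input crops that maximally activate one neuron.

    For convolutional layers the neuron is a channel: its maximal spatial
    activation per image is found, and the receptive-field-sized crop
    around that position (clipped at borders) is returned. For fully
    connected layers the whole image is the patch. Results are sorted by
    activation, descending.
    """
    acts4 = _raw_activations(trained, images, layer)
    config = trained.config
    n = len(images)
    if k > n:
        import logging

        logging.getLogger("subloc").warning("k=%d exceeds dataset size %d", k, n)
        k = n
    rf = receptive_field(config, layer)
    records = []
    if acts4.ndim == 4:
        if not (0 <= neuron < acts4.shape[1]):
            raise ValueError(f"neuron {neuron} out of range for layer {layer}")
        maps = acts4[:, neuron]
        for i in range(n):
            pos = np.unravel_index(int(maps[i].argmax()), maps[i].shape)
            cy, cx = _neuron_center(config, layer, pos)
            records.append((float(maps[i][pos]), i, (cy, cx)))
    else:
        if not (0 <= neuron < acts4.shape[1]):
            raise ValueError(f"neuron {neuron} out of range for layer {layer}")
        side = config.input_shape[1]
        for i in range(n):
            records.append((float(acts4[i, neuron]), i, (side // 2, side // 2)))
    records.sort(key=lambda r: -r[0])
    side = config.input_shape[1]
    half = rf // 2
    out = []
    for act, i, (cy, cx) in records[:k]:
        y0, y1 = max(0, cy - half), min(side, cy + half + 1)
        x0, x1 = max(0, cx - half), min(side, cx + half + 1)
        out.append(
            ActivatingPatch(
                cell_id=cell_ids[i], activation=act,
                patch=np.asarray(images[i][:, y0:y1, x0:x1]), center=(cy, cx),
            )
        )
    return out


def _raw_activations(trained: TrainedNetwork, images: np.ndarray, layer: int) -> np.ndarray:
    """Unpooled post-activation maps (4-D for conv, 2-D for FC)."""
    from .network import preprocess

    net = trained.network
    if not (1 <= layer <= net.n_weight_layers):
        raise ValueError(f"invalid layer index {layer}")
    x = preprocess(np.asarray(images) / trained.intensity_scale, trained.pixel_mean).astype(
        net.dtype
    )
    outs = []
    for i in range(0, len(x), 200):
        _, caps = net.forward(x[i : i + 200], train=False, capture=[layer])
        outs.append(caps[layer].astype(np.float64))
    return np.concatenate(outs)
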