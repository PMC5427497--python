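"""Hand-crafted image features and the random-forest baselines.

Implements the classical feature families used in high-content screening
pipelines — intensity statistics, Otsu-mask geometry, Haralick co-occurrence
texture, Gabor filter-bank responses, and Zernike moment magnitudes — at two
spatial scales for both channels, plus the random-forest compartment
baseline (grid-searched on validation accuracy) and the cell/non-cell
quality filter (grid-searched by 10-fold cross-validation).

Feature extraction is a pure function of the pixel values: re-running it on
the same image yields a bit-identical vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.fft import irfft2, rfft2
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .synth import CellImage, Dataset

logger = logging.getLogger("subloc")


@dataclass
class FeatureVector:
    """Named real-valued features; names are stable and ordered."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != len(self.names):
            raise ValueError("values and names differ in length")

    @property
    def channel_tags(self) -> list[str]:
        """Which channel each feature derives from (``r``/``g``/``rg``)."""
        return [n.split("_", 1)[0] for n in self.names]


# ---------------------------------------------------------------------------
# Haralick texture features
# ---------------------------------------------------------------------------

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_avg", "sum_var",
    "sum_entropy", "entropy", "diff_var", "diff_entropy", "imc1", "imc2",
)


def _quantize(channel: np.ndarray, n_gray_levels: int) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    q = np.floor((channel - lo) / (hi - lo) * n_gray_levels).astype(np.int64)
    return np.clip(q, 0, n_gray_levels - 1).astype(np.uint8)


def _haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized symmetric GLCM."""
    n = P.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = math.sqrt(max(((i - mu_x) ** 2 * px).sum(), 0.0))
    sd_y = math.sqrt(max(((i - mu_y) ** 2 * py).sum(), 0.0))

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    asm = float((P**2).sum())
    contrast = float((P * (ii - jj) ** 2).sum())
    if sd_x * sd_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0  # constant image convention
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    k_sum = np.arange(2 * n - 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_entropy = ent(p_sum)

    k_diff = np.arange(n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    diff_entropy = ent(p_diff)

    hxy = ent(P.ravel())
    with np.errstate(divide="ignore"):
        lpxy = np.where(px[:, None] * py[None, :] > 0, np.log2(px[:, None] * py[None, :]), 0.0)
    hxy1 = float(-(P * lpxy).sum())
    hxy2 = ent((px[:, None] * py[None, :]).ravel())
    hx, hy = ent(px), ent(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return np.array([
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_entropy, entropy_ := hxy, diff_var, diff_entropy, imc1, imc2,
    ])


def haralick_features(
    channel: np.ndarray,
    n_gray_levels: int = 32,
    distance: int = 1,
    prefix: str = "",
) -> FeatureVector:
    """13 Haralick statistics averaged over 4 directions at one distance.

    The channel is min–max quantized to ``n_gray_levels``; the co-occurrence
    matrix for each offset is symmetric and normalized (rows of each matrix
    sum to the marginals, total mass 1). A constant image yields the
    single-cell co-occurrence convention: contrast 0, angular second
    moment 1.
    """
    q = _quantize(channel, n_gray_levels)
    angles = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    glcm = graycomatrix(
        q, distances=[distance], angles=list(angles),
        levels=n_gray_levels, symmetric=True, normed=True,
    )
    stats = np.mean(
        [_haralick_stats(glcm[:, :, 0, a]) for a in range(len(angles))], axis=0
    )
    names = [f"{prefix}har_{n}" for n in HARALICK_NAMES]
    return FeatureVector(stats, names)


def glcm_matrix(channel: np.ndarray, n_gray_levels: int, distance: int = 1) -> np.ndarray:
    """Normalized symmetric GLCMs, shape (levels, levels, 1, 4); exposed for
    verification of the normalization invariant."""
    q = _quantize(channel, n_gray_levels)
    return graycomatrix(
        q, distances=[distance], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=n_gray_levels, symmetric=True, normed=True,
    )


# ---------------------------------------------------------------------------
# Zernike moment magnitudes
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _zernike_basis(size: int, radius: float, max_order: int):
    """Complex Zernike polynomial basis evaluated on the disk pixels.

    Returns (basis matrix [n_moments x n_pixels], flat pixel indices,
    moment names). The disk is centered on the patch center
    ((size-1)/2, (size-1)/2), so it is symmetric under 90-degree rotations.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - c, xx - c
    rho = np.hypot(dy, dx) / radius
    theta = np.arctan2(dy, dx)
    inside = rho <= 1.0
    flat = np.flatnonzero(inside)
    rho_i = rho.ravel()[flat]
    theta_i = theta.ravel()[flat]

    rows, names = [], []
    for n in range(max_order + 1):
        for m in range(n % 2, n + 1, 2):
            # radial polynomial R_n^m
            R = np.zeros_like(rho_i)
            for s in range((n - m) // 2 + 1):
                coef = (
                    (-1) ** s
                    * math.factorial(n - s)
                    / (
                        math.factorial(s)
                        * math.factorial((n + m) // 2 - s)
                        * math.factorial((n - m) // 2 - s)
                    )
                )
                R += coef * rho_i ** (n - 2 * s)
            rows.append((n + 1) / np.pi * R * np.exp(-1j * m * theta_i))
            names.append(f"z{n}_{m}")
    return np.array(rows), flat, names


def zernike_moments(
    channel: np.ndarray, radius: float = 32.0, max_order: int = 9, prefix: str = ""
) -> FeatureVector:
    """Magnitudes |Z(n, m)| over a centered disk, intensity-normalized.

    Magnitudes are rotation invariant; the image mass inside the disk is
    normalized to 1 first, so the moments describe shape rather than
    brightness. An all-zero image returns all-zero magnitudes.
    """
    size = channel.shape[0]
    if channel.shape[0] != channel.shape[1]:
        raise ValueError("square patch required")
    if radius > size:
        raise ValueError(f"radius {radius} exceeds patch size {size}")
    basis, flat, names = _zernike_basis(size, float(radius), max_order)
    f = channel.ravel()[flat].astype(np.float64)
    total = f.sum()
    if total > 0:
        f = f / total
        mags = np.abs(basis @ f)
    else:
        mags = np.zeros(len(names))
    return FeatureVector(mags, [f"{prefix}{n}" for n in names])


# ---------------------------------------------------------------------------
# Gabor filter bank
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _gabor_bank(frequencies: tuple, orientations: tuple, sigma: float):
    """Zero-mean real Gabor kernels for the bank."""
    kernels, names = [], []
    for f in frequencies:
        for th in orientations:
            k = np.real(gabor_kernel(f, theta=np.deg2rad(th), sigma_x=sigma, sigma_y=sigma))
            k = k - k.mean()  # exactly DC-free
            kernels.append(k)
            names.append(f"gab_f{f:g}_t{th:g}")
    return kernels, names


@lru_cache(maxsize=16)
def _gabor_bank_ffts(frequencies: tuple, orientations: tuple, sigma: float, shape: tuple):
    kernels, _ = _gabor_bank(frequencies, orientations, sigma)
    return [rfft2(k, s=shape) for k in kernels]


def gabor_responses(
    channel: np.ndarray,
    frequencies: Sequence[float] = (0.15, 0.3),
    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    sigma: float = 3.0,
    prefix: str = "",
) -> FeatureVector:
    """Mean magnitude and mean energy of each filter response.

    Kernels are zero-mean (DC-free), so a constant image yields (numerically)
    zero responses; responses are evaluated on the valid interior only to
    avoid zero-padding edge effects. Energy is quadratic in intensity.
    """
    if len(frequencies) == 0 or len(orientations) == 0:
        raise ValueError("empty filter bank")
    kernels, knames = _gabor_bank(tuple(frequencies), tuple(orientations), float(sigma))
    h, w = channel.shape
    for k in kernels:
        if k.shape[0] > h or k.shape[1] > w:
            raise ValueError(f"kernel {k.shape} larger than image {channel.shape}")
    kh, kw = kernels[0].shape  # one bank shares sigma, hence kernel size
    fh, fw = h + kh - 1, w + kw - 1
    Fc = rfft2(channel, s=(fh, fw))
    Fks = _gabor_bank_ffts(tuple(frequencies), tuple(orientations), float(sigma), (fh, fw))
    vals, names = [], []
    for Fk, kn in zip(Fks, knames):
        resp = irfft2(Fc * Fk, s=(fh, fw))
        # valid region of the full convolution
        resp = resp[kh - 1 : h, kw - 1 : w]
        vals.extend([np.abs(resp).mean(), (resp**2).mean()])
        names.extend([f"{prefix}{kn}_absmean", f"{prefix}{kn}_energy"])
    return FeatureVector(np.array(vals), names)


# ---------------------------------------------------------------------------
# Intensity and geometry
# ---------------------------------------------------------------------------

_INT_STATS = ("mean", "median", "sd", "q10", "q25", "q75", "q90", "min", "max")


def _channel_intensity(channel: np.ndarray) -> np.ndarray:
    q = np.quantile(channel, [0.1, 0.25, 0.75, 0.9])
    return np.array([
        channel.mean(), np.median(channel), channel.std(),
        q[0], q[1], q[2], q[3], channel.min(), channel.max(),
    ])


_GEOM_STATS = ("area", "perimeter", "eccentricity", "centroid_offset", "solidity", "extent")


def _otsu_geometry(channel: np.ndarray) -> np.ndarray:
    """Shape descriptors of the largest Otsu-foreground component.

    Degenerate masks (constant channel, empty foreground) yield the
    documented sentinel of all zeros.
    """
    try:
        thr = threshold_otsu(channel)
    except ValueError:
        return np.zeros(len(_GEOM_STATS))
    mask = channel > thr
    if not mask.any():
        return np.zeros(len(_GEOM_STATS))
    lab = cc_label(mask)
    props = max(regionprops(lab), key=lambda p: p.area)
    cy, cx = props.centroid
    c = (channel.shape[0] - 1) / 2.0
    offset = math.hypot(cy - c, cx - c)
    return np.array([
        float(props.area), float(props.perimeter), float(props.eccentricity),
        offset, float(props.solidity), float(props.extent),
    ])


def intensity_geometry_features(image: np.ndarray, prefix: str = "") -> FeatureVector:
    """Per-channel intensity statistics, Otsu-mask geometry, and
    cross-channel features (correlation, intensity ratio, green mass inside
    the red mask). Channel-tagged features are exactly symmetric under a
    channel swap."""
    image = np.asarray(image, dtype=np.float64)
    vals, names = [], []
    for ci, tag in enumerate(("r", "g")):
        vals.extend(_channel_intensity(image[ci]))
        names.extend(f"{tag}_{prefix}int_{s}" for s in _INT_STATS)
        vals.extend(_otsu_geometry(image[ci]))
        names.extend(f"{tag}_{prefix}geo_{s}" for s in _GEOM_STATS)
    red, green = image[0].ravel(), image[1].ravel()
    if red.std() > 0 and green.std() > 0:
        corr = float(np.corrcoef(red, green)[0, 1])
    else:
        corr = 0.0
    ratio = float(green.mean() / red.mean()) if red.mean() > 0 else 0.0
    try:
        thr = threshold_otsu(image[0])
        mask = image[0] > thr
        inside = float(image[1][mask].sum() / image[1].sum()) if mask.any() and image[1].sum() > 0 else 0.0
    except ValueError:
        inside = 0.0
    vals.extend([corr, ratio, inside])
    names.extend([f"rg_{prefix}corr", f"rg_{prefix}ratio", f"rg_{prefix}green_in_red"])
    return FeatureVector(np.array(vals), names)


# ---------------------------------------------------------------------------
# Whole-image feature vector and table
# ---------------------------------------------------------------------------


def _downsample2(channel: np.ndarray) -> np.ndarray:
    h, w = channel.shape
    return channel[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def cell_features(image: np.ndarray) -> FeatureVector:
    """The full feature vector of one 2-channel patch.

    Families: intensity + geometry (both scales), Haralick (both scales),
    Gabor (both scales), Zernike magnitudes (full scale), per channel where
    applicable. The resulting width (242) stands in for the classical
    several-hundred-feature screening pipelines.
    """
    image = np.asarray(image, dtype=np.float64)
    parts: list[FeatureVector] = []
    scales = {"s1_": image, "s2_": np.stack([_downsample2(image[0]), _downsample2(image[1])])}
    for stag, img in scales.items():
        parts.append(intensity_geometry_features(img, prefix=stag))
        for ci, ctag in enumerate(("r", "g")):
            parts.append(haralick_features(img[ci], prefix=f"{ctag}_{stag}"))
            parts.append(gabor_responses(img[ci], prefix=f"{ctag}_{stag}"))
    for ci, ctag in enumerate(("r", "g")):
        parts.append(zernike_moments(image[ci], radius=32.0, max_order=9, prefix=f"{ctag}_s1_"))
    values = np.concatenate([p.values for p in parts])
    names = [n for p in parts for n in p.names]
    return FeatureVector(values, names)


def feature_names() -> list[str]:
    """Stable column order of :func:`extract_feature_table`."""
    return cell_features(np.zeros((2, 64, 64))).names


def extract_feature_table(
    dataset: Dataset | Iterable[CellImage],
) -> tuple[pd.DataFrame, list[str]]:
    """One feature row per cell, indexed by cell id, fixed column order.

    Returns (table, rejects): cells whose pixels fail to produce features
    are skipped with a logged warning and listed in ``rejects``.
    """
    cells = dataset.cells() if isinstance(dataset, Dataset) else dataset
    rows, index, rejects = [], [], []
    names = None
    for cell in cells:
        try:
            fv = cell_features(cell.pixels)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("feature extraction failed for %s: %s", cell.cell_id, exc)
            rejects.append(cell.cell_id)
            continue
        if names is None:
            names = fv.names
        rows.append(fv.values)
        index.append(cell.cell_id)
    table = pd.DataFrame(np.array(rows), index=index, columns=names or feature_names())
    table.index.name = "cell_id"
    return table, rejects


# ---------------------------------------------------------------------------
# Random-forest baseline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RFGrid:
    """Hyperparameter grid for the baseline forest.

    ``features_per_split`` entries are either "sqrt" or fractions of the
    feature count (the classical absolute grid assumed a fixed 435-wide
    table; fractions transfer to any width).
    """

    n_trees: tuple[int, ...] = (50, 100, 250, 500, 1000)
    features_per_split: tuple = ("sqrt", 0.25, 0.5, 0.75, 1.0)
    min_node_size: tuple[int, ...] = (1, 2, 5, 10, 50)

    def __post_init__(self):
        if not (self.n_trees and self.features_per_split and self.min_node_size):
            raise ValueError("grid sets must be non-empty")

    @classmethod
    def small(cls) -> "RFGrid":
        """Desk-scale grid for end-to-end runs."""
        return cls(n_trees=(100,), features_per_split=("sqrt", 0.5), min_node_size=(1, 5))

    def __iter__(self):
        for t in self.n_trees:
            for f in self.features_per_split:
                for m in self.min_node_size:
                    yield t, f, m


@dataclass
class BaselineModel:
    model: RandomForestClassifier
    chosen: dict
    grid_results: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table.values)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(table.values)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.model.classes_)


def train_rf_baseline(
    table: pd.DataFrame,
    labels: Sequence[str],
    grid: RFGrid,
    val_table: pd.DataFrame,
    val_labels: Sequence[str],
    seed: int = 0,
    n_jobs: int = 1,
) -> BaselineModel:
    """Grid-search a random forest on validation accuracy.

    Every (n_trees, features_per_split, min_node_size) combination is fit on
    the training table and scored on the validation table; the best
    configuration (ties: first in grid order) is returned together with the
    full grid results.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    records = []
    best = (-1.0, None, None)
    for t, f, m in grid:
        clf = RandomForestClassifier(
            n_estimators=t, max_features=f, min_samples_leaf=m,
            random_state=seed, n_jobs=n_jobs,
        )
        clf.fit(table.values, labels)
        acc = float((clf.predict(val_table.values) == np.asarray(val_labels)).mean())
        records.append(dict(n_trees=t, features_per_split=f, min_node_size=m, val_accuracy=acc))
        if acc > best[0]:
            best = (acc, clf, dict(n_trees=t, features_per_split=f, min_node_size=m))
    return BaselineModel(
        model=best[1], chosen=best[2],
        grid_results=pd.DataFrame(records), feature_names=list(table.columns),
    )


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------


@dataclass
class QualityFilter:
    model: RandomForestClassifier
    cv_accuracy: float
    chosen: dict

    def predict_is_cell(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict(table.values) == "cell"

    def filter(self, table: pd.DataFrame) -> pd.DataFrame:
        """Return the rows classified as good-quality cells."""
        return table[self.predict_is_cell(table)]


def train_quality_filter(
    cell_features_table: pd.DataFrame,
    noncell_features_table: pd.DataFrame,
    cv_folds: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> QualityFilter:
    """Cell vs non-cell forest with cross-validated hyperparameter choice.

    The grid covers the number of features sampled at each split (2 plus
    quartile fractions of the width) and whether to downsample the majority
    good-cell class within every bootstrap sample (balanced subsampling).
    Accuracy is estimated by stratified ``cv_folds``-fold cross-validation;
    the winning configuration is refit on all data.
    """
    if len(cell_features_table) == 0 or len(noncell_features_table) == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([cell_features_table.values, noncell_features_table.values])
    y = np.array(["cell"] * len(cell_features_table) + ["noncell"] * len(noncell_features_table))
    if len(y) < cv_folds:
        raise ValueError(f"need at least {cv_folds} rows for {cv_folds}-fold CV")
    width = X.shape[1]
    fps_grid: list = [2] + [max(2, int(round(width * f))) for f in (0.25, 0.5, 0.75, 1.0)]
    best = (-1.0, None)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for fps in fps_grid:
        for downsample in (False, True):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=fps,
                class_weight="balanced_subsample" if downsample else None,
                random_state=seed, n_jobs=1,
            )
            acc = float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())
            if acc > best[0]:
                best = (acc, dict(features_per_split=fps, downsample=downsample))
    chosen = best[1]
    final = RandomForestClassifier(
        n_estimators=n_trees, max_features=chosen["features_per_split"],
        class_weight="balanced_subsample" if chosen["downsample"] else None,
        random_state=seed, n_jobs=1,
    )
    final.fit(X, y)
    return QualityFilter(model=final, cv_accuracy=best[0], chosen=chosen)


def select_quality_positives(
    manifest: pd.DataFrame,
    per_class: int = 100,
    seed: int = 0,
    scheme: str = "clean",
    correct_a: np.ndarray | None = None,
    correct_b: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sample positive (good-cell) examples for the quality filter.

    ``scheme="clean"`` samples ``per_class`` cells per class directly (the
    synthetic renders are clean by construction). ``scheme="both_correct"``
    restricts to cells classified correctly by both provided models before
    sampling, mirroring the double-agreement labeling used with real
    screens.
    """
    rng = np.random.default_rng(seed)
    pool = manifest
    if scheme == "both_correct":
        if correct_a is None or correct_b is None:
            raise ValueError("both_correct scheme needs correctness masks for both models")
        pool = manifest[np.asarray(correct_a) & np.asarray(correct_b)]
    parts = []
    for cls, group in pool.groupby("label"):
        take = min(per_class, len(group))
        parts.append(group.iloc[rng.permutation(len(group))[:take]])
    return pd.concat(parts).reset_index(drop=True)
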