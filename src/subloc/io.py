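"""File formats, configuration and logging.

Tabular outputs are TSV (UTF-8, '.' decimal). Images are stored as
two-page 16-bit grayscale TIFF (page 0 = red, page 1 = green) or as a pair
of 16-bit PNGs. Manifests are TSV with a small provenance header of
``#``-prefixed lines (format version, class vocabulary, seed).

Coordinates are row-major, origin top-left, 0-based throughout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synth import ALL_LABELS, PATCH, Dataset

logger = logging.getLogger("subloc")

MANIFEST_VERSION = "subloc-manifest v1"
MANIFEST_COLUMNS = ("cell_id", "image_path", "protein_id", "label", "fold", "quality")
VALID_FOLDS = ("train", "val", "test", "none")


def config_digest(obj: Any) -> str:
    """Short stable digest of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a 2x64x64 patch as a 2-page 16-bit TIFF or paired PNGs.

    PNG paths must contain the placeholder ``{channel}`` which is filled
    with ``red`` / ``green``; TIFF paths are used as-is. Values are rounded
    to the nearest integer and clipped to [0, 65535].
    """
    pixels = np.asarray(pixels)
    if pixels.shape != (2, PATCH, PATCH):
        raise ValueError(f"expected 2x{PATCH}x{PATCH} pixels, got {pixels.shape}")
    data = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() == ".png":
        if "{channel}" not in str(path):
            raise ValueError("paired-PNG path must contain a '{channel}' placeholder")
        for i, ch in enumerate(("red", "green")):
            Image.fromarray(data[i]).save(str(path).format(channel=ch))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r} (use .tif or .png)")


def load_image(path: str | Path) -> np.ndarray:
    """Load a 2-channel patch saved by :func:`save_image`, as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim != 3 or data.shape[0] != 2:
            raise ValueError(
                f"expected 2 pages of {PATCH}x{PATCH}, got array of shape {data.shape}"
            )
    elif path.suffix.lower() == ".png":
        if "{channel}" not in str(path):
            raise ValueError("paired-PNG path must contain a '{channel}' placeholder")
        pages = [
            np.asarray(Image.open(str(path).format(channel=ch)), dtype=np.uint16)
            for ch in ("red", "green")
        ]
        data = np.stack(pages)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if data.shape != (2, PATCH, PATCH):
        raise ValueError(f"expected shape (2, {PATCH}, {PATCH}), got {data.shape}")
    return data.astype(np.float64)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Check column set, cell-id uniqueness, fold vocabulary and the
    protein-disjointness of folds; raise ``ValueError`` naming offenders."""
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    dup = manifest["cell_id"][manifest["cell_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate cell_id values: {sorted(set(dup))[:5]}")
    bad_fold = set(manifest["fold"]) - set(VALID_FOLDS)
    if bad_fold:
        raise ValueError(f"invalid fold values {sorted(bad_fold)}")
    bad_label = set(manifest["label"]) - set(ALL_LABELS)
    if bad_label:
        raise ValueError(f"labels outside the class vocabulary: {sorted(bad_label)}")
    assigned = manifest[manifest["fold"] != "none"]
    folds_per_protein = assigned.groupby("protein_id")["fold"].nunique()
    offenders = folds_per_protein[folds_per_protein > 1]
    if len(offenders):
        raise ValueError(
            "folds are not protein-disjoint; offending proteins: "
            f"{list(offenders.index[:5])}"
        )


def write_manifest(
    manifest: pd.DataFrame, path: str | Path, classes=ALL_LABELS, seed: int | None = None
) -> None:
    validate_manifest(manifest)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {MANIFEST_VERSION}\n")
        fh.write(f"# classes: {','.join(classes)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        manifest.to_csv(fh, sep="\t", index=False)


def read_manifest(path: str | Path, check_images: bool = True) -> pd.DataFrame:
    """Read and validate a manifest TSV.

    With ``check_images=True`` every non-empty ``image_path`` must exist and
    parse to a 2x64x64 patch (only existence and parse of the first row's
    file is verified eagerly; the rest are checked for existence).
    """
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t", comment="#", dtype={"cell_id": str, "protein_id": str})
    if manifest.empty and set(MANIFEST_COLUMNS) <= set(manifest.columns):
        return manifest
    validate_manifest(manifest)
    manifest["quality"] = manifest["quality"].astype(bool)
    if check_images:
        paths = [p for p in manifest["image_path"] if isinstance(p, str) and p]
        base = path.parent
        for p in paths:
            full = (base / p) if not Path(p).is_absolute() else Path(p)
            probe = Path(str(full).format(channel="red")) if "{channel}" in str(full) else full
            if not probe.exists():
                raise ValueError(f"dangling image path {p!r}")
        if paths:
            load_image(base / paths[0] if not Path(paths[0]).is_absolute() else paths[0])
    return manifest


def write_dataset(dataset: Dataset, out_dir: str | Path, image_format: str = "tif") -> Path:
    """Write a Dataset's images and manifest under ``out_dir``.

    Returns the manifest path. Images land in ``out_dir/images/``.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    rel_paths = []
    for cell_id in manifest["cell_id"]:
        if image_format == "png":
            rel = f"images/{cell_id}_{{channel}}.png"
        else:
            rel = f"images/{cell_id}.tif"
        save_image(dataset.images[cell_id], out_dir / rel)
        rel_paths.append(rel)
    manifest["image_path"] = rel_paths
    mpath = out_dir / "manifest.tsv"
    write_manifest(manifest, mpath, classes=dataset.classes, seed=dataset.seed)
    return mpath


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a written dataset back into memory."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path, check_images=True)
    base = manifest_path.parent
    images = {
        row.cell_id: load_image(base / row.image_path)
        for row in manifest.itertuples()
    }
    classes = tuple(sorted(set(manifest["label"])))
    return Dataset(manifest=manifest, images=images, classes=classes, seed=-1)


def write_table(df: pd.DataFrame, path: str | Path, provenance: Mapping[str, Any] | None = None):
    """TSV writer adding a provenance header (config digest, seed, version)."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: Every recognised configuration key with its default. Nested by stage.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "subloc_out",
    "simulate": {
        "classes": "core",  # "core" | "transfer" | explicit list
        "cells_per_protein": 60,
        "proteins_per_class": 7,
        "fold_fractions": [0.72, 0.14, 0.14],
    },
    "train": {
        "scale": "small",  # "small" | "paper"
        "epochs": 4,
        "batch_size": 50,
    },
    "evaluate": {
        "n_boot": 2000,
    },
    "aggregate": {
        "prior": 1.0,
        "min_cells": 10,
        "top_k": 3,
    },
    "transfer": {
        "enabled": False,
        "sizes": [1, 3, 5, 10],
        "n_reps": 3,
    },
}


def _check_keys(cfg: Mapping, defaults: Mapping, prefix: str = "") -> None:
    for key, val in cfg.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {prefix + key!r}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(val, Mapping):
                raise ValueError(f"config key {prefix + key!r} must be a mapping")
            _check_keys(val, defaults[key], prefix=f"{prefix}{key}.")


def make_config(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge overrides into the documented defaults; unknown keys are
    rejected before any work happens (typo safety)."""
    overrides = overrides or {}
    _check_keys(overrides, DEFAULT_CONFIG)
    out = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in overrides.items():
        if isinstance(val, Mapping):
            out[key].update(val)
        else:
            out[key] = val
    return out
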