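"""Synthetic two-channel yeast microscopy generator.

Renders labeled 64x64 single-cell image patches whose spatial statistics
mimic the canonical budding-yeast localization archetypes: a red channel
carrying a cytosolic marker that fills the cell body, and a green channel
carrying the tagged protein's compartment pattern (nuclear disk, peripheral
ring, puncta, tubules, ...). Every downstream stage of the pipeline --
feature extraction, network training, population aggregation -- is testable
on these images without any external data.

The archetypes are parametric cartoons (disks, annuli, Gaussian puncta,
random-walk tubules), not optical simulations. Difficulty is controlled by
``RenderParams``: signal-to-background ratio, read noise, signal-scaled shot
noise, and a linear background gradient.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# Class vocabulary
# ---------------------------------------------------------------------------

#: The 12 core compartments, alphabetical (fixed output order everywhere).
CORE_CLASSES: tuple[str, ...] = (
    "cell_periphery",
    "cytoplasm",
    "endosome",
    "endoplasmic_reticulum",
    "golgi",
    "mitochondrion",
    "nuclear_periphery",
    "nucleolus",
    "nucleus",
    "peroxisome",
    "spindle_pole",
    "vacuole",
)

#: Four additional compartments held out for transfer-learning experiments.
TRANSFER_CLASSES: tuple[str, ...] = ("actin", "bud_neck", "lipid_particle", "microtubule")

NONCELL_LABEL = "nonCell"

ALL_LABELS: tuple[str, ...] = CORE_CLASSES + TRANSFER_CLASSES + (NONCELL_LABEL,)

PATCH = 64  #: side length of a patch, pixels
MAX_INTENSITY = 65535.0  #: 16-bit intensity ceiling on disk

_PUNCTATE_DEFAULTS: dict[str, tuple[int, int]] = {
    "endosome": (4, 8),
    "golgi": (2, 5),
    "peroxisome": (1, 3),
    "spindle_pole": (1, 2),
    "lipid_particle": (2, 6),
}


@dataclass(frozen=True)
class RenderParams:
    """Tunable knobs of the renderer.

    Intensities are in arbitrary fluorescence units on a 16-bit scale.
    ``signal_to_background`` must exceed 1 for good-quality cells; the
    ``low_signal`` artifact deliberately violates it.
    """

    cell_radius_range: tuple[float, float] = (15.0, 25.0)
    nucleus_radius_fraction: float = 0.34
    nucleus_fraction_jitter: tuple[float, float] = (0.85, 1.15)
    puncta_count_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_PUNCTATE_DEFAULTS)
    )
    signal_to_background: float = 5.0
    background_level: float = 1500.0
    background_gradient_amplitude: float = 400.0
    gaussian_sd: float = 150.0
    poisson_scaling: float = 8.0
    blur_sigma: float = 0.8
    #: per-cell multiplicative jitter of signal amplitude and background
    #: level, emulating expression-level and illumination variation
    brightness_jitter: tuple[float, float] = (0.5, 1.5)
    background_jitter: tuple[float, float] = (0.7, 1.3)
    #: per-cell jitter of the optical blur width (focus variation)
    blur_jitter: tuple[float, float] = (0.8, 1.15)
    #: fraction of the green signal spread diffusely through the cytoplasm
    #: (unincorporated tagged protein), sampled per cell
    diffuse_fraction_range: tuple[float, float] = (0.05, 0.35)

    def __post_init__(self) -> None:
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must be a non-empty positive range")
        for cls, (a, b) in self.puncta_count_range.items():
            if a > b or a < 0:
                raise ValueError(f"empty puncta count range for {cls!r}")
        if self.signal_to_background <= 1:
            raise ValueError("signal_to_background must exceed 1 for quality cells")


@dataclass
class CellImage:
    """One two-channel 64x64 intensity patch plus its metadata.

    ``pixels`` is float, shape (2, 64, 64), channel 0 = red cytosolic
    marker, channel 1 = green tagged protein. Values are non-negative.
    """

    pixels: np.ndarray
    label: str
    protein_id: str = ""
    fold: str = "none"
    quality: bool = True
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (2, PATCH, PATCH):
            raise ValueError(f"pixels must be 2x{PATCH}x{PATCH}, got {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}; valid labels: {ALL_LABELS}")
        if self.fold not in ("train", "val", "test", "none"):
            raise ValueError(f"invalid fold {self.fold!r}")


@dataclass(frozen=True)
class DatasetSpec:
    """Sampling design for a synthetic dataset.

    Folds are assigned to whole proteins (never to individual cells), so the
    train/validation/test folds are protein-disjoint by construction.
    """

    classes: tuple[str, ...] = CORE_CLASSES
    cells_per_protein: int = 20
    proteins_per_class: int = 5
    fold_fractions: tuple[float, float, float] = (0.72, 0.14, 0.14)
    seed: int = 0
    params: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        if abs(sum(self.fold_fractions) - 1.0) > 1e-9:
            raise ValueError(
                f"fold_fractions must sum to 1, got {sum(self.fold_fractions)!r}"
            )
        unknown = set(self.classes) - set(ALL_LABELS)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        if self.cells_per_protein < 1 or self.proteins_per_class < 1:
            raise ValueError("cells_per_protein and proteins_per_class must be >= 1")


# ---------------------------------------------------------------------------
# Seed derivation
# ---------------------------------------------------------------------------

_SEED_MIX = 0x9E3779B1  # golden-ratio multiplier; documented counter scheme


def derive_seed(master_seed: int, counter: int) -> int:
    """Per-cell seed: ``(master * 2654435761 + counter) mod 2**31``.

    A counter-based scheme so the i-th cell of a run is reproducible in
    isolation, independent of how many cells precede it.
    """
    return (master_seed * _SEED_MIX + counter) % (2**31)


# ---------------------------------------------------------------------------
# Geometry helpers (row-major, origin top-left, 0-based)
# ---------------------------------------------------------------------------

_YY, _XX = np.mgrid[0:PATCH, 0:PATCH].astype(np.float64)


def _disk(cy: float, cx: float, r: float, soft: float = 1.2) -> np.ndarray:
    """Soft-edged disk mask in [0, 1]."""
    d = np.hypot(_YY - cy, _XX - cx)
    return np.clip((r - d) / soft + 0.5, 0.0, 1.0)


def _annulus(cy: float, cx: float, r: float, width: float) -> np.ndarray:
    d = np.hypot(_YY - cy, _XX - cx)
    return np.exp(-0.5 * ((d - r) / (width / 2.0)) ** 2)


def _gauss_spot(cy: float, cx: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (((_YY - cy) ** 2 + (_XX - cx) ** 2) / sigma**2))


def _random_walk_tubule(
    rng: np.random.Generator,
    start: tuple[float, float],
    n_steps: int,
    step: float,
    turn_sd: float,
    heading: float | None = None,
    width: float = 1.2,
) -> np.ndarray:
    """Curvilinear thread rendered as a chain of Gaussian spots."""
    canvas = np.zeros((PATCH, PATCH))
    y, x = start
    theta = rng.uniform(0, 2 * np.pi) if heading is None else heading
    for _ in range(n_steps):
        canvas += _gauss_spot(y, x, width)
        theta += rng.normal(0.0, turn_sd)
        y += step * np.sin(theta)
        x += step * np.cos(theta)
    m = canvas.max()
    return canvas / m if m > 0 else canvas


@dataclass
class _CellGeometry:
    cy: float
    cx: float
    radius: float
    nuc_cy: float
    nuc_cx: float
    nuc_r: float

    @property
    def cell_mask(self) -> np.ndarray:
        return _disk(self.cy, self.cx, self.radius)

    @property
    def nucleus_mask(self) -> np.ndarray:
        return _disk(self.nuc_cy, self.nuc_cx, self.nuc_r)


def _sample_geometry(rng: np.random.Generator, params: RenderParams) -> _CellGeometry:
    lo, hi = params.cell_radius_range
    radius = rng.uniform(lo, hi)
    cy = PATCH / 2 - 0.5 + rng.normal(0, 2.0)
    cx = PATCH / 2 - 0.5 + rng.normal(0, 2.0)
    nuc_r = params.nucleus_radius_fraction * radius * rng.uniform(
        *params.nucleus_fraction_jitter
    )
    # nucleus off-center with random orientation, so nucleolar crescents vary
    off = rng.uniform(0.15, 0.45) * radius
    ang = rng.uniform(0, 2 * np.pi)
    return _CellGeometry(
        cy=cy,
        cx=cx,
        radius=radius,
        nuc_cy=cy + off * np.sin(ang),
        nuc_cx=cx + off * np.cos(ang),
        nuc_r=nuc_r,
    )


def _puncta(
    rng: np.random.Generator,
    geom: _CellGeometry,
    count_range: tuple[int, int],
    sigma: float,
    region: str = "cytoplasm",
    amp_range: tuple[float, float] = (0.7, 1.0),
    cluster_radius: float | None = None,
) -> np.ndarray:
    """k Gaussian puncta inside the cell.

    ``region`` confines spot centers: anywhere in the cytoplasm, or
    adjacent to the nuclear rim. ``cluster_radius`` draws all spots within
    that distance of one randomly placed cluster center (Golgi-like
    stacking).
    """
    k = int(rng.integers(count_range[0], count_range[1] + 1))
    canvas = np.zeros((PATCH, PATCH))
    placed: list[tuple[float, float]] = []
    min_sep = max(3.0, 2.4 * sigma)  # spots stay resolvable (countable)
    cl_y = cl_x = None
    if cluster_radius is not None:
        clearance = geom.nuc_r + 4.0  # clear of the nuclear rim niche
        for _attempt in range(50):
            r = geom.radius * np.sqrt(rng.uniform(0.1, 0.85))
            ang = rng.uniform(0, 2 * np.pi)
            cl_y, cl_x = geom.cy + r * np.sin(ang), geom.cx + r * np.cos(ang)
            if np.hypot(cl_y - geom.nuc_cy, cl_x - geom.nuc_cx) > clearance:
                break
    for _ in range(k):
        for _attempt in range(50):
            if cluster_radius is not None:
                y = cl_y + rng.normal(0, cluster_radius)
                x = cl_x + rng.normal(0, cluster_radius)
            else:
                r = geom.radius * np.sqrt(rng.uniform(0.0, 0.85))
                ang = rng.uniform(0, 2 * np.pi)
                y = geom.cy + r * np.sin(ang)
                x = geom.cx + r * np.cos(ang)
            d_nuc = np.hypot(y - geom.nuc_cy, x - geom.nuc_cx)
            if region == "cytoplasm" and d_nuc < geom.nuc_r + sigma:
                continue
            if region == "near_nucleus" and not (
                geom.nuc_r * 0.9 <= d_nuc <= geom.nuc_r * 1.15
            ):
                continue
            if placed and min(np.hypot(y - py, x - px) for py, px in placed) < min_sep:
                continue
            break
        placed.append((y, x))
        canvas += rng.uniform(*amp_range) * _gauss_spot(y, x, sigma)
    m = canvas.max()
    return canvas / m if m > 0 else canvas


# ---------------------------------------------------------------------------
# Archetype renderers (green-channel pattern in [0, 1])
# ---------------------------------------------------------------------------


def _green_pattern(
    label: str, geom: _CellGeometry, rng: np.random.Generator, params: RenderParams
) -> np.ndarray:
    cyto = np.clip(geom.cell_mask - geom.nucleus_mask, 0, 1)
    pr = params.puncta_count_range

    if label == "cell_periphery":
        return _annulus(geom.cy, geom.cx, geom.radius, 2.5)
    if label == "cytoplasm":
        return 0.9 * cyto
    if label == "endosome":
        return _puncta(rng, geom, pr["endosome"], sigma=1.1, amp_range=(0.5, 0.9))
    if label == "endoplasmic_reticulum":
        ring = _annulus(geom.nuc_cy, geom.nuc_cx, geom.nuc_r + 1.5, 2.0)
        strands = np.zeros((PATCH, PATCH))
        for _ in range(rng.integers(2, 4)):
            ang = rng.uniform(0, 2 * np.pi)
            start = (
                geom.nuc_cy + (geom.nuc_r + 1.5) * np.sin(ang),
                geom.nuc_cx + (geom.nuc_r + 1.5) * np.cos(ang),
            )
            strands += _random_walk_tubule(
                rng, start, n_steps=14, step=1.3, turn_sd=0.35, heading=ang, width=0.85
            )
        out = ring + 0.7 * np.clip(strands, 0, 1)
        return np.clip(out, 0, 1) * geom.cell_mask
    if label == "golgi":
        return _puncta(rng, geom, pr["golgi"], sigma=1.5, cluster_radius=4.5)
    if label == "mitochondrion":
        canvas = np.zeros((PATCH, PATCH))
        for _ in range(rng.integers(2, 5)):
            r0 = geom.radius * np.sqrt(rng.uniform(0.0, 0.6))
            a0 = rng.uniform(0, 2 * np.pi)
            start = (geom.cy + r0 * np.sin(a0), geom.cx + r0 * np.cos(a0))
            canvas += _random_walk_tubule(
                rng, start, n_steps=22, step=1.4, turn_sd=0.45, width=1.35
            )
        return np.clip(canvas, 0, 1) * geom.cell_mask
    if label == "nuclear_periphery":
        return _annulus(geom.nuc_cy, geom.nuc_cx, geom.nuc_r, 1.8)
    if label == "nucleolus":
        # round patch inside the nucleus, off-center; its absolute size
        # overlaps the nuclear disks of other cells, so the discriminating
        # cue is size and position relative to the cell's own nucleus
        ang = rng.uniform(0, 2 * np.pi)
        r_frac = rng.uniform(0.6, 0.8)
        off = (0.95 - r_frac) * geom.nuc_r
        return _disk(
            geom.nuc_cy + off * np.sin(ang),
            geom.nuc_cx + off * np.cos(ang),
            r_frac * geom.nuc_r,
        )
    if label == "nucleus":
        return geom.nucleus_mask
    if label == "peroxisome":
        return _puncta(rng, geom, pr["peroxisome"], sigma=1.0, amp_range=(0.55, 0.95))
    if label == "spindle_pole":
        return _puncta(rng, geom, pr["spindle_pole"], sigma=1.35, region="near_nucleus", amp_range=(0.9, 1.0))
    if label == "vacuole":
        # dark lumen with faint rim, offset from the nucleus
        ang = rng.uniform(0, 2 * np.pi)
        vr = rng.uniform(0.35, 0.5) * geom.radius
        vy = geom.cy - 0.4 * geom.radius * np.sin(ang)
        vx = geom.cx - 0.4 * geom.radius * np.cos(ang)
        rim = _annulus(vy, vx, vr, 2.0)
        lumen = _disk(vy, vx, vr - 1.0)
        return np.clip(0.55 * rim + 0.08 * lumen, 0, 1) * geom.cell_mask
    if label == "actin":
        # cortical patches plus a few cables
        patches = _puncta(rng, geom, (6, 12), sigma=1.0)
        cables = np.zeros((PATCH, PATCH))
        for _ in range(rng.integers(1, 3)):
            ang = rng.uniform(0, 2 * np.pi)
            start = (
                geom.cy + 0.7 * geom.radius * np.sin(ang),
                geom.cx + 0.7 * geom.radius * np.cos(ang),
            )
            cables += _random_walk_tubule(
                rng, start, n_steps=16, step=1.3, turn_sd=0.15, heading=ang + np.pi, width=0.9
            )
        return np.clip(patches + 0.5 * np.clip(cables, 0, 1), 0, 1) * geom.cell_mask
    if label == "bud_neck":
        # band at the mother-daughter junction: bud tangent to the cell edge
        ang = rng.uniform(0, 2 * np.pi)
        ny = geom.cy + geom.radius * np.sin(ang)
        nx = geom.cx + geom.radius * np.cos(ang)
        band = _gauss_spot(ny, nx, 2.2)
        # elongate the band perpendicular to the mother-bud axis
        perp = _gauss_spot(ny + 2.5 * np.cos(ang), nx - 2.5 * np.sin(ang), 1.8) + _gauss_spot(
            ny - 2.5 * np.cos(ang), nx + 2.5 * np.sin(ang), 1.8
        )
        out = band + 0.8 * perp
        return np.clip(out / out.max(), 0, 1)
    if label == "lipid_particle":
        return _puncta(rng, geom, pr["lipid_particle"], sigma=1.4)
    if label == "microtubule":
        canvas = np.zeros((PATCH, PATCH))
        ang = rng.uniform(0, 2 * np.pi)
        start = (
            geom.nuc_cy + geom.nuc_r * np.sin(ang),
            geom.nuc_cx + geom.nuc_r * np.cos(ang),
        )
        for _ in range(rng.integers(1, 4)):
            canvas += _random_walk_tubule(
                rng,
                start,
                n_steps=20,
                step=1.5,
                turn_sd=0.08,
                heading=ang + rng.normal(0, 0.4),
                width=0.9,
            )
        return np.clip(canvas, 0, 1) * geom.cell_mask
    raise ValueError(f"unknown label {label!r}; valid labels: {ALL_LABELS}")


# ---------------------------------------------------------------------------
# Noise model and assembly
# ---------------------------------------------------------------------------


def _background(rng: np.random.Generator, params: RenderParams) -> np.ndarray:
    """Flat background plus a random linear gradient."""
    ang = rng.uniform(0, 2 * np.pi)
    ramp = (_YY - PATCH / 2) * np.sin(ang) + (_XX - PATCH / 2) * np.cos(ang)
    ramp = ramp / (PATCH / 2)
    return params.background_level + params.background_gradient_amplitude * ramp * rng.uniform(
        0, 1
    )


def _apply_noise(
    clean: np.ndarray, rng: np.random.Generator, params: RenderParams
) -> np.ndarray:
    """Additive Gaussian read noise + signal-scaled shot noise, clipped to
    the 16-bit range."""
    read = rng.normal(0.0, params.gaussian_sd, clean.shape)
    shot = rng.normal(0.0, 1.0, clean.shape) * np.sqrt(
        np.maximum(clean, 0.0) * params.poisson_scaling
    )
    return np.clip(clean + read + shot, 0.0, MAX_INTENSITY)


def render_cell(
    label: str,
    params: RenderParams | None = None,
    seed: int = 0,
    noiseless: bool = False,
    return_masks: bool = False,
):
    """Render one labeled cell.

    The red channel fills the simulated cell body (cytosolic marker,
    excluded from the nucleus interior partially); the green channel renders
    the compartment archetype for ``label``, then the noise model is
    applied. Bit-identical output for identical ``(label, params, seed)``.

    Parameters
    ----------
    label
        Compartment name from the 12 core or 4 transfer classes.
    params
        Renderer knobs; defaults are the package's standard difficulty.
    seed
        Seed for all stochastic choices in this render.
    noiseless
        Skip the noise model (useful for oracle computations).
    return_masks
        Also return a dict of geometric masks (cell, nucleus, boundary,
        lumen, background) used by the separability summary statistics.
    """
    if label not in CORE_CLASSES + TRANSFER_CLASSES:
        raise ValueError(f"unknown label {label!r}; valid labels: {ALL_LABELS}")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    geom = _sample_geometry(rng, params)
    bg_scale = rng.uniform(*params.background_jitter)
    bg_r = _background(rng, params) * bg_scale
    bg_g = _background(rng, params) * bg_scale
    signal = (
        params.background_level
        * (params.signal_to_background - 1.0)
        * rng.uniform(*params.brightness_jitter)
    )

    cell = geom.cell_mask
    nuc = geom.nucleus_mask
    red_pattern = np.clip(cell - 0.5 * nuc, 0, 1)  # cytosolic marker, dimmer in nucleus
    green_pattern = _green_pattern(label, geom, rng, params)
    if label != "cytoplasm":
        # unincorporated tagged protein: diffuse cytosolic component
        diffuse = rng.uniform(*params.diffuse_fraction_range)
        cyto = np.clip(cell - nuc, 0, 1)
        green_pattern = (1.0 - diffuse) * green_pattern + diffuse * 0.9 * cyto

    blur = params.blur_sigma * rng.uniform(*params.blur_jitter)
    red = bg_r + 0.8 * signal * ndimage.gaussian_filter(red_pattern, blur)
    green = bg_g + signal * ndimage.gaussian_filter(green_pattern, blur)
    pixels = np.stack([red, green])
    if not noiseless:
        pixels = _apply_noise(pixels, rng, params)
    img = CellImage(pixels=np.clip(pixels, 0, MAX_INTENSITY), label=label, quality=True)
    if return_masks:
        boundary = _annulus(geom.cy, geom.cx, geom.radius, 2.5) > 0.5
        lumen = (_disk(geom.cy, geom.cx, 0.55 * geom.radius) > 0.5) & ~(nuc > 0.5)
        masks = {
            "cell": cell > 0.5,
            "nucleus": nuc > 0.5,
            "boundary": boundary,
            "lumen": lumen,
            "background": ~(cell > 0.25),
        }
        return img, masks
    return img


ARTIFACT_KINDS = ("empty", "low_signal", "debris")


def render_artifact(kind: str, seed: int = 0, params: RenderParams | None = None) -> CellImage:
    """Render a non-cell patch: empty area, low-signal cell, or debris.

    These emulate the segmentation failures and imaging artifacts that a
    quality filter must reject; all carry ``label="nonCell"`` and
    ``quality=False``.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; valid: {ARTIFACT_KINDS}")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)

    if kind == "empty":
        bg = np.stack([_background(rng, params), _background(rng, params)])
        pixels = _apply_noise(bg, rng, params)
    elif kind == "low_signal":
        weak = dataclasses.replace(params, signal_to_background=1.15)
        # reuse the cell renderer path with a crippled signal
        geom = _sample_geometry(rng, weak)
        bg_r = _background(rng, weak)
        bg_g = _background(rng, weak)
        signal = weak.background_level * (weak.signal_to_background - 1.0)
        red = bg_r + 0.8 * signal * ndimage.gaussian_filter(geom.cell_mask, weak.blur_sigma)
        green = bg_g + signal * ndimage.gaussian_filter(
            _green_pattern("cytoplasm", geom, rng, weak), weak.blur_sigma
        )
        pixels = _apply_noise(np.stack([red, green]), rng, weak)
    else:  # debris: bright red streaks lacking a cell-shaped component
        bg = np.stack([_background(rng, params), _background(rng, params)])
        streaks = np.zeros((PATCH, PATCH))
        for _ in range(rng.integers(2, 5)):
            start = (rng.uniform(0, PATCH), rng.uniform(0, PATCH))
            streaks += _random_walk_tubule(
                rng, start, n_steps=25, step=2.2, turn_sd=0.1, width=1.6
            )
        signal = params.background_level * (params.signal_to_background - 1.0)
        bg[0] += 1.2 * signal * np.clip(streaks, 0, 1)
        bg[1] += 0.15 * signal * np.clip(streaks, 0, 1) * (rng.random((PATCH, PATCH)) < 0.3)
        pixels = _apply_noise(bg, rng, params)

    return CellImage(
        pixels=np.clip(pixels, 0, MAX_INTENSITY), label=NONCELL_LABEL, quality=False
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """In-memory dataset: a manifest table plus pixel arrays keyed by cell id."""

    manifest: "pd.DataFrame"  # noqa: F821 — populated by generate_dataset
    images: dict[str, np.ndarray]
    classes: tuple[str, ...]
    seed: int

    def cells(self) -> Iterable[CellImage]:
        for row in self.manifest.itertuples():
            yield CellImage(
                pixels=self.images[row.cell_id],
                label=row.label,
                protein_id=row.protein_id,
                fold=row.fold,
                quality=bool(row.quality),
                cell_id=row.cell_id,
            )

    def subset(self, fold: str) -> "Dataset":
        sub = self.manifest[self.manifest["fold"] == fold].reset_index(drop=True)
        return Dataset(
            manifest=sub,
            images={c: self.images[c] for c in sub["cell_id"]},
            classes=self.classes,
            seed=self.seed,
        )

    def pixel_array(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(self.manifest["cell_id"]) if ids is None else list(ids)
        return np.stack([self.images[c] for c in ids])


def _assign_fold_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n proteins over 3 folds."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_dataset(spec: DatasetSpec) -> Dataset:
    """Generate a labeled dataset with protein-disjoint fold assignment.

    Each protein gets ``cells_per_protein`` cells, all sharing the
    protein's fold, so no protein appears in more than one of the
    training/validation/test folds. Per-cell seeds follow the documented
    counter scheme (:func:`derive_seed`), making regeneration reproducible.
    """
    import pandas as pd

    rows = []
    images: dict[str, np.ndarray] = {}
    counter = 0
    fold_names = ("train", "val", "test")
    for label in spec.classes:
        counts = _assign_fold_counts(spec.proteins_per_class, spec.fold_fractions)
        folds = [f for f, c in zip(fold_names, counts) for _ in range(c)]
        for p in range(spec.proteins_per_class):
            protein_id = f"{label}_p{p:03d}"
            fold = folds[p]
            for c in range(spec.cells_per_protein):
                cell_id = f"{protein_id}_c{c:03d}"
                img = render_cell(label, spec.params, seed=derive_seed(spec.seed, counter))
                counter += 1
                images[cell_id] = img.pixels
                rows.append(
                    dict(
                        cell_id=cell_id,
                        image_path="",
                        protein_id=protein_id,
                        label=label,
                        fold=fold,
                        quality=True,
                    )
                )
    manifest = pd.DataFrame(rows)
    return Dataset(manifest=manifest, images=images, classes=tuple(spec.classes), seed=spec.seed)


def generate_transfer_dataset(
    seed: int = 0,
    per_class_folds: tuple[int, int, int] = (1000, 500, 1000),
    cells_per_protein: int = 25,
    params: RenderParams | None = None,
) -> Dataset:
    """Dataset for the four held-out transfer classes.

    Defaults reproduce the canonical design of 1000 training, 500
    validation, and 1000 testing cells per class. Cells are grouped into
    proteins of ``cells_per_protein`` cells; proteins stay fold-disjoint.
    """
    import pandas as pd

    params = params or RenderParams()
    rows = []
    images: dict[str, np.ndarray] = {}
    counter = 0
    for label in TRANSFER_CLASSES:
        protein_counter = 0
        for fold, n_cells in zip(("train", "val", "test"), per_class_folds):
            done = 0
            while done < n_cells:
                take = min(cells_per_protein, n_cells - done)
                protein_id = f"{label}_p{protein_counter:03d}"
                protein_counter += 1
                for c in range(take):
                    cell_id = f"{protein_id}_c{c:03d}"
                    img = render_cell(label, params, seed=derive_seed(seed, counter))
                    counter += 1
                    images[cell_id] = img.pixels
                    rows.append(
                        dict(
                            cell_id=cell_id,
                            image_path="",
                            protein_id=protein_id,
                            label=label,
                            fold=fold,
                            quality=True,
                        )
                    )
                done += take
    manifest = pd.DataFrame(rows)
    return Dataset(
        manifest=manifest, images=images, classes=TRANSFER_CLASSES, seed=seed
    )


def generate_mixture_protein(
    labels: tuple[str, str],
    fraction: float,
    n_cells: int,
    seed: int = 0,
    params: RenderParams | None = None,
    protein_id: str = "mixture",
) -> list[CellImage]:
    """Cells of one protein that localizes to two compartments.

    Each cell is independently rendered from ``labels[0]`` with probability
    ``fraction``, else from ``labels[1]``; all share one ``protein_id``.
    Emulates genuinely dual-localized proteins (e.g. nucleus + cytoplasm).
    """
    if labels[0] == labels[1]:
        raise ValueError("mixture requires two distinct labels")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be strictly between 0 and 1")
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cells):
        label = labels[0] if rng.random() < fraction else labels[1]
        img = render_cell(label, params, seed=derive_seed(seed, i + 1))
        img.label = label
        img.protein_id = protein_id
        img.cell_id = f"{protein_id}_c{i:03d}"
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# Separability summary statistics
# ---------------------------------------------------------------------------

SUMMARY_STAT_NAMES = (
    "green_mean_nucleus",
    "green_mean_cytoplasm",
    "green_mean_boundary",
    "green_mean_lumen",
    "green_mean_background",
)


def summary_stats(label: str, params: RenderParams | None = None, seed: int = 0) -> np.ndarray:
    """Five masked mean green intensities of a noiseless render.

    Means over the nucleus, cytoplasm (cell minus nucleus minus boundary),
    boundary ring, mid-cell lumen zone, and background masks. A linear
    classifier on these five numbers separates the geometrically distinct
    archetypes, certifying that the synthetic classes are learnable.
    """
    img, masks = render_cell(label, params, seed, noiseless=True, return_masks=True)
    green = img.pixels[1]
    cyto = masks["cell"] & ~masks["nucleus"] & ~masks["boundary"]
    regions = [masks["nucleus"], cyto, masks["boundary"], masks["lumen"], masks["background"]]
    return np.array([green[m].mean() if m.any() else 0.0 for m in regions])
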