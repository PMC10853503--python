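"""Tile extraction, tissue filtering, offline augmentation, synthetic tiles.

Preprocessing mirrors the standard whole-frame workflow for H&E imagery:
square tiles are cropped from larger frames on a sliding grid with bounded
overlap, tiles with insufficient stained-tissue coverage are discarded, and
the surviving tiles are expanded offline with the dihedral transforms
(rotations by 90 and 180 degrees, horizontal and vertical flips).

The synthetic generator produces histology-like RGB tiles from four phenotype
classes (dense cellular, sparse cellular, stromal, background) by rasterizing
dark elliptical "nuclei" and pink fibrous "stroma" streaks on a tinted
background, with per-structure binary masks and a continuous coverage score
(fraction of pixels inside nuclei) that emulates a tumor-cellularity label.
It exists so every other module is testable without any dataset download; see
the methods note for what it does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

__all__ = [
    "TileSpec",
    "SyntheticTile",
    "extract_tiles",
    "tissue_coverage",
    "augment_deterministic",
    "generate_synthetic_dataset",
    "CLASS_NAMES",
]

CLASS_NAMES = ("dense_cellular", "sparse_cellular", "stromal", "background")

# HSV heuristic for "stained tissue": saturated and not near-white. The
# threshold pair excludes glass/background pixels in H&E imagery.
SATURATION_MIN = 0.07
VALUE_MAX = 0.95


@dataclass(frozen=True)
class TileSpec:
    """Cropping rules: tile side, overlap bound, minimum tissue coverage."""

    tile_size: int = 224
    max_overlap_fraction: float = 0.0
    min_tissue_coverage: float = 0.70

    def __post_init__(self):
        if not 0 <= self.max_overlap_fraction <= 0.5:
            raise ValueError(
                f"max_overlap_fraction {self.max_overlap_fraction} outside [0, 0.5]"
            )
        if not 0 <= self.min_tissue_coverage <= 1:
            raise ValueError("min_tissue_coverage outside [0, 1]")
        if self.tile_size < 1:
            raise ValueError("tile_size must be positive")


@dataclass
class SyntheticTile:
    """RGB tile + class label + per-structure masks + coverage score."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    class_label: str
    structure_masks: dict  # name -> (H, W) bool
    coverage_score: float

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0 <= self.coverage_score <= 1:
            raise ValueError("coverage score outside [0, 1]")


# -------------------------------------------------------------- extraction
def _grid_positions(dim: int, tile: int, stride: int) -> list[int]:
    positions = list(range(0, dim - tile + 1, stride))
    if positions[-1] != dim - tile:  # inward-shifted tail covers the edge
        positions.append(dim - tile)
    return positions


def extract_tiles(frame, spec: TileSpec):
    """Sliding-window crops of ``frame`` under ``spec``.

    Stride is ``tile_size * (1 - max_overlap_fraction)``; the final row and
    column are shifted inward so the frame edge is covered. Returns a list
    of ``(tile, (x, y))`` with 0-based half-open coordinates (x = column of
    the left edge, y = row of the top edge).
    """
    img = np.asarray(frame)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("frame must be an RGB (H, W, 3) array")
    h, w = img.shape[:2]
    t = spec.tile_size
    if h < t or w < t:
        raise ValueError(f"frame {w}x{h} smaller than tile size {t}")
    stride = max(1, int(round(t * (1.0 - spec.max_overlap_fraction))))
    out = []
    for y in _grid_positions(h, t, stride):
        for x in _grid_positions(w, t, stride):
            out.append((img[y : y + t, x : x + t], (x, y)))
    return out


def tissue_coverage(tile) -> float:
    """Fraction of pixels classified as stained tissue.

    A pixel counts as tissue iff its HSV saturation exceeds
    ``SATURATION_MIN`` and its value is below ``VALUE_MAX`` (pure white glass
    background fails both)."""
    img = np.asarray(tile, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("tile must be RGB")
    if img.max() > 1.5:
        img = img / 255.0
    hsv = skcolor.rgb2hsv(img)
    mask = (hsv[..., 1] > SATURATION_MIN) & (hsv[..., 2] < VALUE_MAX)
    return float(mask.mean())


def filter_tiles(tiles_with_coords, spec: TileSpec):
    """Keep tiles whose tissue coverage meets ``spec.min_tissue_coverage``."""
    return [
        (tile, xy)
        for tile, xy in tiles_with_coords
        if tissue_coverage(tile) >= spec.min_tissue_coverage
    ]


def augment_deterministic(tile) -> list[np.ndarray]:
    """Offline dataset expansion: identity, rot90, rot180, h-flip, v-flip.

    Returns the deduplicated list (size 1 for fully symmetric inputs, up to
    5 for generic ones). Distinct from the random multi-crop augmentation
    used online during self-distillation."""
    img = np.asarray(tile)
    if img.shape[0] != img.shape[1]:
        raise ValueError("rotation augmentation requires a square tile")
    variants = [
        img,
        np.rot90(img, 1),
        np.rot90(img, 2),
        img[:, ::-1],
        img[::-1, :],
    ]
    out: list[np.ndarray] = []
    for v in variants:
        if not any(np.array_equal(v, u) for u in out):
            out.append(v.copy())
    return out


# ----------------------------------------------------------- synthetic data
# Class-conditional generator settings. Blob (nucleus) count scales with
# tile area; colors approximate an H&E palette (hematoxylin purple nuclei,
# eosin pink stroma, pale pink tissue background, near-white glass).
_CLASS_PARAMS = {
    # blob density per 64x64 px, blob radius range (px, relative to 64),
    # n stroma streaks, background rgb
    "dense_cellular": dict(density=28.0, radius=(2.0, 4.0), streaks=0,
                           bg=(0.91, 0.79, 0.86)),
    "sparse_cellular": dict(density=7.0, radius=(2.0, 4.0), streaks=0,
                            bg=(0.93, 0.83, 0.89)),
    "stromal": dict(density=2.0, radius=(1.5, 3.0), streaks=7,
                    bg=(0.95, 0.84, 0.88)),
    "background": dict(density=0.0, radius=(1.5, 3.0), streaks=0,
                       bg=(0.985, 0.975, 0.98)),
}
_NUCLEUS_RGB = np.array([0.38, 0.22, 0.55])  # hematoxylin purple
_STROMA_RGB = np.array([0.91, 0.55, 0.70])  # eosin pink


def _raster_ellipse(mask, cy, cx, ry, rx, theta, yy, xx):
    ct, st = np.cos(theta), np.sin(theta)
    dy, dx = yy - cy, xx - cx
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    mask |= u * u + v * v <= 1.0


def _make_tile(class_label: str, tile_size: int, rng: np.random.Generator) -> SyntheticTile:
    p = _CLASS_PARAMS[class_label]
    h = w = tile_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    scale = tile_size / 64.0
    cell_mask = np.zeros((h, w), dtype=bool)
    stroma_mask = np.zeros((h, w), dtype=bool)

    n_blobs = rng.poisson(p["density"] * scale * scale)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r_lo, r_hi = p["radius"]
        ry = rng.uniform(r_lo, r_hi) * scale
        rx = ry * rng.uniform(0.6, 1.4)
        _raster_ellipse(cell_mask, cy, cx, ry, rx, rng.uniform(0, np.pi), yy, xx)

    for _ in range(p["streaks"]):
        # a fibrous streak: a thin, long, strongly anisotropic ellipse
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        length = rng.uniform(0.4, 0.9) * tile_size / 2
        thickness = rng.uniform(1.0, 2.5) * scale
        _raster_ellipse(
            stroma_mask, cy, cx, thickness, length, rng.uniform(0, np.pi), yy, xx
        )

    bg = np.array(p["bg"]) + rng.normal(0, 0.012, size=3)
    img = np.ones((h, w, 3)) * np.clip(bg, 0, 1)
    # background texture: low-amplitude smooth noise
    texture = rng.normal(0, 1, size=(h, w))
    k = max(3, int(3 * scale))
    kernel = np.ones(k) / k
    texture = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, texture
    )
    texture = np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, texture
    )
    img += texture[..., None] * 0.015
    img[stroma_mask] = _STROMA_RGB + rng.normal(0, 0.02, size=3)
    nucleus = np.clip(_NUCLEUS_RGB + rng.normal(0, 0.03, size=3), 0, 1)
    img[cell_mask] = nucleus
    img += rng.normal(0, 0.01, size=img.shape)  # sensor noise
    img = np.clip(img, 0.0, 1.0)
    coverage = float(cell_mask.mean())
    return SyntheticTile(
        image=img.astype(np.float32),
        class_label=class_label,
        structure_masks={"cell": cell_mask, "stroma": stroma_mask},
        coverage_score=coverage,
    )


def generate_synthetic_dataset(
    n_tiles: int,
    class_mix=None,
    tile_size: int = 64,
    seed: int = 0,
) -> list[SyntheticTile]:
    """Draw ``n_tiles`` histology-like tiles; reproducible under ``seed``.

    ``class_mix`` maps class name -> probability (must sum to 1); default is
    uniform over the four classes. Classes are separable by nucleus density
    and palette, and the coverage score varies continuously across tiles.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if class_mix is None:
        class_mix = {c: 1.0 / len(CLASS_NAMES) for c in CLASS_NAMES}
    names = list(class_mix)
    probs = np.array([class_mix[c] for c in names], dtype=np.float64)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("class_mix must be non-negative and sum to 1")
    unknown = set(names) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(names), size=n_tiles, p=probs)
    return [_make_tile(names[i], tile_size, rng) for i in labels]


def dataset_manifest(tiles: list[SyntheticTile]):
    """Rows (index, class label, coverage score) for a manifest CSV."""
    return [
        {"index": i, "class_label": t.class_label, "coverage_score": t.coverage_score}
        for i, t in enumerate(tiles)
    ]
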