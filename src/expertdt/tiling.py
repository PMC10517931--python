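"""Tile-grid extraction from raster images standing in for whole-slide images.

A slide is cut into a regular grid of square tiles (default 1000x1000 px),
each downscaled to the classifier input size (default 112x112). Tiles whose
mean intensity at source resolution exceeds a brightness threshold (default
210) are flagged as empty background and excluded from all classification
and voting. For training, rectangular ROI annotations — regions a
pathologist marked as homogeneous tissue — are gridded independently
(ROI-anchored) into labelled tiles.

Conventions: 0-based row-major indices, half-open [start, end) pixel
rectangles, partial border tiles dropped rather than padded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize

__all__ = [
    "TilingConfig",
    "TileGrid",
    "RoiAnnotation",
    "TileSet",
    "read_image",
    "load_annotations",
    "tile_image",
    "mark_background",
    "extract_training_tiles",
    "split_by_patient",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TilingConfig:
    """Geometry and background-removal parameters of the tiling step.

    tile_size_px
        Side of the square tile cut at source resolution (px).
    model_input_px
        Side after downscaling; the size every classifier sees (px).
    background_mean_threshold
        A tile is background iff its channel-averaged mean intensity at
        source resolution is strictly greater than this value (0-255 scale).
    """

    tile_size_px: int = 1000
    model_input_px: int = 112
    background_mean_threshold: float = 210.0

    def __post_init__(self) -> None:
        if not (self.tile_size_px >= self.model_input_px >= 1):
            raise ValueError(
                "need tile_size_px >= model_input_px >= 1, got "
                f"{self.tile_size_px} and {self.model_input_px}"
            )
        if not (0 <= self.background_mean_threshold <= 255):
            raise ValueError("background_mean_threshold must lie in [0, 255]")


@dataclass
class TileGrid:
    """Regular grid of downscaled tiles cut from one image.

    ``patches`` has shape (n_rows, n_cols, m, m) with m = model_input_px,
    intensities on the 0-255 scale; ``tile_means`` holds the channel-averaged
    mean of each tile at source resolution (the quantity the background rule
    thresholds); ``background_mask`` is True where a tile is excluded.
    """

    patches: np.ndarray
    tile_means: np.ndarray
    background_mask: np.ndarray
    config: TilingConfig
    image_id: str | None = None

    @property
    def n_rows(self) -> int:
        return self.patches.shape[0]

    @property
    def n_cols(self) -> int:
        return self.patches.shape[1]

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile_rect(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Source-pixel rectangle (y0, x0, y1, x1) of cell (row, col), half-open."""
        ts = self.config.tile_size_px
        return (row * ts, col * ts, (row + 1) * ts, (col + 1) * ts)

    def tissue_patches(self) -> tuple[np.ndarray, np.ndarray]:
        """Non-background patches as (k, m, m) plus their (row, col) indices."""
        keep = ~self.background_mask
        idx = np.argwhere(keep)
        return self.patches[keep], idx


@dataclass(frozen=True)
class RoiAnnotation:
    """Rectangular region of homogeneous tissue on one image.

    Coordinates are half-open pixel intervals [x0, x1) x [y0, y1).
    """

    image: str
    x0: int
    y0: int
    x1: int
    y1: int
    label: str

    def __post_init__(self) -> None:
        from .labels import ROI_LABELS

        if self.label not in ROI_LABELS:
            raise ValueError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("ROI rectangle must have positive extent")


@dataclass
class TileSet:
    """Labelled training tiles with their provenance.

    ``patches``: (n, m, m) float array on the 0-255 scale; ``labels`` and
    ``patients``: length-n object arrays of strings.
    """

    patches: np.ndarray
    labels: np.ndarray
    patients: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.patients = np.asarray(self.patients, dtype=object)
        if not (len(self.patches) == len(self.labels) == len(self.patients)):
            raise ValueError("patches, labels and patients must share length")

    def __len__(self) -> int:
        return len(self.patches)

    def subset(self, index: np.ndarray) -> "TileSet":
        return TileSet(self.patches[index], self.labels[index], self.patients[index])

    @staticmethod
    def concat(parts: Sequence["TileSet"]) -> "TileSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("nothing to concatenate")
        return TileSet(
            np.concatenate([p.patches for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.patients for p in parts]),
        )


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG or TIFF as a grayscale or RGB numpy array."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return np.asarray(im)


def load_annotations(path: str | Path) -> list[RoiAnnotation]:
    """Load ROI annotations from a JSON list of {image, x0, y0, x1, y1, label}."""
    records = json.loads(Path(path).read_text())
    return [RoiAnnotation(**rec) for rec in records]


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Channel-averaged intensity image as float64."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D or 3-channel image, got shape {arr.shape}")
    return arr


def tile_image(
    image: np.ndarray, config: TilingConfig, image_id: str | None = None
) -> TileGrid:
    """Cut an image into its complete-tile grid and flag background.

    The grid covers floor(height / tile) rows by floor(width / tile) columns;
    right/bottom remainders are dropped. Each tile is downscaled to the model
    input size with anti-aliased (area-style) interpolation. Raises if the
    image cannot hold even a single tile.
    """
    gray = _to_gray(image)
    ts, ip = config.tile_size_px, config.model_input_px
    h, w = gray.shape
    if h < ts or w < ts:
        raise ValueError(
            f"image too small for tiling: {h}x{w} px against tile size {ts}"
        )
    n_rows, n_cols = h // ts, w // ts
    patches = np.empty((n_rows, n_cols, ip, ip), dtype=np.float32)
    means = np.empty((n_rows, n_cols), dtype=np.float64)
    for r in range(n_rows):
        for c in range(n_cols):
            tile = gray[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts]
            means[r, c] = tile.mean()
            if ts == ip:
                patches[r, c] = tile
            else:
                patches[r, c] = resize(
                    tile, (ip, ip), anti_aliasing=True, preserve_range=True
                )
    grid = TileGrid(
        patches=patches,
        tile_means=means,
        background_mask=np.zeros((n_rows, n_cols), dtype=bool),
        config=config,
        image_id=image_id,
    )
    return mark_background(grid, config)


def mark_background(grid: TileGrid, config: TilingConfig) -> TileGrid:
    """Flag tiles whose source-resolution mean intensity is strictly above
    the background threshold; a tile at exactly the threshold counts as
    tissue."""
    mask = grid.tile_means > config.background_mean_threshold
    return TileGrid(grid.patches, grid.tile_means, mask, config, grid.image_id)


def extract_training_tiles(
    images: Mapping[str, np.ndarray],
    annotations: Iterable[RoiAnnotation],
    config: TilingConfig,
    patient_of: Mapping[str, str] | None = None,
) -> TileSet:
    """Grid every ROI into labelled tiles (the ROI-cropping procedure).

    Each ROI is tiled independently, anchored at its own top-left corner, so
    no emitted tile crosses the ROI boundary. Background-flagged tiles inside
    ROIs are discarded. ``patient_of`` maps image id to patient id; when
    omitted the image id doubles as the patient id.
    """
    patches: list[np.ndarray] = []
    labels: list[str] = []
    patients: list[str] = []
    for ann in annotations:
        if ann.image not in images:
            raise KeyError(f"annotation references unknown image {ann.image!r}")
        image = images[ann.image]
        h, w = image.shape[:2]
        if not (0 <= ann.x0 and ann.x1 <= w and 0 <= ann.y0 and ann.y1 <= h):
            raise ValueError(
                f"ROI {ann} exceeds image bounds {h}x{w} of {ann.image!r}"
            )
        roi = image[ann.y0 : ann.y1, ann.x0 : ann.x1]
        if roi.shape[0] < config.tile_size_px or roi.shape[1] < config.tile_size_px:
            logger.warning(
                "ROI %s on %s smaller than one tile (%d px); no tiles emitted",
                ann.label, ann.image, config.tile_size_px,
            )
            continue
        grid = tile_image(roi, config, image_id=ann.image)
        kept, _ = grid.tissue_patches()
        pid = patient_of[ann.image] if patient_of is not None else ann.image
        for patch in kept:
            patches.append(patch)
            labels.append(ann.label)
            patients.append(pid)
    if not patches:
        return TileSet(
            np.empty((0, config.model_input_px, config.model_input_px), np.float32),
            np.empty((0,), object),
            np.empty((0,), object),
        )
    return TileSet(np.stack(patches), np.array(labels, object), np.array(patients, object))


def split_by_patient(
    tiles: TileSet, fraction: float = 0.75, seed: int = 0
) -> tuple[TileSet, TileSet]:
    """Partition tiles into train/validation at the *patient* level.

    All tiles of one patient land on the same side; the split is reproducible
    under ``seed``. ``fraction`` is the share of patients assigned to the
    training side (rounded, but both sides keep at least one patient).
    """
    patients = np.array(sorted(set(tiles.patients.tolist())), dtype=object)
    if len(patients) < 2:
        raise ValueError("patient-level split needs at least 2 patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(fraction * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = set(patients[order[:n_train]].tolist())
    in_train = np.array([p in train_ids for p in tiles.patients])
    return tiles.subset(in_train), tiles.subset(~in_train)
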