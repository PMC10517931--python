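"""Seeded synthetic cohorts with the statistical structure the method assumes.

Each synthetic "slide" is a grayscale raster composed of a near-white empty
margin, a not-tumor tissue region, and a tumor region textured according to
the patient's subtype. Class textures are band-limited Gaussian random
fields parameterized by spatial correlation length and contrast, arranged
in a two-level hierarchy that mirrors the clinical difficulty structure:

* the correlation length separates the two super-groups (ccRCC, papRCC)
  vs (chrRCC, ONCO) at strength ``delta_between`` — the easy axis;
* the contrast separates the two subtypes within each pair at strength
  ``delta_within`` — the hard axis (at ``delta_within = 0`` the within-pair
  textures are drawn from identical distributions).

The generator makes no attempt at visual H&E realism; it provides exactly
the features the pipeline consumes — distinguishable textures, spatial
tumor/not-tumor structure, bright background, multi-slide patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .labels import (
    CCRCC,
    CHRRCC,
    FIBER,
    NECROSIS,
    NORMAL_PARENCHYMA,
    NOT_TUMOR_TISSUES,
    ONCO,
    PAPRCC,
    ROI_LABELS,
    SUBTYPES,
)
from .tiling import RoiAnnotation, TilingConfig

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "Cohort",
    "class_texture",
    "generate_cohort",
    "make_ambiguous_patient",
]

logger = logging.getLogger(__name__)

# Texture family base parameters: correlation length (px at source
# resolution) and contrast (gray-level std) of the random field.
_BASE_ELL = 4.0
_BASE_SIGMA = 24.0
_TUMOR_MEAN = 135.0

# Not-tumor tissues: distinct means/textures, all safely below the
# background brightness threshold.
_NT_PARAMS = {
    FIBER: (185.0, 12.0, 6.0),
    NECROSIS: (105.0, 25.0, 2.0),
    NORMAL_PARENCHYMA: (152.0, 34.0, 3.0),
}
_BACKGROUND_PARAMS = (250.0, 3.0, 1.0)

#: Maximum slides per patient when sampling the truncated geometric law.
_MAX_SLIDES = 6

# Multiplicative lognormal jitter (log-space sd) on a region's contrast and
# correlation length: the within-class variability that the separability
# deltas compete against. Without it any delta > 0 would be trivially
# separable and the between/within difficulty hierarchy would collapse.
_SIGMA_JITTER = 0.25
_ELL_JITTER = 0.12

#: Within-pair partner in the opposite super-group (used by the ambiguous
#: patient generator).
_CROSS_PAIR = {CCRCC: CHRRCC, PAPRCC: ONCO, CHRRCC: CCRCC, ONCO: PAPRCC}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate the clinical setting this pipeline targets: ~2.2
    slides per patient, ~70% of annotated tissue tumorous, a 60/40
    patient-level train/test split, and a texture hierarchy in which the
    super-group split is much easier than the within-pair splits
    (``delta_between >> delta_within``). Geometry is scaled down (64 px
    tiles on 448 px images) so full runs stay CPU-fast.
    """

    n_per_subtype: int = 10
    slides_mean: float = 2.2
    image_size: int = 448
    tile_size_px: int = 64
    model_input_px: int = 32
    background_mean_threshold: float = 210.0
    delta_between: float = 2.0
    delta_within: float = 0.3
    tumor_fraction: float = 0.70
    margin_fraction: float = 0.15
    noise_level: float = 6.0
    train_ratio: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_subtype < 1:
            raise ValueError("need at least one patient per subtype")
        for name in ("tumor_fraction", "margin_fraction", "train_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.margin_fraction >= 1.0 or self.tumor_fraction > 1.0:
            raise ValueError("impossible geometry: fractions exceed the image")
        if self.delta_between < 0 or self.delta_within < 0:
            raise ValueError("separability deltas must be non-negative")
        if self.image_size < self.tile_size_px:
            raise ValueError("image_size must hold at least one tile")

    @property
    def tiling(self) -> TilingConfig:
        return TilingConfig(
            tile_size_px=self.tile_size_px,
            model_input_px=self.model_input_px,
            background_mean_threshold=self.background_mean_threshold,
        )


@dataclass
class SyntheticPatient:
    """One synthetic patient: images, ground-truth masks and annotations.

    ``masks[image_id]`` maps {'tumor', 'not_tumor', 'background'} to boolean
    arrays that partition the image exactly.
    """

    patient_id: str
    subtype: str
    images: dict[str, np.ndarray]
    masks: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    annotations: list[RoiAnnotation] = field(default_factory=list)
    split: str | None = None


@dataclass
class Cohort:
    train: list[SyntheticPatient]
    test: list[SyntheticPatient]
    tiling: TilingConfig
    config: CohortConfig | None = None

    @property
    def patients(self) -> list[SyntheticPatient]:
        return list(self.train) + list(self.test)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "image": img,
                "split": p.split,
                "true_subtype": p.subtype,
            }
            for p in self.patients
            for img in p.images
        ]
        return pd.DataFrame(rows, columns=["patient_id", "image", "split", "true_subtype"])

    def truth(self, split: str | None = None) -> dict[str, str]:
        pats = {"train": self.train, "test": self.test}.get(split, self.patients)
        return {p.patient_id: p.subtype for p in pats}


def _texture_params(
    label: str, delta_between: float, delta_within: float
) -> tuple[float, float, float]:
    """(mean, contrast, correlation length) of a tissue label's texture."""
    if label in SUBTYPES:
        coarse_pair = label in (CCRCC, PAPRCC)
        # contrast direction is opposed across the two pairs, so only the
        # expert super-class layout admits a single clean separating axis
        high_contrast = label in (CCRCC, ONCO)
        ell = _BASE_ELL * (1.0 + delta_between) if coarse_pair else _BASE_ELL / (
            1.0 + delta_between
        )
        sigma = _BASE_SIGMA * (1.0 + delta_within) if high_contrast else _BASE_SIGMA / (
            1.0 + delta_within
        )
        return _TUMOR_MEAN, sigma, ell
    if label in _NT_PARAMS:
        return _NT_PARAMS[label]
    raise ValueError(f"unknown tissue label {label!r}")


def _random_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean: float,
    sigma: float,
    ell: float,
    noise_level: float = 0.0,
    jitter: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    if jitter != (0.0, 0.0):
        sigma = sigma * float(np.exp(jitter[0] * rng.standard_normal()))
        ell = ell * float(np.exp(jitter[1] * rng.standard_normal()))
    field = gaussian_filter(rng.standard_normal(shape), sigma=ell, mode="reflect")
    sd = field.std()
    if sd > 0:
        field /= sd
    img = mean + sigma * field
    if noise_level > 0:
        img = img + noise_level * rng.standard_normal(shape)
    return np.clip(img, 0.0, 255.0)


def class_texture(
    label: str,
    delta_between: float,
    delta_within: float,
    seed: int,
    size: tuple[int, int] = (64, 64),
    noise_level: float = 0.0,
) -> np.ndarray:
    """Procedural texture patch for one tissue label (uint8 grayscale).

    Deterministic under ``seed``; at ``delta_within = 0`` the two members
    of each super-group share the identical generating distribution.
    """
    if label not in ROI_LABELS:
        raise ValueError(f"unknown tissue label {label!r}")
    mean, sigma, ell = _texture_params(label, delta_between, delta_within)
    rng = np.random.default_rng(seed)
    return _random_field(
        rng, size, mean, sigma, ell, noise_level, jitter=(_SIGMA_JITTER, _ELL_JITTER)
    ).astype(np.uint8)


def _background(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    mean, sigma, ell = _BACKGROUND_PARAMS
    # clipped near-white so any complete background tile exceeds the 210 rule
    return np.clip(_random_field(rng, shape, mean, sigma, ell), 242.0, 255.0)


def _compose_image(
    config: CohortConfig,
    rng: np.random.Generator,
    tumor_textures: Sequence[tuple[str, float]],
) -> tuple[np.ndarray, dict[str, np.ndarray], list[tuple[int, int, int, int, str]]]:
    """Build one slide image.

    ``tumor_textures`` lists (subtype, area share) pairs that tile the tumor
    region side by side. Returns the uint8 image, the ground-truth masks,
    and the region rectangles (y0, x0, y1, x1, label) for annotation.
    """
    size = config.image_size
    ts = config.tile_size_px
    # Region boundaries snap to the tile grid: at real scale border tiles
    # (partial tissue) are a negligible share of the thousands of tiles per
    # slide, so the scaled-down cohort keeps tiles texture-pure rather than
    # letting a 7x7 grid be dominated by boundary mixtures.
    m = int(np.ceil(config.margin_fraction * size / 2 / ts)) * ts if (
        config.margin_fraction > 0
    ) else 0
    n_tissue = (size - 2 * m) // ts
    if n_tissue < 1:
        raise ValueError(
            "impossible geometry: margins leave no room for a tissue tile"
        )
    img = _background(rng, (size, size))
    t0 = m
    t1 = m + n_tissue * ts  # tissue bounds, both axes

    tumor_mask = np.zeros((size, size), dtype=bool)
    nt_mask = np.zeros((size, size), dtype=bool)
    rects: list[tuple[int, int, int, int, str]] = []

    horizontal = bool(rng.integers(0, 2))  # split axis of tumor vs not-tumor
    # stochastic rounding keeps the expected tumor share at tumor_fraction
    frac_tiles = config.tumor_fraction * n_tissue
    n_tumor = int(frac_tiles) + int(rng.random() < (frac_tiles % 1))
    n_tumor = min(max(n_tumor, 1), n_tissue)
    if n_tissue >= 2:
        n_tumor = min(n_tumor, n_tissue - 1)  # keep a not-tumor strip
    tumor_extent = n_tumor * ts
    nt_label = str(rng.choice(NOT_TUMOR_TISSUES))

    def paste(y0: int, x0: int, y1: int, x1: int, label: str) -> None:
        mean, sigma, ell = (
            _texture_params(label, config.delta_between, config.delta_within)
            if label in ROI_LABELS
            else _BACKGROUND_PARAMS
        )
        img[y0:y1, x0:x1] = _random_field(
            rng,
            (y1 - y0, x1 - x0),
            mean,
            sigma,
            ell,
            config.noise_level,
            jitter=(_SIGMA_JITTER, _ELL_JITTER),
        )
        rects.append((y0, x0, y1, x1, label))

    if horizontal:
        split = t0 + tumor_extent
        tumor_box = (t0, t0, split, t1)
        nt_box = (split, t0, t1, t1)
    else:
        split = t0 + tumor_extent
        tumor_box = (t0, t0, t1, split)
        nt_box = (t0, split, t1, t1)

    # tumor region, possibly shared between several subtype textures
    ty0, tx0, ty1, tx1 = tumor_box
    if ty1 > ty0 and tx1 > tx0:
        shares = np.array([s for _, s in tumor_textures], dtype=float)
        shares = shares / shares.sum()
        # split the tumor box along its longer side
        along_rows = (ty1 - ty0) >= (tx1 - tx0)
        length = (ty1 - ty0) if along_rows else (tx1 - tx0)
        # sub-region cuts snap to tile boundaries too
        cuts = np.round(np.cumsum(shares) * (length / ts)).astype(int) * ts
        cuts[-1] = length
        start = 0
        for (subtype, _), stop in zip(tumor_textures, cuts):
            if stop <= start:
                continue
            if along_rows:
                box = (ty0 + start, tx0, ty0 + stop, tx1)
            else:
                box = (ty0, tx0 + start, ty1, tx0 + stop)
            paste(*box, subtype)
            tumor_mask[box[0] : box[2], box[1] : box[3]] = True
            start = stop
    ny0, nx0, ny1, nx1 = nt_box
    if ny1 > ny0 and nx1 > nx0:
        paste(ny0, nx0, ny1, nx1, nt_label)
        nt_mask[ny0:ny1, nx0:nx1] = True

    masks = {
        "tumor": tumor_mask,
        "not_tumor": nt_mask,
        "background": ~(tumor_mask | nt_mask),
    }
    return img.astype(np.uint8), masks, rects


def _n_slides(config: CohortConfig, rng: np.random.Generator) -> int:
    p = 1.0 / max(config.slides_mean, 1.0)
    return int(min(rng.geometric(p), _MAX_SLIDES))


def _build_patient(
    patient_id: str,
    subtype: str,
    config: CohortConfig,
    seed_seq: np.random.SeedSequence,
    with_annotations: bool,
    tumor_textures: Sequence[tuple[str, float]] | None = None,
) -> SyntheticPatient:
    rng = np.random.default_rng(seed_seq)
    n_slides = _n_slides(config, rng)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, dict[str, np.ndarray]] = {}
    annotations: list[RoiAnnotation] = []
    textures = tumor_textures or [(subtype, 1.0)]
    for s in range(n_slides):
        image_id = f"{patient_id}_s{s}"
        img, mk, rects = _compose_image(config, rng, textures)
        images[image_id] = img
        masks[image_id] = mk
        if with_annotations:
            for y0, x0, y1, x1, label in rects:
                if (y1 - y0) >= config.tile_size_px and (x1 - x0) >= config.tile_size_px:
                    annotations.append(
                        RoiAnnotation(
                            image=image_id, x0=x0, y0=y0, x1=x1, y1=y1, label=label
                        )
                    )
    return SyntheticPatient(
        patient_id=patient_id,
        subtype=subtype,
        images=images,
        masks=masks,
        annotations=annotations,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full train/test cohort under the config's master seed.

    Patients are split train/test per subtype at ``train_ratio`` (60/40 by
    default); training patients carry ROI annotations, test patients are
    evaluated from their whole images. Regeneration with the same config is
    byte-identical.
    """
    root_ss = np.random.SeedSequence(config.seed)
    patient_seeds = root_ss.spawn(len(SUBTYPES) * config.n_per_subtype)
    train: list[SyntheticPatient] = []
    test: list[SyntheticPatient] = []
    k = 0
    for subtype in SUBTYPES:
        n_train = int(round(config.train_ratio * config.n_per_subtype))
        n_train = min(max(n_train, 1), config.n_per_subtype)
        if config.n_per_subtype >= 2:
            n_train = min(n_train, config.n_per_subtype - 1)
        for i in range(config.n_per_subtype):
            is_train = i < n_train
            patient = _build_patient(
                patient_id=f"P_{subtype}_{i:02d}",
                subtype=subtype,
                config=config,
                seed_seq=patient_seeds[k],
                with_annotations=is_train,
            )
            patient.split = "train" if is_train else "test"
            (train if is_train else test).append(patient)
            k += 1
    logger.info(
        "generated cohort: %d train / %d test patients, %d images",
        len(train), len(test), sum(len(p.images) for p in train + test),
    )
    return Cohort(train=train, test=test, tiling=config.tiling, config=config)


def make_ambiguous_patient(
    config: CohortConfig, balance: float, seed: int, subtype: str = CCRCC
) -> SyntheticPatient:
    """Patient whose tumor area mixes the two super-group textures.

    ``balance`` is the share of tumor area carrying the patient's own
    subtype texture; the remainder carries the corresponding subtype of the
    *other* super-group. balance=0.5 yields near-equal super-group tile
    counts (exercising the node-pruning rule); balance=1.0 is an ordinary
    single-texture patient.
    """
    if not (0.0 <= balance <= 1.0):
        raise ValueError("balance must lie in [0, 1]")
    partner = _CROSS_PAIR[subtype]
    if balance >= 1.0:
        textures = [(subtype, 1.0)]
    elif balance <= 0.0:
        textures = [(partner, 1.0)]
    else:
        textures = [(subtype, balance), (partner, 1.0 - balance)]
    patient = _build_patient(
        patient_id=f"P_ambiguous_{subtype}_b{balance:.2f}",
        subtype=subtype,
        config=config,
        seed_seq=np.random.SeedSequence(seed),
        with_annotations=False,
        tumor_textures=textures,
    )
    patient.split = "test"
    return patient
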