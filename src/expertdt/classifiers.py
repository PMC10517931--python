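"""Binary classifier contract and the balanced per-stage training procedure.

Every stage of the decision tree is a binary classifier behind a minimal
contract: ``fit(patches, y)``, ``predict(patches) -> {0,1}`` and
``predict_score(patches) -> [0,1]`` with the consistency rule
predict = (score >= 0.5). Any backbone honoring the contract can be plugged
in; the shipped default extracts deterministic texture statistics from each
tile and fits a regularized logistic model, which keeps the full pipeline
CPU-fast and seed-reproducible. Before fitting, the two classes are
balanced by random under-sampling of the majority class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TrainingConfig",
    "BinaryClassifier",
    "Stage",
    "texture_features",
    "TextureBackbone",
    "MulticlassTextureBackbone",
    "balance_by_undersampling",
    "fit_stage",
    "default_backbone_factory",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Training knobs. ``max_epochs``, ``patience`` and ``batch_size`` are
    advisory — honored only by iterative backbones; the default closed-form
    logistic backbone uses only ``seed``."""

    seed: int = 0
    max_epochs: int = 150
    patience: int = 20
    batch_size: int = 128

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.patience, self.batch_size) <= 0:
            raise ValueError("max_epochs, patience and batch_size must be positive")


@runtime_checkable
class BinaryClassifier(Protocol):
    """Behavioral contract every tree-stage backbone must satisfy."""

    def fit(self, patches: np.ndarray, y: np.ndarray) -> "BinaryClassifier": ...

    def predict(self, patches: np.ndarray) -> np.ndarray: ...

    def predict_score(self, patches: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class Stage:
    """One binary decision: ``group0`` labels vs ``group1`` labels.

    Encoding is fixed per stage so scores are comparable across runs:
    a tile whose label belongs to ``group1`` trains as class 1.
    """

    name: str
    group0: tuple[str, ...]
    group1: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.group0) & set(self.group1):
            raise ValueError(f"stage {self.name}: groups overlap")

    def encode(self, label: str) -> int | None:
        """0/1 for labels in the stage's groups, None for out-of-stage labels."""
        if label in self.group1:
            return 1
        if label in self.group0:
            return 0
        return None

    def group_name(self, binary: int) -> str:
        members = self.group1 if binary else self.group0
        return "+".join(members)


# --------------------------------------------------------------------------
# Texture features

_N_HIST_BINS = 12


def texture_features(patches: np.ndarray) -> np.ndarray:
    """Deterministic texture statistics per tile.

    For each (m, m) patch on the 0-255 scale: a 12-bin intensity histogram,
    first two moments, gradient-magnitude moments, Laplacian energy, and the
    low/mid/high radial-frequency energy fractions of the power spectrum.
    The frequency bands carry the spatial correlation length of the texture;
    the histogram and moments carry its contrast and brightness.
    """
    P = np.asarray(patches, dtype=np.float64)
    if P.ndim == 2:
        P = P[None]
    n, h, w = P.shape

    mean = P.mean(axis=(1, 2))
    std = P.std(axis=(1, 2))

    gy = np.diff(P, axis=1, prepend=P[:, :1, :])
    gx = np.diff(P, axis=2, prepend=P[:, :, :1])
    gmag = np.hypot(gx, gy)
    gmean = gmag.mean(axis=(1, 2))
    gstd = gmag.std(axis=(1, 2))

    lap = np.stack([ndimage.laplace(p) for p in P])
    lap_energy = np.abs(lap).mean(axis=(1, 2))

    hists = np.empty((n, _N_HIST_BINS))
    for i in range(n):
        hists[i], _ = np.histogram(P[i], bins=_N_HIST_BINS, range=(0.0, 255.0))
    hists /= float(h * w)

    # radial power-spectrum bands (DC excluded)
    F = np.abs(np.fft.rfft2(P, axes=(1, 2))) ** 2
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    bands = np.empty((n, 3))
    edges = (1e-9, 0.08, 0.2, 1.0)
    total = F.sum(axis=(1, 2)) - F[:, 0, 0] + 1e-12
    for b in range(3):
        m = (radius > edges[b]) & (radius <= edges[b + 1])
        bands[:, b] = F[:, m].sum(axis=1) / total

    return np.column_stack([mean, std, gmean, gstd, lap_energy, hists, bands])


# --------------------------------------------------------------------------
# Backbones


class TextureBackbone:
    """Default binary backbone: texture features + regularized logistic model.

    Degenerate fits (a single class present, or constant features) fall back
    to predicting the majority class with a logged warning.
    """

    def __init__(self, config: TrainingConfig | None = None) -> None:
        self.config = config or TrainingConfig()
        self._model = None
        self._constant: int | None = None

    def fit(self, patches: np.ndarray, y: np.ndarray) -> "TextureBackbone":
        y = np.asarray(y, dtype=int)
        if len(patches) == 0:
            raise ValueError("cannot fit backbone on an empty tile set")
        classes = np.unique(y)
        if len(classes) < 2:
            logger.warning(
                "degenerate fit: single class %s present; predicting it constantly",
                classes,
            )
            self._constant = int(classes[0])
            self._model = None
            return self
        X = texture_features(patches)
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=self.config.seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(X, y)
        self._constant = None
        return self

    def predict_score(self, patches: np.ndarray) -> np.ndarray:
        if self._model is None and self._constant is None:
            raise RuntimeError("backbone not fitted")
        n = len(patches)
        if self._constant is not None:
            return np.full(n, float(self._constant))
        X = texture_features(patches)
        return self._model.predict_proba(X)[:, 1]

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return (self.predict_score(patches) >= 0.5).astype(int)


class MulticlassTextureBackbone:
    """Native multiclass analogue of the default backbone (used by the flat
    five-class baseline). ``predict`` returns label strings."""

    def __init__(self, config: TrainingConfig | None = None) -> None:
        self.config = config or TrainingConfig()
        self._model = None

    def fit(self, patches: np.ndarray, labels: np.ndarray) -> "MulticlassTextureBackbone":
        X = texture_features(patches)
        self._model = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=self.config.seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model.fit(X, np.asarray(labels, dtype=object))
        return self

    def predict(self, patches: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("backbone not fitted")
        return self._model.predict(texture_features(patches))

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("backbone not fitted")
        return self._model.predict_proba(texture_features(patches))


def default_backbone_factory(config: TrainingConfig) -> BinaryClassifier:
    """Factory for the shipped texture backbone (the ``default_texture`` key)."""
    return TextureBackbone(config)


BACKBONE_REGISTRY: dict[str, Callable[[TrainingConfig], BinaryClassifier]] = {
    "default_texture": default_backbone_factory,
}


# --------------------------------------------------------------------------
# Balanced stage training


def balance_by_undersampling(
    patches: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize the two class counts by random under-sampling.

    Both classes end with count = min(original counts); the removed items are
    drawn uniformly at random under ``seed`` and the retained order is
    shuffled. Raises if either binary class is absent.
    """
    y = np.asarray(y, dtype=int)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    for val, idx in ((0, idx0), (1, idx1)):
        if len(idx) == 0:
            raise ValueError(f"cannot balance: class {val} is absent")
    rng = np.random.default_rng(seed)
    k = min(len(idx0), len(idx1))
    keep = np.concatenate(
        [
            rng.choice(idx0, size=k, replace=False),
            rng.choice(idx1, size=k, replace=False),
        ]
    )
    rng.shuffle(keep)
    return patches[keep], y[keep]


def fit_stage(
    tiles,
    stage: Stage,
    config: TrainingConfig,
    backbone_factory: Callable[[TrainingConfig], BinaryClassifier] | None = None,
) -> BinaryClassifier:
    """Train one binary stage on the tiles belonging to its two groups.

    Tiles with labels outside both groups are excluded; groups collapse to
    {0, 1} per the stage encoding; classes are balanced by under-sampling;
    then the backbone is fitted. Raises naming the stage if either group has
    no tiles.
    """
    factory = backbone_factory or default_backbone_factory
    enc = np.array([stage.encode(lab) for lab in tiles.labels], dtype=object)
    keep = np.array([e is not None for e in enc])
    if keep.sum() == 0 or len({int(e) for e in enc[keep]}) < 2:
        present = sorted({int(e) for e in enc[keep]}) if keep.any() else []
        missing = [g for b, g in ((0, stage.group0), (1, stage.group1)) if b not in present]
        raise ValueError(
            f"stage {stage.name!r}: no training tiles for group(s) {missing}"
        )
    X = tiles.patches[keep]
    y = enc[keep].astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    Xb, yb = balance_by_undersampling(X, y, seed=config.seed)
    logger.info(
        "stage %s: %d/%d tiles before balancing, %d per class after",
        stage.name, n0, n1, int((yb == 0).sum()),
    )
    clf = factory(config)
    return clf.fit(Xb, yb)
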