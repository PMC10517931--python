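"""Patient-level vote aggregation and cohort evaluation metrics.

A patient's final subtype is the plurality label among their tumor-predicted
tiles, not-tumor tiles excluded; a patient with no tumor tile at all gets
the distinct NO_TUMOR outcome. Cohorts are scored with class-balanced
metrics — balanced accuracy (mean per-class recall, with the spread across
classes) and the multiclass Matthews correlation coefficient in its
covariance form — because the subtypes are heavily imbalanced in practice.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .classifiers import (
    MulticlassTextureBackbone,
    TrainingConfig,
)
from .labels import (
    BACKGROUND,
    NOT_TUMOR,
    NO_TUMOR,
    SENTINELS,
    SUBTYPES,
    collapse_to_super,
)
from .refine import TileLabelMap, refine_map
from .tiling import TileGrid, TileSet, TilingConfig

__all__ = [
    "PatientCase",
    "EvaluationReport",
    "patient_vote",
    "balanced_accuracy",
    "matthews_cc",
    "evaluate_cohort",
    "confusion_matrix_from",
    "FlatBaseline",
    "flat_baseline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatientCase:
    """Bookkeeping record tying a patient to their images and ground truth."""

    patient_id: str
    images: tuple[str, ...]
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("a patient needs at least one image")
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


@dataclass
class EvaluationReport:
    """Cohort-level scores.

    The 4x4 confusion matrix counts subtype predictions (rows = truth,
    columns = prediction); NO_TUMOR predictions are tallied separately per
    true class and count against recall.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    no_tumor_counts: np.ndarray
    per_class_recall: np.ndarray
    balanced_accuracy: float
    recall_std: float
    mcc: float
    misclassified: list[str] = field(default_factory=list)


def patient_vote(tile_labels: Iterable[str]) -> str:
    """Plurality vote over a patient's final tile labels.

    Not-tumor tiles are excluded before counting; if nothing remains the
    outcome is NO_TUMOR. Ties are broken by the fixed prevalence order
    ccRCC > papRCC > chrRCC > ONCO with a logged warning.
    """
    labels = list(tile_labels)
    if not labels:
        raise ValueError("patient_vote needs at least one tile label")
    counts = Counter(
        lab for lab in labels if lab != NOT_TUMOR and lab not in SENTINELS
    )
    unknown = set(counts) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unexpected tile labels in patient vote: {sorted(unknown)}")
    if not counts:
        return NO_TUMOR
    best = max(counts.values())
    winners = [lab for lab in SUBTYPES if counts.get(lab) == best]
    if len(winners) > 1:
        logger.warning(
            "patient vote tie between %s; keeping %s (fixed prevalence order)",
            winners, winners[0],
        )
    return winners[0]


def confusion_matrix_from(
    truth: Sequence[str], pred: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Count matrix with rows = truth, columns = prediction."""
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[index[t], index[p]] += 1
    return cm


def balanced_accuracy(confusion: np.ndarray) -> tuple[float, float]:
    """Mean of per-class recalls and their population standard deviation.

    Recall of class i is confusion[i, i] / row_sum(i); a class with no
    ground-truth patient makes the score undefined and raises.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = cm.sum(axis=1)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"class index {i} has no ground-truth members")
    recalls = np.diag(cm) / row_sums
    return float(recalls.mean()), float(recalls.std())


def matthews_cc(confusion: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    MCC = (c*s - t.p) / sqrt((s^2 - p.p)(s^2 - t.t)) where c is the trace,
    s the total count, t the row (truth) sums and p the column (prediction)
    sums. A degenerate matrix with zero denominator returns 0 with a
    warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    c = np.trace(cm)
    s = cm.sum()
    cov_xy = c * s - t @ p
    cov_xx = s * s - p @ p
    cov_yy = s * s - t @ t
    denom = np.sqrt(cov_xx * cov_yy)
    if denom == 0:
        warnings.warn("degenerate confusion matrix; MCC defined as 0")
        return 0.0
    return float(cov_xy / denom)


def evaluate_cohort(
    predictions: Mapping[str, str], truth: Mapping[str, str]
) -> EvaluationReport:
    """Score patient-level predictions against ground-truth subtypes.

    NO_TUMOR predictions count as misclassifications of the true class and
    are reported separately from the 4x4 subtype confusion matrix.
    """
    missing = sorted(set(truth) - set(predictions))
    extra = sorted(set(predictions) - set(truth))
    if missing or extra:
        raise ValueError(
            f"patient id mismatch: missing predictions for {missing}, "
            f"unexpected predictions for {extra}"
        )
    classes = SUBTYPES
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    no_tumor = np.zeros(len(classes), dtype=int)
    misclassified: list[str] = []
    for pid in sorted(truth):
        t, p = truth[pid], predictions[pid]
        if t not in index:
            raise ValueError(f"patient {pid}: unknown true subtype {t!r}")
        if p == NO_TUMOR:
            no_tumor[index[t]] += 1
        elif p in index:
            cm[index[t], index[p]] += 1
        else:
            raise ValueError(f"patient {pid}: unknown predicted label {p!r}")
        if p != t:
            misclassified.append(pid)

    row_totals = cm.sum(axis=1) + no_tumor
    for i, s in enumerate(row_totals):
        if s == 0:
            raise ValueError(f"class {classes[i]} has no ground-truth patients")
    recalls = np.diag(cm) / row_totals

    # MCC over the full outcome alphabet (subtypes + NO_TUMOR if it occurred)
    if no_tumor.any():
        k = len(classes) + 1
        full = np.zeros((k, k), dtype=int)
        full[: len(classes), : len(classes)] = cm
        full[: len(classes), -1] = no_tumor
        mcc = matthews_cc(full)
    else:
        mcc = matthews_cc(cm)

    return EvaluationReport(
        classes=classes,
        confusion=cm,
        no_tumor_counts=no_tumor,
        per_class_recall=recalls,
        balanced_accuracy=float(recalls.mean()),
        recall_std=float(recalls.std()),
        mcc=mcc,
        misclassified=misclassified,
    )


# --------------------------------------------------------------------------
# Flat five-class baseline


@dataclass
class FlatBaseline:
    """Single five-class tile classifier + the same patient vote.

    The comparison arm: no hierarchy, one multiclass model over the four
    subtypes and NT, aggregated identically to the tree.
    """

    model: MulticlassTextureBackbone
    tiling: TilingConfig

    def classify_grid(self, grid: TileGrid, refine: bool = True) -> TileLabelMap:
        if grid.config.model_input_px != self.tiling.model_input_px:
            raise ValueError("tile size mismatch between baseline and grid")
        labels = np.full((grid.n_rows, grid.n_cols), BACKGROUND, dtype=object)
        patches, idx = grid.tissue_patches()
        if len(patches):
            pred = self.model.predict(patches)
            for (r, c), p in zip(idx, pred):
                labels[r, c] = str(p)
        out = TileLabelMap(labels)
        return refine_map(out) if refine else out

    def classify_patient(
        self, grids: Sequence[TileGrid], refine: bool = True
    ) -> tuple[str, list[TileLabelMap]]:
        maps = [self.classify_grid(g, refine) for g in grids]
        votes = [
            lab
            for m in maps
            for lab in m.labels.ravel().tolist()
            if lab != BACKGROUND
        ]
        label = patient_vote(votes) if votes else NO_TUMOR
        return label, maps


def flat_baseline(
    tiles: TileSet,
    config: TrainingConfig,
    backbone_factory: Callable[[TrainingConfig], MulticlassTextureBackbone] | None = None,
    tiling: TilingConfig | None = None,
) -> FlatBaseline:
    """Fit the flat baseline on training tiles over the 5 terminal classes
    (four subtypes, with the not-tumor tissues collapsed to NT)."""
    if len(tiles) == 0:
        raise ValueError("cannot fit baseline on an empty tile set")
    labels = np.array([collapse_to_super(lab) for lab in tiles.labels], dtype=object)
    present = set(labels.tolist())
    needed = set(SUBTYPES) | {NOT_TUMOR}
    if not needed <= present:
        raise ValueError(f"baseline training lacks classes {sorted(needed - present)}")
    factory = backbone_factory or (lambda cfg: MulticlassTextureBackbone(cfg))
    model = factory(config).fit(tiles.patches, labels)
    m = int(tiles.patches.shape[1])
    tiling = tiling or TilingConfig(tile_size_px=m, model_input_px=m)
    return FlatBaseline(model=model, tiling=tiling)
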