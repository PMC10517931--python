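"""End-to-end orchestration: train models on a cohort, predict patients,
evaluate, and run the standard ablation table.

These functions are the programmatic face of the pipeline; the CLI wraps
them thinly.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Sequence

import pandas as pd

from .classifiers import BinaryClassifier, TrainingConfig
from .evaluation import EvaluationReport, FlatBaseline, evaluate_cohort, flat_baseline
from .synthetic import Cohort, SyntheticPatient
from .tiling import TileGrid, TileSet, extract_training_tiles, tile_image
from .tree import (
    FittedTree,
    PatientResult,
    PruningPolicy,
    classify_patient,
    fit_tree,
    make_tree_spec,
)

__all__ = [
    "training_tiles",
    "patient_grids",
    "train_tree",
    "train_baseline",
    "predict_cohort",
    "evaluate_predictions",
    "run_ablation",
    "ABLATION_ARMS",
]

logger = logging.getLogger(__name__)

ABLATION_ARMS = ("expert", "naive1", "naive2", "baseline", "unpruned", "node_pruned")


def training_tiles(cohort: Cohort) -> TileSet:
    """Extract labelled tiles from all training patients' ROI annotations."""
    images: dict = {}
    patient_of: dict[str, str] = {}
    annotations = []
    for p in cohort.train:
        images.update(p.images)
        for img_id in p.images:
            patient_of[img_id] = p.patient_id
        annotations.extend(p.annotations)
    return extract_training_tiles(images, annotations, cohort.tiling, patient_of)


def patient_grids(patient: SyntheticPatient, cohort: Cohort) -> list[TileGrid]:
    """Tile every image of one patient with the cohort's tiling config."""
    return [
        tile_image(img, cohort.tiling, image_id=img_id)
        for img_id, img in sorted(patient.images.items())
    ]


def train_tree(
    cohort: Cohort,
    tree_name: str = "expert",
    seed: int = 0,
    backbone_factory: Callable[[TrainingConfig], BinaryClassifier] | None = None,
    tiles: TileSet | None = None,
) -> FittedTree:
    spec = make_tree_spec(tree_name)
    tiles = tiles if tiles is not None else training_tiles(cohort)
    return fit_tree(
        spec, tiles, TrainingConfig(seed=seed), backbone_factory, tiling=cohort.tiling
    )


def train_baseline(
    cohort: Cohort, seed: int = 0, tiles: TileSet | None = None
) -> FlatBaseline:
    tiles = tiles if tiles is not None else training_tiles(cohort)
    return flat_baseline(tiles, TrainingConfig(seed=seed), tiling=cohort.tiling)


def predict_cohort(
    model: FittedTree | FlatBaseline,
    patients: Sequence[SyntheticPatient],
    cohort: Cohort,
    policy: PruningPolicy | None = None,
    refine: bool = True,
) -> tuple[dict[str, str], dict[str, PatientResult | list]]:
    """Patient-level predictions (and per-patient detail) for a model arm."""
    predictions: dict[str, str] = {}
    details: dict = {}
    for p in patients:
        grids = patient_grids(p, cohort)
        if isinstance(model, FlatBaseline):
            label, maps = model.classify_patient(grids, refine=refine)
            predictions[p.patient_id] = label
            details[p.patient_id] = maps
        else:
            result = classify_patient(model, grids, policy=policy, refine=refine)
            predictions[p.patient_id] = result.label
            details[p.patient_id] = result
    return predictions, details


def evaluate_predictions(
    predictions: Mapping[str, str], cohort: Cohort, split: str = "test"
) -> EvaluationReport:
    return evaluate_cohort(predictions, cohort.truth(split))


def run_ablation(
    cohort: Cohort,
    seed: int = 0,
    arms: Sequence[str] = ABLATION_ARMS,
    refine_states: Sequence[bool] = (True, False),
) -> pd.DataFrame:
    """Train and evaluate the requested arms on the same cohort and seed.

    Arms: the three tree topologies under selective pruning, the flat
    baseline, and the unpruned / node-pruned variants of the expert tree.
    Returns one row per (arm, refine state) with balanced accuracy, the
    spread of per-class recalls, and MCC.
    """
    unknown = set(arms) - set(ABLATION_ARMS)
    if unknown:
        raise ValueError(f"unknown ablation arm(s): {sorted(unknown)}")
    tiles = training_tiles(cohort)

    models: dict[str, tuple] = {}
    for arm in arms:
        try:
            if arm == "baseline":
                models[arm] = (train_baseline(cohort, seed, tiles), None)
            elif arm in ("unpruned", "node_pruned"):
                if "expert_tree" not in models:
                    models["expert_tree"] = (
                        train_tree(cohort, "expert", seed, tiles=tiles),
                        None,
                    )
                models[arm] = (models["expert_tree"][0], PruningPolicy(mode=arm))
            else:
                policy = PruningPolicy(mode="selective")
                if arm == "expert":
                    if "expert_tree" not in models:
                        models["expert_tree"] = (
                            train_tree(cohort, "expert", seed, tiles=tiles),
                            None,
                        )
                    models[arm] = (models["expert_tree"][0], policy)
                else:
                    models[arm] = (train_tree(cohort, arm, seed, tiles=tiles), policy)
        except Exception as exc:  # surface which arm failed
            raise RuntimeError(f"ablation arm {arm!r} failed: {exc}") from exc

    rows = []
    for arm in arms:
        model, policy = models[arm]
        for refine in refine_states:
            try:
                preds, _ = predict_cohort(
                    model, cohort.test, cohort, policy=policy, refine=refine
                )
                report = evaluate_predictions(preds, cohort)
            except Exception as exc:
                raise RuntimeError(f"ablation arm {arm!r} failed: {exc}") from exc
            rows.append(
                {
                    "arm": arm,
                    "refine": "with" if refine else "without",
                    "balanced_accuracy": report.balanced_accuracy,
                    "recall_std": report.recall_std,
                    "mcc": report.mcc,
                    "n_misclassified": len(report.misclassified),
                }
            )
            logger.info(
                "%s (%s refine): balanced accuracy %.3f ± %.3f, MCC %.3f",
                arm, rows[-1]["refine"], report.balanced_accuracy,
                report.recall_std, report.mcc,
            )
    return pd.DataFrame(rows)
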