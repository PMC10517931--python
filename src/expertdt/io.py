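"""Disk formats: cohort directories, model bundles, label-map and
prediction CSVs.

A cohort directory holds ``images/*.png``, ``annotations.json``,
``manifest.csv`` (patient_id, image, split, true_subtype) and
``cohort_config.yaml``. A tree bundle is a directory with ``spec.json``,
``tiling.yaml`` and one joblib file per fitted stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classifiers import Stage
from .evaluation import FlatBaseline
from .refine import TileLabelMap
from .synthetic import Cohort, CohortConfig, SyntheticPatient
from .tiling import RoiAnnotation, TilingConfig, load_annotations
from .tree import FittedTree, StagedMaps, TreeSpec

__all__ = [
    "write_cohort",
    "read_cohort",
    "save_tree",
    "load_tree",
    "save_baseline",
    "load_baseline",
    "staged_maps_to_frame",
    "write_predictions",
]

_BUNDLE_VERSION = 1


# --------------------------------------------------------------------------
# Cohort directories


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Materialize a cohort as PNG images plus annotation/manifest files."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    annotations = []
    for patient in cohort.patients:
        for image_id, img in sorted(patient.images.items()):
            Image.fromarray(img).save(out / "images" / f"{image_id}.png")
        annotations.extend(
            {
                "image": a.image,
                "x0": int(a.x0),
                "y0": int(a.y0),
                "x1": int(a.x1),
                "y1": int(a.y1),
                "label": a.label,
            }
            for a in patient.annotations
        )
    (out / "annotations.json").write_text(json.dumps(annotations, indent=1))
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
    config = asdict(cohort.config) if cohort.config else asdict(
        CohortConfig()
    ) | {"note": "unknown generation config"}
    (out / "cohort_config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return out


def read_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a cohort directory back into memory (without ground-truth masks)."""
    root = Path(cohort_dir)
    config = CohortConfig(
        **{
            k: v
            for k, v in yaml.safe_load((root / "cohort_config.yaml").read_text()).items()
            if k in CohortConfig.__dataclass_fields__
        }
    )
    manifest = pd.read_csv(root / "manifest.csv")
    annotations = load_annotations(root / "annotations.json")
    by_image: dict[str, list[RoiAnnotation]] = {}
    for a in annotations:
        by_image.setdefault(a.image, []).append(a)

    train: list[SyntheticPatient] = []
    test: list[SyntheticPatient] = []
    for (pid, split, subtype), group in manifest.groupby(
        ["patient_id", "split", "true_subtype"], sort=True
    ):
        images = {}
        anns: list[RoiAnnotation] = []
        for image_id in group["image"]:
            with Image.open(root / "images" / f"{image_id}.png") as im:
                images[image_id] = np.asarray(im)
            anns.extend(by_image.get(image_id, []))
        patient = SyntheticPatient(
            patient_id=pid,
            subtype=subtype,
            images=images,
            annotations=anns,
            split=split,
        )
        (train if split == "train" else test).append(patient)
    return Cohort(train=train, test=test, tiling=config.tiling, config=config)


# --------------------------------------------------------------------------
# Model bundles


def _stage_to_dict(stage: Stage) -> dict:
    return {"name": stage.name, "group0": list(stage.group0), "group1": list(stage.group1)}


def _stage_from_dict(d: dict) -> Stage:
    return Stage(name=d["name"], group0=tuple(d["group0"]), group1=tuple(d["group1"]))


def save_tree(tree: FittedTree, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = {
        "version": _BUNDLE_VERSION,
        "kind": "tree",
        "name": tree.spec.name,
        "stages": [_stage_to_dict(s) for s in tree.spec.stages],
    }
    (out / "spec.json").write_text(json.dumps(spec, indent=1))
    (out / "tiling.yaml").write_text(yaml.safe_dump(asdict(tree.tiling)))
    for name, clf in tree.classifiers.items():
        joblib.dump(clf, out / f"stage_{name}.joblib")
    return out


def load_tree(bundle_dir: str | Path) -> FittedTree:
    root = Path(bundle_dir)
    spec_d = json.loads((root / "spec.json").read_text())
    if spec_d.get("kind") != "tree":
        raise ValueError(f"{root} is not a tree bundle")
    stages = [_stage_from_dict(d) for d in spec_d["stages"]]
    spec = TreeSpec(spec_d["name"], *stages)
    tiling = TilingConfig(**yaml.safe_load((root / "tiling.yaml").read_text()))
    classifiers = {
        s.name: joblib.load(root / f"stage_{s.name}.joblib") for s in stages
    }
    return FittedTree(spec=spec, classifiers=classifiers, tiling=tiling)


def save_baseline(model: FlatBaseline, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "spec.json").write_text(
        json.dumps({"version": _BUNDLE_VERSION, "kind": "flat"})
    )
    (out / "tiling.yaml").write_text(yaml.safe_dump(asdict(model.tiling)))
    joblib.dump(model.model, out / "model.joblib")
    return out


def load_baseline(bundle_dir: str | Path) -> FlatBaseline:
    root = Path(bundle_dir)
    spec_d = json.loads((root / "spec.json").read_text())
    if spec_d.get("kind") != "flat":
        raise ValueError(f"{root} is not a flat-baseline bundle")
    tiling = TilingConfig(**yaml.safe_load((root / "tiling.yaml").read_text()))
    return FlatBaseline(model=joblib.load(root / "model.joblib"), tiling=tiling)


# --------------------------------------------------------------------------
# Tabular outputs


def staged_maps_to_frame(
    maps_by_image: Mapping[str, StagedMaps | Sequence[TileLabelMap]],
) -> pd.DataFrame:
    """Flatten per-image staged label maps to (image, row, col, stage, label)."""
    rows = []
    for image_id, staged in maps_by_image.items():
        if isinstance(staged, StagedMaps):
            stage_maps = [
                ("stage1", staged.stage1),
                ("stage2", staged.stage2),
                ("stage3", staged.stage3),
            ]
        else:
            stage_maps = [(f"stage{i + 1}", m) for i, m in enumerate(staged)]
        for stage_name, label_map in stage_maps:
            if label_map is None:
                continue
            for r in range(label_map.n_rows):
                for c in range(label_map.n_cols):
                    rows.append(
                        {
                            "image": image_id,
                            "row": r,
                            "col": c,
                            "stage": stage_name,
                            "label": label_map.labels[r, c],
                        }
                    )
    return pd.DataFrame(rows, columns=["image", "row", "col", "stage", "label"])


def write_predictions(
    predictions: Mapping[str, str], path: str | Path, truth: Mapping[str, str] | None = None
) -> Path:
    rows = [
        {"patient_id": pid, "predicted_subtype": predictions[pid]}
        | ({"true_subtype": truth[pid]} if truth else {})
        for pid in sorted(predictions)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
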