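"""Heatmap overlays and evaluation figures.

The tile-level segmentation map is rendered over the source image with
healthy (not-tumor) tissue in green and tumor in red, one red shade per
subtype; background tiles stay fully transparent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .evaluation import EvaluationReport
from .labels import BACKGROUND, CCRCC, CHRRCC, NOT_TUMOR, ONCO, PAPRCC
from .refine import TileLabelMap

__all__ = ["LABEL_COLORS", "heatmap_overlay", "save_heatmap", "confusion_figure"]

#: RGB per displayable tile label; tumor subtypes are shades of red.
LABEL_COLORS: dict[str, tuple[int, int, int]] = {
    NOT_TUMOR: (40, 170, 70),
    CCRCC: (165, 0, 20),
    PAPRCC: (230, 55, 45),
    CHRRCC: (255, 110, 80),
    ONCO: (255, 160, 122),
}

_ALPHA = 0.45


def heatmap_overlay(
    image: np.ndarray, label_map: TileLabelMap, tile_size_px: int
) -> np.ndarray:
    """RGBA overlay of a final tile-label map on its source image.

    Tissue tiles are alpha-blended with their label color; background tiles
    (and any image area outside the complete-tile grid) have alpha 0.
    """
    if image.ndim == 2:
        base = np.repeat(image[:, :, None], 3, axis=2).astype(float)
    else:
        base = np.asarray(image, dtype=float)[:, :, :3]
    h, w = base.shape[:2]
    out = np.zeros((h, w, 4), dtype=np.uint8)
    for r in range(label_map.n_rows):
        for c in range(label_map.n_cols):
            lab = label_map.labels[r, c]
            if lab == BACKGROUND or lab not in LABEL_COLORS:
                continue
            y0, x0 = r * tile_size_px, c * tile_size_px
            y1, x1 = y0 + tile_size_px, x0 + tile_size_px
            color = np.array(LABEL_COLORS[lab], dtype=float)
            blended = (1 - _ALPHA) * base[y0:y1, x0:x1] + _ALPHA * color
            out[y0:y1, x0:x1, :3] = np.clip(blended, 0, 255).astype(np.uint8)
            out[y0:y1, x0:x1, 3] = 255
    return out


def save_heatmap(
    image: np.ndarray, label_map: TileLabelMap, tile_size_px: int, path: str | Path
) -> Path:
    rgba = heatmap_overlay(image, label_map, tile_size_px)
    path = Path(path)
    Image.fromarray(rgba, mode="RGBA").save(path)
    return path


def confusion_figure(report: EvaluationReport, path: str | Path) -> Path:
    """Render the confusion matrix as a PNG figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    cm = report.confusion
    im = ax.imshow(cm, cmap="Reds")
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=9)
    ax.set_title(
        f"balanced accuracy {report.balanced_accuracy:.2f} "
        f"± {report.recall_std:.2f}, MCC {report.mcc:.2f}"
    )
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
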