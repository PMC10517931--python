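"""Spatial label smoothing ("Refine") over a tile-label grid.

Each tile's label is replaced by the plurality label of its 9-connected
neighborhood (the 3x3 window centered on the tile, itself included).
Background tiles, and tiles outside the current classification stage, are
sentinels: they neither vote nor change. The update is synchronous — every
new label is computed from the input map — and applied in a single pass,
which gives the operator its low-pass, denoising character: an isolated
misclassified tile surrounded by agreeing neighbors is relabelled, while
homogeneous regions are fixed points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .labels import SENTINELS

__all__ = ["TileLabelMap", "neighborhood", "refine_map"]


@dataclass
class TileLabelMap:
    """Grid-aligned per-tile labels at one pipeline stage.

    ``labels`` is an (n_rows, n_cols) object array of label strings, some of
    which may be sentinels (``BACKGROUND``, ``OUT_OF_STAGE``).  ``scores``
    optionally carries a per-cell confidence in [0, 1].
    """

    labels: np.ndarray
    scores: np.ndarray | None = None
    inactive: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.labels.shape:
                raise ValueError("scores shape must match labels shape")

    @property
    def n_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.labels.shape[1]

    def sentinel_set(self) -> frozenset[str]:
        """Labels that do not participate in voting at this stage."""
        return SENTINELS | self.inactive

    def is_active(self, row: int, col: int) -> bool:
        return self.labels[row, col] not in self.sentinel_set()

    def counts(self) -> Counter:
        return Counter(self.labels.ravel().tolist())

    def copy(self) -> "TileLabelMap":
        return TileLabelMap(
            self.labels.copy(),
            None if self.scores is None else self.scores.copy(),
            self.inactive,
        )


def neighborhood(label_map: TileLabelMap, row: int, col: int) -> list[str]:
    """Labels of the 9-connected neighborhood of (row, col), self included.

    Cells outside the grid and sentinel cells are omitted, so the result has
    between 1 and 9 entries.  Raises if the center cell is itself a sentinel.
    """
    if label_map.labels[row, col] in label_map.sentinel_set():
        raise ValueError(
            f"cell ({row}, {col}) holds sentinel {label_map.labels[row, col]!r}"
        )
    sentinels = label_map.sentinel_set()
    out: list[str] = []
    for r in range(max(row - 1, 0), min(row + 2, label_map.n_rows)):
        for c in range(max(col - 1, 0), min(col + 2, label_map.n_cols)):
            lab = label_map.labels[r, c]
            if lab not in sentinels:
                out.append(lab)
    return out


def refine_map(label_map: TileLabelMap) -> TileLabelMap:
    """One synchronous pass of neighborhood plurality relabelling.

    Every non-sentinel cell takes the plurality label of its neighborhood as
    read from the *input* map; on a tied vote the cell keeps its original
    label.  Sentinel cells are returned unchanged.  Scores are dropped (the
    vote is over labels only).
    """
    sentinels = label_map.sentinel_set()
    src = label_map.labels
    out = src.copy()
    for row in range(label_map.n_rows):
        for col in range(label_map.n_cols):
            if src[row, col] in sentinels:
                continue
            votes = Counter(neighborhood(label_map, row, col))
            top = votes.most_common()
            best_count = top[0][1]
            winners = [lab for lab, cnt in top if cnt == best_count]
            if len(winners) == 1:
                out[row, col] = winners[0]
            # tie: keep original label
    return TileLabelMap(out, None, label_map.inactive)
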