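"""Hierarchical decision tree of binary tile classifiers.

Tiles flow Root -> Node -> Leaf. The Root separates tumor (T) from
not-tumor (NT); the Node separates two super-groups of subtypes; each Leaf
resolves one super-group into its two subtypes. The expert topology pairs
the subtypes the way a pathologist groups the differential diagnoses —
(ccRCC, papRCC) vs (chrRCC, ONCO) — while the two naive topologies are the
other possible pairings and serve as ablation arms.

A per-patient pruning rule guards the Node, which handles the hardest
decision: when the two super-group tile counts are nearly balanced
(relative difference below a threshold, default 30%), the Node is not
trusted and every tumor tile is scored by both leaves instead, taking the
more confident leaf's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .classifiers import (
    BinaryClassifier,
    Stage,
    TrainingConfig,
    default_backbone_factory,
    fit_stage,
)
from .labels import (
    BACKGROUND,
    CCRCC,
    CHRRCC,
    NOT_TUMOR,
    NOT_TUMOR_TISSUES,
    NO_TUMOR,
    ONCO,
    PAPRCC,
    SUBTYPES,
    TUMOR,
)
from .refine import TileLabelMap, refine_map
from .tiling import TileGrid, TileSet, TilingConfig

__all__ = [
    "TreeSpec",
    "PruningPolicy",
    "FittedTree",
    "StagedMaps",
    "PatientResult",
    "NoTumorEvidenceError",
    "make_tree_spec",
    "fit_tree",
    "classify_grid",
    "node_imbalance",
    "classify_patient",
]

logger = logging.getLogger(__name__)

TREE_NAMES = ("expert", "naive1", "naive2")


class NoTumorEvidenceError(ValueError):
    """Raised when a patient has no tumor-labelled tile to reason about."""


@dataclass(frozen=True)
class TreeSpec:
    """Declarative topology: four chained binary stages.

    Invariants: the node's two groups partition the four subtypes; leaf1
    resolves the node's group0 pair and leaf2 its group1 pair.
    """

    name: str
    root: Stage
    node: Stage
    leaf1: Stage
    leaf2: Stage

    def __post_init__(self) -> None:
        union = set(self.node.group0) | set(self.node.group1)
        if union != set(SUBTYPES) or len(self.node.group0) != 2:
            raise ValueError("node groups must partition the four subtypes 2+2")
        if set(self.leaf1.group0) | set(self.leaf1.group1) != set(self.node.group0):
            raise ValueError("leaf1 must resolve the node's group0 pair")
        if set(self.leaf2.group0) | set(self.leaf2.group1) != set(self.node.group1):
            raise ValueError("leaf2 must resolve the node's group1 pair")

    @property
    def stages(self) -> tuple[Stage, Stage, Stage, Stage]:
        return (self.root, self.node, self.leaf1, self.leaf2)

    def leaf_for_group(self, group_label: str) -> Stage:
        if group_label == self.node.group_name(0):
            return self.leaf1
        if group_label == self.node.group_name(1):
            return self.leaf2
        raise KeyError(f"unknown super-group label {group_label!r}")


@dataclass(frozen=True)
class PruningPolicy:
    """Per-patient node-pruning behavior.

    mode 'selective' prunes only when the super-group tile counts are too
    close; 'unpruned' always trusts the node; 'node_pruned' never consults
    it. The threshold is the relative count difference |n1-n0|/(n1+n0)
    below which the node is distrusted; a threshold of 1 means the node is
    never trusted (so the two extremes reproduce the two fixed modes).
    """

    mode: str = "selective"
    imbalance_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.mode not in ("selective", "unpruned", "node_pruned"):
            raise ValueError(f"unknown pruning mode {self.mode!r}")
        if not (0.0 <= self.imbalance_threshold <= 1.0):
            raise ValueError("imbalance_threshold must lie in [0, 1]")


def _pair_stage(name: str, pair: tuple[str, str]) -> Stage:
    return Stage(name=name, group0=(pair[0],), group1=(pair[1],))


def make_tree_spec(name: str) -> TreeSpec:
    """Published topologies by name: 'expert', 'naive1' or 'naive2'.

    Encoding convention (class 1 per stage): T at the root, the node's
    second-listed super-group, and the second-listed subtype of each pair —
    for the expert tree that is pap+cc at the node, ONCO at leaf1 and
    papRCC at leaf2.
    """
    node_groups = {
        "expert": ((CHRRCC, ONCO), (CCRCC, PAPRCC)),
        "naive1": ((CHRRCC, CCRCC), (PAPRCC, ONCO)),
        "naive2": ((ONCO, CCRCC), (PAPRCC, CHRRCC)),
    }
    if name not in node_groups:
        raise ValueError(f"unknown tree name {name!r}; expected one of {TREE_NAMES}")
    g0, g1 = node_groups[name]
    return TreeSpec(
        name=name,
        root=Stage("root", group0=NOT_TUMOR_TISSUES, group1=SUBTYPES),
        node=Stage("node", group0=g0, group1=g1),
        leaf1=_pair_stage("leaf1", g0),
        leaf2=_pair_stage("leaf2", g1),
    )


@dataclass
class StagedMaps:
    """The three per-stage label maps of one image grid.

    stage2 is None on routes where the node classifier is never invoked.
    """

    stage1: TileLabelMap
    stage2: TileLabelMap | None
    stage3: TileLabelMap


@dataclass
class FittedTree:
    spec: TreeSpec
    classifiers: Mapping[str, BinaryClassifier]
    tiling: TilingConfig

    def __post_init__(self) -> None:
        missing = {s.name for s in self.spec.stages} - set(self.classifiers)
        if missing:
            raise ValueError(f"unfitted stages: {sorted(missing)}")


@dataclass
class PatientResult:
    label: str
    maps: list[StagedMaps]
    diagnostics: dict


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def fit_tree(
    spec: TreeSpec,
    tiles: TileSet,
    config: TrainingConfig,
    backbone_factory: Callable[[TrainingConfig], BinaryClassifier] | None = None,
    tiling: TilingConfig | None = None,
) -> FittedTree:
    """Fit the four stage classifiers independently on their label subsets."""
    factory = backbone_factory or default_backbone_factory
    seeds = _stage_seeds(config.seed, len(spec.stages))
    fitted: dict[str, BinaryClassifier] = {}
    for stage, stage_seed in zip(spec.stages, seeds):
        stage_config = TrainingConfig(
            seed=stage_seed,
            max_epochs=config.max_epochs,
            patience=config.patience,
            batch_size=config.batch_size,
        )
        fitted[stage.name] = fit_stage(tiles, stage, stage_config, factory)
    m = int(tiles.patches.shape[1]) if len(tiles) else 0
    tiling = tiling or TilingConfig(
        tile_size_px=max(m, 1), model_input_px=max(m, 1)
    )
    return FittedTree(spec=spec, classifiers=dict(fitted), tiling=tiling)


# --------------------------------------------------------------------------
# Inference


def _blank_map(grid: TileGrid, inactive: frozenset[str] = frozenset()) -> TileLabelMap:
    labels = np.full((grid.n_rows, grid.n_cols), BACKGROUND, dtype=object)
    return TileLabelMap(labels, None, inactive)


def _check_grid(tree: FittedTree, grid: TileGrid) -> None:
    if grid.config.model_input_px != tree.tiling.model_input_px:
        raise ValueError(
            f"tile size mismatch: grid patches are {grid.config.model_input_px} px "
            f"but the tree was fitted for {tree.tiling.model_input_px} px"
        )


def _root_map(tree: FittedTree, grid: TileGrid, refine: bool) -> TileLabelMap:
    out = _blank_map(grid)
    patches, idx = grid.tissue_patches()
    if len(patches):
        pred = tree.classifiers["root"].predict(patches)
        for (r, c), p in zip(idx, pred):
            out.labels[r, c] = TUMOR if p else NOT_TUMOR
    return refine_map(out) if refine else out


def _node_map(
    tree: FittedTree, grid: TileGrid, stage1: TileLabelMap, refine: bool
) -> TileLabelMap:
    labels = stage1.labels.copy()
    coords = [
        (r, c)
        for r in range(stage1.n_rows)
        for c in range(stage1.n_cols)
        if stage1.labels[r, c] == TUMOR
    ]
    if coords:
        patches = np.stack([grid.patches[r, c] for r, c in coords])
        pred = tree.classifiers["node"].predict(patches)
        for (r, c), p in zip(coords, pred):
            labels[r, c] = tree.spec.node.group_name(int(p))
    out = TileLabelMap(labels, None, frozenset({NOT_TUMOR}))
    return refine_map(out) if refine else out


def _leaf_map_from_node(
    tree: FittedTree, grid: TileGrid, stage2: TileLabelMap, refine: bool
) -> TileLabelMap:
    labels = stage2.labels.copy()
    for binary in (0, 1):
        gname = tree.spec.node.group_name(binary)
        leaf = tree.spec.leaf_for_group(gname)
        coords = [
            (r, c)
            for r in range(stage2.n_rows)
            for c in range(stage2.n_cols)
            if stage2.labels[r, c] == gname
        ]
        if not coords:
            continue
        patches = np.stack([grid.patches[r, c] for r, c in coords])
        pred = tree.classifiers[leaf.name].predict(patches)
        for (r, c), p in zip(coords, pred):
            labels[r, c] = leaf.group_name(int(p))
    out = TileLabelMap(labels, None, frozenset({NOT_TUMOR}))
    return refine_map(out) if refine else out


def _leaf_map_pruned(
    tree: FittedTree, grid: TileGrid, stage1: TileLabelMap, refine: bool
) -> tuple[TileLabelMap, list[tuple[str, str]]]:
    """Route every tumor tile through BOTH leaves; keep the more confident
    leaf's label (ties resolved toward leaf1 with a warning). Also returns
    the per-tile (leaf1 label, leaf2 label) pairs for double-vote mode."""
    labels = stage1.labels.copy()
    coords = [
        (r, c)
        for r in range(stage1.n_rows)
        for c in range(stage1.n_cols)
        if stage1.labels[r, c] == TUMOR
    ]
    pairs: list[tuple[str, str]] = []
    if coords:
        patches = np.stack([grid.patches[r, c] for r, c in coords])
        s1 = tree.classifiers["leaf1"].predict_score(patches)
        s2 = tree.classifiers["leaf2"].predict_score(patches)
        lab1 = [tree.spec.leaf1.group_name(int(s >= 0.5)) for s in s1]
        lab2 = [tree.spec.leaf2.group_name(int(s >= 0.5)) for s in s2]
        conf1 = np.abs(s1 - 0.5) * 2
        conf2 = np.abs(s2 - 0.5) * 2
        n_ties = 0
        for (r, c), l1, l2, c1, c2 in zip(coords, lab1, lab2, conf1, conf2):
            if c1 == c2:
                n_ties += 1
            labels[r, c] = l1 if c1 >= c2 else l2
            pairs.append((l1, l2))
        if n_ties:
            logger.warning(
                "pruned route: %d tile(s) with equal leaf confidences; "
                "kept leaf1's decision", n_ties,
            )
    out = TileLabelMap(labels, None, frozenset({NOT_TUMOR}))
    return (refine_map(out) if refine else out), pairs


def classify_grid(tree: FittedTree, grid: TileGrid, refine: bool = True) -> StagedMaps:
    """Run one image grid through root, node and leaves (the node-trusted
    route), applying one refine pass after each stage when ``refine``.

    Background cells never enter a classifier; NT cells keep their label
    through later stages and never vote there.
    """
    _check_grid(tree, grid)
    stage1 = _root_map(tree, grid, refine)
    stage2 = _node_map(tree, grid, stage1, refine)
    stage3 = _leaf_map_from_node(tree, grid, stage2, refine)
    return StagedMaps(stage1, stage2, stage3)


def node_imbalance(
    stage2_maps: Sequence[TileLabelMap], node: Stage
) -> float:
    """Relative super-group count difference, pooled over a patient's images.

    Returns |n1 - n0| / (n1 + n0); raises NoTumorEvidenceError when the
    patient has no tumor tile at all.
    """
    n0 = n1 = 0
    g0, g1 = node.group_name(0), node.group_name(1)
    for m in stage2_maps:
        counts = m.counts()
        n0 += counts.get(g0, 0)
        n1 += counts.get(g1, 0)
    if n0 + n1 == 0:
        raise NoTumorEvidenceError("patient has no tumor-classified tile")
    return abs(n1 - n0) / (n1 + n0)


def _should_prune(policy: PruningPolicy, imbalance: float | None) -> bool:
    if policy.mode == "unpruned":
        return False
    if policy.mode == "node_pruned":
        return True
    if imbalance is None:
        return False
    # threshold 1 means "never trust the node", matching node_pruned exactly
    return imbalance < policy.imbalance_threshold or policy.imbalance_threshold >= 1.0


def classify_patient(
    tree: FittedTree,
    grids: Sequence[TileGrid],
    policy: PruningPolicy | None = None,
    refine: bool = True,
    pruned_vote: str = "argmax",
) -> PatientResult:
    """Classify all of a patient's image grids and aggregate to one subtype.

    The node route is used unless the pruning policy fires, in which case
    tumor tiles are resolved by the more confident of the two leaves
    (``pruned_vote='argmax'``) or contribute both leaf labels to the patient
    tally (``pruned_vote='double'``). Patients without any tumor tile get
    the NO_TUMOR outcome.
    """
    from .evaluation import patient_vote

    if not grids:
        raise ValueError("patient must have at least one image grid")
    if pruned_vote not in ("argmax", "double"):
        raise ValueError(f"unknown pruned_vote mode {pruned_vote!r}")
    policy = policy or PruningPolicy()

    stage1_maps = [_root_map(tree, g, refine) for g in grids]

    stage2_maps: list[TileLabelMap] | None = None
    imbalance: float | None = None
    if policy.mode != "node_pruned":
        stage2_maps = [
            _node_map(tree, g, s1, refine) for g, s1 in zip(grids, stage1_maps)
        ]
        try:
            imbalance = node_imbalance(stage2_maps, tree.spec.node)
        except NoTumorEvidenceError:
            imbalance = None

    fired = _should_prune(policy, imbalance)

    extra_votes: list[str] = []
    maps: list[StagedMaps] = []
    for i, grid in enumerate(grids):
        _check_grid(tree, grid)
        if fired:
            stage3, pairs = _leaf_map_pruned(tree, grid, stage1_maps[i], refine)
            if pruned_vote == "double":
                extra_votes.extend(lab for pair in pairs for lab in pair)
        else:
            assert stage2_maps is not None
            stage3 = _leaf_map_from_node(tree, grid, stage2_maps[i], refine)
        maps.append(
            StagedMaps(
                stage1_maps[i],
                stage2_maps[i] if stage2_maps is not None else None,
                stage3,
            )
        )

    votes: list[str] = []
    for sm in maps:
        for lab in sm.stage3.labels.ravel().tolist():
            if lab != BACKGROUND:
                votes.append(lab)
    if fired and pruned_vote == "double":
        votes = [v for v in votes if v == NOT_TUMOR] + extra_votes

    label = patient_vote(votes) if votes else NO_TUMOR
    diagnostics = {
        "node_imbalance": imbalance,
        "pruning_fired": bool(fired),
        "mode": policy.mode,
        "n_votes": len([v for v in votes if v != NOT_TUMOR]),
    }
    return PatientResult(label=label, maps=maps, diagnostics=diagnostics)
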