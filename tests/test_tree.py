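"""Tree topologies, tile routing, node imbalance and the pruning rule."""

from __future__ import annotations

import numpy as np
import pytest

from expertdt.labels import BACKGROUND, NOT_TUMOR, NO_TUMOR, SUBTYPES, TUMOR
from expertdt.pipeline import patient_grids, train_tree
from expertdt.refine import TileLabelMap
from expertdt.tiling import TileSet
from expertdt.tree import (
    NoTumorEvidenceError,
    PruningPolicy,
    classify_grid,
    classify_patient,
    fit_tree,
    make_tree_spec,
    node_imbalance,
)
from expertdt.classifiers import TrainingConfig

from test_classifiers import texture_set


class TestTreeSpecs:
    def test_expert_topology(self):
        spec = make_tree_spec("expert")
        assert set(spec.node.group0) == {"chrRCC", "ONCO"}
        assert set(spec.node.group1) == {"ccRCC", "papRCC"}
        assert set(spec.leaf1.group0) | set(spec.leaf1.group1) == {"chrRCC", "ONCO"}
        assert set(spec.leaf2.group0) | set(spec.leaf2.group1) == {"ccRCC", "papRCC"}
        # documented encodings: T=1, pap+cc=1, ONCO=1, papRCC=1
        assert spec.root.encode("ccRCC") == 1
        assert spec.node.encode("papRCC") == 1
        assert spec.leaf1.encode("ONCO") == 1
        assert spec.leaf2.encode("papRCC") == 1

    def test_naive_topologies(self):
        n1 = make_tree_spec("naive1")
        assert set(n1.node.group0) == {"chrRCC", "ccRCC"}
        assert set(n1.node.group1) == {"papRCC", "ONCO"}
        n2 = make_tree_spec("naive2")
        assert set(n2.node.group0) == {"ONCO", "ccRCC"}
        assert set(n2.node.group1) == {"papRCC", "chrRCC"}

    def test_unknown_name_raises(self):
        with pytest.raises(ValueError, match="unknown tree"):
            make_tree_spec("expert2")


class TestFitTree:
    def test_missing_subtype_fails_naming_the_leaf(self):
        tiles = texture_set({"ccRCC": 30, "papRCC": 30, "chrRCC": 30, "fiber": 30})
        with pytest.raises(ValueError, match="leaf1"):
            fit_tree(make_tree_spec("expert"), tiles, TrainingConfig(seed=0))

    def test_two_fits_same_seed_agree_on_probe(self, small_cohort, small_tiles):
        probe = texture_set({"ccRCC": 10, "chrRCC": 10}, seed=42)
        t1 = train_tree(small_cohort, "expert", seed=5, tiles=small_tiles)
        t2 = train_tree(small_cohort, "expert", seed=5, tiles=small_tiles)
        for name in ("root", "node", "leaf1", "leaf2"):
            assert np.array_equal(
                t1.classifiers[name].predict(probe.patches),
                t2.classifiers[name].predict(probe.patches),
            )


class TestNodeImbalance:
    def _map(self, n0: int, n1: int) -> TileLabelMap:
        spec = make_tree_spec("expert")
        labels = np.array(
            [spec.node.group_name(0)] * n0 + [spec.node.group_name(1)] * n1
            + [NOT_TUMOR, BACKGROUND],
            dtype=object,
        )
        side = int(np.ceil(np.sqrt(len(labels))))
        padded = np.full(side * side, BACKGROUND, dtype=object)
        padded[: len(labels)] = labels
        return TileLabelMap(padded.reshape(side, side))

    @pytest.mark.parametrize("n0,n1,expected", [(50, 50, 0.0), (35, 65, 0.30), (0, 120, 1.0)])
    def test_formula(self, n0, n1, expected):
        spec = make_tree_spec("expert")
        value = node_imbalance([self._map(n0, n1)], spec.node)
        assert value == pytest.approx(expected)

    def test_zero_tumor_tiles_is_signalled_distinctly(self):
        spec = make_tree_spec("expert")
        empty = TileLabelMap(np.full((2, 2), NOT_TUMOR, dtype=object))
        with pytest.raises(NoTumorEvidenceError):
            node_imbalance([empty], spec.node)

    def test_pooled_across_images(self):
        spec = make_tree_spec("expert")
        value = node_imbalance([self._map(30, 0), self._map(5, 65)], spec.node)
        assert value == pytest.approx(abs(65 - 35) / 100)


@pytest.fixture(scope="module")
def classified(small_cohort, small_expert_tree):
    patient = small_cohort.test[0]
    grids = patient_grids(patient, small_cohort)
    return grids, [classify_grid(small_expert_tree, g, refine=False) for g in grids]


class TestRouting:
    def test_label_flow_conservation_at_every_stage(self, classified):
        grids, staged = classified
        spec = make_tree_spec("expert")
        groups = {spec.node.group_name(0), spec.node.group_name(1)}
        for grid, sm in zip(grids, staged):
            total = grid.n_tiles
            for stage_map, tumor_labels in (
                (sm.stage1, {TUMOR}),
                (sm.stage2, groups),
                (sm.stage3, set(SUBTYPES)),
            ):
                counts = stage_map.counts()
                n_bg = counts.get(BACKGROUND, 0)
                n_nt = counts.get(NOT_TUMOR, 0)
                n_tumor = sum(counts.get(lab, 0) for lab in tumor_labels)
                assert n_bg + n_nt + n_tumor == total

    def test_not_tumor_is_never_resurrected(self, classified):
        _, staged = classified
        for sm in staged:
            nt_cells = sm.stage1.labels == NOT_TUMOR
            assert (sm.stage2.labels[nt_cells] == NOT_TUMOR).all()
            assert (sm.stage3.labels[nt_cells] == NOT_TUMOR).all()

    def test_background_is_never_classified(self, classified):
        grids, staged = classified
        for grid, sm in zip(grids, staged):
            bg = grid.background_mask
            for m in (sm.stage1, sm.stage2, sm.stage3):
                assert (m.labels[bg] == BACKGROUND).all()

    def test_final_label_stays_in_node_assigned_supergroup(self, classified):
        # refine off, node trusted: routing consistency
        _, staged = classified
        spec = make_tree_spec("expert")
        for sm in staged:
            for binary in (0, 1):
                gname = spec.node.group_name(binary)
                members = set(spec.node.group1 if binary else spec.node.group0)
                cells = sm.stage2.labels == gname
                assert all(lab in members for lab in sm.stage3.labels[cells])

    def test_tile_size_mismatch_raises(self, small_expert_tree):
        from expertdt.tiling import TilingConfig, tile_image

        img = np.full((64, 64), 100, dtype=np.uint8)
        wrong = tile_image(img, TilingConfig(16, 16, 210))
        with pytest.raises(ValueError, match="mismatch"):
            classify_grid(small_expert_tree, wrong)


class TestPruningPolicy:
    def test_invalid_mode_and_threshold_rejected(self):
        with pytest.raises(ValueError):
            PruningPolicy(mode="sometimes")
        with pytest.raises(ValueError):
            PruningPolicy(imbalance_threshold=1.5)

    def test_threshold_zero_reproduces_unpruned_exactly(self, small_cohort, small_expert_tree):
        patient = small_cohort.test[1]
        grids = patient_grids(patient, small_cohort)
        a = classify_patient(small_expert_tree, grids,
                             PruningPolicy("selective", 0.0))
        b = classify_patient(small_expert_tree, grids, PruningPolicy("unpruned"))
        assert a.label == b.label
        assert not a.diagnostics["pruning_fired"]
        for ma, mb in zip(a.maps, b.maps):
            assert (ma.stage3.labels == mb.stage3.labels).all()

    def test_threshold_one_reproduces_node_pruned_exactly(self, small_cohort, small_expert_tree):
        patient = small_cohort.test[1]
        grids = patient_grids(patient, small_cohort)
        a = classify_patient(small_expert_tree, grids,
                             PruningPolicy("selective", 1.0))
        b = classify_patient(small_expert_tree, grids, PruningPolicy("node_pruned"))
        assert a.label == b.label
        assert a.diagnostics["pruning_fired"]
        for ma, mb in zip(a.maps, b.maps):
            assert (ma.stage3.labels == mb.stage3.labels).all()

    def test_node_pruned_never_consults_the_node(self, small_cohort, small_expert_tree):
        patient = small_cohort.test[0]
        grids = patient_grids(patient, small_cohort)

        class Exploding:
            def predict(self, X):
                raise AssertionError("node classifier must not be called")

            def predict_score(self, X):
                raise AssertionError("node classifier must not be called")

        guarded = type(small_expert_tree)(
            spec=small_expert_tree.spec,
            classifiers={**small_expert_tree.classifiers, "node": Exploding()},
            tiling=small_expert_tree.tiling,
        )
        result = classify_patient(guarded, grids, PruningPolicy("node_pruned"))
        assert result.label in SUBTYPES
        assert all(sm.stage2 is None for sm in result.maps)

    def test_all_background_patient_yields_no_tumor(self, small_cohort, small_expert_tree):
        from expertdt.tiling import tile_image

        white = np.full((320, 320), 255, dtype=np.uint8)
        grid = tile_image(white, small_cohort.tiling)
        result = classify_patient(small_expert_tree, [grid], PruningPolicy())
        assert result.label == NO_TUMOR
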