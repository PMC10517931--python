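"""Grid tiling, background flagging, ROI extraction and patient splits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from expertdt.tiling import (
    RoiAnnotation,
    TileSet,
    TilingConfig,
    extract_training_tiles,
    mark_background,
    split_by_patient,
    tile_image,
)

SMALL = TilingConfig(tile_size_px=8, model_input_px=4, background_mean_threshold=210)


class TestTileImage:
    @pytest.mark.parametrize(
        "shape,expected",
        [
            ((3000, 2000), (3, 2)),   # floor division both axes
            ((1000, 1000), (1, 1)),
            ((1999, 1999), (1, 1)),   # right/bottom remainders dropped
        ],
    )
    def test_grid_dimensions(self, shape, expected):
        config = TilingConfig()  # 1000 -> 112
        img = np.full(shape, 128, dtype=np.uint8)
        grid = tile_image(img, config)
        assert (grid.n_rows, grid.n_cols) == expected
        assert grid.patches.shape[2:] == (112, 112)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="too small"):
            tile_image(np.zeros((7, 100), dtype=np.uint8), SMALL)

    def test_grid_is_exhaustive_over_complete_tiles(self):
        img = np.zeros((83, 50), dtype=np.uint8)
        grid = tile_image(img, SMALL)
        ts = SMALL.tile_size_px
        assert grid.n_rows * ts <= 83 < (grid.n_rows + 1) * ts
        assert grid.n_cols * ts <= 50 < (grid.n_cols + 1) * ts

    def test_rgb_input_is_channel_averaged(self):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        img[..., 0] = 255  # pure red: channel mean 85
        grid = tile_image(img, SMALL)
        assert grid.tile_means[0, 0] == pytest.approx(85.0)


class TestBackgroundRule:
    @pytest.mark.parametrize(
        "value,is_background",
        [(255, True), (100, False), (210, False)],  # strictly-greater rule
    )
    def test_constant_tiles(self, value, is_background):
        img = np.full((8, 8), value, dtype=np.uint8)
        grid = tile_image(img, SMALL)
        assert grid.background_mask[0, 0] == is_background

    def test_matches_brute_force_means_on_random_images(self):
        rng = np.random.default_rng(42)
        config = TilingConfig(tile_size_px=5, model_input_px=5,
                              background_mean_threshold=127)
        for _ in range(100):
            h, w = rng.integers(5, 30, size=2)
            img = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
            grid = mark_background(tile_image(img, config), config)
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    tile = img[r * 5 : r * 5 + 5, c * 5 : c * 5 + 5]
                    assert grid.background_mask[r, c] == (tile.mean() > 127)


class TestExtractTrainingTiles:
    def test_roi_yields_complete_tiles_with_its_label(self):
        img = np.full((16, 8), 100, dtype=np.uint8)
        ann = RoiAnnotation("img", x0=0, y0=0, x1=8, y1=16, label="ccRCC")
        tiles = extract_training_tiles({"img": img}, [ann], SMALL)
        assert len(tiles) == 2
        assert set(tiles.labels) == {"ccRCC"}

    def test_not_tumor_labels_are_preserved_verbatim(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        ann = RoiAnnotation("img", 0, 0, 8, 8, label="fiber")
        tiles = extract_training_tiles({"img": img}, [ann], SMALL)
        assert tiles.labels.tolist() == ["fiber"]

    def test_unknown_label_is_rejected_by_name(self):
        with pytest.raises(ValueError, match="sarcoma"):
            RoiAnnotation("img", 0, 0, 8, 8, label="sarcoma")

    def test_undersized_roi_emits_nothing(self, caplog):
        img = np.full((20, 20), 100, dtype=np.uint8)
        ann = RoiAnnotation("img", 0, 0, 7, 7, label="ONCO")
        with caplog.at_level("WARNING"):
            tiles = extract_training_tiles({"img": img}, [ann], SMALL)
        assert len(tiles) == 0
        assert "smaller than one tile" in caplog.text

    def test_roi_out_of_bounds_raises(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        ann = RoiAnnotation("img", 0, 0, 9, 8, label="ONCO")
        with pytest.raises(ValueError, match="bounds"):
            extract_training_tiles({"img": img}, [ann], SMALL)

    def test_tiles_never_cross_roi_boundary(self):
        # ROI interior 100, exterior 0: every emitted tile must be pure 100
        img = np.zeros((40, 40), dtype=np.uint8)
        img[5:29, 3:19] = 100
        ann = RoiAnnotation("img", x0=3, y0=5, x1=19, y1=29, label="papRCC")
        config = TilingConfig(tile_size_px=8, model_input_px=8,
                              background_mean_threshold=210)
        tiles = extract_training_tiles({"img": img}, [ann], config)
        assert len(tiles) == 3 * 2
        assert np.all(tiles.patches == 100)

    def test_background_tiles_inside_roi_are_discarded(self):
        img = np.full((8, 16), 100, dtype=np.uint8)
        img[:, 8:] = 255  # right tile is empty background
        ann = RoiAnnotation("img", 0, 0, 16, 8, label="chrRCC")
        tiles = extract_training_tiles({"img": img}, [ann], SMALL)
        assert len(tiles) == 1


def _patient_tiles(n_patients: int, per_patient: int = 3) -> TileSet:
    n = n_patients * per_patient
    return TileSet(
        patches=np.zeros((n, 4, 4), dtype=np.float32),
        labels=np.array(["ccRCC"] * n, dtype=object),
        patients=np.array(
            [f"P{i}" for i in range(n_patients) for _ in range(per_patient)],
            dtype=object,
        ),
    )


class TestSplitByPatient:
    def test_75_25_split_of_eight_patients(self):
        train, val = split_by_patient(_patient_tiles(8), fraction=0.75, seed=0)
        assert len(set(train.patients)) == 6
        assert len(set(val.patients)) == 2

    def test_same_seed_is_reproducible(self):
        a = split_by_patient(_patient_tiles(8), 0.75, seed=9)
        b = split_by_patient(_patient_tiles(8), 0.75, seed=9)
        assert set(a[0].patients) == set(b[0].patients)

    def test_single_patient_raises(self):
        with pytest.raises(ValueError, match="2 patients"):
            split_by_patient(_patient_tiles(1), 0.75, seed=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 12))
    def test_partition_is_disjoint_and_complete(self, seed, n):
        tiles = _patient_tiles(n)
        train, val = split_by_patient(tiles, 0.75, seed=seed)
        train_p, val_p = set(train.patients), set(val.patients)
        assert not (train_p & val_p)
        assert len(train) + len(val) == len(tiles)
        assert train_p | val_p == set(tiles.patients)
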