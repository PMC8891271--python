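"""Tile grid, the 2% rule, uncertainty band, tissue checks, slide filter."""
import warnings

import numpy as np
import pytest

from hemlabel.config import LabelingConfig, RegistrationConfig
from hemlabel.labeling import (
    apply_slide_filter,
    build_dataset,
    label_slide,
    label_tile,
    labels_from_annotation,
    tile_grid,
    tissue_presence_check,
)
from hemlabel.synthetic import SyntheticSpec, generate_pair
from hemlabel.types import SlideStatus, TileLabel, TileRecord


class TestTileGrid:
    @pytest.mark.parametrize(
        "shape,tile_px,expected",
        [
            ((448, 448), 224, 4),
            ((500, 448), 224, 4),  # bottom 52-px band dropped
            ((100, 100), 224, 0),
            ((224, 672), 224, 3),
        ],
    )
    def test_counts(self, shape, tile_px, expected):
        assert len(tile_grid(shape, tile_px)) == expected

    def test_row_major_and_disjoint(self):
        grid = tile_grid((448, 672), 224)
        assert grid == [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]
        assert len(set(grid)) == len(grid)

    def test_invalid_tile_size(self):
        with pytest.raises(ValueError):
            tile_grid((100, 100), 0)


class TestLabelTile:
    def _tile(self, n_positive, lpx=45, dab_level=1.0):
        pos = np.zeros((lpx, lpx), dtype=bool)
        pos.ravel()[:n_positive] = True
        dab = np.where(pos, dab_level, 0.0)
        tissue = np.ones((lpx, lpx), dtype=bool)
        return pos, dab, tissue

    def test_41_of_2025_pixels_is_cancer(self):
        # 2025 * 0.02 = 40.5, so 41 positive pixels exceed the 2% rule
        cfg = LabelingConfig()
        label, frac, _ = label_tile(*self._tile(41), cfg)
        assert frac == pytest.approx(41 / 2025)
        assert label is TileLabel.CANCER

    def test_40_of_2025_pixels_is_normal(self):
        cfg = LabelingConfig()
        label, frac, _ = label_tile(*self._tile(40), cfg)
        assert frac == pytest.approx(40 / 2025)
        assert label is TileLabel.NORMAL

    def test_uncertain_band_overrides_fraction_rule(self):
        cfg = LabelingConfig(dab_uncertain_low=0.05, dab_uncertain_high=0.45)
        # plenty of positive pixels, but mean DAB OD inside the band
        pos, dab, tissue = self._tile(600, dab_level=0.9)
        label, frac, mean_od = label_tile(pos, dab, tissue, cfg)
        assert frac > cfg.cancer_fraction_threshold
        assert cfg.dab_uncertain_low <= mean_od <= cfg.dab_uncertain_high
        assert label is TileLabel.UNCERTAIN

    def test_empty_tile_rejected(self):
        cfg = LabelingConfig()
        with pytest.raises(ValueError):
            label_tile(np.zeros((0, 0), bool), np.zeros((0, 0)), np.zeros((0, 0), bool), cfg)

    def test_threshold_monotonicity(self):
        # raising the cancer threshold never turns a normal tile to cancer
        pos, dab, tissue = self._tile(100, dab_level=1.0)
        labels = []
        for thr in (0.01, 0.02, 0.05, 0.1):
            cfg = LabelingConfig(
                cancer_fraction_threshold=thr,
                dab_uncertain_low=0.0, dab_uncertain_high=0.0,
            )
            label, _, _ = label_tile(pos, dab, tissue, cfg)
            labels.append(label is TileLabel.CANCER)
        assert labels == sorted(labels, reverse=True)


class TestTissuePresence:
    def test_both_background_dropped_as_no_tissue(self):
        cfg = LabelingConfig()
        keep, reason = tissue_presence_check(0.0, 0.0, cfg)
        assert not keep and reason == "no_tissue"

    def test_single_sided_tissue_is_mismatch(self):
        cfg = LabelingConfig()
        keep, reason = tissue_presence_check(0.6, 0.0, cfg)
        assert not keep and reason == "tissue_mismatch"

    def test_both_sides_tissue_kept(self):
        cfg = LabelingConfig()
        assert tissue_presence_check(0.6, 0.4, cfg) == (True, "")

    def test_grabcut_requires_opencv(self, aligned_pair):
        from hemlabel.labeling import he_tissue_mask

        cfg = LabelingConfig(tissue_method="grabcut")
        with pytest.raises(ModuleNotFoundError, match="opencv"):
            he_tissue_mask(aligned_pair[0].he_image, cfg)


class TestSlideFilter:
    def _records(self):
        recs = (
            [TileRecord("s", 0, i, label=TileLabel.CANCER) for i in range(30)]
            + [TileRecord("s", 1, i, label=TileLabel.NORMAL) for i in range(10)]
            + [TileRecord("s", 2, i, label=TileLabel.UNCERTAIN) for i in range(5)]
        )
        return recs

    def test_cancer_slide_keeps_cancer_tiles(self):
        out = apply_slide_filter(self._records(), SlideStatus.CANCER)
        assert sum(r.label is TileLabel.CANCER for r in out) == 30
        assert sum(r.label is TileLabel.NORMAL for r in out) == 0

    def test_normal_slide_keeps_normal_tiles(self):
        out = apply_slide_filter(self._records(), SlideStatus.NON_CANCER)
        assert sum(r.label is TileLabel.NORMAL for r in out) == 10
        assert sum(r.label is TileLabel.CANCER for r in out) == 0

    def test_evaluation_mode_keeps_everything(self):
        out = apply_slide_filter(self._records(), SlideStatus.CANCER, training=False)
        assert sum(r.label is TileLabel.CANCER for r in out) == 30
        assert sum(r.label is TileLabel.NORMAL for r in out) == 10
        assert len(out) == 45

    def test_filtered_tiles_carry_reason(self):
        out = apply_slide_filter(self._records(), SlideStatus.CANCER)
        demoted = [r for r in out if r.reason.startswith("slide_filter")]
        assert len(demoted) == 10


class TestLabelSlide:
    def test_labels_match_truth_on_aligned_slide(self, aligned_pair):
        pair, truth = aligned_pair
        # 256-px slide with 64-px tiles at downscale 1: masks line up 1:1
        cfg = LabelingConfig(
            tile_px=64, downscale=1,
            dab_uncertain_low=0.0, dab_uncertain_high=0.0,
        )
        records = label_slide(pair, pair.ihc_image, cfg, training=False)
        n_checked = n_correct = 0
        for rec in records:
            if rec.label not in (TileLabel.CANCER, TileLabel.NORMAL):
                continue
            sl = np.s_[
                rec.tile_row * 64 : (rec.tile_row + 1) * 64,
                rec.tile_col * 64 : (rec.tile_col + 1) * 64,
            ]
            frac = truth.cancer_mask[sl].mean()
            if 0.005 < frac < 0.1:
                continue  # boundary tiles sit on the 2% decision edge
            n_checked += 1
            expected = TileLabel.CANCER if frac > 0.02 else TileLabel.NORMAL
            n_correct += rec.label is expected
        assert n_checked > 0
        assert n_correct / n_checked >= 0.95

    def test_partition_and_conservation(self, aligned_pair):
        pair, _ = aligned_pair
        cfg = LabelingConfig(tile_px=64, downscale=1)
        records = label_slide(pair, pair.ihc_image, cfg, training=True)
        keys = {(r.tile_row, r.tile_col) for r in records}
        assert len(keys) == len(records) == len(tile_grid((256, 256), 64))


def test_build_dataset_counts_and_filtering():
    cfg = LabelingConfig(tile_px=64, downscale=1)
    reg_cfg = RegistrationConfig(downscale=1)
    pairs = []
    truths = []
    for seed, frac in [(101, 0.4), (102, 0.5), (103, 0.0)]:
        spec = SyntheticSpec(
            seed=seed, image_shape=(256, 256), smooth_px=40.0,
            cancer_region_fraction=frac,
            rotation_deg=1.0, translation_px=(4.0, -3.0),
        )
        pair, truth = generate_pair(spec)
        pairs.append(pair)
        truths.append(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = build_dataset(pairs, cfg, reg_cfg, training=True)
    per_slide = manifest.groupby("slide_id")["label"].value_counts()
    # every grid tile appears exactly once per slide
    n_grid = len(tile_grid((256, 256), 64))
    assert (manifest.groupby("slide_id").size() == n_grid).all()
    # cancer slides contribute no normal-labeled tiles and vice versa
    for pair, truth in zip(pairs, truths):
        labels = set(
            manifest[manifest["slide_id"] == pair.slide_id]["label"]
        )
        if pair.status is SlideStatus.CANCER:
            assert "normal" not in labels
        else:
            assert "cancer" not in labels
    # cancer slides keep a plausible share of cancer tiles for their purity
    cancer_kept = per_slide.get(("synthetic-101", "cancer"), 0)
    assert cancer_kept >= 2


def test_build_dataset_empty_input():
    manifest = build_dataset([], LabelingConfig())
    assert manifest.empty


def test_labels_from_annotation_majority_rule(aligned_pair):
    pair, truth = aligned_pair
    cfg = LabelingConfig(tile_px=64, downscale=1)
    records = labels_from_annotation(pair, cfg)
    assert len(records) == len(tile_grid((256, 256), 64))
    for rec in records:
        sl = np.s_[
            rec.tile_row * 64 : (rec.tile_row + 1) * 64,
            rec.tile_col * 64 : (rec.tile_col + 1) * 64,
        ]
        cover = pair.annotation_mask[sl].mean()
        expected = TileLabel.CANCER if cover >= 0.5 else TileLabel.NORMAL
        assert rec.label is expected
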