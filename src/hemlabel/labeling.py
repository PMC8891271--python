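"""Tile-level transfer of DAB positivity onto the H&E grid.

The H&E image is cut into non-overlapping 224 x 224 px tiles. Pixel-level
DAB masks live on the registered IHC image, which is at the registration
downscale (default 5x), so each tile corresponds to a 45 x 45 px label
tile there. A tile is called cancer when more than 2% of its label-tile
pixels are DAB-positive; tiles whose mean DAB OD falls inside a
user-selectable band are uncertain regardless of the fraction (the band
takes precedence, so an ambiguous tile is never labeled cancer). Tiles
where exactly one of the H&E / IHC pair contains tissue are discarded as
probable registration artifacts, and for training the slide-level filter
keeps only cancer tiles from cancer slides and only normal tiles from
normal slides.
"""
from __future__ import annotations

import logging
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import LabelingConfig, RegistrationConfig
from .io import records_to_manifest
from .registration import downscale_image, register_and_warp
from .separation import (
    ChannelStack,
    MaskSet,
    compute_masks,
    deconvolve_hed,
    tissue_mask,
)
from .types import SlidePair, SlideStatus, TileLabel, TileRecord

logger = logging.getLogger(__name__)


def tile_grid(image_shape: Tuple[int, int], tile_px: int) -> List[Tuple[int, int]]:
    """Grid coordinates (row, col) of all fully contained tiles, row-major.

    Tiles that would overhang the image are dropped, not padded; a
    partial tile would distort per-tile DAB fractions.
    """
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    h, w = image_shape[:2]
    return [(r, c) for r in range(h // tile_px) for c in range(w // tile_px)]


def label_tile(
    dab_positive_tile: np.ndarray,
    dab_od_tile: np.ndarray,
    tissue_tile: np.ndarray,
    cfg: LabelingConfig,
) -> tuple[TileLabel, float, float]:
    """Label one downsampled tile from its DAB statistics.

    Returns ``(label, dab_positive_fraction, mean_dab_od)``. The fraction
    counts positive pixels over *all* tile pixels; the mean DAB OD is
    taken over the tile's tissue pixels (background would dilute it) and
    drives the uncertainty band, which overrides the 2% rule.
    """
    if dab_positive_tile.size == 0:
        raise ValueError("empty tile")
    fraction = float(np.count_nonzero(dab_positive_tile) / dab_positive_tile.size)
    if tissue_tile.any():
        mean_od = float(np.asarray(dab_od_tile)[tissue_tile].mean())
    else:
        mean_od = 0.0
    if cfg.dab_uncertain_low <= mean_od <= cfg.dab_uncertain_high:
        label = TileLabel.UNCERTAIN
    elif fraction > cfg.cancer_fraction_threshold:
        label = TileLabel.CANCER
    else:
        label = TileLabel.NORMAL
    return label, fraction, mean_od


def he_tissue_mask(he_image: np.ndarray, cfg: LabelingConfig) -> np.ndarray:
    """Slide-level H&E tissue mask at the labeling downscale.

    Default method thresholds the slide's hematoxylin channel with Otsu
    (deterministic). The GrabCut alternative requires OpenCV, which is an
    optional dependency.
    """
    if cfg.tissue_method == "grabcut":
        raise ModuleNotFoundError(
            "tissue_method='grabcut' requires the optional opencv-python "
            "dependency; use the default 'otsu' method instead"
        )
    he_down = downscale_image(he_image, cfg.downscale)
    mask, _ = tissue_mask(he_down)
    return mask


def tissue_presence_check(
    tissue_fraction_he: float,
    tissue_fraction_ihc: float,
    cfg: LabelingConfig,
) -> tuple[bool, str]:
    """Decide whether to keep a tile based on matched tissue presence.

    Returns ``(keep, reason)``. A pair where exactly one side contains
    tissue indicates a registration error ("tissue_mismatch"); a pair
    where neither side has tissue is background ("no_tissue").
    """
    he_has = tissue_fraction_he >= cfg.tissue_presence_min
    ihc_has = tissue_fraction_ihc >= cfg.tissue_presence_min
    if he_has and ihc_has:
        return True, ""
    if not he_has and not ihc_has:
        return False, "no_tissue"
    return False, "tissue_mismatch"


def apply_slide_filter(
    records: Sequence[TileRecord],
    status: SlideStatus,
    training: bool = True,
) -> List[TileRecord]:
    """Slide-level training filter.

    In training mode a cancer slide contributes only its cancer tiles and
    a non-cancer slide only its normal tiles; everything else is
    re-labeled uncertain (with a reason) so no mislabeled tile reaches the
    classifier. In evaluation mode records pass through unchanged.
    """
    status = SlideStatus(status)
    if not training:
        return list(records)
    keep_label = (
        TileLabel.CANCER if status is SlideStatus.CANCER else TileLabel.NORMAL
    )
    out = []
    for rec in records:
        if rec.label in (TileLabel.UNCERTAIN, TileLabel.DISCARDED):
            out.append(rec)
        elif rec.label is keep_label:
            out.append(rec)
        else:
            rec.label = TileLabel.UNCERTAIN
            rec.reason = f"slide_filter:{status.value}"
            out.append(rec)
    return out


def label_slide(
    pair: SlidePair,
    registered_ihc: np.ndarray,
    cfg: LabelingConfig,
    masks: Optional[MaskSet] = None,
    stack: Optional[ChannelStack] = None,
    training: bool = True,
) -> List[TileRecord]:
    """Label every grid tile of one slide.

    ``registered_ihc`` is the color IHC image already registered onto the
    H&E grid at ``cfg.downscale``. Masks and channels are computed here
    unless supplied.
    """
    if stack is None:
        stack = deconvolve_hed(registered_ihc)
    if masks is None:
        masks = compute_masks(stack)
    he = pair.he_image
    he_tissue = he_tissue_mask(he, cfg)
    lpx = cfg.label_tile_px
    records: List[TileRecord] = []
    for row, col in tile_grid(he.shape[:2], cfg.tile_px):
        sl = np.s_[row * lpx : (row + 1) * lpx, col * lpx : (col + 1) * lpx]
        pos_tile = masks.dab_positive[sl]
        tis_tile = masks.tissue[sl]
        he_tis_tile = he_tissue[sl]
        if pos_tile.shape != (lpx, lpx) or he_tis_tile.shape != (lpx, lpx):
            continue  # label grid ran past the registered image
        dab_tile = stack.dab[sl]
        tf_he = float(he_tis_tile.mean())
        tf_ihc = float(tis_tile.mean())
        keep, reason = tissue_presence_check(tf_he, tf_ihc, cfg)
        if not keep:
            records.append(
                TileRecord(
                    slide_id=pair.slide_id,
                    tile_row=row,
                    tile_col=col,
                    he_tile_px=cfg.tile_px,
                    label_tile_px=lpx,
                    tissue_fraction_he=tf_he,
                    tissue_fraction_ihc=tf_ihc,
                    label=TileLabel.DISCARDED,
                    reason=reason,
                )
            )
            continue
        label, fraction, mean_od = label_tile(pos_tile, dab_tile, tis_tile, cfg)
        records.append(
            TileRecord(
                slide_id=pair.slide_id,
                tile_row=row,
                tile_col=col,
                he_tile_px=cfg.tile_px,
                label_tile_px=lpx,
                dab_positive_fraction=fraction,
                mean_dab_od=mean_od,
                tissue_fraction_he=tf_he,
                tissue_fraction_ihc=tf_ihc,
                label=label,
            )
        )
    if training:
        records = apply_slide_filter(records, pair.status, training=True)
        kept = [r for r in records if r.label in (TileLabel.CANCER, TileLabel.NORMAL)]
        if pair.status is SlideStatus.CANCER and not kept:
            warnings.warn(
                f"slide {pair.slide_id}: no tiles survived the cancer-slide "
                "filter (empty DAB mask?)",
                stacklevel=2,
            )
    return records


def build_dataset(
    pairs: Sequence[SlidePair],
    cfg: LabelingConfig,
    reg_cfg: Optional[RegistrationConfig] = None,
    training: bool = True,
) -> pd.DataFrame:
    """Run masks -> grid -> label -> tissue check -> slide filter per slide.

    Pairs are expected to be stain-normalized already. Registration runs
    here (IHC onto H&E at ``cfg.downscale``); per-slide label counts are
    logged. Returns the aggregate label manifest.
    """
    reg_cfg = reg_cfg or RegistrationConfig(downscale=cfg.downscale)
    if reg_cfg.downscale != cfg.downscale:
        raise ValueError("registration and labeling downscale must agree")
    all_records: List[TileRecord] = []
    for pair in pairs:
        try:
            _, registered, _, report = register_and_warp(
                pair.he_image, pair.ihc_image, reg_cfg
            )
            records = label_slide(pair, registered, cfg, training=training)
        except Exception as exc:
            raise type(exc)(f"slide {pair.slide_id}: {exc}") from exc
        counts = {
            label.value: sum(1 for r in records if r.label is label)
            for label in TileLabel
        }
        logger.info(
            "slide %s: MI %.3f -> %.3f, labels %s",
            pair.slide_id,
            report.mi_before,
            report.mi_after_bspline,
            counts,
        )
        all_records.extend(records)
    return records_to_manifest(all_records)


def labels_from_annotation(
    pair: SlidePair, cfg: LabelingConfig
) -> List[TileRecord]:
    """Tile labels from a pathologist annotation mask (evaluation truth).

    A tile is cancer when at least ``cfg.annotation_cover_threshold`` of
    its area lies inside the annotation mask.
    """
    if pair.annotation_mask is None:
        raise ValueError(f"slide {pair.slide_id} has no annotation mask")
    records = []
    for row, col in tile_grid(pair.he_image.shape[:2], cfg.tile_px):
        sl = np.s_[
            row * cfg.tile_px : (row + 1) * cfg.tile_px,
            col * cfg.tile_px : (col + 1) * cfg.tile_px,
        ]
        cover = float(pair.annotation_mask[sl].mean())
        records.append(
            TileRecord(
                slide_id=pair.slide_id,
                tile_row=row,
                tile_col=col,
                he_tile_px=cfg.tile_px,
                label_tile_px=cfg.label_tile_px,
                label=(
                    TileLabel.CANCER
                    if cover >= cfg.annotation_cover_threshold
                    else TileLabel.NORMAL
                ),
            )
        )
    return records
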