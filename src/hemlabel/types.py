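"""Core value types shared by all pipeline stages.

Images are plain numpy arrays: an RGB slide is ``uint8`` of shape
``(H, W, 3)``, an optical-density image is ``float64`` of the same shape,
masks are boolean ``(H, W)``. The helpers here validate those conventions
once so downstream code can assume them.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Tile side length at full resolution (pixels).
DEFAULT_TILE_PX = 224
#: Downscale factor between full-resolution H&E and the registered IHC.
DEFAULT_DOWNSCALE = 5


class SlideStatus(str, enum.Enum):
    """Slide-level diagnosis used for training-set filtering."""

    CANCER = "cancer"
    NON_CANCER = "non_cancer"


class TileLabel(str, enum.Enum):
    """Outcome of label transfer for one tile."""

    CANCER = "cancer"
    NORMAL = "normal"
    UNCERTAIN = "uncertain"
    DISCARDED = "discarded"


def as_rgb(pixels: np.ndarray) -> np.ndarray:
    """Validate and return an 8-bit RGB image array.

    Raises
    ------
    ValueError
        If the array is not ``(H, W, 3)`` or values fall outside [0, 255].
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate a boolean raster, optionally against an expected shape."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("mask must be binary (0/1 or 0/255)")
        arr = arr > 0
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} != expected {tuple(shape)}")
    return arr


@dataclass
class SlidePair:
    """A matched H&E / IHC slide pair from adjacent tissue sections.

    ``annotation_mask``, when present, is a boolean raster in H&E level-0
    pixel coordinates marking the pathologist-annotated cancer region.
    """

    slide_id: str
    he_image: np.ndarray
    ihc_image: np.ndarray
    status: SlideStatus
    magnification: float = 10.0
    annotation_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.he_image = as_rgb(self.he_image)
        self.ihc_image = as_rgb(self.ihc_image)
        self.status = SlideStatus(self.status)
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.annotation_mask is not None:
            self.annotation_mask = as_mask(
                self.annotation_mask, self.he_image.shape[:2]
            )


@dataclass
class TileRecord:
    """One grid tile with its DAB statistics and transferred label."""

    slide_id: str
    tile_row: int
    tile_col: int
    he_tile_px: int = DEFAULT_TILE_PX
    label_tile_px: int = round(DEFAULT_TILE_PX / DEFAULT_DOWNSCALE)
    dab_positive_fraction: float = 0.0
    mean_dab_od: float = 0.0
    tissue_fraction_he: float = 0.0
    tissue_fraction_ihc: float = 0.0
    label: TileLabel = TileLabel.NORMAL
    reason: str = ""
    tile_path: str = ""

    def __post_init__(self) -> None:
        self.label = TileLabel(self.label)
        for name in (
            "dab_positive_fraction",
            "tissue_fraction_he",
            "tissue_fraction_ihc",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.label is TileLabel.DISCARDED and not self.reason:
            raise ValueError("discarded tile must carry a reason")


@dataclass
class Prediction:
    """Per-tile cancer probability from the classifier."""

    slide_id: str
    tile_row: int
    tile_col: int
    p_cancer: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cancer <= 1.0:
            raise ValueError("p_cancer must lie in [0, 1]")


@dataclass
class PurityEstimate:
    """Slide-level tumor purity as tissue-area-weighted cancer fraction."""

    slide_id: str
    cancer_tissue_area: float
    total_tissue_area: float

    @property
    def purity(self) -> float:
        return self.cancer_tissue_area / self.total_tissue_area

    def __post_init__(self) -> None:
        if not 0.0 <= self.cancer_tissue_area <= self.total_tissue_area:
            raise ValueError("cancer tissue area must lie in [0, total]")


@dataclass
class MiReport:
    """Mutual information (nats) before/after each registration phase."""

    mi_before: float
    mi_after_affine: float
    mi_after_bspline: float
    histogram_bins: int = 50

    def __post_init__(self) -> None:
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        for v in (self.mi_before, self.mi_after_affine, self.mi_after_bspline):
            if not np.isfinite(v):
                raise ValueError("mutual information must be finite")


@dataclass
class EvalReport:
    """Classifier evaluation after class balancing."""

    accuracy: float
    confusion: np.ndarray  # rows = truth, cols = prediction, [normal, cancer]
    roc_auc: float
    n_per_class: int
    balancing_seed: int

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if not 0.0 <= self.roc_auc <= 1.0:
            raise ValueError("roc_auc must lie in [0, 1]")


@dataclass
class ChannelStack:
    """Hematoxylin / eosin / DAB optical-density channels of one image."""

    hematoxylin: np.ndarray
    eosin: np.ndarray
    dab: np.ndarray
    deconv_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.deconv_matrix = np.asarray(self.deconv_matrix, dtype=float)
        if self.deconv_matrix.shape != (3, 3):
            raise ValueError("deconvolution matrix must be 3x3")


@dataclass
class MaskSet:
    """Tissue and DAB-positive masks with the Otsu thresholds used."""

    tissue: np.ndarray
    dab_positive: np.ndarray
    otsu_tissue_threshold: float
    otsu_dab_threshold: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.tissue = as_mask(self.tissue)
        self.dab_positive = as_mask(self.dab_positive, self.tissue.shape)
        if np.any(self.dab_positive & ~self.tissue):
            raise ValueError("dab_positive must be a subset of tissue")
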