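"""Color deconvolution of IHC images and Otsu-based mask extraction.

A DAB-stained IHC slide carries three chromogens whose colors are known
unit vectors in optical-density space: hematoxylin (nuclei), eosin and the
brown DAB reaction product marking p53-positive cells. Per-pixel stain
amounts follow from inverting the 3x3 stain matrix (Ruifrok & Johnston).

Masks are computed in two Otsu stages: the hematoxylin channel separates
tissue from slide background over the whole image, then a second Otsu on
the DAB channel restricted to tissue pixels separates positive (high-OD,
strong brown) from faint background staining. Thresholds are computed
independently per slide so staining differences between slides do not
leak across.
"""
from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateInputError, InsufficientTissueError, RankError
from .normalization import rgb_to_od
from .types import ChannelStack, MaskSet, as_rgb

#: Published Ruifrok-Johnston H / E / DAB unit color vectors (OD space).
RUIFROK_HED = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.072, 0.990, 0.105],
        [0.268, 0.570, 0.776],
    ]
)
RUIFROK_HED = RUIFROK_HED / np.linalg.norm(RUIFROK_HED, axis=1, keepdims=True)

OTSU_BINS = 256


def deconvolve_hed(img: np.ndarray, M: np.ndarray | None = None) -> ChannelStack:
    """Unmix an RGB image into H, E and DAB optical-density channels.

    Solves ``OD = c @ M`` exactly per pixel (``M`` is 3x3 so the solve is
    a single matrix inverse). Channels may go slightly negative in noisy
    pixels; they are returned unclipped so the round trip through
    :func:`remix` is exact.
    """
    M = RUIFROK_HED if M is None else np.asarray(M, dtype=np.float64)
    if M.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    if abs(np.linalg.det(M)) < 1e-8:
        raise RankError("stain matrix is singular; cannot deconvolve")
    img = as_rgb(img)
    od = rgb_to_od(img).od
    conc = od.reshape(-1, 3) @ np.linalg.inv(M)
    conc = conc.reshape(img.shape)
    return ChannelStack(
        hematoxylin=conc[..., 0],
        eosin=conc[..., 1],
        dab=conc[..., 2],
        deconv_matrix=M,
    )


def remix(stack: ChannelStack) -> np.ndarray:
    """Forward Beer-Lambert mix of a channel stack back to OD."""
    conc = np.stack([stack.hematoxylin, stack.eosin, stack.dab], axis=-1)
    return conc.reshape(-1, 3) @ stack.deconv_matrix


def otsu_threshold(values: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Threshold maximizing between-class variance of a 1-D sample.

    The histogram spans the observed value range with ``bins`` bins and
    the threshold is the bin edge with maximal between-class variance
    ``w0 * w1 * (mu0 - mu1)^2``; ties break toward the lower edge.

    Raises
    ------
    DegenerateInputError
        If the sample is constant (no second class exists).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateInputError("empty sample")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateInputError("constant sample has no Otsu threshold")
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)[:-1]
    mu0 = sum0 / np.where(w0 > 0, w0, np.nan)
    mu1 = (counts * centers).sum() - sum0
    mu1 = mu1 / np.where(w1 > 0, w1, np.nan)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, -np.inf)
    best = int(np.argmax(between))  # argmax returns the first (lowest) tie
    return float(edges[best + 1])


def tissue_mask(img_or_stack: np.ndarray | ChannelStack) -> tuple[np.ndarray, float]:
    """Hematoxylin-Otsu tissue mask of a whole slide image.

    Accepts an RGB image or an existing :class:`ChannelStack`; returns
    ``(mask, threshold)``. The threshold is computed over the whole image,
    where the background/tissue bimodality makes Otsu reliable (per-tile
    Otsu would split whatever it is given, even pure background).
    """
    stack = (
        img_or_stack
        if isinstance(img_or_stack, ChannelStack)
        else deconvolve_hed(img_or_stack)
    )
    h = np.asarray(stack.hematoxylin, dtype=np.float64)
    try:
        thr = otsu_threshold(h)
    except DegenerateInputError as exc:
        raise InsufficientTissueError(
            "hematoxylin channel is constant; no tissue detected"
        ) from exc
    return h > thr, thr


def compute_masks(stack: ChannelStack, min_dab_od: float = 0.1) -> MaskSet:
    """Two-stage Otsu masks: tissue from hematoxylin, DAB-positive within tissue.

    Returns a :class:`MaskSet`; ``dab_positive`` is empty (with a warning)
    when the DAB signal inside tissue is degenerate, e.g. a slide with no
    staining at all.

    ``min_dab_od`` guards the second stage: Otsu always splits a sample in
    two, so on a slide without genuine DAB deposits the split lands inside
    the faint-background noise. A real chromogen deposit has OD far above
    background, so when the mean OD of the putative positive class falls
    below ``min_dab_od`` the slide is read as having no distinct positive
    staining and the positive mask is left empty.
    """
    h = np.asarray(stack.hematoxylin, dtype=np.float64)
    try:
        t_thr = otsu_threshold(h)
    except DegenerateInputError as exc:
        raise InsufficientTissueError(
            "hematoxylin channel is constant; no tissue detected"
        ) from exc
    tissue = h > t_thr
    if not tissue.any():
        raise InsufficientTissueError("no pixels above the tissue threshold")
    dab_tissue = np.asarray(stack.dab, dtype=np.float64)[tissue]
    try:
        d_thr = otsu_threshold(dab_tissue)
    except DegenerateInputError:
        d_thr = None
    # Judge the split by the mean OD of the positive class (the threshold
    # itself can sit on a tie plateau right above the negative mode).
    pos_mean = (
        float(dab_tissue[dab_tissue > d_thr].mean()) if d_thr is not None else 0.0
    )
    if d_thr is None or pos_mean < min_dab_od:
        warnings.warn(
            "no distinct DAB-positive staining within tissue "
            f"(threshold {'degenerate' if d_thr is None else f'{d_thr:.3f} OD'}); "
            "positive mask left empty",
            stacklevel=2,
        )
        return MaskSet(
            tissue=tissue,
            dab_positive=np.zeros_like(tissue),
            otsu_tissue_threshold=t_thr,
            otsu_dab_threshold=float("nan") if d_thr is None else d_thr,
        )
    dab_positive = tissue & (stack.dab > d_thr)
    return MaskSet(
        tissue=tissue,
        dab_positive=dab_positive,
        otsu_tissue_threshold=t_thr,
        otsu_dab_threshold=d_thr,
    )
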