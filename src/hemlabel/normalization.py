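"""H&E stain color normalization.

Stained tissue follows the Beer-Lambert law: optical density adds linearly
in the per-stain concentrations, ``OD = C @ S``, where the rows of the
stain matrix ``S`` are unit color vectors in OD space and ``C`` holds the
per-pixel stain concentrations. Normalization re-colors a source slide by
estimating its own ``S_source`` and ``C_source`` and re-mixing the
concentrations through a template slide's stain matrix,
``OD_norm = C_source @ S_template``, so every slide takes on the template's
stain appearance while keeping its own tissue structure.

Two stain-matrix estimators are provided: sparse non-negative dictionary
learning (Vahadane) and the SVD-plane percentile-angle method (Macenko).
Reinhard normalization (per-channel moment matching in LAB space) is kept
as a simpler alternative that bypasses the stain model entirely.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.color import lab2rgb, rgb2lab

from .config import NormalizationConfig
from .errors import DegenerateInputError, InsufficientTissueError, RankError
from .types import SlideStatus, as_rgb

#: White level after luminosity standardization.
DEFAULT_I0 = 255.0
#: Minimum tissue pixels required for a stain-matrix fit.
MIN_TISSUE_PIXELS = 100


@dataclass
class OdImage:
    """Optical-density transform of an RGB image."""

    od: np.ndarray  # (H, W, 3) float64, >= 0
    source_white: float = DEFAULT_I0


@dataclass
class StainModel:
    """Stain matrix plus per-pixel concentrations for one slide.

    ``S`` is (2, 3) with unit-norm rows, hematoxylin first; ``C`` is
    (N, 2) non-negative, N the number of flattened pixels.
    """

    S: np.ndarray
    C: Optional[np.ndarray] = None
    #: 99th-percentile concentration per stain, used for scaling.
    c_scale: Optional[np.ndarray] = None


def standardize_luminosity(img: np.ndarray) -> np.ndarray:
    """Rescale brightness so the slide background is near-white.

    The LAB lightness channel is divided by its 95th percentile (and
    clipped), leaving chroma untouched. On a typical slide the 95th
    percentile sits in the white background, which therefore maps to
    full lightness.
    """
    img = as_rgb(img)
    lab = rgb2lab(img)
    p95 = float(np.percentile(lab[..., 0], 95))
    if p95 <= 0:
        raise DegenerateInputError("image is black; cannot standardize luminosity")
    lab[..., 0] = np.clip(lab[..., 0] * (100.0 / p95), 0.0, 100.0)
    out = lab2rgb(lab)
    return np.clip(out * 255.0, 0, 255).round().astype(np.uint8)


def rgb_to_od(img: np.ndarray, I0: float = DEFAULT_I0) -> OdImage:
    """Convert 8-bit RGB to optical density, ``-log10(I / I0)``.

    Intensities are clamped to >= 1 before the log so the transform is
    finite everywhere; a pixel at the white level I0 maps to OD 0.
    """
    if I0 <= 0:
        raise ValueError("I0 must be positive")
    arr = np.maximum(np.asarray(img, dtype=np.float64), 1.0)
    od = -np.log10(arr / I0)
    return OdImage(od=np.maximum(od, 0.0), source_white=float(I0))


def od_to_rgb(od: np.ndarray | OdImage, I0: float = DEFAULT_I0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (rounded to 8 bits)."""
    if isinstance(od, OdImage):
        I0 = od.source_white
        od = od.od
    intensity = I0 * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(intensity, 0, 255).round().astype(np.uint8)


def _tissue_od_pixels(od: OdImage, beta: float) -> np.ndarray:
    """Flattened OD rows whose maximum channel exceeds the cutoff ``beta``.

    A pure stain can be almost transparent in one channel (eosin barely
    absorbs red), so thresholding on the maximum channel keeps near-pure
    stain pixels — which anchor the stain-vector fit — while still
    rejecting the white background.
    """
    flat = od.od.reshape(-1, 3)
    return flat[flat.max(axis=1) > beta]


def _order_he_rows(S: np.ndarray) -> np.ndarray:
    """Put hematoxylin in row 0.

    Hematoxylin (blue-violet) absorbs red strongly while eosin (pink)
    transmits it almost completely, so the row with the larger red-channel
    OD component is hematoxylin (0.65 vs 0.07 for the published vectors).
    """
    order = np.argsort(-S[:, 0])
    return S[order]


def _unit_rows(S: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise RankError("stain vector with zero norm")
    return S / norms


def estimate_stain_matrix(
    od: OdImage,
    method: str = "vahadane",
    config: NormalizationConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Estimate the 2x3 H&E stain matrix of a slide.

    vahadane
        Sparse non-negative dictionary learning with 2 atoms on the tissue
        OD pixels (sklearn ``DictionaryLearning`` with positive code and
        dictionary, sparsity weight ``config.sparsity``).
    macenko
        Project tissue OD onto the top-2 SVD plane and take the stain
        vectors at the 1st/99th percentile angles.

    Rows are unit-norm with hematoxylin first.
    """
    cfg = config or NormalizationConfig()
    pixels = _tissue_od_pixels(od, cfg.beta)
    if len(pixels) < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {len(pixels)} tissue pixels above beta={cfg.beta}; "
            f"need >= {MIN_TISSUE_PIXELS}"
        )
    rng = np.random.default_rng(seed)
    if len(pixels) > cfg.max_fit_pixels:
        pixels = pixels[
            rng.choice(len(pixels), cfg.max_fit_pixels, replace=False)
        ]
    # Two distinct stains require OD directions spanning a 2-D plane.
    sv = np.linalg.svd(pixels - 0, compute_uv=False)
    if sv[1] < 1e-3 * sv[0]:
        raise RankError(
            "tissue OD is effectively one-dimensional (single stain?); "
            "cannot estimate two stain vectors"
        )
    if method == "vahadane":
        S = _vahadane_matrix(pixels, cfg, rng)
    elif method == "macenko":
        S = _macenko_matrix(pixels)
    else:
        raise ValueError(f"unknown stain estimation method {method!r}")
    return _order_he_rows(_unit_rows(S))


def _vahadane_matrix(
    pixels: np.ndarray, cfg: NormalizationConfig, rng: np.random.Generator
) -> np.ndarray:
    from sklearn.decomposition import DictionaryLearning

    dl = DictionaryLearning(
        n_components=2,
        alpha=cfg.sparsity,
        positive_code=True,
        positive_dict=True,
        fit_algorithm="cd",
        transform_algorithm="lasso_cd",
        max_iter=50,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dl.fit(pixels)
    S = _unit_rows(np.maximum(dl.components_, 0.0))
    # The L1 code penalty biases the learned atoms toward the interior of
    # the data cone; a few alternating NNLS sweeps without the penalty
    # sharpen them onto the stain directions.
    od_img = OdImage(od=pixels.reshape(-1, 1, 3))
    for _ in range(5):
        C, _ = estimate_concentrations(od_img, S)
        S_new, *_ = np.linalg.lstsq(C, pixels, rcond=None)
        S = _unit_rows(np.maximum(S_new, 0.0))
    return S


def _macenko_matrix(pixels: np.ndarray) -> np.ndarray:
    # Eigenvectors of the OD covariance span the stain plane; extreme
    # percentile angles within the plane are the stain directions.
    _, _, vt = np.linalg.svd(pixels, full_matrices=False)
    plane = vt[:2]
    # Orient basis so projections are mostly positive.
    plane = plane * np.sign(plane.sum(axis=1, keepdims=True) + 1e-12)
    proj = pixels @ plane.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, (1, 99))
    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    S = np.vstack([v1, v2])
    S[S < 0] = 0.0
    return S


def estimate_concentrations(od: OdImage, S: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-pixel non-negative least-squares solve of ``OD = C @ S``.

    Returns ``(C, residual)`` where ``C`` is (N, k) with N flattened
    pixels and ``residual`` is the root-mean-square OD reconstruction
    error. Exact for k <= 3 via active-set enumeration, vectorized over
    pixels.
    """
    S = np.asarray(S, dtype=np.float64)
    k = S.shape[0]
    if np.linalg.matrix_rank(S) < k:
        raise RankError("stain matrix is rank deficient")
    flat = od.od.reshape(-1, 3)
    n = len(flat)
    best_c = np.zeros((n, k))
    best_res = np.einsum("ij,ij->i", flat, flat)  # residual with C = 0
    # Enumerate non-empty active sets; keep the feasible solution with the
    # smallest residual. For k = 2 this is exact NNLS.
    for mask_bits in range(1, 2**k):
        idx = [i for i in range(k) if mask_bits >> i & 1]
        Ssub = S[idx]
        pinv = np.linalg.pinv(Ssub)
        c_sub = flat @ pinv  # (n, |idx|) unconstrained LS on subset
        feasible = np.all(c_sub >= -1e-12, axis=1)
        recon = c_sub @ Ssub
        res = np.einsum("ij,ij->i", flat - recon, flat - recon)
        better = feasible & (res < best_res - 1e-15)
        if np.any(better):
            best_res[better] = res[better]
            best_c[better] = 0.0
            best_c[np.ix_(better, idx)] = np.maximum(c_sub[better], 0.0)
    rms = float(np.sqrt(best_res.mean()))
    return best_c, rms


def fit_stain_model(
    img: np.ndarray,
    method: str = "vahadane",
    config: NormalizationConfig | None = None,
    seed: int = 0,
) -> StainModel:
    """Estimate stain matrix, concentrations and concentration scale."""
    cfg = config or NormalizationConfig()
    od = rgb_to_od(img)
    S = estimate_stain_matrix(od, method=method, config=cfg, seed=seed)
    C, _ = estimate_concentrations(od, S)
    c_scale = np.percentile(C, cfg.scale_percentile, axis=0)
    return StainModel(S=S, C=C, c_scale=np.maximum(c_scale, 1e-8))


def normalize_to_template(
    src: np.ndarray,
    template: StainModel,
    method: str = "vahadane",
    config: NormalizationConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Re-color a source slide with the template's stain profile.

    For ``vahadane``/``macenko`` the source concentrations are rescaled so
    their 99th percentile matches the template's, then re-mixed through
    ``S_template``. For ``reinhard``, per-channel mean/std matching in LAB
    space is applied instead (``template.C`` must then hold the template's
    LAB statistics from :func:`reinhard_stats`).
    """
    src = as_rgb(src)
    if method == "reinhard":
        return _reinhard_normalize(src, template)
    cfg = config or NormalizationConfig()
    # A pure-background image has nothing to re-color: leave it unchanged.
    od_src = rgb_to_od(src)
    if len(_tissue_od_pixels(od_src, cfg.beta)) == 0:
        return src.copy()
    model = fit_stain_model(src, method=method, config=cfg, seed=seed)
    scale = template.c_scale / np.percentile(
        model.C, cfg.scale_percentile, axis=0
    ).clip(1e-8)
    od_norm = (model.C * scale) @ template.S
    return od_to_rgb(od_norm.reshape(src.shape))


def reinhard_stats(img: np.ndarray) -> StainModel:
    """Template statistics for Reinhard normalization (LAB mean/std)."""
    lab = rgb2lab(as_rgb(img))
    stats = np.vstack([lab.reshape(-1, 3).mean(0), lab.reshape(-1, 3).std(0)])
    return StainModel(S=np.eye(2, 3), C=stats)


def _reinhard_normalize(src: np.ndarray, template: StainModel) -> np.ndarray:
    if template.C is None or template.C.shape != (2, 3):
        raise ValueError("reinhard template must come from reinhard_stats()")
    t_mean, t_std = template.C
    lab = rgb2lab(src)
    s_mean = lab.reshape(-1, 3).mean(0)
    s_std = np.maximum(lab.reshape(-1, 3).std(0), 1e-8)
    lab = (lab - s_mean) * (t_std / s_std) + t_mean
    out = lab2rgb(lab)
    return np.clip(out * 255.0, 0, 255).round().astype(np.uint8)


def select_template(
    slides: Sequence[np.ndarray],
    statuses: Optional[Sequence[SlideStatus]] = None,
) -> int:
    """Pick the template slide for normalization.

    Returns the index of the slide whose mean (R, G, B) vector is closest
    (Euclidean) to the componentwise median of all slides' mean vectors.
    When statuses are given, only cancer slides are eligible, but the
    median is still taken over the full cohort. Ties break to the lowest
    index.
    """
    if len(slides) == 0:
        raise ValueError("no slides to select a template from")
    means = np.array([as_rgb(s).reshape(-1, 3).mean(0) for s in slides])
    median = np.median(means, axis=0)
    dist = np.linalg.norm(means - median, axis=1)
    if statuses is not None:
        statuses = [SlideStatus(s) for s in statuses]
        eligible = [
            i for i, s in enumerate(statuses) if s is SlideStatus.CANCER
        ]
        if not eligible:
            eligible = list(range(len(slides)))
        dist_eligible = dist[eligible]
        return eligible[int(np.argmin(dist_eligible))]
    return int(np.argmin(dist))
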