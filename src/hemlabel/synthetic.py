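"""Synthetic adjacent-section slide pairs with full ground truth.

Every pipeline stage is tested against pairs of pseudo-H&E and pseudo-IHC
images rendered from a known forward model:

* tissue and cancer regions are smoothed Gaussian random fields
  thresholded at the quantile matching the requested area fractions
  (smooth blobs, no attempt at histologic realism);
* per-pixel stain concentrations follow a nuclei/stroma structure with
  smooth positive textures; cancer regions have an elevated nuclear
  density (``cancer_nuclear_boost``), emulating tumor hypercellularity so
  cancer is morphologically visible in the H&E rendering, not only in
  the DAB channel;
* images are rendered through Beer-Lambert mixing ``OD = C @ S`` with
  known stain matrices, additive Gaussian OD noise, and a white slide
  background;
* the IHC image carries a DAB deposit of known optical density on the
  cancer mask plus faint non-specific background staining, and is then
  warped by a known misalignment (affine, optionally plus a smooth
  sinusoidal displacement) with white fill.

The returned :class:`SyntheticTruth` holds the masks, the aligning
transform the registration stage should recover, and the true area
purity, all exactly consistent with the rendered images.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import gaussian_filter

from .normalization import od_to_rgb
from .registration import TransformChain
from .separation import RUIFROK_HED
from .types import SlidePair, SlideStatus

#: Default H&E stain matrix (hematoxylin, eosin rows of the published
#: Ruifrok-Johnston vectors).
DEFAULT_S_HE = RUIFROK_HED[:2].copy()
#: Default IHC stain matrix (H, E, DAB).
DEFAULT_S_IHC = RUIFROK_HED.copy()


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic slide pair. ``seed`` is mandatory."""

    seed: int
    image_shape: Tuple[int, int] = (1024, 1024)
    #: Fraction of the image covered by tissue.
    tissue_fraction: float = 0.55
    #: Correlation length of the random fields, pixels. Tumor regions in a
    #: colorectal section span millimeters, i.e. many 224-px tiles at x10,
    #: so the regions are drawn much larger than one tile.
    smooth_px: float = 110.0
    #: Target fraction of tissue that is cancer (area purity).
    cancer_region_fraction: float = 0.3
    #: Correlation length of the nuclear-density field, pixels — cellular
    #: scale, an order of magnitude below the region scale.
    nuclear_px: float = 9.0
    #: Optical blur (point-spread) applied to the concentration fields,
    #: pixels; emulates microscope resolution and section thickness.
    psf_px: float = 1.5
    stain_matrix_he: np.ndarray = field(default_factory=lambda: DEFAULT_S_HE.copy())
    stain_matrix_ihc: np.ndarray = field(default_factory=lambda: DEFAULT_S_IHC.copy())
    #: Mean stain concentrations (OD units at unit stain vector).
    h_concentration: float = 0.6
    e_concentration: float = 0.35
    #: DAB optical density in cancer regions of the IHC image.
    dab_concentration: float = 1.0
    #: Faint non-specific DAB background within tissue.
    dab_background: float = 0.02
    #: Nuclear-density elevation in cancer regions (hypercellularity):
    #: added to the [0, 1] nuclei field before it drives hematoxylin.
    cancer_nuclear_boost: float = 0.35
    #: Misalignment of the IHC image: rotation about the image center,
    #: translation, isotropic scale, optional smooth sinusoidal warp.
    rotation_deg: float = 2.0
    translation_px: Tuple[float, float] = (8.0, -6.0)
    scale: float = 1.0
    warp_amplitude_px: float = 0.0
    warp_wavelength_px: float = 200.0
    #: Additive Gaussian noise in OD space.
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.cancer_region_fraction <= 1.0:
            raise ValueError("cancer_region_fraction must lie in [0, 1]")
        if not 0.0 < self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one synthetic pair (H&E coordinates)."""

    tissue_mask: np.ndarray
    cancer_mask: np.ndarray
    #: Transform aligning the misaligned IHC back onto the H&E grid
    #: (affine part; what the registration stage should recover).
    true_transform: TransformChain
    #: Forward misalignment as a SimpleITK transform (full-resolution
    #: coordinates), for residual-displacement checks.
    forward_misalignment: sitk.Transform
    true_concentrations: dict
    true_purity: float

    def __post_init__(self) -> None:
        if np.any(self.cancer_mask & ~self.tissue_mask):
            raise ValueError("cancer mask must be a subset of tissue")
        area = self.tissue_mask.sum()
        purity = self.cancer_mask.sum() / area if area else 0.0
        if abs(purity - self.true_purity) > 1e-6:
            raise ValueError("true_purity inconsistent with masks")


def _smooth_field(rng: np.random.Generator, shape, smooth_px: float) -> np.ndarray:
    # Generated on a coarse grid and bilinearly upsampled: for correlation
    # lengths of tens of pixels the result is indistinguishable from
    # filtering at full resolution and much cheaper on large slides.
    ds = max(1, int(smooth_px / 6.0))
    if ds == 1:
        f = gaussian_filter(rng.standard_normal(shape), smooth_px)
    else:
        from scipy.ndimage import zoom

        coarse_shape = tuple(int(np.ceil(s / ds)) + 1 for s in shape)
        f = gaussian_filter(rng.standard_normal(coarse_shape), smooth_px / ds)
        f = zoom(f, ds, order=1)[: shape[0], : shape[1]]
    return (f - f.mean()) / max(f.std(), 1e-12)


def _texture(rng: np.random.Generator, shape, smooth_px: float) -> np.ndarray:
    """Smooth positive multiplicative texture, mean 1, sd 0.1."""
    return np.clip(1.0 + 0.1 * _smooth_field(rng, shape, smooth_px / 3.0), 0.7, 1.3)


def _threshold_at_fraction(values: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean mask selecting the top ``fraction`` of ``values``."""
    if fraction <= 0:
        return np.zeros(values.shape, dtype=bool)
    if fraction >= 1:
        return np.ones(values.shape, dtype=bool)
    thr = np.quantile(values, 1.0 - fraction)
    return values > thr


def _render(od: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return od_to_rgb(np.maximum(od, 0.0))


def _misalignment_transform(spec: SyntheticSpec) -> sitk.Transform:
    h, w = spec.image_shape
    center = (w / 2.0, h / 2.0)
    aff = sitk.AffineTransform(2)
    theta = np.radians(spec.rotation_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    aff.SetMatrix(tuple((spec.scale * rot).ravel()))
    aff.SetCenter(center)
    aff.SetTranslation(tuple(spec.translation_px))
    if spec.warp_amplitude_px <= 0:
        return aff
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    k = 2.0 * np.pi / spec.warp_wavelength_px
    disp = np.zeros((h, w, 2), dtype=np.float64)
    disp[..., 0] = spec.warp_amplitude_px * np.sin(k * yy)  # dx
    disp[..., 1] = spec.warp_amplitude_px * np.cos(k * xx)  # dy
    disp_img = sitk.GetImageFromArray(disp, isVector=True)
    disp_t = sitk.DisplacementFieldTransform(disp_img)
    # Affine applied first, then the smooth warp.
    return sitk.CompositeTransform([disp_t, aff])


def _invert_affine(aff: sitk.AffineTransform) -> TransformChain:
    m = np.array(aff.GetMatrix()).reshape(2, 2)
    c = np.array(aff.GetCenter())
    t = np.array(aff.GetTranslation())
    m_inv = np.linalg.inv(m)
    return TransformChain(
        affine_matrix=m_inv,
        affine_translation=-m_inv @ t,
        affine_center=c,
        downscale=1,
    )


def _warp_rgb(img: np.ndarray, transform: sitk.Transform) -> np.ndarray:
    out = np.empty_like(img)
    for ch in range(3):
        s = sitk.GetImageFromArray(img[..., ch].astype(np.float32))
        r = sitk.Resample(s, s, transform, sitk.sitkLinear, 255.0)
        out[..., ch] = np.clip(sitk.GetArrayFromImage(r), 0, 255).round()
    return out


def generate_pair(spec: SyntheticSpec) -> tuple[SlidePair, SyntheticTruth]:
    """Render one matched H&E / IHC pair with ground truth.

    Deterministic for a fixed spec (same seed gives byte-identical
    images). The H&E image is in reference coordinates; the IHC image is
    warped by the spec's misalignment, which registration must undo.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)

    tissue = _threshold_at_fraction(
        _smooth_field(rng, shape, spec.smooth_px), spec.tissue_fraction
    )
    cancer_field = _smooth_field(rng, shape, spec.smooth_px)
    if tissue.any() and spec.cancer_region_fraction > 0:
        inner = _threshold_at_fraction(
            cancer_field[tissue], spec.cancer_region_fraction
        )
        cancer = np.zeros(shape, dtype=bool)
        cancer[tissue] = inner
    else:
        cancer = np.zeros(shape, dtype=bool)

    # Nuclear structure: hematoxylin concentrates in nuclei-rich patches,
    # eosin in the complementary stroma/cytoplasm, on top of a baseline of
    # both stains everywhere in tissue. Anti-correlation keeps the stain
    # vectors identifiable from the rendered mix, as in real H&E.
    # Cancer raises the nuclear density (hypercellularity), not the stain
    # strength of individual nuclei, so the signal survives per-slide
    # concentration rescaling during stain normalization.
    # Nuclei occupy roughly a quarter of the tissue area; the baseline
    # hematoxylin in stroma/cytoplasm stays well above slide background so
    # whole-slide Otsu tissue detection has a clean background/tissue gap.
    nuclei = 1.0 / (
        1.0 + np.exp(-3.0 * (_smooth_field(rng, shape, spec.nuclear_px) - 0.6))
    )
    nuclei = np.clip(nuclei + spec.cancer_nuclear_boost * cancer, 0.0, 1.0)
    tex_h = _texture(rng, shape, spec.smooth_px)
    tex_e = _texture(rng, shape, spec.smooth_px)
    c_h = spec.h_concentration * (0.55 + 0.9 * nuclei) * tex_h
    c_h *= tissue
    c_e = spec.e_concentration * (1.45 - 0.9 * nuclei) * tex_e
    c_e *= tissue

    if spec.psf_px > 0:
        c_h = gaussian_filter(c_h, spec.psf_px)
        c_e = gaussian_filter(c_e, spec.psf_px)
    s_he = np.asarray(spec.stain_matrix_he, dtype=float)
    s_he = s_he / np.linalg.norm(s_he, axis=1, keepdims=True)
    od_he = c_h[..., None] * s_he[0] + c_e[..., None] * s_he[1]
    he_img = _render(od_he, spec.noise_sd, rng)

    c_dab = np.where(cancer, spec.dab_concentration, 0.0)
    c_dab += spec.dab_background * tissue
    c_dab *= _texture(rng, shape, spec.smooth_px)
    if spec.psf_px > 0:
        c_dab = gaussian_filter(c_dab, spec.psf_px)
    s_ihc = np.asarray(spec.stain_matrix_ihc, dtype=float)
    s_ihc = s_ihc / np.linalg.norm(s_ihc, axis=1, keepdims=True)
    od_ihc = c_h[..., None] * s_ihc[0] + c_dab[..., None] * s_ihc[2]
    ihc_aligned = _render(od_ihc, spec.noise_sd, rng)

    forward = _misalignment_transform(spec)
    if isinstance(forward, sitk.AffineTransform):
        aligning = _invert_affine(forward)
    else:
        aligning = _invert_affine(
            sitk.AffineTransform(
                sitk.CompositeTransform(forward).GetNthTransform(1)
            )
        )
    is_identity = (
        spec.rotation_deg == 0
        and spec.scale == 1.0
        and spec.translation_px == (0.0, 0.0)
        and spec.warp_amplitude_px <= 0
    )
    ihc_img = ihc_aligned if is_identity else _warp_rgb(ihc_aligned, forward)

    status = (
        SlideStatus.CANCER if spec.cancer_region_fraction > 0
        else SlideStatus.NON_CANCER
    )
    pair = SlidePair(
        slide_id=f"synthetic-{spec.seed}",
        he_image=he_img,
        ihc_image=ihc_img,
        status=status,
        annotation_mask=cancer.copy() if status is SlideStatus.CANCER else None,
    )
    purity = float(cancer.sum() / tissue.sum()) if tissue.any() else 0.0
    truth = SyntheticTruth(
        tissue_mask=tissue,
        cancer_mask=cancer,
        true_transform=aligning,
        forward_misalignment=forward,
        true_concentrations={"hematoxylin": c_h, "eosin": c_e, "dab": c_dab},
        true_purity=purity,
    )
    return pair, truth


def _perturb_stains(
    S: np.ndarray, rng: np.random.Generator, sd: float = 0.08
) -> np.ndarray:
    out = np.clip(S + rng.normal(0.0, sd, S.shape), 0.0, None)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def generate_cohort(
    n_cancer: int,
    n_normal: int,
    purity_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    base_spec: Optional[SyntheticSpec] = None,
    vary_stains: bool = True,
) -> List[tuple[SlidePair, SyntheticTruth]]:
    """Generate a cohort of slide pairs with varied stain appearance.

    Cancer slides take their target purity from ``purity_grid`` (cycled;
    default 0.3); normal slides have an empty cancer mask. Per-slide
    stain matrices are randomly perturbed when ``vary_stains`` so the
    cohort exercises stain normalization. Reproducible from ``seed``.
    """
    if n_cancer < 0 or n_normal < 0:
        raise ValueError("counts must be >= 0")
    base = base_spec or SyntheticSpec(seed=seed)
    rng = np.random.default_rng(seed)
    purities = list(purity_grid) if purity_grid else [base.cancer_region_fraction]
    out: List[tuple[SlidePair, SyntheticTruth]] = []
    for i in range(n_cancer + n_normal):
        is_cancer = i < n_cancer
        spec = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            cancer_region_fraction=(
                purities[i % len(purities)] if is_cancer else 0.0
            ),
            stain_matrix_he=(
                _perturb_stains(np.asarray(base.stain_matrix_he), rng)
                if vary_stains
                else np.asarray(base.stain_matrix_he).copy()
            ),
        )
        pair, truth = generate_pair(spec)
        pair.slide_id = f"{'cancer' if is_cancer else 'normal'}-{i:02d}"
        out.append((pair, truth))
    return out
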