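"""Mutual-information registration of IHC images onto H&E images.

Adjacent tissue sections are close to identical but the two slides are
scanned independently, so the IHC image is misaligned with respect to its
H&E counterpart. Both images are converted to grayscale, downscaled by a
user-set factor (default 5), and the IHC image is aligned by maximizing
the mutual information of the joint grayscale histogram: first with an
affine transform (translation, rotation, scale, shear), then with a
B-spline free-form deformation for residual local warps, each within a
multi-resolution pyramid. Only the IHC image is ever resampled; the H&E
image stays untouched. Out-of-field pixels are filled with white, the
color of the empty slide.

The fit itself runs through SimpleITK (Mattes mutual information,
gradient-descent optimizer); the reported mutual information values are
computed by this module's own joint-histogram estimator in nats.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import SimpleITK as sitk
from skimage.transform import rescale

from .config import RegistrationConfig
from .errors import RegistrationError, TransformError
from .types import MiReport, as_rgb

#: ITU-R BT.601 luminance weights used for the grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance channel (0.299 R + 0.587 G + 0.114 B), 8-bit."""
    img = as_rgb(img)
    return (img.astype(np.float64) @ LUMA_WEIGHTS).round().astype(np.uint8)


def downscale_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Anti-aliased downscaling by an integer factor (RGB or grayscale)."""
    if factor < 1:
        raise ValueError("downscale factor must be >= 1")
    if factor == 1:
        return np.asarray(img).copy()
    channel_axis = 2 if img.ndim == 3 else None
    out = rescale(
        img.astype(np.float64),
        1.0 / factor,
        anti_aliasing=True,
        channel_axis=channel_axis,
        preserve_range=True,
    )
    return np.clip(out, 0, 255).round().astype(np.uint8)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 50) -> float:
    """Mutual information of two grayscale images in nats.

    ``I(A, B) = sum_{a,b} p(a,b) log( p(a,b) / (p(a) p(b)) )`` evaluated
    on the joint histogram of pixel intensities. Symmetric, non-negative,
    and zero when either image is constant.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same number of pixels")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    p = joint / joint.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


@dataclass
class TransformChain:
    """Affine followed by B-spline displacement, H&E -> IHC sampling.

    The transform maps a point of the (downscaled) H&E grid to the
    location in the (downscaled) IHC image whose intensity should land
    there, i.e. it is used directly for resampling the IHC image.
    """

    affine_matrix: np.ndarray  # (2, 2), x/y convention
    affine_translation: np.ndarray  # (2,)
    affine_center: np.ndarray  # (2,)
    downscale: int = 1
    bspline_fixed_parameters: Optional[list] = None
    bspline_parameters: Optional[list] = None

    def __post_init__(self) -> None:
        self.affine_matrix = np.asarray(self.affine_matrix, dtype=float).reshape(2, 2)
        self.affine_translation = np.asarray(self.affine_translation, dtype=float)
        self.affine_center = np.asarray(self.affine_center, dtype=float)
        if abs(np.linalg.det(self.affine_matrix)) < 1e-12:
            raise TransformError("affine matrix is singular")
        if self.bspline_parameters is not None and not np.all(
            np.isfinite(self.bspline_parameters)
        ):
            raise TransformError("non-finite B-spline displacements")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_sitk(
        cls,
        affine: sitk.Transform,
        bspline: Optional[sitk.BSplineTransform] = None,
        downscale: int = 1,
    ) -> "TransformChain":
        aff = sitk.AffineTransform(sitk.CompositeTransform(affine).GetNthTransform(0))
        return cls(
            affine_matrix=np.array(aff.GetMatrix()).reshape(2, 2),
            affine_translation=np.array(aff.GetTranslation()),
            affine_center=np.array(aff.GetCenter()),
            downscale=downscale,
            bspline_fixed_parameters=(
                list(bspline.GetFixedParameters()) if bspline is not None else None
            ),
            bspline_parameters=(
                list(bspline.GetParameters()) if bspline is not None else None
            ),
        )

    def to_sitk(self) -> sitk.Transform:
        aff = sitk.AffineTransform(2)
        aff.SetMatrix(tuple(self.affine_matrix.ravel()))
        aff.SetTranslation(tuple(self.affine_translation))
        aff.SetCenter(tuple(self.affine_center))
        if self.bspline_parameters is None:
            return aff
        bsp = sitk.BSplineTransform(2, 3)
        bsp.SetFixedParameters(tuple(self.bspline_fixed_parameters))
        bsp.SetParameters(tuple(self.bspline_parameters))
        # Moving-initial-transform convention: B-spline applied first,
        # affine second.
        return sitk.CompositeTransform([aff, bsp])

    # -- geometry helpers ------------------------------------------------
    def transform_points(self, points_xy: np.ndarray) -> np.ndarray:
        """Map (N, 2) x/y points through the chain."""
        t = self.to_sitk()
        return np.array([t.TransformPoint(tuple(p)) for p in np.atleast_2d(points_xy)])

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the affine's linear part, degrees."""
        m = self.affine_matrix
        return float(np.degrees(np.arctan2(m[1, 0], m[0, 0])))

    def displacement_at(self, point_xy) -> np.ndarray:
        """Displacement vector T(p) - p at one point (affine part only)."""
        p = np.asarray(point_xy, dtype=float)
        return (
            self.affine_matrix @ (p - self.affine_center)
            + self.affine_center
            + self.affine_translation
            - p
        )

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "affine_matrix": self.affine_matrix.ravel().tolist(),
            "affine_translation": self.affine_translation.tolist(),
            "affine_center": self.affine_center.tolist(),
            "downscale": self.downscale,
            "bspline_fixed_parameters": self.bspline_fixed_parameters,
            "bspline_parameters": self.bspline_parameters,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransformChain":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        return cls(
            affine_matrix=np.array(data["affine_matrix"]).reshape(2, 2),
            affine_translation=data["affine_translation"],
            affine_center=data["affine_center"],
            downscale=data["downscale"],
            bspline_fixed_parameters=data["bspline_fixed_parameters"],
            bspline_parameters=data["bspline_parameters"],
        )


def _as_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.asarray(img, dtype=np.float32))


def _levels_for(cfg: RegistrationConfig, shape: tuple[int, int]) -> tuple[list, list]:
    """Drop pyramid levels that would shrink the image below 32 px."""
    min_side = min(shape)
    shrink, smooth = [], []
    for f, s in zip(cfg.shrink_factors, cfg.smoothing_sigmas):
        if min_side / f >= 32 or f == 1:
            shrink.append(f)
            smooth.append(s)
    return shrink or [1], smooth or [0.0]


def _run_registration(method: sitk.ImageRegistrationMethod, fixed, moving):
    try:
        result = method.Execute(fixed, moving)
        final_metric = method.GetMetricValue()
    except RuntimeError as exc:
        raise RegistrationError(f"registration optimizer failed: {exc}") from exc
    if not np.isfinite(final_metric):
        raise RegistrationError(
            f"non-finite registration metric ({final_metric}); "
            f"optimizer stop: {method.GetOptimizerStopConditionDescription()}"
        )
    return result


def register_pair(
    he: np.ndarray,
    ihc: np.ndarray,
    cfg: RegistrationConfig | None = None,
) -> tuple[TransformChain, MiReport]:
    """Fit the IHC -> H&E alignment and report mutual information.

    Both images are converted to grayscale and downscaled by
    ``cfg.downscale`` before fitting. Mutual information (this module's
    joint-histogram estimator, ``cfg.histogram_bins`` bins) is recorded
    before registration, after the affine phase and after the B-spline
    phase.
    """
    cfg = cfg or RegistrationConfig()
    fixed_np = downscale_image(to_grayscale(he), cfg.downscale)
    moving_np = downscale_image(to_grayscale(ihc), cfg.downscale)
    fixed = _as_sitk(fixed_np)
    moving = _as_sitk(moving_np)

    identity_resampled = sitk.GetArrayFromImage(
        sitk.Resample(moving, fixed, sitk.Transform(2, sitk.sitkIdentity),
                      sitk.sitkLinear, 255.0)
    )
    mi_before = mutual_information(fixed_np, identity_resampled, cfg.histogram_bins)

    shrink, smooth = _levels_for(cfg, fixed_np.shape)

    def _make_method() -> sitk.ImageRegistrationMethod:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(cfg.histogram_bins)
        reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.learning_rate,
            minStep=1e-4,
            numberOfIterations=cfg.iterations,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel(smooth)
        return reg

    def _measure(transform: sitk.Transform) -> float:
        resampled = sitk.GetArrayFromImage(
            sitk.Resample(moving, fixed, transform, sitk.sitkLinear, 255.0)
        )
        return mutual_information(fixed_np, resampled, cfg.histogram_bins)

    # ---- linear phase: rigid capture, then affine refinement -----------
    # A rigid (rotation + translation) fit first is far more robust to the
    # initial misalignment than a direct 6-DOF affine; the affine then
    # refines scale/shear and is kept only if it actually improves MI.
    reg = _make_method()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler2DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=True)
    rigid = sitk.Euler2DTransform(
        sitk.CompositeTransform(_run_registration(reg, fixed, moving)).GetNthTransform(0)
    )
    rigid_as_affine = sitk.AffineTransform(2)
    rigid_as_affine.SetMatrix(rigid.GetMatrix())
    rigid_as_affine.SetCenter(rigid.GetCenter())
    rigid_as_affine.SetTranslation(rigid.GetTranslation())
    mi_rigid = _measure(rigid_as_affine)

    reg_a = _make_method()
    affine_init = sitk.AffineTransform(2)
    affine_init.SetMatrix(rigid.GetMatrix())
    affine_init.SetCenter(rigid.GetCenter())
    affine_init.SetTranslation(rigid.GetTranslation())
    reg_a.SetInitialTransform(affine_init, inPlace=True)
    affine = sitk.AffineTransform(
        sitk.CompositeTransform(_run_registration(reg_a, fixed, moving)).GetNthTransform(0)
    )
    mi_affine = _measure(affine)
    if mi_affine < mi_rigid:
        affine, mi_affine = rigid_as_affine, mi_rigid

    # ---- B-spline phase ------------------------------------------------
    bspline = None
    mi_bspline = mi_affine
    if cfg.use_bspline:
        mesh = [
            max(1, int(round(sz / cfg.bspline_spacing_px)))
            for sz in fixed.GetSize()
        ]
        bsp0 = sitk.BSplineTransformInitializer(fixed, mesh)
        reg_b = sitk.ImageRegistrationMethod()
        reg_b.SetMetricAsMattesMutualInformation(cfg.histogram_bins)
        # Random (seeded) subsampling keeps the dense B-spline phase fast
        # while staying reproducible.
        reg_b.SetMetricSamplingStrategy(reg_b.RANDOM)
        reg_b.SetMetricSamplingPercentage(cfg.bspline_sampling_fraction, cfg.seed + 1)
        reg_b.SetInterpolator(sitk.sitkLinear)
        reg_b.SetOptimizerAsRegularStepGradientDescent(
            learningRate=cfg.learning_rate,
            minStep=1e-4,
            numberOfIterations=cfg.bspline_iterations,
        )
        reg_b.SetOptimizerScalesFromPhysicalShift()
        n_levels = max(1, cfg.bspline_levels)
        reg_b.SetShrinkFactorsPerLevel([2] * (n_levels - 1) + [1])
        reg_b.SetSmoothingSigmasPerLevel([1.0] * (n_levels - 1) + [0.0])
        reg_b.SetMovingInitialTransform(affine)
        reg_b.SetInitialTransformAsBSpline(
            bsp0, inPlace=True, scaleFactors=[2**i for i in range(n_levels)]
        )
        bspline = sitk.BSplineTransform(_run_registration(reg_b, fixed, moving))

        chain_tmp = TransformChain.from_sitk(affine, bspline, cfg.downscale)
        after_bspline = sitk.GetArrayFromImage(
            sitk.Resample(moving, fixed, chain_tmp.to_sitk(), sitk.sitkLinear, 255.0)
        )
        mi_bspline = mutual_information(fixed_np, after_bspline, cfg.histogram_bins)
        # Keep the B-spline only if it did not degrade the alignment.
        if mi_bspline < mi_affine:
            bspline, mi_bspline = None, mi_affine

    chain = TransformChain.from_sitk(affine, bspline, cfg.downscale)
    report = MiReport(
        mi_before=mi_before,
        mi_after_affine=mi_affine,
        mi_after_bspline=mi_bspline,
        histogram_bins=cfg.histogram_bins,
    )
    return chain, report


def apply_transform(
    ihc: np.ndarray,
    chain: TransformChain,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Resample an RGB IHC image onto the H&E grid with a fitted chain.

    Every channel is resampled with the same transform (linear
    interpolation); pixels mapping outside the IHC field of view are
    filled with white (255, 255, 255). ``ihc`` must already be at the
    working downscale of the chain; ``target_shape`` is the downscaled
    H&E shape.
    """
    ihc = as_rgb(ihc)
    t = chain.to_sitk()
    reference = sitk.Image(int(target_shape[1]), int(target_shape[0]), sitk.sitkFloat32)
    out = np.empty((*target_shape, 3), dtype=np.uint8)
    for ch in range(3):
        img = _as_sitk(ihc[..., ch])
        res = sitk.Resample(img, reference, t, sitk.sitkLinear, 255.0)
        out[..., ch] = np.clip(
            sitk.GetArrayFromImage(res), 0, 255
        ).round().astype(np.uint8)
    return out


def register_and_warp(
    he: np.ndarray,
    ihc: np.ndarray,
    cfg: RegistrationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, TransformChain, MiReport]:
    """Full registration convenience: returns downscaled H&E, registered
    downscaled color IHC, the transform chain and the MI report."""
    cfg = cfg or RegistrationConfig()
    chain, report = register_pair(he, ihc, cfg)
    he_down = downscale_image(he, cfg.downscale)
    ihc_down = downscale_image(ihc, cfg.downscale)
    registered = apply_transform(ihc_down, chain, he_down.shape[:2])
    return he_down, registered, chain, report
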