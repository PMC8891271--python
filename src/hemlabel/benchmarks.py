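"""Reference experiments validating the pipeline on synthetic ground truth.

Each function runs one self-contained experiment used by the validation
test suite and the reproduction script: rigid-misalignment recovery,
deconvolution round-trip exactness, Otsu-vs-brute-force agreement, stain
normalization variance reduction, and the end-to-end label-transfer /
classification / purity study. All randomness is driven by an explicit
seed; problem sizes are chosen so the whole set runs on one CPU in
minutes (256-px slides for registration, 1120-px ten-slide cohorts for
the end-to-end study, 2240-px slides for the purity-recovery check).
"""
from __future__ import annotations

import warnings
from typing import Dict, List

import numpy as np

from .classifier import train
from .config import (
    ClassifierConfig,
    LabelingConfig,
    NormalizationConfig,
    RegistrationConfig,
)
from .evaluation import estimate_purity, roc_auc
from .labeling import label_slide, tile_grid
from .normalization import (
    fit_stain_model,
    normalize_to_template,
    select_template,
    standardize_luminosity,
)
from .registration import downscale_image, register_and_warp, register_pair
from .separation import otsu_threshold, tissue_mask
from .synthetic import SyntheticSpec, generate_cohort, generate_pair
from .types import Prediction, TileLabel


def registration_recovery(
    n_cases: int = 20,
    seed: int = 42,
    image_px: int = 256,
    max_rotation_deg: float = 10.0,
    max_translation_px: float = 20.0,
) -> Dict[str, object]:
    """Recover seeded rigid misalignments with affine MI registration.

    Returns per-case angle/displacement errors (degrees / pixels at the
    fitting resolution), the count recovered within 1 px and 0.5 deg, and
    whether mutual information increased on every pair.
    """
    rng = np.random.default_rng(seed)
    cfg = RegistrationConfig(downscale=1, use_bspline=False)
    angle_errors, disp_errors, mi_increased = [], [], []
    center = (image_px / 2.0, image_px / 2.0)
    for i in range(n_cases):
        rot = rng.uniform(-max_rotation_deg, max_rotation_deg)
        tx, ty = rng.uniform(-max_translation_px, max_translation_px, 2)
        spec = SyntheticSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            image_shape=(image_px, image_px),
            smooth_px=20.0,
            rotation_deg=rot,
            translation_px=(float(tx), float(ty)),
        )
        pair, truth = generate_pair(spec)
        chain, report = register_pair(pair.he_image, pair.ihc_image, cfg)
        angle_errors.append(
            abs(chain.rotation_deg - truth.true_transform.rotation_deg)
        )
        disp_errors.append(
            float(
                np.linalg.norm(
                    chain.displacement_at(center)
                    - truth.true_transform.displacement_at(center)
                )
            )
        )
        mi_increased.append(report.mi_after_bspline > report.mi_before)
    recovered = sum(
        1 for a, d in zip(angle_errors, disp_errors) if a <= 0.5 and d <= 1.0
    )
    return {
        "n_cases": n_cases,
        "recovered": recovered,
        "angle_errors_deg": angle_errors,
        "displacement_errors_px": disp_errors,
        "mi_increased": mi_increased,
        "mi_increase_fraction": float(np.mean(mi_increased)),
    }


def deconvolution_roundtrip(seed: int = 0, n_pixels: int = 2000) -> Dict[str, float]:
    """Max abs error of concentrations after forward mix + deconvolution."""
    from .separation import RUIFROK_HED, deconvolve_hed
    from .normalization import od_to_rgb

    rng = np.random.default_rng(seed)
    conc = rng.uniform(0.0, 1.2, (n_pixels, 3))
    od = conc @ RUIFROK_HED
    # Work in OD directly (noise-free contract): solve back through the
    # same matrix.
    recovered = od @ np.linalg.inv(RUIFROK_HED)
    err_od = float(np.abs(recovered - conc).max())
    # And through the full 8-bit render (quantization-limited, looser).
    img = od_to_rgb(od.reshape(-1, 1, 3))
    stack = deconvolve_hed(img)
    rec2 = np.stack(
        [stack.hematoxylin, stack.eosin, stack.dab], axis=-1
    ).reshape(-1, 3)
    err_rgb = float(np.abs(rec2 - conc).max())
    return {"od_roundtrip_max_err": err_od, "rgb_roundtrip_max_err": err_rgb}


def brute_force_otsu(values: np.ndarray, bins: int = 256) -> float:
    """Independent exhaustive-search Otsu: try every candidate edge."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    edges = np.histogram_bin_edges(values, bins=bins, range=(lo, hi))
    best_t, best_v = None, -np.inf
    for t in edges[1:-1]:
        left = values[values <= t]
        right = values[values > t]
        if len(left) == 0 or len(right) == 0:
            continue
        w0, w1 = len(left) / len(values), len(right) / len(values)
        v = w0 * w1 * (left.mean() - right.mean()) ** 2
        if v > best_v + 1e-15:
            best_v, best_t = v, t
    return float(best_t)


def otsu_agreement(seed: int = 0, n_trials: int = 20) -> Dict[str, object]:
    """Compare the histogram Otsu against exhaustive search on random
    bimodal samples; agreement within one bin width counts as a match."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_trials):
        mu = sorted(rng.uniform(0, 2, 2))
        sd = rng.uniform(0.02, 0.15)
        n1 = int(rng.integers(200, 800))
        vals = np.concatenate(
            [rng.normal(mu[0], sd, n1), rng.normal(mu[1], sd, 1000 - n1)]
        )
        t_fast = otsu_threshold(vals)
        t_brute = brute_force_otsu(vals)
        bin_w = (vals.max() - vals.min()) / 256
        matches += abs(t_fast - t_brute) <= bin_w + 1e-12
    return {"n_trials": n_trials, "matches": matches}


def normalization_variance_reduction(
    n_slides: int = 10,
    seed: int = 7,
    image_px: int = 512,
    method: str = "vahadane",
) -> Dict[str, object]:
    """SD of per-slide mean channel intensities before vs after
    normalization across a cohort with heterogeneous stain matrices."""
    base = SyntheticSpec(seed=seed, image_shape=(image_px, image_px))
    cohort = generate_cohort(
        n_cancer=n_slides // 2,
        n_normal=n_slides - n_slides // 2,
        seed=seed,
        base_spec=base,
        vary_stains=True,
    )
    slides = [standardize_luminosity(p.he_image) for p, _ in cohort]
    statuses = [p.status for p, _ in cohort]
    idx = select_template(slides, statuses)
    cfg = NormalizationConfig()
    template = fit_stain_model(slides[idx], method=method, config=cfg, seed=seed)
    normalized = [
        normalize_to_template(s, template, method=method, config=cfg, seed=seed)
        for s in slides
    ]
    means_before = np.array([s.reshape(-1, 3).mean(0) for s in slides])
    means_after = np.array([s.reshape(-1, 3).mean(0) for s in normalized])
    return {
        "n_slides": n_slides,
        "sd_before": means_before.std(axis=0).tolist(),
        "sd_after": means_after.std(axis=0).tolist(),
    }


def label_rule_checks() -> Dict[str, object]:
    """Hand-checkable label-transfer arithmetic on constructed tiles."""
    from .labeling import apply_slide_filter, label_tile
    from .types import SlideStatus, TileRecord

    cfg = LabelingConfig()
    lpx = cfg.label_tile_px  # 45 for 224 / 5

    def tile_with(n_positive: int):
        pos = np.zeros((lpx, lpx), dtype=bool)
        pos.ravel()[:n_positive] = True
        dab = np.where(pos, 1.0, 0.0)
        tissue = np.ones((lpx, lpx), dtype=bool)
        return label_tile(pos, dab, tissue, cfg)

    label_41, frac_41, _ = tile_with(41)
    label_40, frac_40, _ = tile_with(40)

    records = (
        [TileRecord("toy", 0, i, label=TileLabel.CANCER) for i in range(30)]
        + [TileRecord("toy", 1, i, label=TileLabel.NORMAL) for i in range(10)]
        + [TileRecord("toy", 2, i, label=TileLabel.UNCERTAIN) for i in range(5)]
    )
    kept_cancer = [
        r
        for r in apply_slide_filter(
            [TileRecord(**vars(r)) for r in records], SlideStatus.CANCER
        )
        if r.label is TileLabel.CANCER
    ]
    kept_normal = [
        r
        for r in apply_slide_filter(
            [TileRecord(**vars(r)) for r in records], SlideStatus.NON_CANCER
        )
        if r.label is TileLabel.NORMAL
    ]
    return {
        "label_tile_px": lpx,
        "fraction_41": frac_41,
        "label_41": label_41.value,
        "fraction_40": frac_40,
        "label_40": label_40.value,
        "cancer_slide_kept": len(kept_cancer),
        "normal_slide_kept": len(kept_normal),
    }


# ---------------------------------------------------------------------------
# end-to-end study


def _eval_slide_tiles(pair, truth, template, lab_cfg, norm_method, seed):
    """Normalized tiles, truth labels and tissue fractions of one slide."""
    he_n = normalize_to_template(
        standardize_luminosity(pair.he_image), template, norm_method, seed=seed
    )
    he_tis, _ = tissue_mask(downscale_image(he_n, lab_cfg.downscale))
    lpx = lab_cfg.label_tile_px
    tiles, keys, truths, fractions = [], [], [], {}
    for r, c in tile_grid(he_n.shape[:2], lab_cfg.tile_px):
        sl224 = np.s_[
            r * lab_cfg.tile_px : (r + 1) * lab_cfg.tile_px,
            c * lab_cfg.tile_px : (c + 1) * lab_cfg.tile_px,
        ]
        tmask = truth.tissue_mask[sl224]
        cmask = truth.cancer_mask[sl224]
        fractions[(pair.slide_id, r, c)] = float(
            he_tis[r * lpx : (r + 1) * lpx, c * lpx : (c + 1) * lpx].mean()
        )
        if tmask.mean() < 0.05:
            continue
        tiles.append(he_n[sl224])
        keys.append((pair.slide_id, r, c))
        truths.append(1 if cmask.sum() / tmask.sum() >= 0.5 else 0)
    return tiles, keys, truths, fractions


def end_to_end_study(
    seed: int = 11,
    train_image_px: int = 1120,
    eval_image_px: int = 1120,
    n_eval: int = 10,
    norm_method: str = "vahadane",
) -> Dict[str, object]:
    """Full pipeline on synthetic cohorts with known cancer geometry.

    Trains on a five-cancer / five-normal cohort (normalize -> register ->
    transfer labels -> train the tiny-backbone head), then scores held-out
    slides spanning true purities 0.1-0.8: tile-level ROC AUC against
    ground-truth region membership and the regression slope of estimated
    vs true tumor purity.
    """
    base = SyntheticSpec(seed=seed, image_shape=(train_image_px, train_image_px))
    cohort = generate_cohort(
        5, 5, purity_grid=[0.25, 0.4, 0.55], seed=seed, base_spec=base
    )
    slides = [standardize_luminosity(p.he_image) for p, _ in cohort]
    idx = select_template(slides, [p.status for p, _ in cohort])
    template = fit_stain_model(slides[idx], method=norm_method, seed=seed)
    lab_cfg = LabelingConfig()
    reg_cfg = RegistrationConfig(seed=seed)
    tiles, labels = [], []
    for (pair, _), he in zip(cohort, slides):
        pair.he_image = normalize_to_template(
            he, template, norm_method, seed=seed
        )
        _, registered, _, _ = register_and_warp(
            pair.he_image, pair.ihc_image, reg_cfg
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            records = label_slide(pair, registered, lab_cfg, training=True)
        for rec in records:
            if rec.label in (TileLabel.CANCER, TileLabel.NORMAL):
                px = lab_cfg.tile_px
                tiles.append(
                    pair.he_image[
                        rec.tile_row * px : (rec.tile_row + 1) * px,
                        rec.tile_col * px : (rec.tile_col + 1) * px,
                    ]
                )
                labels.append(rec.label)
    model = train(tiles, labels, ClassifierConfig(seed=seed))

    purities = np.linspace(0.1, 0.8, n_eval)
    rng = np.random.default_rng(seed + 1)
    y_true: List[int] = []
    scores: List[float] = []
    predictions: List[Prediction] = []
    fractions: Dict[tuple, float] = {}
    true_purity: Dict[str, float] = {}
    for frac in purities:
        spec = SyntheticSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            image_shape=(eval_image_px, eval_image_px),
            cancer_region_fraction=float(frac),
            rotation_deg=0.0,
            translation_px=(0.0, 0.0),
        )
        pair, truth = generate_pair(spec)
        pair.slide_id = f"eval-{frac:.2f}"
        true_purity[pair.slide_id] = truth.true_purity
        t, keys, truths, fr = _eval_slide_tiles(
            pair, truth, template, lab_cfg, norm_method, seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = model.predict_tiles(t)
        y_true += truths
        scores += list(map(float, p))
        predictions += [
            Prediction(k[0], k[1], k[2], float(pp)) for k, pp in zip(keys, p)
        ]
        fractions.update(fr)

    auc = roc_auc(scores, y_true)
    estimates = estimate_purity(predictions, fractions)
    est_by_slide = {e.slide_id: e.purity for e in estimates}
    tp = np.array([true_purity[s] for s in est_by_slide])
    ep = np.array([est_by_slide[s] for s in est_by_slide])
    slope, intercept = np.polyfit(tp, ep, 1)
    return {
        "n_train_tiles": len(tiles),
        "n_eval_tiles": len(y_true),
        "tile_auc": float(auc),
        "true_purities": tp.tolist(),
        "estimated_purities": ep.tolist(),
        "purity_slope": float(slope),
        "purity_intercept": float(intercept),
    }


def purity_oracle_recovery(
    seed: int = 5,
    fractions=(0.2, 0.5, 0.8),
    n_per_fraction: int = 3,
    image_px: int = 2240,
) -> Dict[str, object]:
    """Tissue-area-weighted purity with ground-truth tile predictions.

    For each target cancer-area fraction, generates slides, takes the
    oracle tile call (cancer iff the majority of the tile's tissue is
    cancer) and compares the tile-based purity estimate to the pixel-level
    true purity. Reports the mean error per fraction.
    """
    rng = np.random.default_rng(seed)
    cfg = LabelingConfig()
    errors = {}
    for frac in fractions:
        errs = []
        for _ in range(n_per_fraction):
            spec = SyntheticSpec(
                seed=int(rng.integers(0, 2**31 - 1)),
                image_shape=(image_px, image_px),
                cancer_region_fraction=frac,
                rotation_deg=0.0,
                translation_px=(0.0, 0.0),
            )
            pair, truth = generate_pair(spec)
            preds, fr = [], {}
            for r, c in tile_grid(pair.he_image.shape[:2], cfg.tile_px):
                sl = np.s_[
                    r * cfg.tile_px : (r + 1) * cfg.tile_px,
                    c * cfg.tile_px : (c + 1) * cfg.tile_px,
                ]
                tmask = truth.tissue_mask[sl]
                fr[("s", r, c)] = float(tmask.mean())
                if tmask.any():
                    call = truth.cancer_mask[sl].sum() / tmask.sum() >= 0.5
                    preds.append(Prediction("s", r, c, 1.0 if call else 0.0))
            est = estimate_purity(preds, fr)[0]
            errs.append(est.purity - truth.true_purity)
        errors[frac] = errs
    return {
        "errors": {str(k): v for k, v in errors.items()},
        "mean_abs_error": {
            str(k): float(np.abs(np.mean(v))) for k, v in errors.items()
        },
    }
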