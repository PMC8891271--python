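"""File-based orchestration of the pipeline stages.

Each stage reads its inputs from and writes its outputs to a working
directory, so stages are independently re-runnable and a failed run can
resume. Stage order is fixed: simulate -> normalize -> register -> label
-> train -> predict -> evaluate -> purity. Every run appends a
provenance record (config hash, seed, stages, package version) to
``provenance.json``.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd

from . import __version__
from .classifier import TileClassifier, predict_manifest, train
from .config import PipelineConfig
from .errors import MissingArtifactError
from .evaluation import estimate_purity, evaluate
from .io import (
    read_image,
    read_manifest,
    write_image,
    write_manifest,
    write_mask,
    write_tiles,
)
from .labeling import label_slide
from .normalization import (
    fit_stain_model,
    normalize_to_template,
    reinhard_stats,
    select_template,
    standardize_luminosity,
)
from .registration import register_and_warp
from .synthetic import SyntheticSpec, generate_cohort
from .types import Prediction, SlidePair, SlideStatus, TileLabel

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "normalize",
    "register",
    "label",
    "train",
    "predict",
    "evaluate",
    "purity",
)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path}; run the '{stage}' stage first"
        )
    return path


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str],
    workdir: str | Path,
    n_cancer: int = 5,
    n_normal: int = 5,
    image_px: int = 1024,
) -> Dict[str, object]:
    """Run the requested stages in fixed order; returns stage outputs."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        results[stage] = _STAGE_FUNCS[stage](
            config, workdir, n_cancer, n_normal, image_px
        )
    _write_provenance(config, stages, workdir)
    return results


def _write_provenance(config, stages, workdir: Path) -> None:
    path = workdir / "provenance.json"
    records = json.loads(path.read_text()) if path.exists() else []
    records.append(
        {
            "config_hash": _config_hash(config),
            "config": config.model_dump(),
            "seed": config.seed,
            "stages": list(stages),
            "version": __version__,
        }
    )
    path.write_text(json.dumps(records, indent=1))


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: PipelineConfig, workdir: Path, n_cancer, n_normal, image_px=1024):
    cohort = generate_cohort(
        n_cancer=n_cancer,
        n_normal=n_normal,
        seed=config.seed,
        base_spec=SyntheticSpec(
            seed=config.seed, image_shape=(image_px, image_px)
        ),
    )
    slides_dir = workdir / "slides"
    truth_dir = workdir / "truth"
    rows = []
    for pair, truth in cohort:
        he_path = slides_dir / f"{pair.slide_id}_he.png"
        ihc_path = slides_dir / f"{pair.slide_id}_ihc.png"
        write_image(pair.he_image, he_path)
        write_image(pair.ihc_image, ihc_path)
        write_mask(truth.tissue_mask, truth_dir / f"{pair.slide_id}_tissue.png")
        write_mask(truth.cancer_mask, truth_dir / f"{pair.slide_id}_cancer.png")
        truth.true_transform.to_json(truth_dir / f"{pair.slide_id}_transform.json")
        rows.append(
            {
                "slide_id": pair.slide_id,
                "status": pair.status.value,
                "true_purity": truth.true_purity,
                "he_path": str(he_path),
                "ihc_path": str(ihc_path),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(workdir / "cohort.csv", index=False)
    return df


def _load_cohort(workdir: Path) -> pd.DataFrame:
    return pd.read_csv(_require(workdir / "cohort.csv", "simulate"))


def _stage_normalize(config: PipelineConfig, workdir: Path, *_):
    cohort = _load_cohort(workdir)
    cfg = config.normalization
    slides = [standardize_luminosity(read_image(p)) for p in cohort["he_path"]]
    statuses = [SlideStatus(s) for s in cohort["status"]]
    if cfg.template is not None:
        tmpl_idx = int(cohort.index[cohort["slide_id"] == cfg.template][0])
    else:
        tmpl_idx = select_template(slides, statuses)
    if cfg.method == "reinhard":
        template_model = reinhard_stats(slides[tmpl_idx])
    else:
        template_model = fit_stain_model(
            slides[tmpl_idx], method=cfg.method, config=cfg, seed=config.seed
        )
    out_dir = workdir / "normalized"
    paths = []
    for slide, sid in zip(slides, cohort["slide_id"]):
        norm = normalize_to_template(
            slide, template_model, method=cfg.method, config=cfg, seed=config.seed
        )
        path = out_dir / f"{sid}_he.png"
        write_image(norm, path)
        paths.append(str(path))
    cohort["normalized_he_path"] = paths
    cohort.to_csv(workdir / "cohort.csv", index=False)
    (workdir / "template.json").write_text(
        json.dumps({"template_slide": cohort["slide_id"][tmpl_idx], "method": cfg.method})
    )
    return cohort


def _stage_register(config: PipelineConfig, workdir: Path, *_):
    cohort = _load_cohort(workdir)
    if "normalized_he_path" not in cohort.columns:
        raise MissingArtifactError(
            "cohort has no normalized slides; run the 'normalize' stage first"
        )
    out_dir = workdir / "registered"
    out_dir.mkdir(parents=True, exist_ok=True)
    mi_rows, reg_paths = [], []
    for row in cohort.itertuples():
        he = read_image(row.normalized_he_path)
        ihc = read_image(row.ihc_path)
        _, registered, chain, report = register_and_warp(
            he, ihc, config.registration
        )
        path = out_dir / f"{row.slide_id}_ihc.png"
        write_image(registered, path)
        chain.to_json(out_dir / f"{row.slide_id}_transform.json")
        reg_paths.append(str(path))
        mi_rows.append({"slide_id": row.slide_id, **asdict(report)})
    cohort["registered_ihc_path"] = reg_paths
    cohort.to_csv(workdir / "cohort.csv", index=False)
    mi = pd.DataFrame(mi_rows)
    mi.to_csv(workdir / "mi_report.csv", index=False)
    return mi


def _stage_label(config: PipelineConfig, workdir: Path, *_):
    cohort = _load_cohort(workdir)
    if "registered_ihc_path" not in cohort.columns:
        raise MissingArtifactError(
            "cohort has no registered IHC images; run the 'register' stage first"
        )
    cfg = config.labeling
    train_records, eval_records = [], []
    tiles_dir = workdir / "tiles"
    manifests = []
    for row in cohort.itertuples():
        pair = SlidePair(
            slide_id=row.slide_id,
            he_image=read_image(row.normalized_he_path),
            ihc_image=read_image(row.ihc_path),
            status=SlideStatus(row.status),
        )
        registered = read_image(row.registered_ihc_path)
        eval_recs = label_slide(pair, registered, cfg, training=False)
        eval_records.extend(eval_recs)
        train_recs = label_slide(pair, registered, cfg, training=True)
        manifests.append(write_tiles(pair.he_image, train_recs, tiles_dir))
        train_records.extend(train_recs)
    train_manifest = pd.concat(manifests, ignore_index=True)
    write_manifest(train_manifest, workdir / "train_labels.csv")
    from .io import records_to_manifest

    write_manifest(records_to_manifest(eval_records), workdir / "eval_labels.csv")
    summary = {
        label.value: int((train_manifest["label"] == label.value).sum())
        for label in TileLabel
    }
    (workdir / "label_summary.json").write_text(json.dumps(summary, indent=1))
    return train_manifest


def _stage_train(config: PipelineConfig, workdir: Path, *_):
    manifest = read_manifest(_require(workdir / "train_labels.csv", "label"))
    rows = manifest[manifest["label"].isin(["cancer", "normal"])]
    tiles = [read_image(p) for p in rows["tile_path"]]
    model = train(tiles, list(rows["label"]), config.classifier)
    model.save(workdir / "model.json")
    return model


def _stage_predict(config: PipelineConfig, workdir: Path, *_):
    model = TileClassifier.load(_require(workdir / "model.json", "train"))
    manifest = read_manifest(_require(workdir / "train_labels.csv", "label"))
    preds = predict_manifest(manifest, model)
    df = pd.DataFrame([asdict(p) for p in preds])
    df.to_csv(workdir / "predictions.csv", index=False)
    return preds


def _load_predictions(workdir: Path) -> List[Prediction]:
    df = pd.read_csv(_require(workdir / "predictions.csv", "predict"))
    return [Prediction(**row) for row in df.to_dict("records")]


def _stage_evaluate(config: PipelineConfig, workdir: Path, *_):
    preds = _load_predictions(workdir)
    truth = read_manifest(_require(workdir / "eval_labels.csv", "label"))
    report = evaluate(
        preds,
        truth,
        seed=config.evaluation.balancing_seed,
        threshold=config.evaluation.threshold,
    )
    payload = {
        "accuracy": report.accuracy,
        "confusion": report.confusion.tolist(),
        "roc_auc": report.roc_auc,
        "n_per_class": report.n_per_class,
        "balancing_seed": report.balancing_seed,
    }
    (workdir / "eval_report.json").write_text(json.dumps(payload, indent=1))
    return report


def _stage_purity(config: PipelineConfig, workdir: Path, *_):
    preds = _load_predictions(workdir)
    manifest = read_manifest(_require(workdir / "eval_labels.csv", "label"))
    estimates = estimate_purity(
        preds,
        manifest,
        threshold=config.evaluation.threshold,
        probabilistic=config.evaluation.probabilistic_purity,
    )
    df = pd.DataFrame(
        [
            {
                "slide_id": e.slide_id,
                "cancer_tissue_area": e.cancer_tissue_area,
                "total_tissue_area": e.total_tissue_area,
                "purity": e.purity,
            }
            for e in estimates
        ]
    )
    df.to_csv(workdir / "purity.csv", index=False)
    return estimates


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "register": _stage_register,
    "label": _stage_label,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "purity": _stage_purity,
}
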