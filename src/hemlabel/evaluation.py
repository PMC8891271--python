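"""Classifier scoring and tumor purity estimation.

Predictions are scored against tile truth labels from either the DAB
pipeline or a pathologist annotation mask. Because cancer and normal
tiles are not evenly represented, the dominant class is subsampled to the
minority count before computing accuracy, the confusion matrix and ROC
AUC. Slide-level tumor purity is the tissue-area-weighted fraction of
cancer tiles: a tile that is half background and half tissue contributes
half a tile worth of area.
"""
from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .types import EvalReport, Prediction, PurityEstimate, TileLabel

_BINARY = (TileLabel.NORMAL.value, TileLabel.CANCER.value)


def balance_classes(
    records: pd.DataFrame, seed: int = 0, label_col: str = "label"
) -> pd.DataFrame:
    """Subsample the dominant class to the minority class count.

    The minority class is kept untouched; the subsample is reproducible
    for a given seed.
    """
    counts = records[label_col].value_counts()
    present = [l for l in _BINARY if l in counts.index]
    if len(present) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = int(counts[present].min())
    rng = np.random.default_rng(seed)
    parts = []
    for label in present:
        rows = records[records[label_col] == label]
        if len(rows) > n_min:
            idx = rng.choice(len(rows), n_min, replace=False)
            rows = rows.iloc[np.sort(idx)]
        parts.append(rows)
    return pd.concat(parts).sort_index()


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outranks a random
    negative, with ties counted half.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _join(predictions: Sequence[Prediction], truth: pd.DataFrame) -> pd.DataFrame:
    pred_df = pd.DataFrame(
        [
            {
                "slide_id": p.slide_id,
                "tile_row": p.tile_row,
                "tile_col": p.tile_col,
                "p_cancer": p.p_cancer,
            }
            for p in predictions
        ]
    )
    truth = truth[truth["label"].isin(_BINARY)]
    if pred_df.empty or truth.empty:
        return pd.DataFrame()
    return pred_df.merge(
        truth[["slide_id", "tile_row", "tile_col", "label"]],
        on=["slide_id", "tile_row", "tile_col"],
        how="inner",
    )


def evaluate(
    predictions: Sequence[Prediction],
    truth_labels: pd.DataFrame,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Score predictions against tile truth labels.

    Truth rows join predictions on (slide_id, tile_row, tile_col); only
    cancer/normal truth tiles are scored. Class balancing is applied
    before the metrics. Confusion-matrix convention: rows = truth,
    columns = prediction, order [normal, cancer].
    """
    joined = _join(predictions, truth_labels)
    if joined.empty:
        raise ValueError("no overlapping tiles between predictions and truth")
    balanced = balance_classes(joined, seed=seed)
    y = (balanced["label"] == TileLabel.CANCER.value).to_numpy(int)
    scores = balanced["p_cancer"].to_numpy(float)
    y_hat = (scores > threshold).astype(int)
    conf = _sk_confusion(y, y_hat, labels=[0, 1])
    return EvalReport(
        accuracy=float((y == y_hat).mean()),
        confusion=conf,
        roc_auc=roc_auc(scores, y),
        n_per_class=int((y == 1).sum()),
        balancing_seed=seed,
    )


def estimate_purity(
    predictions: Sequence[Prediction],
    tissue_fractions: Dict[tuple, float] | pd.DataFrame,
    threshold: float = 0.5,
    probabilistic: bool = False,
) -> List[PurityEstimate]:
    """Tissue-area-weighted tumor purity per slide.

    ``purity = sum(1[p_cancer > threshold] * tissue_fraction) /
    sum(tissue_fraction)`` over tiles with positive tissue fraction.
    With ``probabilistic`` the indicator is replaced by ``p_cancer``.

    ``tissue_fractions`` maps (slide_id, tile_row, tile_col) to the
    fraction of the tile's area that is tissue (or a manifest DataFrame
    with a ``tissue_fraction_he`` column).
    """
    if isinstance(tissue_fractions, pd.DataFrame):
        tissue_fractions = {
            (r.slide_id, r.tile_row, r.tile_col): r.tissue_fraction_he
            for r in tissue_fractions.itertuples()
        }
    per_slide: Dict[str, List[tuple[float, float]]] = {}
    for p in predictions:
        tf = tissue_fractions.get((p.slide_id, p.tile_row, p.tile_col))
        if tf is None or tf <= 0:
            continue
        if not 0.0 <= tf <= 1.0:
            raise ValueError(f"tissue fraction {tf} outside [0, 1]")
        weight = p.p_cancer if probabilistic else float(p.p_cancer > threshold)
        per_slide.setdefault(p.slide_id, []).append((weight, tf))
    out = []
    for slide_id in sorted(per_slide):
        pairs = per_slide[slide_id]
        total = sum(tf for _, tf in pairs)
        if total <= 0:
            raise ValueError(f"slide {slide_id} has zero total tissue area")
        cancer = sum(w * tf for w, tf in pairs)
        out.append(
            PurityEstimate(
                slide_id=slide_id,
                cancer_tissue_area=cancer,
                total_tissue_area=total,
            )
        )
    if not out:
        raise ValueError("no tiles with positive tissue fraction")
    return out
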