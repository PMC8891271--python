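"""Transfer-learning tile classifier: frozen backbone + trainable head.

The architecture follows the transfer-learning recipe: a frozen feature
extractor turns each 224 x 224 tile into a fixed-length vector, and only
a dense head (256 units + one sigmoid output) is trained with binary
cross-entropy. ImageNet CNN backbones (vgg16 and friends, 512-d pooled
features for vgg16) plug in when tensorflow is installed; the built-in
``tiny`` backbone is a deterministic 32-dimensional bank of pooled color,
stain-channel and texture statistics that needs no pretrained weights, so
the whole pipeline runs on a plain CPU.

Training augments each tile with its eight rotation/flip (dihedral)
variants, which inherit the tile's label: tumor content does not depend
on viewing orientation. The head is a small numpy MLP trained with Adam;
everything is seeded and reproducible.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClassifierConfig
from .errors import TrainingError
from .separation import deconvolve_hed
from .types import Prediction, TileLabel, as_rgb

TINY_FEATURE_DIM = 32
#: Feature length per ImageNet backbone (global max-pool output).
BACKBONE_DIMS = {
    "tiny": TINY_FEATURE_DIM,
    "vgg16": 512,
    "vgg19": 512,
    "resnet50": 2048,
    "inceptionv3": 2048,
    "xception": 2048,
}


def dihedral_variants(tile: np.ndarray) -> List[np.ndarray]:
    """The 8 rotation/flip variants of a tile (label-preserving)."""
    out = []
    for k in range(4):
        rot = np.rot90(tile, k)
        out.append(rot)
        out.append(rot[:, ::-1])
    return out


def _tiny_features(tile: np.ndarray) -> np.ndarray:
    """Pooled color / stain / texture statistics, 32-d, deterministic."""
    tile = as_rgb(tile)
    f = np.asarray(tile, dtype=np.float64)
    feats: List[float] = []
    # Color moments (6).
    feats += f.mean(axis=(0, 1)).tolist()
    feats += f.std(axis=(0, 1)).tolist()
    # Stain-channel statistics (9): mean, std, p90 of H / E / DAB.
    stack = deconvolve_hed(tile)
    for ch in (stack.hematoxylin, stack.eosin, stack.dab):
        feats += [ch.mean(), ch.std(), np.percentile(ch, 90)]
    # Hematoxylin histogram (6 bins over 0..1.5 OD) — nuclear density.
    hist, _ = np.histogram(stack.hematoxylin, bins=6, range=(0.0, 1.5))
    feats += (hist / stack.hematoxylin.size).tolist()
    # Quadrant hematoxylin means (4) — coarse spatial layout.
    h, w = stack.hematoxylin.shape
    for qs in (
        np.s_[: h // 2, : w // 2],
        np.s_[: h // 2, w // 2 :],
        np.s_[h // 2 :, : w // 2],
        np.s_[h // 2 :, w // 2 :],
    ):
        feats.append(stack.hematoxylin[qs].mean())
    # Texture (4): grayscale mean/std and gradient magnitude mean/std.
    gray = f @ np.array([0.299, 0.587, 0.114])
    gy, gx = np.gradient(gray)
    grad = np.hypot(gx, gy)
    feats += [gray.mean(), gray.std(), grad.mean(), grad.std()]
    # Stain coverage fractions (3).
    feats += [
        float((stack.hematoxylin > 0.3).mean()),
        float((stack.eosin > 0.15).mean()),
        float((stack.dab > 0.3).mean()),
    ]
    vec = np.asarray(feats, dtype=np.float64)
    assert vec.shape == (TINY_FEATURE_DIM,)
    return vec


def extract_features(
    tile: np.ndarray, spec: ClassifierConfig | None = None
) -> np.ndarray:
    """Frozen-backbone feature vector of one tile.

    The tile must match the backbone input size (``spec.backbone``
    documents the feature length: 512 for vgg16, 32 for tiny).
    """
    spec = spec or ClassifierConfig()
    tile = as_rgb(tile)
    if spec.backbone == "tiny":
        # pooled statistics work at any square tile size
        if tile.shape[0] != tile.shape[1] or tile.shape[0] < 8:
            raise ValueError(
                f"tiny backbone expects square tiles >= 8 px, got {tile.shape[:2]}"
            )
        return _tiny_features(tile)
    if tile.shape[:2] != (224, 224):
        raise ValueError(
            f"backbone {spec.backbone!r} expects 224x224 tiles, "
            f"got {tile.shape[:2]}"
        )
    return _imagenet_features(tile, spec.backbone)


def _imagenet_features(tile: np.ndarray, backbone: str) -> np.ndarray:
    try:
        import tensorflow  # noqa: F401
    except ModuleNotFoundError as exc:
        raise ModuleNotFoundError(
            f"backbone {backbone!r} needs the optional tensorflow dependency "
            "with pretrained ImageNet weights; the built-in 'tiny' backbone "
            "has no such requirement"
        ) from exc
    from tensorflow.keras import applications  # pragma: no cover

    models = {  # pragma: no cover
        "vgg16": applications.VGG16,
        "vgg19": applications.VGG19,
        "resnet50": applications.ResNet50,
        "inceptionv3": applications.InceptionV3,
        "xception": applications.Xception,
    }
    model = models[backbone](  # pragma: no cover
        include_top=False, pooling="max", input_shape=(224, 224, 3)
    )
    return model.predict(tile[None].astype(np.float32), verbose=0)[0]


@dataclass
class TileClassifier:
    """Dense head (256 units, ReLU) + sigmoid output over frozen features."""

    spec: ClassifierConfig = field(default_factory=ClassifierConfig)
    w1: Optional[np.ndarray] = None
    b1: Optional[np.ndarray] = None
    w2: Optional[np.ndarray] = None
    b2: Optional[np.ndarray] = None
    feat_mean: Optional[np.ndarray] = None
    feat_std: Optional[np.ndarray] = None
    #: Mean training-tile RGB, used to warn about unnormalized inputs.
    train_rgb_mean: Optional[np.ndarray] = None
    history: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def fit_features(self, X: np.ndarray, y: np.ndarray) -> "TileClassifier":
        """Train the head on a feature matrix (backbone already applied)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if set(np.unique(y)) != {0.0, 1.0}:
            raise TrainingError(
                "training needs both classes present (labels 0 and 1)"
            )
        rng = np.random.default_rng(self.spec.seed)
        self.feat_mean = X.mean(axis=0)
        self.feat_std = np.maximum(X.std(axis=0), 1e-8)
        Xs = (X - self.feat_mean) / self.feat_std

        n_val = int(round(len(Xs) * self.spec.validation_fraction))
        order = rng.permutation(len(Xs))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0 or len(np.unique(y[train_idx])) < 2:
            train_idx = order
            val_idx = np.array([], dtype=int)

        d, h = Xs.shape[1], self.spec.head_width
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / d), (d, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / h), (h, 1))
        self.b2 = np.zeros(1)

        params = [self.w1, self.b1, self.w2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.spec.learning_rate
        step = 0
        losses, val_losses = [], []
        Xt, yt = Xs[train_idx], y[train_idx]
        for epoch in range(self.spec.epochs):
            perm = rng.permutation(len(Xt))
            epoch_loss = 0.0
            for start in range(0, len(Xt), self.spec.batch_size):
                idx = perm[start : start + self.spec.batch_size]
                xb, yb = Xt[idx], yt[idx]
                grads, loss = self._backward(xb, yb)
                epoch_loss += loss * len(idx)
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            losses.append(epoch_loss / len(Xt))
            if len(val_idx):
                p_val = self._forward(Xs[val_idx])[0]
                val_losses.append(float(_bce(y[val_idx], p_val)))
        self.history = {"loss": losses, "val_loss": val_losses}
        return self

    def _forward(self, Xs: np.ndarray):
        a1 = np.maximum(Xs @ self.w1 + self.b1, 0.0)
        z2 = a1 @ self.w2 + self.b2
        p = 1.0 / (1.0 + np.exp(-z2))
        return p.ravel(), a1

    def _backward(self, xb: np.ndarray, yb: np.ndarray):
        p, a1 = self._forward(xb)
        n = len(xb)
        dz2 = (p - yb)[:, None] / n  # d(BCE)/dz2
        gw2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ self.w2.T
        dz1 = da1 * (a1 > 0)
        gw1 = xb.T @ dz1
        gb1 = dz1.sum(axis=0)
        return [gw1, gb1, gw2, gb2], float(_bce(yb, p))

    # ------------------------------------------------------------------
    def predict_features(self, X: np.ndarray) -> np.ndarray:
        if self.w1 is None:
            raise TrainingError("classifier head is not trained")
        Xs = (np.asarray(X, dtype=np.float64) - self.feat_mean) / self.feat_std
        return self._forward(Xs)[0]

    def predict_tiles(self, tiles: Sequence[np.ndarray]) -> np.ndarray:
        tiles = [as_rgb(t) for t in tiles]
        if self.train_rgb_mean is not None and len(tiles):
            batch_mean = np.mean([t.mean(axis=(0, 1)) for t in tiles], axis=0)
            if np.linalg.norm(batch_mean - self.train_rgb_mean) > 40.0:
                warnings.warn(
                    "input tiles' stain profile deviates strongly from the "
                    "training tiles; did you normalize to the training "
                    "template?",
                    stacklevel=2,
                )
        X = np.array([extract_features(t, self.spec) for t in tiles])
        return self.predict_features(X)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec.model_dump(),
            "arrays": {
                k: (None if getattr(self, k) is None else np.asarray(getattr(self, k)).tolist())
                for k in ("w1", "b1", "w2", "b2", "feat_mean", "feat_std", "train_rgb_mean")
            },
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TileClassifier":
        data = json.loads(Path(path).read_text())
        obj = cls(spec=ClassifierConfig.model_validate(data["spec"]))
        for k, val in data["arrays"].items():
            setattr(obj, k, None if val is None else np.asarray(val, dtype=np.float64))
        obj.history = data.get("history", {})
        return obj


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def train(
    tiles: Sequence[np.ndarray],
    labels: Sequence[str | TileLabel],
    spec: ClassifierConfig | None = None,
) -> TileClassifier:
    """Train the head on labeled tiles (cancer = 1, normal = 0).

    Tiles labeled anything other than cancer/normal are rejected. With
    ``spec.augment`` each tile contributes its 8 dihedral variants, all
    inheriting the tile's label. Only the head's weights are trained; the
    backbone has no trainable state.
    """
    spec = spec or ClassifierConfig()
    labels = [TileLabel(l) for l in labels]
    if any(l not in (TileLabel.CANCER, TileLabel.NORMAL) for l in labels):
        raise TrainingError("training labels must be cancer or normal only")
    if len(tiles) != len(labels):
        raise ValueError("tiles and labels length mismatch")
    # Balance classes by subsampling the dominant one (seeded), the same
    # strategy used at evaluation time; keeps the head's operating point
    # near p = 0.5 under equal priors.
    idx_c = [i for i, l in enumerate(labels) if l is TileLabel.CANCER]
    idx_n = [i for i, l in enumerate(labels) if l is TileLabel.NORMAL]
    if idx_c and idx_n and len(idx_c) != len(idx_n):
        rng = np.random.default_rng(spec.seed)
        n_min = min(len(idx_c), len(idx_n))
        keep = sorted(
            list(rng.choice(idx_c, n_min, replace=False))
            + list(rng.choice(idx_n, n_min, replace=False))
        )
        tiles = [tiles[i] for i in keep]
        labels = [labels[i] for i in keep]
    y_list: List[float] = []
    feats: List[np.ndarray] = []
    for tile, label in zip(tiles, labels):
        variants = dihedral_variants(tile) if spec.augment else [tile]
        for var in variants:
            feats.append(extract_features(np.ascontiguousarray(var), spec))
            y_list.append(1.0 if label is TileLabel.CANCER else 0.0)
    X, y = np.asarray(feats), np.asarray(y_list)
    if len(np.unique(y)) < 2:
        raise TrainingError("training needs at least one tile of each class")
    clf = TileClassifier(spec=spec)
    clf.train_rgb_mean = np.mean(
        [as_rgb(t).mean(axis=(0, 1)) for t in tiles], axis=0
    )
    return clf.fit_features(X, y)


def predict(
    tiles: Sequence[np.ndarray],
    keys: Sequence[tuple[str, int, int]],
    model: TileClassifier,
) -> List[Prediction]:
    """One cancer probability per tile; order independent."""
    probs = model.predict_tiles(tiles)
    return [
        Prediction(slide_id=k[0], tile_row=k[1], tile_col=k[2], p_cancer=float(p))
        for k, p in zip(keys, probs)
    ]


def predict_manifest(
    manifest: pd.DataFrame,
    model: TileClassifier,
    tile_loader: Optional[Callable[[str], np.ndarray]] = None,
) -> List[Prediction]:
    """Predict for every non-discarded manifest row with a tile file."""
    if tile_loader is None:
        from .io import read_image as tile_loader  # type: ignore[assignment]
    rows = manifest[
        (manifest["label"] != TileLabel.DISCARDED.value)
        & (manifest["tile_path"] != "")
    ]
    tiles = [tile_loader(p) for p in rows["tile_path"]]
    keys = list(zip(rows["slide_id"], rows["tile_row"], rows["tile_col"]))
    return predict(tiles, keys, model)
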