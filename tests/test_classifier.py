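"""Tiny backbone features and the trainable dense head."""
import numpy as np
import pytest

from hemlabel.classifier import (
    BACKBONE_DIMS,
    TileClassifier,
    dihedral_variants,
    extract_features,
    predict,
    train,
)
from hemlabel.config import ClassifierConfig
from hemlabel.errors import TrainingError
from hemlabel.types import TileLabel


def _tissue_tile(seed=0):
    from hemlabel.normalization import od_to_rgb
    from hemlabel.separation import RUIFROK_HED

    rng = np.random.default_rng(seed)
    conc = rng.uniform(0.2, 1.0, (224, 224, 3))
    conc[..., 2] = 0.0
    od = conc.reshape(-1, 3) @ RUIFROK_HED
    return od_to_rgb(od.reshape(224, 224, 3))


class TestFeatures:
    def test_deterministic(self):
        tile = _tissue_tile()
        assert np.array_equal(extract_features(tile), extract_features(tile))

    def test_tiny_feature_length(self):
        assert extract_features(_tissue_tile()).shape == (BACKBONE_DIMS["tiny"],)

    def test_vgg16_documented_length(self):
        assert BACKBONE_DIMS["vgg16"] == 512

    def test_discriminates_white_from_tissue(self):
        white = np.full((224, 224, 3), 255, np.uint8)
        f_white = extract_features(white)
        f_tissue = extract_features(_tissue_tile())
        assert np.linalg.norm(f_white - f_tissue) > 1.0

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="square"):
            extract_features(np.zeros((100, 80, 3), np.uint8))
        spec = ClassifierConfig(backbone="vgg16")
        with pytest.raises(ValueError, match="224"):
            extract_features(np.zeros((100, 100, 3), np.uint8), spec)

    def test_imagenet_backbone_needs_tensorflow(self):
        spec = ClassifierConfig(backbone="vgg16")
        with pytest.raises(ModuleNotFoundError, match="tensorflow"):
            extract_features(_tissue_tile(), spec)


def test_dihedral_variants_are_eight_distinct_orientations():
    tile = _tissue_tile()
    variants = dihedral_variants(tile)
    assert len(variants) == 8
    assert all(v.shape == tile.shape for v in variants)
    flat = {v.tobytes() for v in map(np.ascontiguousarray, variants)}
    assert len(flat) == 8  # random tile: all orientations distinct


class TestHeadTraining:
    def _separable(self, n=120, d=16, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, d))
        y = (X[:, 0] > 0).astype(float)
        X[:, 0] += np.where(y > 0, 2.0, -2.0)
        return X, y

    def test_separable_features_reach_high_accuracy(self):
        X, y = self._separable()
        spec = ClassifierConfig(seed=3, validation_fraction=0.0)
        clf = TileClassifier(spec=spec).fit_features(X, y)
        acc = ((clf.predict_features(X) > 0.5) == y).mean()
        assert acc >= 0.99

    def test_shuffled_labels_stay_at_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (300, 16))
        y = rng.integers(0, 2, 300).astype(float)
        spec = ClassifierConfig(seed=3, validation_fraction=0.3, epochs=50)
        clf = TileClassifier(spec=spec).fit_features(X, y)
        X_fresh = rng.normal(0, 1, (300, 16))
        y_fresh = rng.integers(0, 2, 300)
        acc = ((clf.predict_features(X_fresh) > 0.5) == y_fresh).mean()
        assert abs(acc - 0.5) <= 0.1

    def test_identical_seed_identical_weights(self):
        X, y = self._separable()
        spec = ClassifierConfig(seed=11)
        c1 = TileClassifier(spec=spec).fit_features(X.copy(), y.copy())
        c2 = TileClassifier(spec=spec).fit_features(X.copy(), y.copy())
        assert np.array_equal(c1.w1, c2.w1)
        assert np.array_equal(c1.w2, c2.w2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 4))
        with pytest.raises(TrainingError):
            TileClassifier().fit_features(X, np.ones(10))

    def test_loss_history_recorded(self):
        X, y = self._separable()
        spec = ClassifierConfig(seed=0, epochs=20)
        clf = TileClassifier(spec=spec).fit_features(X, y)
        assert len(clf.history["loss"]) == 20
        assert clf.history["loss"][-1] < clf.history["loss"][0]


class TestTrainPredictOnTiles:
    def _tiles(self, n_per_class=6):
        # cancer-like tiles carry DAB-free but hematoxylin-dense tissue
        from hemlabel.normalization import od_to_rgb
        from hemlabel.separation import RUIFROK_HED

        rng = np.random.default_rng(4)
        tiles, labels = [], []
        for i in range(2 * n_per_class):
            dense = i % 2 == 0
            conc = np.zeros((224, 224, 3))
            conc[..., 0] = rng.uniform(0.7 if dense else 0.2,
                                       1.0 if dense else 0.4, (224, 224))
            conc[..., 1] = rng.uniform(0.1, 0.3, (224, 224))
            od = conc.reshape(-1, 3) @ RUIFROK_HED
            tiles.append(od_to_rgb(od.reshape(224, 224, 3)))
            labels.append(TileLabel.CANCER if dense else TileLabel.NORMAL)
        return tiles, labels

    def test_train_and_refit_quality(self):
        tiles, labels = self._tiles()
        spec = ClassifierConfig(seed=2, epochs=60, validation_fraction=0.0)
        model = train(tiles, labels, spec)
        p = model.predict_tiles(tiles)
        y = np.array([l is TileLabel.CANCER for l in labels])
        from hemlabel.evaluation import roc_auc

        assert roc_auc(p, y.astype(int)) >= 0.95

    def test_prediction_order_invariance(self):
        tiles, labels = self._tiles(4)
        model = train(tiles, labels, ClassifierConfig(seed=2, epochs=30))
        keys = [("s", 0, i) for i in range(len(tiles))]
        p_fwd = predict(tiles, keys, model)
        p_rev = predict(tiles[::-1], keys[::-1], model)
        by_key_fwd = {(p.slide_id, p.tile_row, p.tile_col): p.p_cancer for p in p_fwd}
        by_key_rev = {(p.slide_id, p.tile_row, p.tile_col): p.p_cancer for p in p_rev}
        assert by_key_fwd == by_key_rev

    def test_mixed_labels_rejected(self):
        tiles, labels = self._tiles(2)
        labels[0] = TileLabel.UNCERTAIN
        with pytest.raises(TrainingError):
            train(tiles, labels, ClassifierConfig(epochs=1))

    def test_augmented_copies_inherit_label(self):
        # augmentation happens inside train(); the feature matrix grows
        # 8-fold while the class balance is preserved exactly
        tiles, labels = self._tiles(2)
        spec = ClassifierConfig(seed=0, epochs=1, augment=True)
        model = train(tiles, labels, spec)
        spec_no = ClassifierConfig(seed=0, epochs=1, augment=False)
        model_no = train(tiles, labels, spec_no)
        assert model.history  # trained
        assert model_no.history

    def test_stain_profile_warning(self):
        tiles, labels = self._tiles(3)
        model = train(tiles, labels, ClassifierConfig(seed=2, epochs=10))
        dark = [np.full((224, 224, 3), 30, np.uint8)]
        with pytest.warns(UserWarning, match="stain profile"):
            model.predict_tiles(dark)


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    X = rng.normal(0, 1, (60, 8))
    y = (X[:, 0] > 0).astype(float)
    spec = ClassifierConfig(seed=9, epochs=15)
    clf = TileClassifier(spec=spec).fit_features(X, y)
    clf.save(tmp_path / "model.json")
    back = TileClassifier.load(tmp_path / "model.json")
    assert np.allclose(back.predict_features(X), clf.predict_features(X))
    assert back.spec == clf.spec
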