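"""Tile-classifier tests: training determinism, the two-stage scheme's
contracts, argmax prediction rules and the evaluation report."""

import numpy as np
import pytest

from stromascore.classifier import (
    ClassifierModel,
    TileDataset,
    TrainConfig,
    clopper_pearson,
    evaluate,
    fine_tune,
    predict_tile,
    pretrain,
)
from stromascore.synthetic import generate_tile_corpus
from stromascore.taxonomy import N_CLASSES, TileClass


def small_dataset(tiles_per_class=10, side=64, seed=0, tag="pretrain"):
    tiles, labels = generate_tile_corpus(tiles_per_class, side_px=side, rng_seed=seed)
    return TileDataset(tiles, labels, tag)


class _StubModel:
    """Minimal predictor stub: fixed probability rows keyed by tile mean."""

    def __init__(self, proba_fn):
        self.proba_fn = proba_fn
        self.config = TrainConfig()
        self.class_names = tuple(c.label for c in TileClass)

    def predict_proba(self, features):
        features = np.atleast_2d(features)
        return np.stack([self.proba_fn(f) for f in features])


class TestTraining:
    def test_seeded_pretraining_is_bit_reproducible(self):
        ds = small_dataset()
        cfg = TrainConfig(epochs=3, seed=5, learning_rate=0.01)
        a = pretrain(ds, cfg)
        b = pretrain(ds, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(a.mlp.coefs_, b.mlp.coefs_))
        assert all(np.array_equal(x, y) for x, y in zip(a.mlp.intercepts_, b.mlp.intercepts_))

    def test_training_loss_decreases(self):
        model = pretrain(small_dataset(), TrainConfig(epochs=10, seed=0, learning_rate=0.01))
        assert model.history[-1]["train_loss"] < model.history[0]["train_loss"]
        assert "val_accuracy" in model.history[0]

    def test_missing_class_warns_but_proceeds(self):
        ds = small_dataset()
        keep = ds.labels != int(TileClass.MUCUS)
        partial = TileDataset(
            [t for t, k in zip(ds.tiles, keep) if k], ds.labels[keep], "pretrain"
        )
        with pytest.warns(UserWarning, match="mucus"):
            model = pretrain(partial, TrainConfig(epochs=1, seed=0))
        assert model.predict_proba(np.zeros(16 * 16 * 3 + 9)).shape == (1, N_CLASSES)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TileDataset([], np.array([]), "pretrain")

    def test_fine_tune_zero_epochs_returns_unchanged_copy(self):
        ds = small_dataset()
        model = pretrain(ds, TrainConfig(epochs=2, seed=0, learning_rate=0.01))
        tuned = fine_tune(model, ds, TrainConfig(epochs=0))
        assert tuned is not model
        x = np.random.default_rng(0).random((4, 16 * 16 * 3 + 9))
        assert np.allclose(model.predict_proba(x), tuned.predict_proba(x))

    def test_fine_tune_leaves_input_model_untouched(self):
        ds = small_dataset()
        model = pretrain(ds, TrainConfig(epochs=2, seed=0, learning_rate=0.01))
        before = [w.copy() for w in model.mlp.coefs_]
        fine_tune(model, ds, TrainConfig(epochs=2, seed=1, learning_rate=0.01))
        assert all(np.array_equal(a, b) for a, b in zip(before, model.mlp.coefs_))

    def test_fine_tune_on_same_corpus_does_not_degrade(self, corpus_split, trained_model):
        """Continuing the transfer recipe on the pretraining corpus must not
        cost more than 2 points of held-out accuracy."""
        train, test = corpus_split
        base = pretrain(train, TrainConfig(epochs=80, learning_rate=0.01, seed=1))
        base_acc = evaluate(base, test).accuracy
        tuned_acc = evaluate(trained_model, test).accuracy
        assert tuned_acc >= base_acc - 0.02

    def test_architecture_mismatch_rejected(self):
        ds = small_dataset()
        model = pretrain(ds, TrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="feature_side"):
            fine_tune(model, ds, TrainConfig(epochs=1, feature_side=8))


class TestPrediction:
    def test_argmax_class_is_returned(self):
        k = 4
        proba = np.full(N_CLASSES, 0.05)
        proba[k] = 0.60
        stub = _StubModel(lambda f: proba / proba.sum())
        cls, p = predict_tile(stub, np.zeros((64, 64, 3), dtype=np.uint8))
        assert int(cls) == k
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_exact_tie_goes_to_lower_class_index(self):
        proba = np.zeros(N_CLASSES)
        proba[[2, 6]] = 0.5
        stub = _StubModel(lambda f: proba)
        cls, _ = predict_tile(stub, np.zeros((64, 64, 3), dtype=np.uint8))
        assert int(cls) == 2

    def test_probabilities_sum_to_one(self, trained_model):
        tile = np.random.default_rng(1).integers(0, 255, (224, 224, 3), dtype=np.uint8)
        _, proba = predict_tile(trained_model, tile)
        assert proba.sum() == pytest.approx(1.0, abs=1e-6)

    def test_non_rgb_tile_rejected(self, trained_model):
        with pytest.raises(ValueError, match="RGB"):
            predict_tile(trained_model, np.zeros((64, 64)))

    def test_model_roundtrips_through_disk(self, trained_model, model_path):
        loaded = ClassifierModel.load(model_path)
        tile = np.random.default_rng(2).integers(0, 255, (224, 224, 3), dtype=np.uint8)
        _, a = predict_tile(trained_model, tile)
        _, b = predict_tile(loaded, tile)
        assert np.array_equal(a, b)


class TestEvaluation:
    def test_two_stage_training_separates_synthetic_classes(
        self, corpus_split, trained_model
    ):
        _, test = corpus_split
        report = evaluate(trained_model, test)
        assert report.accuracy >= 0.95
        assert report.confusion.sum() == report.n
        assert np.trace(report.confusion) / report.n == pytest.approx(report.accuracy)

    def test_clopper_pearson_matches_exact_binomial_oracle(self):
        # independent oracle: statsmodels' exact (beta) binomial interval
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(973, 1000), (0, 50), (50, 50), (7, 9)]:
            lo, hi = clopper_pearson(k, n)
            olo, ohi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(olo, abs=1e-6)
            assert hi == pytest.approx(ohi, abs=1e-6)

    def test_example_accuracy_interval(self):
        lo, hi = clopper_pearson(973, 1000)
        assert lo == pytest.approx(0.961, abs=2e-3)
        assert hi == pytest.approx(0.982, abs=2e-3)

    def test_label_permuting_predictor_scores_fixed_point_fraction(self):
        """A predictor that permutes labels must score exactly the fraction
        of classes the permutation leaves fixed (brute-force oracle)."""
        perm = np.array([1, 0, 2, 4, 3, 5, 6, 8, 7])  # fixed points: 2,5,6
        tiles, labels = generate_tile_corpus(20, side_px=64, rng_seed=1)
        # stub keyed off the known label order of generate_tile_corpus
        order = np.repeat(np.arange(N_CLASSES), 20)

        class PermModel(_StubModel):
            def __init__(self):
                super().__init__(None)
                self.calls = 0

            def predict_proba(self, features):
                features = np.atleast_2d(features)
                out = np.zeros((len(features), N_CLASSES))
                for i in range(len(features)):
                    out[i, perm[order[self.calls + i]]] = 1.0
                self.calls += len(features)
                return out

        ds = TileDataset(tiles, labels, "test")
        report = evaluate(PermModel(), ds)
        expected = np.mean(perm == np.arange(N_CLASSES))
        assert report.accuracy == pytest.approx(expected)

    def test_all_correct_gives_clean_confusion(self):
        tiles, labels = generate_tile_corpus(3, side_px=64, rng_seed=2)

        class OracleModel(_StubModel):
            def __init__(self):
                super().__init__(None)
                self.calls = 0

            def predict_proba(self, features):
                features = np.atleast_2d(features)
                out = np.zeros((len(features), N_CLASSES))
                for i in range(len(features)):
                    out[i, labels[self.calls + i]] = 1.0
                self.calls += len(features)
                return out

        report = evaluate(OracleModel(), TileDataset(tiles, labels, "test"))
        assert report.accuracy == 1.0
        assert (report.confusion - np.diag(np.diag(report.confusion)) == 0).all()

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            TileDataset([], np.array([]), "test")
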