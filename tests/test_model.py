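"""Fusion, k-means vocabulary, trial encoding, classifiers and evaluation."""

import numpy as np
import pytest
from sklearn.cluster import KMeans as SkKMeans

import bohdf.model as model_mod
from bohdf._kmeans import kmeans
from bohdf.deep import DeepFeatureVector
from bohdf.model import (RAW_FEATURE_LENGTH, BoHDFClassifier, BoHDFEncoder,
                         Vocabulary, build_vocabulary, encode_trial, evaluate,
                         fuse_features, train_classifier)

from .oracles import nearest_centroid


class TestFusion:
    def test_zero_fusion(self):
        rv = fuse_features(np.zeros(1000), np.zeros(600))
        assert rv.values.shape == (1600,)
        assert np.all(rv.values == 0)

    def test_layout_deep_then_texture(self, rng):
        deep = DeepFeatureVector(rng.random(1000), "mock", "h")
        texture = rng.random(600)
        rv = fuse_features(deep, texture, trial_id="t", channel="CH01", label=2)
        assert rv.values.shape == (RAW_FEATURE_LENGTH,)
        assert rv.values[1000] == texture[0]
        assert np.array_equal(rv.values[:1000], deep.values)
        assert (rv.trial_id, rv.channel, rv.label) == ("t", "CH01", 2)


class TestKMeans:
    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.standard_normal((200, 5))
        res = kmeans(X, 6, seed=0)
        hist = np.array(res.inertia_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_final_assignment_is_argmin(self, rng):
        X = rng.standard_normal((100, 4))
        res = kmeans(X, 5, seed=1)
        for i, x in enumerate(X):
            assert res.labels[i] == nearest_centroid(x, res.centroids)

    def test_matches_sklearn_objective_on_easy_data(self, rng):
        """On well-separated blobs both our Lloyd and sklearn's find the same
        partition; sklearn is the independent oracle."""
        means = np.array([[0.0, 0], [10, 0], [0, 10]])
        X = np.vstack([m + 0.1 * rng.standard_normal((30, 2)) for m in means])
        ours = kmeans(X, 3, seed=0)
        sk = SkKMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)
        assert np.allclose(np.sort(ours.centroids, axis=0),
                           np.sort(sk.cluster_centers_, axis=0), atol=1e-6)

    def test_k1_is_mean(self, rng):
        X = rng.standard_normal((40, 3))
        res = kmeans(X, 1, seed=0)
        assert np.allclose(res.centroids[0], X.mean(axis=0), atol=1e-12)


class TestVocabulary:
    def test_single_class_k1_word_is_class_mean(self, rng):
        X = rng.standard_normal((20, 6))
        vocab = build_vocabulary(X, np.zeros(20, dtype=int), k_per_class=1, seed=0)
        assert vocab.n_words == 1
        assert np.allclose(vocab.unstandardize_words()[0], X.mean(axis=0), atol=1e-9)

    def test_planted_clouds_recovered(self, rng):
        """Two classes of two tight well-separated clouds each: per-class
        k-means with k=2 recovers the cloud means within 1e-3 after
        unstandardising."""
        centers = {0: [np.full(4, 0.0), np.full(4, 20.0)],
                   1: [np.full(4, -30.0), np.full(4, 50.0)]}
        X, y, true_means = [], [], []
        for cls, cs in centers.items():
            for c in cs:
                pts = c + 1e-4 * rng.standard_normal((25, 4))
                X.append(pts)
                y.extend([cls] * 25)
                true_means.append(pts.mean(axis=0))
        vocab = build_vocabulary(np.vstack(X), y, k_per_class=2, seed=0)
        words = vocab.unstandardize_words()
        assert vocab.n_words == 4
        for tm in true_means:
            err = np.abs(words - tm).max(axis=1).min()
            assert err < 1e-3

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((60, 8))
        y = np.repeat([0, 1, 2], 20)
        a = build_vocabulary(X, y, k_per_class=4, seed=7)
        b = build_vocabulary(X, y, k_per_class=4, seed=7)
        assert np.array_equal(a.words, b.words)
        assert np.array_equal(a.word_classes, b.word_classes)

    def test_word_count_is_k_times_classes(self, rng):
        X = rng.standard_normal((60, 8))
        y = np.repeat([0, 1, 2], 20)
        vocab = build_vocabulary(X, y, k_per_class=5, seed=0)
        assert vocab.n_words == 15
        assert np.array_equal(vocab.word_classes, np.repeat([0, 1, 2], 5))

    def test_too_few_vectors_names_class(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValueError, match="class 1"):
            build_vocabulary(X, y, k_per_class=4)

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((40, 5))
        y = np.repeat([0, 1], 20)
        vocab = build_vocabulary(X, y, k_per_class=2, seed=0)
        vocab.save(tmp_path / "vocab")
        back = Vocabulary.load(tmp_path / "vocab")
        assert np.array_equal(back.words, vocab.words)
        assert np.array_equal(back.scaler_mean, vocab.scaler_mean)
        assert back.k_per_class == 2


class TestEncodeTrial:
    def _vocab(self, rng, n_words=6, dim=10):
        X = rng.standard_normal((60, dim))
        y = np.repeat([0, 1], 30)
        return build_vocabulary(X, y, k_per_class=n_words // 2, seed=0)

    def test_exact_centroid_goes_to_its_word(self, rng):
        vocab = self._vocab(rng)
        raw_word = vocab.unstandardize_words()[3]
        counts = encode_trial(np.tile(raw_word, (5, 1)), vocab, normalize=False)
        assert counts[3] == 5
        assert counts.sum() == 5

    def test_counts_sum_to_channel_count(self, rng):
        vocab = self._vocab(rng)
        counts = encode_trial(rng.standard_normal((32, 10)), vocab, normalize=False)
        assert counts.sum() == 32
        norm = encode_trial(rng.standard_normal((32, 10)), vocab, normalize=True)
        assert norm.sum() == pytest.approx(1.0)

    def test_assignments_match_exhaustive_scan(self, rng):
        vocab = self._vocab(rng)
        X = rng.standard_normal((20, 10))
        counts = encode_trial(X, vocab, normalize=False)
        expected = np.zeros(vocab.n_words)
        for z in vocab.standardize(X):
            expected[nearest_centroid(z, vocab.words)] += 1
        assert np.array_equal(counts, expected)

    def test_dimension_mismatch_rejected(self, rng):
        vocab = self._vocab(rng)
        with pytest.raises(ValueError, match="dimension"):
            encode_trial(rng.standard_normal((4, 7)), vocab)


class TestClassifiers:
    def test_knn_own_point_own_label(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.repeat([0, 1], 10)
        clf = train_classifier(X, y, kind="knn_weighted", n_neighbors=1)
        assert np.array_equal(clf.predict(X), y)

    def test_svm_separable_clouds_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.standard_normal((30, 3)) - 5,
                       rng.standard_normal((30, 3)) + 5])
        y = np.repeat([0, 1], 30)
        for kind in ("svm_rbf", "svm_cubic"):
            clf = train_classifier(X, y, kind=kind)
            assert (clf.predict(X) == y).mean() == 1.0

    def test_single_class_and_empty_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(rng.standard_normal((10, 3)), np.zeros(10))
        with pytest.raises(ValueError, match="empty"):
            train_classifier(np.empty((0, 3)), [])


def _toy_trials(rng, n_per_class=10, n_channels=4, dim=12, spread=0.05):
    """Trials whose channel vectors sit near class-specific centers."""
    X, y = [], []
    for cls in range(3):
        center = np.zeros(dim)
        center[cls * 4:(cls + 1) * 4] = 5.0
        for _ in range(n_per_class):
            X.append(center + spread * rng.standard_normal((n_channels, dim)))
            y.append(cls)
    return X, np.array(y)


class TestEvaluate:
    def test_identical_trials_per_class_are_perfect(self, rng):
        X, y = _toy_trials(rng, spread=0.0)
        report = evaluate(X, y, estimator=BoHDFClassifier(k_per_class=2, seed=0),
                          n_splits=5, seed=0)
        assert report["mean_accuracy"] == 1.0
        conf = np.array(report["confusion_matrix"])
        assert conf.trace() == len(y)

    def test_fold_mean_is_arithmetic_mean(self, rng):
        X, y = _toy_trials(rng, spread=2.0)
        report = evaluate(X, y, estimator=BoHDFClassifier(k_per_class=2, seed=0),
                          n_splits=5, seed=0)
        assert report["mean_accuracy"] == pytest.approx(
            np.mean(report["fold_accuracies"]))
        assert len(report["fold_accuracies"]) == 5
        assert report["config"]["k_per_class"] == 2

    def test_too_few_trials_per_class_rejected(self, rng):
        X, y = _toy_trials(rng, n_per_class=3)
        with pytest.raises(ValueError, match="n_splits"):
            evaluate(X, y, n_splits=5)

    def test_holdout_mode(self, rng):
        X, y = _toy_trials(rng, spread=0.0)
        report = evaluate(X, y, estimator=BoHDFClassifier(k_per_class=2, seed=0),
                          mode="holdout", seed=0)
        assert report["accuracy"] == 1.0
        assert report["test_size"] == 0.3

    def test_vocabulary_rebuilt_per_fold_from_training_only(self, rng, monkeypatch):
        """Leakage audit: each fold builds its vocabulary from exactly the
        fold's training trials (channel vectors), never from the full set."""
        X, y = _toy_trials(rng, n_per_class=10, n_channels=4)
        calls = []
        original = model_mod.build_vocabulary

        def spy(features, labels, **kw):
            calls.append(np.asarray(features).shape[0])
            return original(features, labels, **kw)

        monkeypatch.setattr(model_mod, "build_vocabulary", spy)
        evaluate(X, y, estimator=BoHDFClassifier(k_per_class=2, seed=0),
                 n_splits=5, seed=0)
        # 30 trials, 5 folds: 24 training trials x 4 channels per fold
        assert calls == [24 * 4] * 5


def test_encoder_transform_requires_fit(rng):
    with pytest.raises(RuntimeError, match="not fitted"):
        BoHDFEncoder().transform([rng.standard_normal((2, 5))])


def test_classifier_sklearn_params_round_trip():
    est = BoHDFClassifier(k_per_class=4, classifier="svm_rbf", seed=3)
    params = est.get_params()
    clone_est = BoHDFClassifier(**params)
    assert clone_est.get_params() == params
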