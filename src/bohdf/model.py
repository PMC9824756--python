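"""Feature fusion, bag-of-words vocabulary, trial encoding and classification.

One raw feature vector per channel per trial: the deep backend's 1000 values
concatenated with the 600 texture values (1600 total).  A vocabulary is built
from training trials only: raw vectors are z-scored per dimension, then
k-means (k words per class, run independently within each class) yields the
word centroids.  A trial is encoded as the histogram of nearest-word
assignments of its channel vectors — the bag-of-hybrid-deep-features
(BoHDF) vector — and the histograms are classified with weighted KNN or SVM.

Estimators follow scikit-learn conventions; :class:`BoHDFClassifier` is the
end-to-end fit/predict surface over (n_trials, n_channels, n_features)
arrays, and the module functions are the step-wise API underneath it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from ._kmeans import kmeans
from .deep import DeepFeatureVector
from .omtlbp import DESCRIPTOR_LENGTH

RAW_FEATURE_LENGTH = 1000 + DESCRIPTOR_LENGTH   # deep + texture = 1600


@dataclass
class RawFeatureVector:
    """Per-channel fusion of deep (first) and texture (last 600) features."""

    values: np.ndarray
    trial_id: str = ""
    channel: str = ""
    label: Optional[int] = None


def fuse_features(deep: DeepFeatureVector | np.ndarray,
                  texture: np.ndarray,
                  trial_id: str = "", channel: str = "",
                  label: Optional[int] = None) -> RawFeatureVector:
    """Concatenate deep-then-texture into one raw feature vector."""
    deep_values = deep.values if isinstance(deep, DeepFeatureVector) else np.asarray(deep)
    values = np.concatenate([np.ravel(deep_values), np.ravel(texture)])
    return RawFeatureVector(values=values, trial_id=trial_id, channel=channel,
                            label=label)


@dataclass
class Vocabulary:
    """Bag-of-words vocabulary: word centroids with their source class, plus
    the training-data standardiser that makes Euclidean distance meaningful
    across the differently-scaled deep and texture halves."""

    words: np.ndarray              # (n_words, n_features), standardized space
    word_classes: np.ndarray       # (n_words,)
    k_per_class: int
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    meta: dict = dataclass_field(default_factory=dict)

    @property
    def n_words(self) -> int:
        return self.words.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.scaler_mean) / self.scaler_scale

    def unstandardize_words(self) -> np.ndarray:
        """Word centroids mapped back to raw feature space."""
        return self.words * self.scaler_scale + self.scaler_mean

    def save(self, path: str | Path) -> None:
        """Versioned JSON metadata + .npy matrices bundle."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "words.npy", self.words)
        np.save(path / "scaler_mean.npy", self.scaler_mean)
        np.save(path / "scaler_scale.npy", self.scaler_scale)
        payload = {"format_version": 1, "k_per_class": self.k_per_class,
                   "word_classes": [int(c) for c in self.word_classes],
                   "meta": self.meta}
        (path / "vocabulary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        path = Path(path)
        payload = json.loads((path / "vocabulary.json").read_text())
        return cls(words=np.load(path / "words.npy"),
                   word_classes=np.asarray(payload["word_classes"]),
                   k_per_class=payload["k_per_class"],
                   scaler_mean=np.load(path / "scaler_mean.npy"),
                   scaler_scale=np.load(path / "scaler_scale.npy"),
                   meta=payload.get("meta", {}))


def build_vocabulary(features: np.ndarray, labels: Sequence[int],
                     k_per_class: int = 8, seed: int = 0,
                     mode: str = "per_class") -> Vocabulary:
    """Build the k-means vocabulary from labeled training feature vectors.

    ``mode="per_class"`` (canonical) clusters each class independently into
    ``k_per_class`` words; ``mode="global"`` runs one k-means with
    ``k_per_class * n_classes`` clusters for comparison.  Clustering runs to
    convergence (relative centroid movement below 1e-6, at most 300
    iterations) and is deterministic given the seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be (n_vectors, n_features)")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    classes = np.unique(y)
    sub_seeds = np.random.SeedSequence(seed).generate_state(max(len(classes), 1))
    if mode == "global":
        result = kmeans(Z, k_per_class * len(classes), seed=int(sub_seeds[0]))
        words, word_classes = result.centroids, np.full(result.centroids.shape[0], -1)
    elif mode == "per_class":
        word_list, class_list = [], []
        for ci, c in enumerate(classes):
            Zc = Z[y == c]
            if Zc.shape[0] < k_per_class:
                raise ValueError(
                    f"class {c} has only {Zc.shape[0]} training vectors; "
                    f"need at least k_per_class = {k_per_class}")
            result = kmeans(Zc, k_per_class, seed=int(sub_seeds[ci]))
            word_list.append(result.centroids)
            class_list.extend([c] * k_per_class)
        words = np.vstack(word_list)
        word_classes = np.asarray(class_list)
    else:
        raise ValueError(f"unknown vocabulary mode {mode!r}")
    return Vocabulary(words=words, word_classes=word_classes,
                      k_per_class=k_per_class, scaler_mean=mean,
                      scaler_scale=scale, meta={"mode": mode, "seed": seed})


def encode_trial(channel_features: np.ndarray, vocab: Vocabulary,
                 normalize: bool = True) -> np.ndarray:
    """Encode one trial's channel feature vectors as word frequencies.

    Each channel vector is standardised with the vocabulary's scaler and
    assigned to its nearest word (Euclidean; lowest word index on ties);
    counts are accumulated over channels and optionally L1-normalised.
    """
    X = np.atleast_2d(np.asarray(channel_features, dtype=np.float64))
    if X.shape[0] == 0:
        raise ValueError("trial has no channel feature vectors")
    if X.shape[1] != vocab.words.shape[1]:
        raise ValueError(f"feature dimension {X.shape[1]} does not match "
                         f"vocabulary dimension {vocab.words.shape[1]}")
    Z = vocab.standardize(X)
    d = ((Z[:, None, :] - vocab.words[None]) ** 2).sum(axis=2)
    assignment = np.argmin(d, axis=1)
    counts = np.bincount(assignment, minlength=vocab.n_words).astype(np.float64)
    return counts / counts.sum() if normalize else counts


def train_classifier(encoded: np.ndarray, labels: Sequence[int],
                     kind: str = "knn_weighted", **params):
    """Fit the final classifier on encoded BoHDF vectors.

    Kinds: ``knn_weighted`` (inverse-distance weighted KNN, default 10
    neighbours, Euclidean), ``svm_rbf`` (Gaussian kernel, gamma scaled to
    feature count), ``svm_cubic`` (degree-3 polynomial kernel).
    """
    X = np.asarray(encoded, dtype=np.float64)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class; need >= 2")
    if kind == "knn_weighted":
        n_neighbors = min(int(params.pop("n_neighbors", 10)), X.shape[0])
        clf = KNeighborsClassifier(n_neighbors=n_neighbors, weights="distance",
                                   metric="euclidean", **params)
    elif kind == "svm_rbf":
        clf = SVC(kernel="rbf", gamma="scale", **params)
    elif kind == "svm_cubic":
        clf = SVC(kernel="poly", degree=3, gamma="scale", **params)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    return clf


class BoHDFEncoder(BaseEstimator, TransformerMixin):
    """Transformer: channel-level raw feature arrays -> per-trial BoHDF
    histograms.

    ``fit`` expects ``X`` of shape (n_trials, n_channels, n_features) (or a
    list of per-trial 2D arrays) with trial labels ``y``; it standardises the
    pooled channel vectors and builds the per-class k-means vocabulary from
    them.  ``transform`` encodes trials against that vocabulary.
    """

    def __init__(self, k_per_class: int = 8, seed: int = 0,
                 normalize: bool = True, mode: str = "per_class"):
        self.k_per_class = k_per_class
        self.seed = seed
        self.normalize = normalize
        self.mode = mode

    @staticmethod
    def _as_trials(X) -> list[np.ndarray]:
        return [np.atleast_2d(np.asarray(t, dtype=np.float64)) for t in X]

    def fit(self, X, y):
        trials = self._as_trials(X)
        y = np.asarray(y)
        if len(trials) != y.shape[0]:
            raise ValueError("X and y length mismatch")
        pooled = np.vstack(trials)
        pooled_labels = np.concatenate(
            [np.full(t.shape[0], lab) for t, lab in zip(trials, y)])
        self.vocabulary_ = build_vocabulary(pooled, pooled_labels,
                                            k_per_class=self.k_per_class,
                                            seed=self.seed, mode=self.mode)
        self.n_features_in_ = pooled.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("BoHDFEncoder is not fitted")
        return np.stack([encode_trial(t, self.vocabulary_, normalize=self.normalize)
                         for t in self._as_trials(X)])


class BoHDFClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end BoHDF classifier over per-channel raw feature vectors.

    Parameters
    ----------
    k_per_class : int, default 8
        Vocabulary words per class.
    classifier : {"knn_weighted", "svm_rbf", "svm_cubic"}, default "knn_weighted"
    n_neighbors : int, default 10
        KNN neighbour count (inverse-distance weighting).
    normalize : bool, default True
        L1-normalise the per-trial word histograms.
    vocab_mode : {"per_class", "global"}, default "per_class"
    seed : int, default 0
        Drives vocabulary clustering; the pipeline is deterministic given it.
    """

    def __init__(self, k_per_class: int = 8, classifier: str = "knn_weighted",
                 n_neighbors: int = 10, normalize: bool = True,
                 vocab_mode: str = "per_class", seed: int = 0):
        self.k_per_class = k_per_class
        self.classifier = classifier
        self.n_neighbors = n_neighbors
        self.normalize = normalize
        self.vocab_mode = vocab_mode
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y)
        self.encoder_ = BoHDFEncoder(k_per_class=self.k_per_class, seed=self.seed,
                                     normalize=self.normalize, mode=self.vocab_mode)
        encoded = self.encoder_.fit(X, y).transform(X)
        params = {"n_neighbors": self.n_neighbors} if self.classifier == "knn_weighted" else {}
        self.clf_ = train_classifier(encoded, y, kind=self.classifier, **params)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "clf_"):
            raise RuntimeError("BoHDFClassifier is not fitted")
        return self.clf_.predict(self.encoder_.transform(X))


def evaluate(X, y, estimator: Optional[BoHDFClassifier] = None,
             n_splits: int = 5, seed: int = 0, mode: str = "cv",
             test_size: float = 0.3) -> dict:
    """Evaluate the pipeline with stratified cross-validation (canonical) or
    a stratified 70/30 holdout (``mode="holdout"``).

    The vocabulary, scaler and classifier are re-fitted inside every fold
    from that fold's training portion only, so no test information leaks
    into the encoding.  The report carries per-fold accuracies, their mean,
    the summed confusion matrix, and the estimator configuration.
    """
    y = np.asarray(y)
    estimator = estimator if estimator is not None else BoHDFClassifier(seed=seed)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("evaluation needs at least 2 classes")
    report: dict = {
        "mode": mode,
        "n_trials": int(y.shape[0]),
        "classes": [int(c) for c in classes],
        "config": {k: v for k, v in estimator.get_params().items()},
        "seed": int(seed),
    }
    X = list(X)
    if mode == "holdout":
        idx_train, idx_test = train_test_split(
            np.arange(y.shape[0]), test_size=test_size, stratify=y, random_state=seed)
        est = clone(estimator).fit([X[i] for i in idx_train], y[idx_train])
        pred = est.predict([X[i] for i in idx_test])
        acc = float(np.mean(pred == y[idx_test]))
        report.update({
            "test_size": test_size,
            "accuracy": acc,
            "mean_accuracy": acc,
            "confusion_matrix": _sk_confusion(y[idx_test], pred, labels=classes).tolist(),
        })
        return report
    if mode != "cv":
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if counts.min() < n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} trials; need at least "
            f"n_splits = {n_splits} per class for stratified CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_acc = []
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    for idx_train, idx_test in skf.split(np.zeros(y.shape[0]), y):
        est = clone(estimator).fit([X[i] for i in idx_train], y[idx_train])
        pred = est.predict([X[i] for i in idx_test])
        fold_acc.append(float(np.mean(pred == y[idx_test])))
        confusion += _sk_confusion(y[idx_test], pred, labels=classes)
    report.update({
        "n_splits": n_splits,
        "fold_accuracies": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
        "confusion_matrix": confusion.tolist(),
    })
    return report
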