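"""Single-classifier and beat-indexed ensemble strategies.

Two ways to turn nine per-beat MFCC vectors into one normal/abnormal call:

* **single** — the nine 52-dimensional beat vectors are averaged and one
  classifier decides on the 52 mean MFCCs;
* **ensemble** — nine classifiers are trained, classifier *j* on beat *j* of
  every training signal (each beat inheriting its signal's label), and the
  signal-level decision is a majority vote: strictly more normal beat votes
  than abnormal gives normal, otherwise abnormal.  With nine voters no tie
  can occur.

Backends are ordinary scikit-learn classifiers (kNN, SVM, decision tree) and
the strategy itself is a scikit-learn estimator, so it composes with
``clone``, pipelines and model selection.  Features are z-scored with
training-fold statistics by default since kNN and SVM are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .mfcc import BeatFeatureVector

__all__ = [
    "SignalFeatureSet",
    "PcgStrategyClassifier",
    "average_beats",
    "majority_vote",
    "stack_feature_sets",
    "train_single",
    "train_ensemble",
    "predict",
]

#: Classifier families ("DT" = decision tree).
FAMILIES = ("knn", "svm", "dt")
STRATEGIES = ("single", "ensemble")


class DegenerateTrainingError(ValueError):
    """Training data does not contain both classes."""


@dataclass
class SignalFeatureSet:
    """The nine beat feature vectors of one signal, ordered by beat index."""

    beats: np.ndarray  # (n_beats, 52)
    signal_id: str
    label: str

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        if self.beats.ndim != 2 or self.beats.shape[1] != 52:
            raise ValueError(f"expected (n_beats, 52) array, got {self.beats.shape}")

    @classmethod
    def from_vectors(cls, vectors: Sequence[BeatFeatureVector]) -> "SignalFeatureSet":
        ordered = sorted(vectors, key=lambda v: v.beat_index)
        ids = {v.signal_id for v in ordered}
        labels = {v.label for v in ordered}
        if len(ids) != 1 or len(labels) != 1:
            raise ValueError("feature vectors must come from a single signal")
        return cls(
            beats=np.stack([v.values for v in ordered]),
            signal_id=ordered[0].signal_id,
            label=ordered[0].label,
        )


def average_beats(beats: np.ndarray | SignalFeatureSet) -> np.ndarray:
    """Element-wise mean of the nine beat vectors → 52 mean MFCCs."""
    arr = beats.beats if isinstance(beats, SignalFeatureSet) else np.asarray(beats, float)
    if arr.ndim != 2 or arr.shape[0] != 9:
        raise ValueError(f"expected exactly 9 beat vectors, got shape {arr.shape}")
    return arr.mean(axis=0)


def majority_vote(labels: Sequence[str]) -> str:
    """Signal-level decision from beat votes: strictly more "normal" votes
    than "abnormal" gives "normal"; otherwise "abnormal"."""
    votes = list(labels)
    n_normal = sum(1 for v in votes if v == "normal")
    return "normal" if n_normal > len(votes) - n_normal else "abnormal"


class PcgStrategyClassifier(ClassifierMixin, BaseEstimator):
    """Signal classifier over per-beat MFCC features.

    Parameters
    ----------
    strategy : {"single", "ensemble"}
        Average beats into one vector for a single classifier, or train one
        classifier per beat position and majority-vote their decisions.
    family : {"knn", "svm", "dt"}
        Backend classifier type (shared by all ensemble members).
    knn_k : int
        Neighbor count for kNN; must be odd so neighbor votes cannot tie.
    svm_kernel : {"linear", "rbf", "poly"}
        SVM kernel ("rbf" is the Gaussian kernel).
    svm_degree, svm_c : polynomial degree and regularization constant.
    dt_criterion : split impurity criterion for the decision tree.
    standardize : z-score features with training statistics before the
        backend (recommended for kNN/SVM).
    random_state : seed for backends that break ties randomly (the tree).

    Attributes (after fit)
    ----------------------
    classes_ : array of class labels.
    models_ : list of fitted backends (1 for single, n_beats for ensemble).
    n_beats_ : number of beat positions seen during fit.
    """

    def __init__(
        self,
        strategy: str = "ensemble",
        family: str = "svm",
        knn_k: int = 3,
        svm_kernel: str = "poly",
        svm_degree: int = 3,
        svm_c: float = 1.0,
        dt_criterion: str = "gini",
        standardize: bool = True,
        random_state: int | None = 0,
    ):
        self.strategy = strategy
        self.family = family
        self.knn_k = knn_k
        self.svm_kernel = svm_kernel
        self.svm_degree = svm_degree
        self.svm_c = svm_c
        self.dt_criterion = dt_criterion
        self.standardize = standardize
        self.random_state = random_state

    def _make_backend(self):
        if self.family == "knn":
            if self.knn_k < 1 or self.knn_k % 2 == 0:
                raise ValueError("knn_k must be odd and >= 1")
            model = KNeighborsClassifier(n_neighbors=self.knn_k, metric="euclidean")
        elif self.family == "svm":
            model = SVC(
                kernel=self.svm_kernel,
                degree=self.svm_degree,
                C=self.svm_c,
                gamma="scale",
            )
        elif self.family == "dt":
            model = DecisionTreeClassifier(
                criterion=self.dt_criterion, random_state=self.random_state
            )
        else:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("model", model)])
        return model

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_signals, n_beats, n_features); got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y):
        """Fit on ``X`` of shape (n_signals, n_beats, 52) and labels ``y``."""
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise DegenerateTrainingError(
                f"training labels contain a single class: {self.classes_}"
            )
        self.n_beats_ = X.shape[1]
        if self.strategy == "single":
            model = self._make_backend()
            model.fit(X.mean(axis=1), y)
            self.models_ = [model]
        else:
            self.models_ = []
            for j in range(self.n_beats_):
                model = self._make_backend()
                model.fit(X[:, j, :], y)
                self.models_.append(model)
        return self

    def predict(self, X):
        """Predict a label per signal (majority vote in ensemble mode)."""
        if not hasattr(self, "models_"):
            raise RuntimeError("classifier is not fitted")
        X = self._validate_X(X)
        if X.shape[1] != self.n_beats_:
            raise ValueError(
                f"expected {self.n_beats_} beats per signal, got {X.shape[1]}"
            )
        if self.strategy == "single":
            return self.models_[0].predict(X.mean(axis=1))
        beat_votes = np.stack(
            [self.models_[j].predict(X[:, j, :]) for j in range(self.n_beats_)]
        )  # (n_beats, n_signals)
        return np.array([majority_vote(beat_votes[:, i]) for i in range(X.shape[0])])


def stack_feature_sets(
    feature_sets: Sequence[SignalFeatureSet],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack signal feature sets into ``(X, y, ids)`` for the estimator."""
    if not feature_sets:
        raise DegenerateTrainingError("no training signals given")
    n_beats = {fs.beats.shape[0] for fs in feature_sets}
    if len(n_beats) != 1:
        raise ValueError(f"inconsistent beat counts across signals: {sorted(n_beats)}")
    X = np.stack([fs.beats for fs in feature_sets])
    y = np.array([fs.label for fs in feature_sets])
    return X, y, [fs.signal_id for fs in feature_sets]


def train_single(
    train_sets: Sequence[SignalFeatureSet], **params
) -> PcgStrategyClassifier:
    """Fit the averaged-feature single-classifier strategy."""
    X, y, _ = stack_feature_sets(train_sets)
    return PcgStrategyClassifier(strategy="single", **params).fit(X, y)


def train_ensemble(
    train_sets: Sequence[SignalFeatureSet], **params
) -> PcgStrategyClassifier:
    """Fit the beat-indexed ensemble strategy (one classifier per position)."""
    X, y, _ = stack_feature_sets(train_sets)
    return PcgStrategyClassifier(strategy="ensemble", **params).fit(X, y)


def predict(strategy: PcgStrategyClassifier, fs: SignalFeatureSet) -> str:
    """Classify one signal with a trained strategy."""
    return str(strategy.predict(fs.beats[np.newaxis])[0])


def clone_strategy(strategy: PcgStrategyClassifier) -> PcgStrategyClassifier:
    """Unfitted copy with identical parameters (sklearn ``clone``)."""
    return clone(strategy)
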