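"""Imbalance-aware classifiers over binary presence features.

Syncope appears in roughly 2% of records, so both classifiers carry an
imbalance control named as a hyper-parameter:

* :class:`UndersampledBernoulliNB` — Bernoulli Naive Bayes with additive
  smoothing, trained after randomly discarding negatives down to a fixed
  ratio of negatives per positive.
* :class:`WeightedLinearSVC` — linear soft-margin SVM with an elevated
  misclassification weight on the positive class.

Both follow the scikit-learn estimator API (``fit`` / ``predict`` /
``decision_function``) and delegate the underlying optimisation to
scikit-learn.  :func:`train` / :func:`predict` wrap them into a portable
:class:`TrainedModel` whose parameters (log-probabilities or weight
vector) serialise to JSON and are applied without scikit-learn at predict
time, so a stored model is self-contained.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Union

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import LinearSVC

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "undersample",
    "undersample_indices",
    "train",
    "predict",
    "UndersampledBernoulliNB",
    "WeightedLinearSVC",
    "CLASSIFIER_FAMILIES",
    "register_classifier",
]


def undersample_indices(
    y: np.ndarray, ratio: Optional[float], seed: Optional[int] = None
) -> np.ndarray:
    """Row indices keeping all positives and a random subset of negatives.

    ``ratio`` is the number of negatives kept per positive (>= 1), or None
    ("off") to keep everything.  The returned indices preserve original row
    order and are reproducible under ``seed``.
    """
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0:
        raise ValueError("undersampling requires at least one positive record")
    if ratio is None or math.isinf(ratio):
        return np.arange(len(y))
    if ratio < 1:
        raise ValueError(f"undersampling ratio must be >= 1 or None, got {ratio}")
    n_keep = min(int(math.ceil(ratio * pos.size)), neg.size)
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg, size=n_keep, replace=False)
    return np.sort(np.concatenate([pos, kept_neg]))


def undersample(matrix, y, ratio: Optional[float], seed: Optional[int] = None):
    """Apply :func:`undersample_indices` to a feature matrix and labels."""
    idx = undersample_indices(y, ratio, seed)
    return matrix[idx], np.asarray(y)[idx]


class UndersampledBernoulliNB(BaseEstimator, ClassifierMixin):
    """Bernoulli Naive Bayes trained on an undersampled split.

    Parameters
    ----------
    ratio : float or None
        Negatives kept per positive during training; None disables
        undersampling.
    alpha : float
        Additive (Laplace) smoothing on the Bernoulli feature likelihoods.
    random_state : int or None
        Seed for the negative subsampling.
    """

    def __init__(self, ratio: Optional[float] = None, alpha: float = 1.0,
                 random_state: Optional[int] = None):
        self.ratio = ratio
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        idx = undersample_indices(y, self.ratio, self.random_state)
        self.nb_ = BernoulliNB(alpha=self.alpha)
        self.nb_.fit(X[idx], y[idx])
        self.classes_ = self.nb_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        self._check_features(X)
        return self.nb_.predict(X)

    def predict_proba(self, X):
        self._check_features(X)
        return self.nb_.predict_proba(X)

    def decision_function(self, X):
        """Log posterior odds of the positive class."""
        self._check_features(X)
        logp = self.nb_.predict_log_proba(X)
        return logp[:, 1] - logp[:, 0]

    def _check_features(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature-set mismatch: model has {self.n_features_in_} features, "
                f"input has {X.shape[1]}"
            )


class WeightedLinearSVC(BaseEstimator, ClassifierMixin):
    """Linear SVM with an explicit positive-class weight.

    ``pos_weight`` multiplies the hinge-loss penalty of positive examples
    ("balanced" uses the inverse class frequencies); ``C`` is the usual
    inverse regularisation strength.
    """

    def __init__(self, pos_weight: Union[float, str] = 1.0, C: float = 1.0,
                 random_state: Optional[int] = None):
        self.pos_weight = pos_weight
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both classes present")
        if self.pos_weight == "balanced":
            class_weight = "balanced"
        else:
            if not self.pos_weight > 0:
                raise ValueError("pos_weight must be positive")
            class_weight = {0: 1.0, 1: float(self.pos_weight)}
        self.svc_ = LinearSVC(
            C=self.C, class_weight=class_weight, random_state=self.random_state
        )
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        self.coef_ = self.svc_.coef_
        self.intercept_ = self.svc_.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        self._check_features(X)
        return self.svc_.predict(X)

    def decision_function(self, X):
        self._check_features(X)
        return self.svc_.decision_function(X)

    def _check_features(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature-set mismatch: model has {self.n_features_in_} features, "
                f"input has {X.shape[1]}"
            )


#: classifier plug-in registry: family name -> estimator factory taking
#: (hyperparams dict, seed) and returning an unfitted estimator
CLASSIFIER_FAMILIES: dict[str, Callable] = {
    "nb_bernoulli": lambda hp, seed: UndersampledBernoulliNB(
        ratio=hp.get("ratio"), alpha=hp.get("alpha", 1.0), random_state=seed
    ),
    "svm_linear": lambda hp, seed: WeightedLinearSVC(
        pos_weight=hp.get("pos_weight", 1.0), C=hp.get("C", 1.0), random_state=seed
    ),
}


def register_classifier(name: str, factory: Callable) -> None:
    """Register an additional classifier family (e.g. a decision tree)."""
    CLASSIFIER_FAMILIES[name] = factory


@dataclass
class ModelSpec:
    """Classifier family plus hyper-parameters."""

    family: str
    hyperparams: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"known: {sorted(CLASSIFIER_FAMILIES)}"
            )


@dataclass
class TrainedModel:
    """Portable fitted model: parameters only, applied without sklearn."""

    family: str
    params: dict
    n_features: int
    feature_hash: str
    seed: Optional[int]
    spec: dict

    VERSION = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.VERSION,
                "family": self.family,
                "params": self.params,
                "n_features": self.n_features,
                "feature_hash": self.feature_hash,
                "seed": self.seed,
                "spec": self.spec,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        if d.get("version") != cls.VERSION:
            raise ValueError(f"unsupported model version {d.get('version')}")
        return cls(
            family=d["family"], params=d["params"], n_features=d["n_features"],
            feature_hash=d["feature_hash"], seed=d["seed"], spec=d["spec"],
        )


def _feature_hash(n_features: int, feature_names=None) -> str:
    payload = json.dumps([n_features, list(feature_names or [])]).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _densify(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def train(
    spec: ModelSpec, matrix, labels, seed: Optional[int] = None, feature_names=None
) -> TrainedModel:
    """Fit a model per ``spec`` and extract its portable parameters."""
    est = CLASSIFIER_FAMILIES[spec.family](spec.hyperparams, seed)
    est.fit(matrix, labels)
    if spec.family == "nb_bernoulli":
        params = {
            "class_log_prior": est.nb_.class_log_prior_.tolist(),
            "feature_log_prob": est.nb_.feature_log_prob_.tolist(),
        }
    elif spec.family == "svm_linear":
        params = {
            "coef": est.coef_.ravel().tolist(),
            "intercept": float(est.intercept_[0]),
        }
    else:  # plug-in families store nothing portable; keep the estimator
        params = {"_estimator": est}
    return TrainedModel(
        family=spec.family,
        params=params,
        n_features=matrix.shape[1],
        feature_hash=_feature_hash(matrix.shape[1], feature_names),
        seed=seed,
        spec={"family": spec.family, "hyperparams": spec.hyperparams},
    )


def predict(model: TrainedModel, matrix) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision scores from a portable model.

    For Naive Bayes the score is the log posterior odds computed from both
    presence and absence likelihoods; for the SVM it is the signed distance
    to the separating hyperplane.
    """
    X = _densify(matrix)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature-set mismatch: model has {model.n_features} features, "
            f"input has {X.shape[1]}"
        )
    if model.family == "nb_bernoulli":
        log_prior = np.asarray(model.params["class_log_prior"])
        log_prob = np.asarray(model.params["feature_log_prob"])  # (2, n_features)
        log_not = np.log1p(-np.exp(log_prob))
        joint = X @ log_prob.T + (1 - X) @ log_not.T + log_prior  # (n, 2)
        scores = joint[:, 1] - joint[:, 0]
        labels = (scores > 0).astype(int)
    elif model.family == "svm_linear":
        coef = np.asarray(model.params["coef"])
        scores = X @ coef + model.params["intercept"]
        labels = (scores > 0).astype(int)
    else:
        est = model.params["_estimator"]
        labels = est.predict(matrix)
        scores = est.decision_function(matrix)
    return labels, scores
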