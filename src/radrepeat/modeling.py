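"""Feature ranking (mRMR) and imbalance-aware ensemble classification.

Both steps are scikit-learn estimators so they compose with pipelines
and model selection:

* :class:`MRMRSelector` — greedy minimum-redundancy maximum-relevance
  ranking with the mutual-information difference (MID) criterion,
  estimating MI on features discretized into three bins at mean +/- SD.
* :class:`EasyEnsembleClassifier` — trains ``n_ensemble`` base
  classifiers, each on all minority-class samples plus a fresh
  without-replacement down-sample of the majority class of equal size,
  and predicts the mean of the member probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "MRMRSelector",
    "EasyEnsembleClassifier",
    "mrmr_rank",
    "train_easy_ensemble",
    "predict_proba",
]

CLASSIFIER_KINDS = ("logistic_regression", "svm", "random_forest", "gaussian_naive_bayes")


@dataclass
class ModelConfig:
    """Modelling settings: classifier family, top-k selection, ensemble size."""

    classifier_kind: str = "logistic_regression"
    n_selected: int = 5
    n_ensemble: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier_kind {self.classifier_kind!r}; "
                f"choose from {CLASSIFIER_KINDS}")
        if self.n_selected < 1 or self.n_ensemble < 1:
            raise ValueError("n_selected and n_ensemble must be >= 1")


def _discretize_3bin(x: np.ndarray) -> np.ndarray:
    """Three-level coding at mean +/- one SD (continuous MI surrogate)."""
    mu, sd = x.mean(), x.std()
    out = np.ones(x.shape, dtype=np.int64)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


class MRMRSelector(BaseEstimator, TransformerMixin):
    """Greedy mRMR feature ranking (MID criterion).

    The first feature maximizes relevance I(f; y); each subsequent pick
    maximizes I(f; y) - mean of I(f; s) over already-selected s.  Exact
    score ties break lexicographically on the feature name.

    Parameters
    ----------
    n_selected : number of features to rank and keep.
    criterion : "difference" (MID, default) or "quotient" (MIQ).

    Attributes
    ----------
    ranking_ : list of selected column names in pick order.
    support_ : boolean mask of selected columns.
    """

    def __init__(self, n_selected: int = 5, criterion: str = "difference"):
        self.n_selected = n_selected
        self.criterion = criterion

    def fit(self, X, y):
        if self.criterion not in ("difference", "quotient"):
            raise ValueError("criterion must be 'difference' or 'quotient'")
        names = (list(X.columns) if isinstance(X, pd.DataFrame)
                 else [f"x{i}" for i in range(np.asarray(X).shape[1])])
        Xa = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.n_selected > Xa.shape[1]:
            raise ValueError(
                f"n_selected={self.n_selected} exceeds {Xa.shape[1]} candidates")
        disc = np.column_stack([_discretize_3bin(Xa[:, j]) for j in range(Xa.shape[1])])
        relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(Xa.shape[1])])

        selected: list[int] = []
        remaining = list(range(Xa.shape[1]))
        redundancy_sum = np.zeros(Xa.shape[1])
        while len(selected) < self.n_selected:
            if selected:
                red = redundancy_sum[remaining] / len(selected)
                if self.criterion == "difference":
                    scores = relevance[remaining] - red
                else:
                    scores = relevance[remaining] / (red + np.spacing(1.0))
            else:
                scores = relevance[remaining]
            order = sorted(range(len(remaining)),
                           key=lambda t: (-scores[t], names[remaining[t]]))
            pick = remaining[order[0]]
            selected.append(pick)
            remaining.remove(pick)
            for j in remaining:
                redundancy_sum[j] += mutual_info_score(disc[:, pick], disc[:, j])

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.ranking_ = [names[j] for j in selected]
        self.selected_indices_ = selected
        self.support_ = np.zeros(Xa.shape[1], dtype=bool)
        self.support_[selected] = True
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        if isinstance(X, pd.DataFrame):
            return X[self.ranking_]
        return np.asarray(X)[:, self.selected_indices_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


def _base_classifier(kind: str, seed: int):
    if kind == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if kind == "svm":
        # RBF kernel; Platt-scaled probabilities fitted on the member subset
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "gaussian_naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier kind {kind!r}")


class EasyEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Easy-ensemble classifier over majority-class down-samples.

    Every member sees all minority-class samples plus an independent
    without-replacement draw of the majority class of the same size, on
    features standardized with training-set statistics.  The predicted
    probability is the arithmetic mean over members.

    Parameters
    ----------
    classifier_kind : one of logistic_regression, svm, random_forest,
        gaussian_naive_bayes.
    n_ensemble : number of down-sampling rounds / members.
    random_state : seed controlling all down-sampling and member seeds.
    """

    def __init__(self, classifier_kind: str = "logistic_regression",
                 n_ensemble: int = 500, random_state: int | None = None):
        self.classifier_kind = classifier_kind
        self.n_ensemble = n_ensemble
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("EasyEnsembleClassifier requires exactly two classes")
        if counts.min() < 2:
            raise ValueError("minority class needs at least 2 samples")
        self.classes_ = classes
        min_idx = int(np.argmin(counts))  # ties -> first class is "minority"
        minority = classes[min_idx]
        majority = classes[1 - min_idx]
        idx_min = np.flatnonzero(y == minority)
        idx_maj = np.flatnonzero(y == majority)

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for _ in range(self.n_ensemble):
            seed = int(rng.integers(2**31 - 1))
            take = rng.choice(idx_maj, size=len(idx_min), replace=False)
            rows = np.concatenate([idx_min, take])
            member = _base_classifier(self.classifier_kind, seed)
            member.fit(Xs[rows], y[rows])
            self.estimators_.append(member)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "estimators_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=np.float64))
        acc = np.zeros((Xs.shape[0], 2))
        for member in self.estimators_:
            proba = member.predict_proba(Xs)
            cols = {c: i for i, c in enumerate(member.classes_)}
            for j, c in enumerate(self.classes_):
                acc[:, j] += proba[:, cols[c]]
        return acc / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ModelBundle:
    """A trained model: ordered selected descriptors + fitted ensemble."""

    selected: list[str]
    ensemble: EasyEnsembleClassifier
    classifier_kind: str

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [d for d in self.selected if d not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor(s) in input table: {missing}")
        return self.ensemble.predict_proba(X[self.selected].to_numpy())[:, 1]


def mrmr_rank(
    features: pd.DataFrame,
    outcomes: np.ndarray,
    candidates: list[str] | None = None,
    n_select: int = 5,
) -> list[str]:
    """Rank candidate descriptors by greedy mRMR; returns pick order."""
    candidates = list(features.columns) if candidates is None else list(candidates)
    missing = [c for c in candidates if c not in features.columns]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    sel = MRMRSelector(n_selected=n_select).fit(features[candidates], np.asarray(outcomes))
    return sel.ranking_


def train_easy_ensemble(
    features: pd.DataFrame,
    outcomes: np.ndarray,
    config: ModelConfig,
    selected: list[str] | None = None,
) -> ModelBundle:
    """Fit an easy-ensemble bundle on the given (already selected) features."""
    selected = list(features.columns) if selected is None else list(selected)
    ens = EasyEnsembleClassifier(
        classifier_kind=config.classifier_kind,
        n_ensemble=config.n_ensemble,
        random_state=config.seed,
    ).fit(features[selected].to_numpy(), np.asarray(outcomes))
    return ModelBundle(selected, ens, config.classifier_kind)


def predict_proba(bundle: ModelBundle, X: pd.DataFrame) -> np.ndarray:
    """Per-subject event probability (mean of member probabilities)."""
    return bundle.predict_proba(X)
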