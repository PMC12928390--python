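"""Benchmarking harness: SMOTE, z-scoring, and tuned comparator learners.

The comparators (linear/RBF SVM, random forest, elastic-net logistic
regression) are standard algorithms delegated to scikit-learn; this
module owns the harness discipline around them:

* hyperparameters tuned by random search, scored by mean balanced
  accuracy over stratified 5-fold CV on the *training* data only;
* SMOTE, when enabled, applied inside each CV fold to the fold's
  training portion only (never before splitting), and once to the full
  training set for the final refit;
* z-score standardization constants computed on training data only and
  re-applied to any test data.

Every trained comparator exposes a continuous decision score with the
convention higher = more likely sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .core import _sensitive_mask

__all__ = [
    "ComparatorSpec",
    "TrainedComparator",
    "smote_balance",
    "zscore_fit",
    "zscore_apply",
    "tune_and_train",
    "majority_class_predictor",
]

COMPARATOR_KINDS = ("svm_linear", "svm_rbf", "random_forest", "elastic_net")


@dataclass
class ComparatorSpec:
    """Configuration of one comparator run."""

    kind: str
    n_random_draws: int = 20
    folds: int = 5
    seed: int = 0
    balance: str = "none"  # none | smote
    standardize: bool | None = None  # default: True for SVM / elastic net
    smote_k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.kind not in COMPARATOR_KINDS:
            raise ValueError(f"unknown comparator {self.kind!r}; one of {COMPARATOR_KINDS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_random_draws < 1:
            raise ValueError("n_random_draws must be >= 1")
        if self.balance not in ("none", "smote"):
            raise ValueError(f"balance must be none/smote, got {self.balance!r}")
        if self.standardize is None:
            self.standardize = self.kind in ("svm_linear", "svm_rbf", "elastic_net")


def smote_balance(X: np.ndarray, y: Sequence, k_neighbors: int = 5,
                  seed: int | np.random.Generator = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Over-sampling: upsample the minority to parity.

    Each synthetic point is x + u·(x_nn − x) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors (Euclidean) chosen
    uniformly.  The effective neighbor count is min(k, minority − 1).
    X is samples × features; returns the augmented matrix and boolean
    labels (True = original minority... True = sensitive).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    sens = _sensitive_mask(y)
    n_pos, n_neg = int(sens.sum()), int((~sens).sum())
    minority_is_sens = n_pos <= n_neg
    minority = X[sens] if minority_is_sens else X[~sens]
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min < 2:
        raise ValueError(f"minority class has {n_min} sample(s); SMOTE needs >= 2")
    n_new = n_maj - n_min
    if n_new == 0:
        return X.copy(), sens.copy()
    k_eff = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_eff, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    neigh = minority[idx[base, pick + 1]]
    synthetic = minority[base] + u[:, None] * (neigh - minority[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([sens, np.full(n_new, minority_is_sens)])
    return X_out, y_out


def zscore_fit(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean, sample sd) from training data; zero sds recorded as-is."""
    train = np.asarray(train, dtype=float)
    ddof = 1 if train.shape[0] > 1 else 0
    return train.mean(axis=0), train.std(axis=0, ddof=ddof)


def zscore_apply(constants: tuple[np.ndarray, np.ndarray], data: np.ndarray) -> np.ndarray:
    """Standardize with train constants; zero-sd features map to 0."""
    mean, sd = constants
    data = np.asarray(data, dtype=float)
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (data - mean) / safe_sd
    out[:, sd == 0] = 0.0
    return out


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "svm_linear":
        return SVC(kernel="linear", C=params["cost"], random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", C=params["cost"], gamma=params["gamma"], random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=500, max_features=params["max_features"], random_state=seed
        )
    if kind == "elastic_net":
        return LogisticRegression(
            solver="saga", l1_ratio=params["mixing"],
            C=1.0 / params["penalty"], max_iter=2000, random_state=seed,
        )
    raise ValueError(kind)


def _draw_params(kind: str, rng: np.random.Generator, n_features: int) -> dict:
    loguni = lambda lo, hi: float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    if kind == "svm_linear":
        return {"cost": loguni(1e-3, 1e3)}
    if kind == "svm_rbf":
        return {"cost": loguni(1e-3, 1e3), "gamma": loguni(1e-5, 1e1)}
    if kind == "random_forest":
        hi = max(1, int(round(2 * np.sqrt(n_features))))
        return {"max_features": int(rng.integers(1, min(hi, n_features) + 1))}
    if kind == "elastic_net":
        return {"mixing": float(rng.uniform(0.0, 1.0)), "penalty": loguni(1e-4, 1e1)}
    raise ValueError(kind)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    sens_mask = y_true
    tp = np.sum(y_pred & sens_mask)
    tn = np.sum(~y_pred & ~sens_mask)
    sensitivity = tp / sens_mask.sum() if sens_mask.sum() else np.nan
    specificity = tn / (~sens_mask).sum() if (~sens_mask).sum() else np.nan
    return float((sensitivity + specificity) / 2.0)


@dataclass
class TrainedComparator:
    """A refit comparator plus everything needed to apply it to new samples."""

    kind: str
    estimator: object
    chosen_params: dict
    cv_score: float
    standardize_constants: tuple[np.ndarray, np.ndarray] | None
    spec: ComparatorSpec

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize_constants is not None:
            X = zscore_apply(self.standardize_constants, X)
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Boolean predictions, True = sensitive."""
        return self.estimator.predict(self._prep(X)).astype(bool)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous scores, higher = sensitive."""
        Xp = self._prep(X)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(Xp), dtype=float)
        proba = self.estimator.predict_proba(Xp)
        pos = list(self.estimator.classes_).index(True)
        return np.asarray(proba[:, pos], dtype=float)


def tune_and_train(spec: ComparatorSpec, X: np.ndarray, y: Sequence) -> TrainedComparator:
    """Random-search tuning under stratified CV, then refit on all training data.

    X is samples × features.  A pure function of (training data, spec):
    no test information enters tuning, standardization or SMOTE.
    """
    X = np.asarray(X, dtype=float)
    sens = _sensitive_mask(y)
    if sens.all() or not sens.any():
        raise ValueError("both classes must be present in the training labels")
    n_min = min(int(sens.sum()), int((~sens).sum()))
    if n_min < spec.folds:
        raise ValueError(
            f"minority class ({n_min}) smaller than fold count ({spec.folds}); "
            "stratified folds would lose a class"
        )
    rng = np.random.default_rng(spec.seed)
    draws = [_draw_params(spec.kind, rng, X.shape[1]) for _ in range(spec.n_random_draws)]
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(X, sens))

    best_idx, best_score = 0, -np.inf
    for i, params in enumerate(draws):
        fold_scores = []
        for f, (tr, te) in enumerate(splits):
            X_tr, y_tr = X[tr], sens[tr]
            if spec.balance == "smote":
                X_tr, y_tr = smote_balance(
                    X_tr, y_tr, k_neighbors=spec.smote_k_neighbors,
                    seed=np.random.default_rng([spec.seed, i, f]),
                )
            if spec.standardize:
                consts = zscore_fit(X_tr)
                X_fit = zscore_apply(consts, X_tr)
                X_eval = zscore_apply(consts, X[te])
            else:
                X_fit, X_eval = X_tr, X[te]
            est = _make_estimator(spec.kind, params, spec.seed)
            est.fit(X_fit, y_tr)
            fold_scores.append(_balanced_accuracy(sens[te], est.predict(X_eval).astype(bool)))
        score = float(np.mean(fold_scores))
        if score > best_score:
            best_idx, best_score = i, score

    params = draws[best_idx]
    X_full, y_full = X, sens
    if spec.balance == "smote":
        X_full, y_full = smote_balance(
            X_full, y_full, k_neighbors=spec.smote_k_neighbors,
            seed=np.random.default_rng([spec.seed, spec.n_random_draws]),
        )
    consts = None
    if spec.standardize:
        consts = zscore_fit(X_full)
        X_full = zscore_apply(consts, X_full)
    est = _make_estimator(spec.kind, params, spec.seed)
    est.fit(X_full, y_full)
    return TrainedComparator(spec.kind, est, params, best_score, consts, spec)


class majority_class_predictor:
    """Baseline that always predicts the majority training class.

    Its balanced accuracy is exactly 0.5 whenever both classes occur in
    the test set (sensitivity 0 or specificity 0, the other 1).
    """

    def __init__(self, y_train: Sequence):
        sens = _sensitive_mask(y_train)
        self.majority_sensitive = bool(sens.sum() > (~sens).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = np.asarray(X).shape[0]
        return np.full(n, self.majority_sensitive)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        n = np.asarray(X).shape[0]
        return np.full(n, 0.5)
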