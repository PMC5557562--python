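"""RBF-kernel C-SVC training, grid search, and persistence.

Training delegates to the libsvm solver (scikit-learn's ``SVC``); the fitted
machine is stored as explicit support data (scaled support vectors, dual
coefficients, intercept) so that decision values can be recomputed exactly,
including after a JSON round trip. Features are min-max scaled to [0, 1]
with bounds learned on the training set, the standard libsvm preprocessing.
Hyperparameters (C, gamma) are chosen by exhaustive grid search maximizing
mean out-of-fold ROC-AUC under stratified, seeded 10-fold cross-validation;
ties prefer the smaller C, then the smaller gamma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C_GRID = [2.0**e for e in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]


@dataclass
class SVMConfig:
    """Hyperparameters and search grid for the RBF C-SVC."""

    C: float = 1.0
    gamma: float = 0.125
    grid_C: List[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    grid_gamma: List[float] = field(
        default_factory=lambda: list(DEFAULT_GAMMA_GRID)
    )
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def rbf_kernel(
    x1: Sequence[float], x2: Sequence[float], gamma: float
) -> float:
    """K(x1, x2) = exp(-gamma * ||x1 - x2||^2)."""
    a, b = np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal dimension")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((a - b) ** 2)))


@dataclass
class MinMaxScaler:
    """Per-feature min-max map to [0, 1] with training-set bounds.

    Constant features map to 0; prediction-time data is transformed with the
    stored bounds without clipping.
    """

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        return cls(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span == 0, 1.0, span)
        return (X - self.lo) / span


@dataclass
class TrainedModel:
    """A fitted RBF C-SVC plus everything needed to apply it.

    Decision values are computed from the stored support data as
    ``sum_i alpha_i K(sv_i, x) + b`` in the scaled feature space; scores
    above ``decision_threshold`` (default 0) classify as methylated.
    """

    C: float
    gamma: float
    feature_names: List[str]
    scaler: MinMaxScaler
    support_vectors: np.ndarray  # scaled space, shape (n_sv, n_features)
    dual_coef: np.ndarray  # shape (n_sv,), sign-carrying alphas
    intercept: float
    decision_threshold: float = 0.0
    metadata: Dict = field(default_factory=dict)

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "C": self.C,
            "gamma": self.gamma,
            "feature_names": self.feature_names,
            "scaler_lo": self.scaler.lo.tolist(),
            "scaler_hi": self.scaler.hi.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "decision_threshold": self.decision_threshold,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "TrainedModel":
        return cls(
            C=d["C"],
            gamma=d["gamma"],
            feature_names=list(d["feature_names"]),
            scaler=MinMaxScaler(
                np.array(d["scaler_lo"]), np.array(d["scaler_hi"])
            ),
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            intercept=d["intercept"],
            decision_threshold=d.get("decision_threshold", 0.0),
            metadata=d.get("metadata", {}),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_matrix(
    X: Union[pd.DataFrame, np.ndarray], feature_names: Optional[List[str]]
) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing}")
            X = X[feature_names]
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    return X, names


def train_svm(
    X: Union[pd.DataFrame, np.ndarray],
    labels: Sequence[int],
    config: SVMConfig,
    feature_names: Optional[List[str]] = None,
    metadata: Optional[Dict] = None,
) -> TrainedModel:
    """Fit the soft-margin RBF C-SVC at ``config.C``/``config.gamma``.

    Labels are 0/1 with 1 = methylated; both classes must be present.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    Xm, names = _as_matrix(X, feature_names)
    scaler = MinMaxScaler.fit(Xm)
    Xs = scaler.transform(Xm)
    svc = SVC(kernel="rbf", C=config.C, gamma=config.gamma, tol=1e-6)
    svc.fit(Xs, y)
    # libsvm orients the decision function toward classes_[1]; with 0/1
    # labels that is the positive class already.
    sign = 1.0 if svc.classes_[1] == 1 else -1.0
    return TrainedModel(
        C=config.C,
        gamma=config.gamma,
        feature_names=names,
        scaler=scaler,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=sign * svc.dual_coef_[0].copy(),
        intercept=sign * float(svc.intercept_[0]),
        metadata=metadata or {},
    )


def decision_values(
    model: TrainedModel, X: Union[pd.DataFrame, np.ndarray]
) -> np.ndarray:
    """Raw SVM decision scores, one per row; positive above the threshold."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing={missing}, extra={extra}"
            )
        X = X[model.feature_names]
    Xs = model.scaler.transform(np.asarray(X, dtype=float))
    sq = (
        (Xs**2).sum(axis=1)[:, None]
        - 2.0 * Xs @ model.support_vectors.T
        + (model.support_vectors**2).sum(axis=1)[None, :]
    )
    K = np.exp(-model.gamma * np.maximum(sq, 0.0))
    return K @ model.dual_coef + model.intercept


def predict_labels(
    model: TrainedModel, X: Union[pd.DataFrame, np.ndarray]
) -> np.ndarray:
    """0/1 labels at the model's decision threshold."""
    return (decision_values(model, X) > model.decision_threshold).astype(int)


def grid_search_cv(
    X: Union[pd.DataFrame, np.ndarray],
    labels: Sequence[int],
    config: SVMConfig,
) -> Tuple[float, float, float, pd.DataFrame]:
    """Exhaustive (C, gamma) grid search by mean out-of-fold ROC-AUC.

    Folds are stratified and shuffled under ``config.seed`` and shared by
    every grid point. Returns ``(best_C, best_gamma, best_auc, table)``
    where ``table`` holds the mean CV AUC of every grid point; ties prefer
    smaller C, then smaller gamma.
    """
    y = np.asarray(labels)
    Xm, _ = _as_matrix(X, None)
    if y.size < config.folds:
        raise ValueError("fewer samples than folds")
    if not config.grid_C or not config.grid_gamma:
        raise ValueError("empty grid")
    skf = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(Xm, y))
    rows = []
    for C in config.grid_C:
        for gamma in config.grid_gamma:
            aucs = []
            for tr, te in folds:
                scaler = MinMaxScaler.fit(Xm[tr])
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit(scaler.transform(Xm[tr]), y[tr])
                scores = svc.decision_function(scaler.transform(Xm[te]))
                if svc.classes_[1] != 1:
                    scores = -scores
                aucs.append(roc_auc_score(y[te], scores))
            rows.append((C, gamma, float(np.mean(aucs))))
    table = pd.DataFrame(rows, columns=["C", "gamma", "cv_auc"])
    # ties: smaller C, then smaller gamma (grid is enumerated in that order)
    best = table.iloc[int(np.argmax(table["cv_auc"].to_numpy()))]
    return float(best["C"]), float(best["gamma"]), float(best["cv_auc"]), table
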