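"""Stacked-generalization multiclass ensemble.

Three base learners — a random forest, gradient-boosted trees and an
L1-regularized multinomial linear model — are fitted with out-of-fold
(OOF) prediction over spatially blocked folds; a multinomial logistic
meta-learner is trained on the concatenated 3K OOF class probabilities.
Pixel-level prediction reports the meta probabilities plus, per class, the
sample standard deviation of the three base learners' probabilities as an
uncertainty layer.

Default hyperparameters are the package's tuned configuration: RF 452
trees / min node size 9 / mtry 10; GBT 20 rounds, depth 5, learning rate
0.5, minimum loss reduction 10, subsample 1, column subsample 0.5; lasso
lambda 1.1e-5 (glmnet parameterization, mapped to scikit-learn's C as
1/(n*lambda)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .maps import ProbabilityCube
from .synthetic import CovariateStack

__all__ = [
    "HyperParams",
    "OOFMatrix",
    "StackedModel",
    "LEARNER_NAMES",
    "fit_base_learners",
    "fit_meta_learner",
    "fit_stacked_model",
    "predict_probabilities",
    "consensus_importance",
]

LEARNER_NAMES = ("rf", "gbt", "glm")


@dataclass(frozen=True)
class HyperParams:
    """Tuned ensemble configuration (see module docstring)."""

    rf_trees: int = 452
    rf_min_node: int = 9
    rf_mtry: int = 10
    gbt_rounds: int = 20
    gbt_max_depth: int = 5
    gbt_learning_rate: float = 0.5
    gbt_min_loss_reduction: float = 10.0
    gbt_subsample: float = 1.0
    gbt_colsample: float = 0.5
    glm_lambda: float = 1.1e-5

    def __post_init__(self) -> None:
        counts = (self.rf_trees, self.rf_min_node, self.rf_mtry,
                  self.gbt_rounds, self.gbt_max_depth)
        if any(c < 1 for c in counts):
            raise ValueError("count hyperparameters must be >= 1")
        for frac in (self.gbt_subsample, self.gbt_colsample):
            if not (0.0 < frac <= 1.0):
                raise ValueError("subsample fractions must lie in (0, 1]")
        if self.gbt_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.glm_lambda < 0:
            raise ValueError("lambda must be non-negative")


class _BaseLearner:
    """A fitted base learner with class-aligned probability output.

    Learners are trained on whatever classes the training partition holds;
    probabilities are re-expanded to the global K-class list with zero
    columns for absent classes and renormalized.
    """

    def __init__(self, name: str, estimator):
        self.name = name
        self.est = estimator
        self.classes_: np.ndarray | None = None  # global codes seen in training

    def fit(self, X: np.ndarray, y_codes: np.ndarray) -> "_BaseLearner":
        uniq, y_local = np.unique(y_codes, return_inverse=True)
        self.classes_ = uniq
        if self.name == "gbt":
            # xgboost requires contiguous 0..m-1 labels
            self.est.fit(X, y_local)
        else:
            self.est.fit(X, y_codes)
        return self

    def predict_proba_aligned(self, X: np.ndarray, K: int) -> np.ndarray:
        P_local = self.est.predict_proba(X)
        if self.name == "gbt":
            cols = self.classes_
        else:
            cols = np.asarray(self.est.classes_ if not isinstance(self.est, Pipeline)
                              else self.est[-1].classes_, dtype=int)
        P = np.zeros((X.shape[0], K), dtype=float)
        P[:, cols] = P_local
        P /= P.sum(axis=1, keepdims=True)
        return P


def _make_learner(name: str, hp: HyperParams, n_features: int, n_train: int,
                  seed: int) -> _BaseLearner:
    if name == "rf":
        est = RandomForestClassifier(
            n_estimators=hp.rf_trees,
            min_samples_leaf=hp.rf_min_node,
            max_features=min(hp.rf_mtry, n_features),
            random_state=seed,
            n_jobs=1,
        )
    elif name == "gbt":
        est = XGBClassifier(
            n_estimators=hp.gbt_rounds,
            max_depth=hp.gbt_max_depth,
            learning_rate=hp.gbt_learning_rate,
            gamma=hp.gbt_min_loss_reduction,
            subsample=hp.gbt_subsample,
            colsample_bytree=hp.gbt_colsample,
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    elif name == "glm":
        # glmnet-style lambda (penalty per observation) -> sklearn C
        C = 1.0 / (n_train * hp.glm_lambda) if hp.glm_lambda > 0 else 1e9
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "logit",
                    LogisticRegression(
                        l1_ratio=1.0,
                        C=C,
                        solver="saga",
                        max_iter=3000,
                        tol=1e-4,
                        random_state=seed,
                    ),
                ),
            ]
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown learner {name!r}")
    return _BaseLearner(name, est)


@dataclass
class OOFMatrix:
    """Out-of-fold class probabilities: per learner an (n, K) block."""

    probs: dict[str, np.ndarray]
    fold: np.ndarray
    class_list: list
    learner_names: tuple[str, ...] = LEARNER_NAMES

    def stacked(self) -> np.ndarray:
        """Concatenated (n, 3K) meta-feature matrix."""
        return np.hstack([self.probs[name] for name in self.learner_names])

    def __len__(self) -> int:
        return len(self.fold)


@dataclass
class StackedModel:
    """Fitted stack: three base learners + multinomial meta-learner."""

    class_list: list
    learners: dict[str, _BaseLearner]
    meta: LogisticRegression
    feature_names: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.class_list)

    def base_probabilities(self, X: np.ndarray) -> dict[str, np.ndarray]:
        return {
            name: self.learners[name].predict_proba_aligned(X, self.K)
            for name in LEARNER_NAMES
        }

    def meta_probabilities(self, stacked: np.ndarray) -> np.ndarray:
        P_local = self.meta.predict_proba(stacked)
        cols = np.asarray(self.meta.classes_, dtype=int)
        P = np.zeros((stacked.shape[0], self.K), dtype=float)
        P[:, cols] = P_local
        P /= P.sum(axis=1, keepdims=True)
        return P

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        base = self.base_probabilities(X)
        stacked = np.hstack([base[name] for name in LEARNER_NAMES])
        return self.meta_probabilities(stacked)

    def save(self, path) -> None:
        """Serialize the fitted stack to a single archive file; the
        feature-name manifest and a format version travel with it."""
        joblib.dump(
            {
                "format_version": 1,
                "class_list": self.class_list,
                "feature_names": self.feature_names,
                "learners": self.learners,
                "meta": self.meta,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "StackedModel":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != 1:
            raise ValueError(f"unsupported model archive version: {version!r}")
        return cls(
            class_list=payload["class_list"],
            learners=payload["learners"],
            meta=payload["meta"],
            feature_names=payload["feature_names"],
        )


def _as_fold_array(folds) -> np.ndarray:
    fold = getattr(folds, "fold", folds)
    return np.asarray(fold, dtype=int)


def fit_base_learners(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    hp: HyperParams | None = None,
    seed: int = 0,
    n_classes: int | None = None,
):
    """Fit the three base learners with out-of-fold prediction.

    For every fold f each learner is trained on the points *not* in f and
    predicts class probabilities for the points in f; afterwards each
    learner is refitted on all points for deployment. ``y`` must hold
    integer class codes 0..K-1 (use ObservationTable.label_codes()).

    Returns (OOFMatrix, {"rf": ..., "gbt": ..., "glm": ...}).
    """
    hp = hp or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    fold = _as_fold_array(folds)
    if not (len(X) == len(y) == len(fold)):
        raise ValueError("X, y and folds must align row-wise")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the feature matrix")
    K = n_classes if n_classes is not None else int(y.max()) + 1
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")

    n = len(y)
    oof = {name: np.full((n, K), np.nan) for name in LEARNER_NAMES}
    for f in np.unique(fold):
        tr = fold != f
        te = ~tr
        if np.unique(y[tr]).size < 2:
            raise ValueError(
                f"training partition for fold {f} contains a single class"
            )
        for name in LEARNER_NAMES:
            learner = _make_learner(name, hp, X.shape[1], int(tr.sum()), seed)
            learner.fit(X[tr], y[tr])
            oof[name][te] = learner.predict_proba_aligned(X[te], K)

    learners = {}
    for name in LEARNER_NAMES:
        learner = _make_learner(name, hp, X.shape[1], n, seed)
        learners[name] = learner.fit(X, y)

    matrix = OOFMatrix(probs=oof, fold=fold, class_list=list(range(K)))
    return matrix, learners


def fit_meta_learner(
    oof: OOFMatrix,
    y: np.ndarray,
    learners: dict[str, _BaseLearner] | None = None,
    class_list: list | None = None,
    feature_names: list[str] | None = None,
) -> StackedModel:
    """Train the multinomial logistic meta-learner on stacked OOF features.

    The meta-learner minimizes multinomial deviance over the 3K stacked
    probability columns; a small L2 ridge keeps the optimum finite when the
    stacked features are separable.
    """
    Z = oof.stacked()
    if np.isnan(Z).any():
        raise ValueError("OOF matrix is incomplete (missing rows)")
    if np.any(Z.std(axis=0) == 0.0):
        warnings.warn("constant stacked features in the OOF matrix", stacklevel=2)
    y = np.asarray(y, dtype=int)
    meta = LogisticRegression(C=100.0, solver="lbfgs", max_iter=2000)
    meta.fit(Z, y)
    K = len(oof.class_list)
    return StackedModel(
        class_list=list(class_list) if class_list is not None else list(range(K)),
        learners=learners or {},
        meta=meta,
        feature_names=list(feature_names) if feature_names else [],
    )


def fit_stacked_model(
    X: np.ndarray,
    y: np.ndarray,
    folds,
    hp: HyperParams | None = None,
    feature_names: list[str] | None = None,
    class_list: list | None = None,
    seed: int = 0,
) -> StackedModel:
    """Full stacking fit: OOF base learners, meta-learner, deployment refit."""
    n_classes = len(class_list) if class_list is not None else None
    oof, learners = fit_base_learners(X, y, folds, hp=hp, seed=seed,
                                      n_classes=n_classes)
    return fit_meta_learner(oof, y, learners=learners, class_list=class_list,
                            feature_names=feature_names)


def predict_probabilities(model: StackedModel, stack: CovariateStack):
    """Predict the per-pixel probability cube plus base-learner-spread SD.

    Returns (ProbabilityCube in percent, sd) where ``sd`` is a (K, H, W)
    array: per class the sample standard deviation (n = 3, ddof = 1) of the
    three base learners' probabilities, in percent. Masked pixels are NaN
    in every output.
    """
    if not model.feature_names:
        raise ValueError("model carries no feature-name manifest")
    X, flat_idx = stack.feature_matrix(model.feature_names)
    base = model.base_probabilities(X)
    stacked = np.hstack([base[name] for name in LEARNER_NAMES])
    P = model.meta_probabilities(stacked)

    H, W = stack.grid.shape
    K = model.K
    values = np.full((K, H, W), np.nan)
    sd = np.full((K, H, W), np.nan)
    rows, cols = np.unravel_index(flat_idx, (H, W))
    base_arr = np.stack([base[name] for name in LEARNER_NAMES])  # (3, n, K)
    sd_flat = base_arr.std(axis=0, ddof=1) * 100.0
    for k in range(K):
        values[k, rows, cols] = P[:, k] * 100.0
        sd[k, rows, cols] = sd_flat[:, k]
    cube = ProbabilityCube(
        grid=stack.grid, class_list=list(model.class_list), values=values,
        mask=stack.mask.copy(),
    )
    return cube, sd


def _importance_ranks(model: StackedModel) -> dict[str, np.ndarray]:
    """Per learner: descending-importance feature scores."""
    p = len(model.feature_names)
    scores: dict[str, np.ndarray] = {}

    rf = model.learners["rf"].est
    scores["rf"] = np.asarray(rf.feature_importances_, dtype=float)

    booster = model.learners["gbt"].est.get_booster()
    gain = booster.get_score(importance_type="total_gain")
    g = np.zeros(p)
    for key, val in gain.items():
        g[int(key[1:])] = val
    scores["gbt"] = g

    logit = model.learners["glm"].est[-1]
    scores["glm"] = np.max(np.abs(logit.coef_), axis=0)
    return scores


def consensus_importance(model: StackedModel, top_k: int = 20) -> list[str]:
    """Features in every learner's top-k importance list.

    Importance is impurity importance for RF, total gain for GBT and the
    largest absolute class coefficient for the linear model; the
    intersection of the three top-k sets is returned ordered by mean rank.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not model.feature_names:
        raise ValueError("model carries no feature-name manifest")
    scores = _importance_ranks(model)
    p = len(model.feature_names)
    ranks = {}
    top_sets = []
    for name, s in scores.items():
        order = np.argsort(-s, kind="stable")
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(p)
        ranks[name] = rank
        top_sets.append(set(order[: min(top_k, p)]))
    common = set.intersection(*top_sets)
    mean_rank = {i: np.mean([ranks[n][i] for n in scores]) for i in common}
    ordered = sorted(common, key=lambda i: (mean_rank[i], i))
    return [model.feature_names[i] for i in ordered]
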