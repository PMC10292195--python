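"""Performance metrics and the repeated spatially blocked CV harness.

Metrics follow the logloss-skill framing: alongside overall accuracy the
harness reports the mean multiclass logloss (natural log, nats per
observation) and its skill score

    R2_logloss = 1 - LL(model) / LL(baseline)

against the constant class-prevalence predictor of the corresponding
training partition (1 = perfect, 0 = no better than prevalence, negative =
worse). Per-class scores use the one-vs-rest binary logloss of the class
probability against the class indicator with the class's training
prevalence as baseline, plus the true positive rate and F1.

The harness applies base learners AND meta-learner strictly out-of-fold:
for each outer fold the meta-learner is trained on the inner OOF matrix of
the training partition only (nested application), so no point's stacked
prediction ever saw its own fold's labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocking import BlockAssignment, make_spatial_folds
from .ensemble import (
    LEARNER_NAMES,
    HyperParams,
    fit_base_learners,
    fit_meta_learner,
)

__all__ = [
    "MetricsReport",
    "multiclass_logloss",
    "r2_logloss",
    "per_class_tpr_f1",
    "run_spatial_cv",
]

_EPS = 1e-15


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def multiclass_logloss(y: np.ndarray, P: np.ndarray) -> float:
    """Mean -log p(true class) in nats, probabilities clipped to
    [1e-15, 1 - 1e-15]."""
    y = np.asarray(y, dtype=int)
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or len(y) != P.shape[0]:
        raise ValueError("y and P shapes do not match")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    return float(-np.mean(np.log(_clip(P[np.arange(len(y)), y]))))


def r2_logloss(
    y: np.ndarray,
    P: np.ndarray,
    baseline_prevalence: np.ndarray,
) -> float:
    """Logloss skill against a constant prevalence predictor.

    ``baseline_prevalence`` may be a K-vector (one constant predictor) or an
    (n, K) matrix giving each observation its own baseline row (used when
    different CV partitions supply different prevalences).
    """
    y = np.asarray(y, dtype=int)
    P = np.asarray(P, dtype=float)
    B = np.asarray(baseline_prevalence, dtype=float)
    if B.ndim == 1:
        B = np.broadcast_to(B, P.shape)
    ll_model = multiclass_logloss(y, P)
    # lower clip only: a baseline putting mass 1 on every true label must
    # yield logloss exactly 0 so the degenerate case is detectable
    ll_base = float(-np.mean(np.log(np.clip(B[np.arange(len(y)), y], _EPS, None))))
    if ll_base == 0.0:
        raise ZeroDivisionError("degenerate single-class truth: baseline logloss is 0")
    return 1.0 - ll_model / ll_base


def _binary_logloss(indicator: np.ndarray, p: np.ndarray) -> float:
    p = _clip(np.asarray(p, dtype=float))
    ind = np.asarray(indicator, dtype=float)
    return float(-np.mean(ind * np.log(p) + (1 - ind) * np.log(1 - p)))


def per_class_r2_logloss(
    y: np.ndarray, P: np.ndarray, baseline_prevalence: np.ndarray, k: int
) -> float:
    """One-vs-rest logloss skill for class k (baseline = its prevalence)."""
    y = np.asarray(y, dtype=int)
    B = np.asarray(baseline_prevalence, dtype=float)
    pk_base = B[k] if B.ndim == 1 else B[:, k]
    ind = (y == k).astype(float)
    ll_model = _binary_logloss(ind, P[:, k])
    base = np.clip(np.broadcast_to(pk_base, ind.shape), _EPS, 1.0 - _EPS)
    if np.all(ind == 1.0) and np.all(pk_base >= 1.0):
        raise ZeroDivisionError(f"baseline logloss for class {k} is 0")
    ll_base = _binary_logloss(ind, base)
    if ll_base == 0.0:
        raise ZeroDivisionError(f"baseline logloss for class {k} is 0")
    return 1.0 - ll_model / ll_base


def per_class_tpr_f1(
    y: np.ndarray, y_hat: np.ndarray, n_classes: int | None = None
) -> pd.DataFrame:
    """TPR and F1 per class from hard labels.

    A class never predicted gets precision 0, hence F1 = 0; a class absent
    from the truth gets TPR = 0 by the same zero-denominator convention.
    """
    y = np.asarray(y, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if len(y) != len(y_hat):
        raise ValueError("y and y_hat must have the same length")
    K = n_classes if n_classes is not None else int(max(y.max(), y_hat.max())) + 1
    rows = []
    for k in range(K):
        tp = int(np.sum((y == k) & (y_hat == k)))
        fp = int(np.sum((y != k) & (y_hat == k)))
        fn = int(np.sum((y == k) & (y_hat != k)))
        tpr = tp / (tp + fn) if (tp + fn) else 0.0
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = 2 * prec * tpr / (prec + tpr) if (prec + tpr) else 0.0
        rows.append({"class": k, "n_obs": tp + fn, "tpr": tpr, "f1": f1})
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Repeated-CV performance summary.

    ``per_repeat`` holds one row per repeat (accuracy, logloss,
    r2_logloss); ``class_table`` mirrors the per-class report (n_obs, TPR,
    F1, R2_logloss averaged over repeats); ``summary`` holds mean and SD of
    the overall metrics across repeats.
    """

    per_repeat: pd.DataFrame
    class_table: pd.DataFrame
    summary: dict
    class_list: list

    def to_json_dict(self) -> dict:
        return {
            "summary": self.summary,
            "per_repeat": self.per_repeat.to_dict(orient="records"),
            "class_table": self.class_table.to_dict(orient="records"),
        }


def _stacked_oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    fold: np.ndarray,
    hp: HyperParams,
    K: int,
    seed: int,
):
    """Fully out-of-fold stacked predictions plus per-point baseline rows."""
    n = len(y)
    P = np.full((n, K), np.nan)
    B = np.full((n, K), np.nan)
    for f in np.unique(fold):
        tr = fold != f
        te = ~tr
        oof_tr, learners = fit_base_learners(
            X[tr], y[tr], fold[tr], hp=hp, seed=seed, n_classes=K
        )
        meta = fit_meta_learner(oof_tr, y[tr], learners=learners,
                                class_list=list(range(K)))
        P[te] = meta.predict_proba(X[te])
        prev = np.bincount(y[tr], minlength=K) / tr.sum()
        B[te] = prev
    return P, B


def run_spatial_cv(
    X: np.ndarray,
    y: np.ndarray,
    blocks: BlockAssignment,
    k: int = 5,
    repeats: int = 5,
    hp: HyperParams | None = None,
    seed: int = 0,
    class_list: list | None = None,
) -> MetricsReport:
    """k-fold spatially blocked CV of the stacked ensemble, repeated.

    For every repeat a fresh block-level fold assignment is drawn and the
    whole stack (base learners and meta-learner) is evaluated out-of-fold;
    overall and per-class metrics are reported per repeat and summarized as
    mean +/- SD across repeats.
    """
    hp = hp or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    K = len(class_list) if class_list is not None else int(y.max()) + 1
    names = list(class_list) if class_list is not None else list(range(K))

    repeat_rows = []
    class_rows = []
    for r in range(1, repeats + 1):
        folds = make_spatial_folds(blocks, k=k, repeat_index=r, seed=seed)
        learner_seed = (seed + 7919 * r) % (2**31)
        P, B = _stacked_oof_predictions(X, y, folds.fold, hp, K, learner_seed)
        y_hat = np.argmax(P, axis=1)
        acc = float(np.mean(y_hat == y))
        ll = multiclass_logloss(y, P)
        r2 = r2_logloss(y, P, B)
        repeat_rows.append(
            {"repeat": r, "accuracy": acc, "logloss": ll, "r2_logloss": r2}
        )
        tab = per_class_tpr_f1(y, y_hat, n_classes=K)
        tab["r2_logloss"] = [
            per_class_r2_logloss(y, P, B, kk) for kk in range(K)
        ]
        tab["repeat"] = r
        class_rows.append(tab)

    per_repeat = pd.DataFrame(repeat_rows)
    all_classes = pd.concat(class_rows, ignore_index=True)
    class_table = (
        all_classes.groupby("class", as_index=False)
        .agg(
            n_obs=("n_obs", "first"),
            tpr=("tpr", "mean"),
            f1=("f1", "mean"),
            r2_logloss=("r2_logloss", "mean"),
        )
    )
    class_table["class"] = [names[i] for i in class_table["class"]]
    summary = {}
    for col in ("accuracy", "logloss", "r2_logloss"):
        summary[f"{col}_mean"] = float(per_repeat[col].mean())
        summary[f"{col}_sd"] = float(per_repeat[col].std(ddof=1)) if repeats > 1 else 0.0
    return MetricsReport(
        per_repeat=per_repeat,
        class_table=class_table,
        summary=summary,
        class_list=names,
    )
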