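"""Classifier training, cross-validated model selection and SNP importances.

Three model families rank markers by their contribution to case/control
prediction:

* **logreg** — L2-penalized logistic regression; importance of marker ``j``
  is the coefficient magnitude ``|theta_j|``.
* **gbdt** — gradient-boosted decision trees (xgboost backend); importance is
  the average information gain over all tree splits using the feature
  ("average gain").
* **tabnet** — the sparse-attention network of :mod:`paretognome.tabnet`;
  importance is the cumulative sparsemax mask summed over decision steps,
  averaged over samples and normalized.

Hyperparameters are chosen by exhaustive grid search with seeded stratified
k-fold cross-validation, maximizing the mean F1 of the *control* class —
under heavy case enrichment the case-class metrics are uninformative, so
model selection tracks the minority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .io import EncodedDesign
from .tabnet import TabNetClassifier

__all__ = [
    "TrainingConfig",
    "CVReport",
    "make_model",
    "stratified_folds",
    "cv_report",
    "grid_search_cv",
    "train_model",
    "extract_importance",
    "entropy_information_gain",
    "DEFAULT_GRIDS",
]

MODEL_KINDS = ("logreg", "gbdt", "tabnet")

DEFAULT_GRIDS = {
    "logreg": {"C": [0.01, 0.1, 1.0], "class_weight": [None, "balanced"]},
    "gbdt": {
        "n_estimators": [100, 200],
        "max_depth": [3, 6],
        "learning_rate": [0.1, 0.3],
    },
    "tabnet": {"n_steps": [2, 3], "lambda_sparse": [1e-4, 1e-3]},
}


class DegenerateFoldError(ValueError):
    """A CV fold contained a single class."""


@dataclass
class TrainingConfig:
    """Grid-search setup for one model family."""

    model_kind: str
    grid: dict = None
    folds: int = 5
    seed: int = 0
    encoding: str = "additive"

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model_kind].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def grid_points(self):
        names = list(self.grid)
        for combo in product(*(self.grid[n] for n in names)):
            yield dict(zip(names, combo))


@dataclass
class CVReport:
    """Per-class CV metrics, mean +/- SD over folds (Table-style layout)."""

    accuracy: tuple
    control_precision: tuple
    control_recall: tuple
    control_f1: tuple
    case_precision: tuple
    case_recall: tuple
    case_f1: tuple
    per_fold: pd.DataFrame = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        """One-row frame: accuracy, then control P/R/F1, then case P/R/F1."""
        cols = [
            "accuracy",
            "control_precision", "control_recall", "control_f1",
            "case_precision", "case_recall", "case_f1",
        ]
        data = {c: [f"{getattr(self, c)[0]:.2f} ± {getattr(self, c)[1]:.2f}"] for c in cols}
        return pd.DataFrame(data)


def make_model(model_kind: str, params: dict, seed: int = 0):
    """Instantiate an unfitted estimator of the requested family."""
    params = dict(params)
    if model_kind == "logreg":
        params.setdefault("C", 1.0)
        params.setdefault("solver", "liblinear")
        params.setdefault("max_iter", 1000)
        # default penalty is L2; strength comes through C
        return LogisticRegression(random_state=seed, **params)
    if model_kind == "gbdt":
        from xgboost import XGBClassifier

        params.setdefault("n_estimators", 100)
        params.setdefault("max_depth", 3)
        return XGBClassifier(
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            **params,
        )
    if model_kind == "tabnet":
        return TabNetClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model kind {model_kind!r}")


def stratified_folds(y: np.ndarray, folds: int = 5, seed: int = 0):
    """Seeded stratified fold assignment; raises on degenerate folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros_like(y), y))
    for i, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DegenerateFoldError(f"fold {i} contains a single class")
    return splits


def _fold_metrics(y_true, y_pred):
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    return {
        "accuracy": float((y_true == y_pred).mean()),
        "control_precision": prec[0], "control_recall": rec[0], "control_f1": f1[0],
        "case_precision": prec[1], "case_recall": rec[1], "case_f1": f1[1],
    }


def cv_report(X, y, model_kind: str, params: dict, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold CV metrics for one hyperparameter point."""
    X = np.asarray(X)
    y = np.asarray(y)
    rows = []
    for tr, te in stratified_folds(y, folds, seed):
        model = make_model(model_kind, params, seed=seed)
        model.fit(X[tr], y[tr])
        rows.append(_fold_metrics(y[te], model.predict(X[te])))
    per_fold = pd.DataFrame(rows)
    stats = {c: (float(per_fold[c].mean()), float(per_fold[c].std(ddof=1))) for c in per_fold}
    return CVReport(per_fold=per_fold, **stats)


def _complexity(model_kind: str, params: dict) -> float:
    """Rough effective-parameter count, used only as a tie-break."""
    if model_kind == "logreg":
        return float(params.get("C", 1.0))  # larger C = weaker penalty = more effective params
    if model_kind == "gbdt":
        return params.get("n_estimators", 100) * 2.0 ** params.get("max_depth", 3)
    if model_kind == "tabnet":
        return params.get("n_steps", 3) * (params.get("n_d", 8) + params.get("n_a", 8))
    return 0.0


def grid_search_cv(X, y, config: TrainingConfig):
    """Evaluate every grid point; the winner maximizes mean control-class F1.

    Ties break by lower effective complexity, then grid order.  Returns
    ``(best_params, CVReport of the winner, full results DataFrame)``.
    """
    rows = []
    best = None
    for order, params in enumerate(config.grid_points()):
        report = cv_report(X, y, config.model_kind, params, config.folds, config.seed)
        score = report.control_f1[0]
        key = (-score, _complexity(config.model_kind, params), order)
        rows.append({**params, "control_f1_mean": score, "control_f1_sd": report.control_f1[1]})
        if best is None or key < best[0]:
            best = (key, params, report)
    results = pd.DataFrame(rows)
    return best[1], best[2], results


def train_model(X, y, model_kind: str, params: dict, seed: int = 0):
    """Fit one model of the given family on the full data, seeded."""
    model = make_model(model_kind, params, seed=seed)
    model.fit(np.asarray(X), np.asarray(y))
    return model


# ---------------------------------------------------------------------------
# importances


def _aggregate_columns(scores: np.ndarray, design: EncodedDesign, how: str = "max") -> np.ndarray:
    """Collapse per-column scores to per-marker scores via the provenance map."""
    out = np.zeros(design.n_markers)
    reduce_at = {"max": np.fmax.at, "sum": np.add.at}[how]
    reduce_at(out, design.column_to_marker, scores)
    return out


def extract_importance(model, design: EncodedDesign, model_kind: str, aggregate: str = "max") -> np.ndarray:
    """Per-marker nonnegative importance vector for a fitted model.

    One-hot designs are collapsed to markers by ``max`` (default) or ``sum``
    over each marker's indicator columns.
    """
    if model_kind == "logreg":
        scores = np.abs(np.ravel(model.coef_))
    elif model_kind == "gbdt":
        booster = model.get_booster()
        gain = booster.get_score(importance_type="gain")
        scores = np.zeros(design.matrix.shape[1])
        for name, value in gain.items():
            scores[int(name[1:])] = value  # xgboost names features f0, f1, ...
    elif model_kind == "tabnet":
        scores = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    per_marker = _aggregate_columns(scores, design, aggregate)
    if model_kind == "tabnet":
        total = per_marker.sum()
        if total > 0:
            per_marker = per_marker / total
    return per_marker


# ---------------------------------------------------------------------------
# decision-tree split quality


def _entropy_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty node")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_information_gain(parent_counts, left_counts, right_counts) -> float:
    """Information gain (bits) of a binary split: H(parent) minus the
    child entropies weighted by their sample shares.  ``0*log(0) = 0``.
    """
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.allclose(left + right, parent):
        raise ValueError("left + right must equal parent per class")
    n = parent.sum()
    if n == 0:
        raise ValueError("empty parent node")
    ig = _entropy_bits(parent)
    for child in (left, right):
        share = child.sum() / n
        if share > 0:
            ig -= share * _entropy_bits(child)
    return float(ig)
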