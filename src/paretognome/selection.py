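"""Greedy block-wise feature selection on the chi-square ranking.

Markers are sorted by association p-value; a logistic-regression model is
fitted on the top block of 1,000 markers with stratified 5-fold CV, the next
block is appended and the model refitted, and so on until the control-class
F1 stops improving.  The whole curve is always returned so the stopping
point can be overridden by inspection.

The stopping rule (the field reports only that metrics "stabilize") is:
halt at the first step where the ``stop_window``-step moving average of mean
control-F1 (window truncated at the start of the curve) improves over the
previous step's moving average by less than ``stop_tol``; the reported stop
is then the step with the best mean control-F1 seen up to the halt, so the
selected set is never worse than the first block.  Fold assignment is seeded
once and shared across steps so the curve is smooth in the number of
markers, not in fold noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .io import EncodedDesign
from .models import _fold_metrics, make_model, stratified_folds

__all__ = ["SelectionCurve", "GreedyBlockSelector", "incremental_selection", "selected_design"]


@dataclass
class SelectionCurve:
    """Per-step CV record of the incremental selection run."""

    table: pd.DataFrame  # step, n_markers, f1_mean, f1_sd, acc_mean
    stop_index: int
    chosen_n: int

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


class GreedyBlockSelector(SelectorMixin, BaseEstimator):
    """Feature selector growing the marker set in ranked blocks.

    Parameters
    ----------
    ranked_columns : array-like of int
        Design-column order, most significant first (from the association
        ranking).  Required.
    block_size : int, default=1000
    folds : int, default=5
    stop_window : int, default=3
        Width of the moving average used by the stopping rule.
    stop_tol : float, default=0.005
        Minimum moving-average improvement in mean control-F1 to continue.
    max_blocks : int or None
        Hard cap on evaluated blocks (None = all markers).
    model_params : dict, optional
        Passed to the logistic-regression evaluator.
    random_state : int, default=0

    Attributes
    ----------
    curve_ : :class:`SelectionCurve`
    chosen_n_ : number of markers retained at the stopping point.
    support_ : boolean mask over design columns.
    """

    def __init__(
        self,
        ranked_columns=None,
        block_size: int = 1000,
        folds: int = 5,
        stop_window: int = 3,
        stop_tol: float = 0.005,
        max_blocks=None,
        model_params=None,
        random_state: int = 0,
    ):
        self.ranked_columns = ranked_columns
        self.block_size = block_size
        self.folds = folds
        self.stop_window = stop_window
        self.stop_tol = stop_tol
        self.max_blocks = max_blocks
        self.model_params = model_params
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if self.ranked_columns is None:
            raise ValueError("ranked_columns is required (association-ranked order)")
        ranked = np.asarray(self.ranked_columns, dtype=int)
        m = len(ranked)
        n_blocks = int(np.ceil(m / self.block_size))
        if self.max_blocks is not None:
            n_blocks = min(n_blocks, self.max_blocks)
        folds = stratified_folds(y, self.folds, self.random_state)
        params = dict(self.model_params or {})

        records = []
        means = []
        halt = None
        for k in range(1, n_blocks + 1):
            cols = ranked[: min(k * self.block_size, m)]
            f1s, accs = [], []
            for tr, te in folds:
                model = make_model("logreg", params, seed=self.random_state)
                model.fit(X[np.ix_(tr, cols)], y[tr])
                metrics = _fold_metrics(y[te], model.predict(X[np.ix_(te, cols)]))
                f1s.append(metrics["control_f1"])
                accs.append(metrics["accuracy"])
            records.append(
                {
                    "step": k,
                    "n_markers": len(cols),
                    "f1_mean": float(np.mean(f1s)),
                    "f1_sd": float(np.std(f1s, ddof=1)),
                    "acc_mean": float(np.mean(accs)),
                }
            )
            means.append(records[-1]["f1_mean"])
            if halt is None and k >= 2:
                # moving averages ending at this step and at the previous one,
                # each over up to stop_window steps
                recent = float(np.mean(means[max(0, k - self.stop_window) : k]))
                previous = float(np.mean(means[max(0, k - 1 - self.stop_window) : k - 1]))
                if recent - previous < self.stop_tol:
                    halt = k
                    break
        if halt is None:
            halt = records[-1]["step"]
        table = pd.DataFrame(records)
        upto = table[table["step"] <= halt]
        stop_index = int(upto.loc[upto["f1_mean"].idxmax(), "step"])  # idxmax: earliest max
        chosen_n = int(table.loc[table["step"] == stop_index, "n_markers"].iloc[0])

        self.curve_ = SelectionCurve(table, stop_index, chosen_n)
        self.chosen_n_ = chosen_n
        self.selected_columns_ = ranked[:chosen_n]
        self.n_features_in_ = X.shape[1]
        support = np.zeros(X.shape[1], dtype=bool)
        support[self.selected_columns_] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        return self.support_


def incremental_selection(
    design: EncodedDesign,
    phenotypes,
    ranked_markers,
    block_size: int = 1000,
    folds: int = 5,
    stop_window: int = 3,
    stop_tol: float = 0.005,
    max_blocks=None,
    seed: int = 0,
    model_params=None,
) -> SelectionCurve:
    """Functional wrapper over :class:`GreedyBlockSelector`.

    ``ranked_markers`` are marker ids or design-marker column indices in
    most-significant-first order.
    """
    if len(ranked_markers) and isinstance(ranked_markers[0], str):
        index = {mid: j for j, mid in enumerate(design.marker_ids)}
        ranked_cols = np.array([index[m] for m in ranked_markers], dtype=int)
    else:
        ranked_cols = np.asarray(ranked_markers, dtype=int)
    labels = phenotypes.labels if hasattr(phenotypes, "labels") else np.asarray(phenotypes)
    selector = GreedyBlockSelector(
        ranked_columns=ranked_cols,
        block_size=block_size,
        folds=folds,
        stop_window=stop_window,
        stop_tol=stop_tol,
        max_blocks=max_blocks,
        model_params=model_params,
        random_state=seed,
    )
    selector.fit(design.matrix, labels)
    return selector.curve_


def selected_design(design: EncodedDesign, curve: SelectionCurve, ranked_markers) -> EncodedDesign:
    """Design restricted to the first ``curve.chosen_n`` ranked markers."""
    if len(ranked_markers) and isinstance(ranked_markers[0], str):
        index = {mid: j for j, mid in enumerate(design.marker_ids)}
        ranked_cols = np.array([index[m] for m in ranked_markers], dtype=int)
    else:
        ranked_cols = np.asarray(ranked_markers, dtype=int)
    return design.restrict_markers(ranked_cols[: curve.chosen_n])
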