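"""Pareto-optimal consensus over multiple SNP-importance dimensions.

Each marker gets a 4-vector of importances — chi-square ``-log10 p``,
logistic-regression ``|theta|``, GBDT average gain, and cumulative attention
mass — all oriented "larger = more associated".  The consensus set is the
Pareto front under weak dominance: marker ``j`` is dominated iff some marker
is at least as good in every dimension and strictly better in one; markers
with identical score vectors are all kept.

Also builds the per-method top-K lists and the exclusive intersection
(UpSet-style) counts of the five lists (four top-K + the front).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "IMPORTANCE_DIMENSIONS",
    "assemble_importance_matrix",
    "pareto_front",
    "top_k_list",
    "consensus_report",
    "ConsensusReport",
]

IMPORTANCE_DIMENSIONS = ("chisq_neglog10p", "logreg", "gbdt", "tabnet")


def assemble_importance_matrix(
    chisq_results: pd.DataFrame,
    lr_importance: pd.Series,
    gbdt_importance: pd.Series,
    tabnet_importance: pd.Series,
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Markers x 4 importance matrix indexed by marker id.

    The chi-square dimension (``-log10 p``) covers every marker; model
    dimensions are importance Series indexed by marker id.  Markers absent
    from a model dimension (e.g. excluded by greedy selection) get 0 there
    when ``zero_fill`` is set, otherwise the mismatch is an error.
    """
    index = pd.Index(chisq_results["id"], name="marker_id")
    matrix = pd.DataFrame(index=index, columns=list(IMPORTANCE_DIMENSIONS), dtype=float)
    matrix["chisq_neglog10p"] = chisq_results["neg_log10_p"].to_numpy()
    for dim, series in (("logreg", lr_importance), ("gbdt", gbdt_importance), ("tabnet", tabnet_importance)):
        series = pd.Series(series)
        extra = series.index.difference(index)
        if len(extra):
            raise ValueError(f"{dim} importance has markers outside the tested set: {list(extra[:5])}")
        if not zero_fill and len(index.difference(series.index)):
            raise ValueError(f"{dim} importance does not cover every marker (zero_fill disabled)")
        matrix[dim] = series.reindex(index).fillna(0.0).to_numpy()
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("importance matrix contains non-finite values")
    return matrix


def pareto_front(matrix: pd.DataFrame) -> pd.DataFrame:
    """Non-dominated markers of an importance matrix (maximization).

    Weak-dominance convention: duplicated score vectors are all on the
    front.  Output rows are sorted by marker id.  Implementation sorts by
    score sum and prunes; it is exactly equivalent to all-pairs domination.
    """
    scores = matrix.to_numpy(dtype=float)
    n = scores.shape[0]
    order = np.argsort(-scores.sum(axis=1), kind="mergesort")
    s = scores[order]
    keep = np.ones(n, dtype=bool)
    front_rows: list[int] = []
    for i in range(n):
        if not keep[i]:
            continue
        # a dominator must have a score sum >= ours, so it precedes i in the
        # sorted order: compare against the accepted front only
        si = s[i]
        dominated = False
        for j in front_rows:
            sj = s[j]
            if (sj >= si).all() and (sj > si).any():
                dominated = True
                break
        if dominated:
            keep[i] = False
        else:
            front_rows.append(i)
    ids = matrix.index[order[np.array(front_rows, dtype=int)]]
    return matrix.loc[ids].sort_index()


def top_k_list(importance: pd.Series, k: int) -> tuple[list, bool]:
    """Top-k marker ids by descending score, ids ascending within ties.

    If a tie group straddles rank k the whole group is included and the
    tie-extension flag is returned True.  ``k > n`` returns every marker.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    importance = pd.Series(importance)
    ordered = importance.sort_index().sort_values(ascending=False, kind="mergesort")
    if k >= len(ordered):
        return list(ordered.index), False
    cutoff = ordered.iloc[k - 1]
    extended = ordered[ordered >= cutoff]
    return list(extended.index), len(extended) > k


@dataclass
class ConsensusReport:
    """Five marker lists, their union, and exclusive intersection counts."""

    lists: dict          # label -> list of marker ids
    union: set
    counts: pd.DataFrame  # columns: combination (label tuple), bitmask, count

    def nonzero_combinations(self) -> dict:
        return {
            tuple(row.combination): int(row["count"])
            for _, row in self.counts.iterrows()
            if row["count"] > 0
        }


def consensus_report(lists: dict) -> ConsensusReport:
    """UpSet-style exclusive intersection counts over the given marker lists.

    ``lists`` maps a method label to its marker ids (typically the four
    top-K lists plus the Pareto front).  Every non-empty combination of
    methods gets the count of markers belonging to exactly that combination,
    so the counts partition the union.
    """
    labels = list(lists)
    sets = {lab: set(lists[lab]) for lab in labels}
    union = set().union(*sets.values()) if sets else set()
    membership = {}
    for marker in union:
        combo = tuple(lab for lab in labels if marker in sets[lab])
        membership[combo] = membership.get(combo, 0) + 1
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            bitmask = "".join("1" if lab in combo else "0" for lab in labels)
            rows.append(
                {"combination": combo, "bitmask": bitmask, "count": membership.get(combo, 0)}
            )
    counts = pd.DataFrame(rows)
    return ConsensusReport(lists={lab: list(lists[lab]) for lab in labels}, union=union, counts=counts)
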