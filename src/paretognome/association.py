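"""Per-marker allelic chi-square association testing.

The allelic test compares minor/major allele counts between cases and
controls in a 2x2 table (each individual contributes two alleles).  The
Pearson statistic sum((O-E)^2/E) is computed without continuity correction
(the GWAS convention) with df = 1; monomorphic markers — a zero column
margin — are retained with ``chisq = 0, p = 1`` so every ranking keeps full
marker dimension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import MISSING, GenotypeMatrix, PhenotypeVector

__all__ = [
    "allelic_counts",
    "chisq_test",
    "allelic_chisq_scan",
    "rank_by_p",
    "bonferroni",
    "manhattan_table",
]

DEFAULT_GENOMEWIDE_P = 1.0e-9  # Manhattan highlight threshold


def allelic_counts(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeVector, marker
) -> np.ndarray:
    """2x2 allele-count table for one marker.

    Rows are (case, control); columns are (minor, major) allele counts over
    non-missing individuals.  ``marker`` may be a marker id or column index.
    """
    j = genotypes.marker_index[marker] if isinstance(marker, str) else int(marker)
    g = genotypes.values[:, j]
    obs = g != MISSING
    table = np.zeros((2, 2), dtype=np.int64)
    for row, is_case in ((0, 1), (1, 0)):
        sel = obs & (phenotypes.labels == is_case)
        minor = int(g[sel].sum())
        total = 2 * int(sel.sum())
        table[row] = (minor, total - minor)
    return table


def chisq_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    A zero column margin (monomorphic marker) returns ``(0.0, 1.0)``.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=1) == 0).any():
        raise ValueError("empty row in allele table")
    col = table.sum(axis=0)
    if (col == 0).any():
        return 0.0, 1.0
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def allelic_chisq_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized allelic chi-square over every marker.

    Returns a DataFrame with columns ``chrom pos id minor major case_minor
    case_major ctrl_minor ctrl_major chisq p neg_log10_p``, one row per
    marker in input order.  Missing calls are dropped per marker; markers
    where one group has no calls, or that are monomorphic, get ``p = 1``.
    """
    vals = genotypes.values
    obs = vals != MISSING
    case = phenotypes.labels == 1

    def group_counts(sel):
        v = vals[sel]
        o = obs[sel]
        minor = np.where(o, v, 0).sum(axis=0).astype(np.int64)
        total = 2 * o.sum(axis=0).astype(np.int64)
        return minor, total - minor

    a, b = group_counts(case)       # case minor/major
    c, d = group_counts(~case)      # control minor/major
    n = a + b + c + d
    col_minor = a + c
    col_major = b + d
    row_case = a + b
    row_ctrl = c + d
    ok = (col_minor > 0) & (col_major > 0) & (row_case > 0) & (row_ctrl > 0)
    # Pearson statistic for 2x2 in closed form: n(ad-bc)^2 / (r1 r2 c1 c2)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n.astype(float) * (a * d - b * c).astype(float) ** 2
        den = (
            row_case.astype(float)
            * row_ctrl.astype(float)
            * col_minor.astype(float)
            * col_major.astype(float)
        )
        stat = np.where(ok, num / np.where(den > 0, den, 1.0), 0.0)
    p = np.where(ok, chi2.sf(stat, df=1), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if variants is not None:
        base = variants[["chrom", "pos", "id"]].reset_index(drop=True)
    else:
        base = pd.DataFrame(
            {"chrom": "0", "pos": np.arange(1, genotypes.n_markers + 1), "id": genotypes.marker_ids}
        )
    return base.assign(
        case_minor=a, case_major=b, ctrl_minor=c, ctrl_major=d,
        chisq=stat, p=p, neg_log10_p=-np.log10(p),
    )


def rank_by_p(results: pd.DataFrame) -> pd.DataFrame:
    """Order markers most-significant-first (ascending p).

    Ties break by (chrom, pos, id) so the ranking is deterministic under
    input permutation.
    """
    out = results.sort_values(
        ["p", "chrom", "pos", "id"], kind="mergesort"
    ).reset_index(drop=True)
    return out


def bonferroni(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Markers passing the Bonferroni family-wise threshold alpha/m."""
    m = len(results)
    if m < 1:
        raise ValueError("no results to correct")
    return results[results["p"] <= alpha / m].reset_index(drop=True)


def manhattan_table(
    results: pd.DataFrame, threshold_p: float = DEFAULT_GENOMEWIDE_P, path=None
) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, id, p, -log10 p and a significance flag.

    The flag marks markers strictly below ``threshold_p``.
    """
    table = results[["chrom", "pos", "id", "p", "neg_log10_p"]].copy()
    table["significant"] = results["p"] < threshold_p
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
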