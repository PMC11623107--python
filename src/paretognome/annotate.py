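"""Gene mapping and over-representation testing for selected markers.

Markers are assigned to genes by interval containment: a marker inside one
or more gene intervals is *genic* (all overlapping symbols reported); a
marker between intervals is *intergenic* and reports its nearest flanking
gene on each side with distances (both flanks when equidistant).  Gene
lists are then tested for over-representation in user-supplied collections
(GMT) with the exact hypergeometric upper-tail test and Benjamini-Hochberg
FDR control, and intersected with reference gene lists (e.g. disease or
druggable-genome catalogues).

Coordinates: BED input is 0-based half-open and converted on read; GFF3 and
the internal representation are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "GeneInterval",
    "SnpAnnotation",
    "read_bed",
    "read_gff3",
    "read_gmt",
    "read_gene_list",
    "map_snps_to_genes",
    "hypergeometric_enrichment",
    "bh_fdr",
    "intersect_gene_lists",
]


@dataclass(frozen=True)
class GeneInterval:
    """A gene span with 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    symbol: str
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start > end for {self.symbol}")
        if not self.symbol:
            raise ValueError("empty gene symbol")


@dataclass
class SnpAnnotation:
    """Gene assignment of one marker."""

    marker_id: str
    category: str             # "genic" | "intergenic"
    genes: tuple              # overlapping symbols, or up to two flanks
    distances: tuple = ()     # per-flank distance, intergenic only


def read_bed(path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            symbol = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GeneInterval(chrom, start + 1, end, symbol, strand))
    return out


def read_gff3(path, feature_type: str = "gene") -> list[GeneInterval]:
    """Read gene records from GFF3 (already 1-based inclusive).

    The symbol is the ``Name=`` attribute, falling back to ``ID=``.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != feature_type:
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            symbol = attrs.get("Name") or attrs.get("ID") or ""
            out.append(GeneInterval(fields[0], int(fields[3]), int(fields[4]), symbol, fields[6]))
    return out


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name -> set of symbols."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {_norm(s) for s in fields[2:] if s.strip()}
    return sets


def read_gene_list(path) -> set:
    """One-symbol-per-line reference gene list."""
    with open(path) as fh:
        return {_norm(line) for line in fh if line.strip()}


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def map_snps_to_genes(markers: pd.DataFrame, intervals: list) -> list:
    """Assign every marker to genes by interval containment.

    ``markers`` needs columns ``chrom pos id``.  Returns one
    :class:`SnpAnnotation` per input marker, in input order.  Markers on a
    chromosome absent from the interval list are intergenic with no flanks
    (warned).
    """
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(str(iv.chrom), []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end, iv.symbol))

    out = []
    missing_chroms = set()
    for row in markers.itertuples(index=False):
        chrom = str(row.chrom)
        pos = int(row.pos)
        ivs = by_chrom.get(chrom)
        if not ivs:
            missing_chroms.add(chrom)
            out.append(SnpAnnotation(row.id, "intergenic", ()))
            continue
        hits = [iv.symbol for iv in ivs if iv.start <= pos <= iv.end]
        if hits:
            out.append(SnpAnnotation(row.id, "genic", tuple(dict.fromkeys(hits))))
            continue
        left = [(pos - iv.end, iv.symbol) for iv in ivs if iv.end < pos]
        right = [(iv.start - pos, iv.symbol) for iv in ivs if iv.start > pos]
        flanks, dists = [], []
        best_left = min(left) if left else None
        best_right = min(right) if right else None
        for best in (best_left, best_right):
            if best is not None:
                dists.append(best[0])
                flanks.append(best[1])
        if best_left and best_right and best_left[0] == best_right[0]:
            pass  # equidistant: both flanks already reported
        out.append(SnpAnnotation(row.id, "intergenic", tuple(flanks), tuple(dists)))
    if missing_chroms:
        warnings.warn(
            f"markers on chromosomes absent from the interval file: {sorted(missing_chroms)}",
            stacklevel=2,
        )
    return out


def annotation_genes(annotations: list) -> set:
    """All gene symbols touched by the annotations (genic hits and flanks)."""
    out = set()
    for ann in annotations:
        out.update(_norm(g) for g in ann.genes)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def hypergeometric_enrichment(
    query_genes,
    collection: dict,
    universe,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Exact over-representation test of a gene list against a collection.

    Query and every set are intersected with the universe first.  For each
    set, ``p = P(X >= k)`` under ``Hypergeometric(N, K, n)`` with N the
    universe size, K the set size, n the query size and k the overlap; BH
    FDR is computed across all tested sets.  Sorted ascending by p.
    """
    universe = {_norm(g) for g in universe}
    if not universe:
        raise ValueError("empty gene universe")
    query = {_norm(g) for g in query_genes} & universe
    if not query:
        warnings.warn("query is empty after intersecting with the universe", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "N", "K", "n", "k", "p", "fdr", "significant"]
        )
    N, n = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        members = {_norm(g) for g in genes} & universe
        K = len(members)
        k = len(members & query)
        # upper tail P(X >= k); survival function is P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "N": N, "K": K, "n": n, "k": k, "p": min(max(p, 0.0), 1.0)})
    result = pd.DataFrame(rows)
    result["fdr"] = bh_fdr(result["p"].to_numpy())
    result["significant"] = result["fdr"] < fdr_threshold
    return result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


def intersect_gene_lists(query, reference, label: str = "reference") -> dict:
    """Case-insensitive overlap of a query gene list with a reference list."""
    q = {_norm(g) for g in query}
    r = {_norm(g) for g in reference}
    if not r:
        warnings.warn(f"reference list {label!r} is empty", stacklevel=2)
    overlap = sorted(q & r)
    return {
        "label": label,
        "query_size": len(q),
        "reference_size": len(r),
        "overlap_count": len(overlap),
        "overlap": overlap,
    }
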