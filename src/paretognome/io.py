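"""Genotype and phenotype I/O plus design-matrix encodings.

Genotypes live in a :class:`GenotypeMatrix`: an ``individuals x markers``
``int8`` array of minor-allele counts (0/1/2) with ``-1`` marking a missing
call.  Readers accept VCF (GT field, biallelic records only) or a plain
genotype TSV; phenotypes are a two-column sample/label TSV with binary
case/control labels (1 = case).

Encodings:

* *additive* — each marker is one column counting copies of the dataset-minor
  allele (``additive_encode`` flips markers whose ALT allele is the major one).
* *one-hot* — each marker expands to three indicator columns, one per genotype
  class; requires missing calls to be imputed first (``impute_missing``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel for a missing genotype call in :class:`GenotypeMatrix` values."""

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "minor_allele", "maf"]


class GenotypeError(ValueError):
    """Malformed or contract-violating genotype/phenotype input."""


class MultiallelicError(GenotypeError):
    """VCF contains multiallelic records; lists the offending record ids."""

    def __init__(self, records: list[str]):
        self.records = list(records)
        shown = ", ".join(self.records[:10])
        more = "" if len(self.records) <= 10 else f" (+{len(self.records) - 10} more)"
        super().__init__(f"multiallelic records not supported: {shown}{more}")


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of minor-allele counts.

    Attributes
    ----------
    values : ndarray of int8, shape (n_individuals, n_markers)
        Genotype codes in {0, 1, 2} with :data:`MISSING` (-1) for no-calls.
    sample_ids : ndarray of str
        Unique individual identifiers, one per row.
    marker_ids : ndarray of str
        Unique marker identifiers, one per column.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    marker_ids: np.ndarray
    _marker_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.values.ndim != 2:
            raise GenotypeError("genotype values must be 2-D")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise GenotypeError("id lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise GenotypeError("duplicate marker ids")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeError("genotype values must be in {0,1,2} or missing")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def marker_index(self) -> dict:
        """Mapping marker id -> column position."""
        if self._marker_index is None:
            self._marker_index = {mid: j for j, mid in enumerate(self.marker_ids)}
        return self._marker_index

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned with a genotype matrix's samples."""

    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.labels.shape != self.sample_ids.shape:
            raise GenotypeError("labels and sample ids differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise GenotypeError("labels must be 0 (control) or 1 (case)")

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def class_counts(self) -> tuple[int, int]:
        """(n_controls, n_cases)."""
        return self.n_controls, self.n_cases


@dataclass
class EncodedDesign:
    """Numeric design matrix with provenance back to source markers.

    ``column_to_marker[j]`` is the column of the source
    :class:`GenotypeMatrix` that produced design column ``j``.
    """

    matrix: np.ndarray
    column_to_marker: np.ndarray
    marker_ids: np.ndarray
    encoding: str  # "additive" | "one_hot"

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def restrict_markers(self, marker_cols: np.ndarray) -> "EncodedDesign":
        """Design restricted to the given source-marker columns, order kept."""
        marker_cols = np.asarray(marker_cols)
        keep = np.concatenate(
            [np.flatnonzero(self.column_to_marker == c) for c in marker_cols]
        ) if len(marker_cols) else np.array([], dtype=int)
        remap = {c: i for i, c in enumerate(marker_cols)}
        return EncodedDesign(
            matrix=self.matrix[:, keep],
            column_to_marker=np.array([remap[c] for c in self.column_to_marker[keep]], dtype=int),
            marker_ids=self.marker_ids[marker_cols],
            encoding=self.encoding,
        )


# ---------------------------------------------------------------------------
# readers


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a biallelic VCF into a genotype matrix plus a variant table.

    Genotypes are initially coded as ALT-allele counts; apply
    :func:`additive_encode` to obtain minor-allele coding.  Multiallelic
    records raise :class:`MultiallelicError` naming the offending ids.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    columns = []
    bad = []
    seen = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            bad.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            continue
        mid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if mid in seen:
            raise GenotypeError(f"duplicate marker id: {mid}")
        seen.add(mid)
        # gt_types with gts012=False: 0=hom-ref,1=het,2=unknown,3=hom-alt
        gt = rec.gt_types
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        columns.append(col.astype(np.int8))
        rows.append((rec.CHROM, rec.POS, mid, rec.REF, rec.ALT[0]))
    if bad:
        raise MultiallelicError(bad)
    if not columns:
        raise GenotypeError("no markers in VCF body")
    values = np.stack(columns, axis=1)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    gm = GenotypeMatrix(values, np.array(samples, dtype=object), variants["id"].to_numpy(dtype=object))
    return gm, variants


def read_matrix_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: first column sample id, remaining columns markers,
    missing token ``NA``."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    values = df.apply(pd.to_numeric).to_numpy()
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    return GenotypeMatrix(values, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object))


def read_phenotypes(path, genotypes: GenotypeMatrix | None = None) -> PhenotypeVector:
    """Read a two-column sample/label TSV.

    With ``genotypes`` given, rows are joined on sample id (order-insensitive)
    and returned in genotype sample order; unmatched ids are an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "label"], dtype={0: str})
    bad = df[~df["label"].isin([0, 1])]
    if len(bad):
        row = bad.iloc[0]
        raise GenotypeError(
            f"non-binary label {row['label']!r} for sample {row['sample_id']!r}"
        )
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise GenotypeError("duplicate sample ids in phenotype file")
    if genotypes is None:
        return PhenotypeVector(df["label"].to_numpy(), df.index.to_numpy(dtype=object))
    missing = set(genotypes.sample_ids) - set(df.index)
    extra = set(df.index) - set(genotypes.sample_ids)
    if missing or extra:
        raise GenotypeError(
            f"sample id mismatch between genotypes and phenotypes: "
            f"{len(missing)} missing, {len(extra)} unmatched"
        )
    aligned = df.loc[list(genotypes.sample_ids), "label"].to_numpy()
    return PhenotypeVector(aligned, genotypes.sample_ids.copy())


# ---------------------------------------------------------------------------
# encodings


def alt_allele_frequency(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-marker frequency of the counted allele over non-missing calls."""
    vals = genotypes.values
    obs = vals != MISSING
    counts = np.where(obs, vals, 0).sum(axis=0)
    denom = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return freq


def additive_encode(
    genotypes: GenotypeMatrix, variants: pd.DataFrame | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Re-code genotypes as counts of the dataset-minor allele.

    The minor allele is determined over the whole dataset (cases and controls
    pooled).  Markers whose counted (ALT) allele frequency exceeds 0.5 are
    flipped ``g -> 2 - g``; an exact tie at 0.5 keeps the counted allele.
    Returns the re-coded matrix and a variant table carrying ``minor_allele``
    and ``maf`` columns.
    """
    freq = alt_allele_frequency(genotypes)
    flip = freq > 0.5
    vals = genotypes.values.copy()
    obs = vals != MISSING
    vals[:, flip] = np.where(obs[:, flip], 2 - vals[:, flip], MISSING)
    out = GenotypeMatrix(vals, genotypes.sample_ids.copy(), genotypes.marker_ids.copy())

    if variants is None:
        variants = pd.DataFrame(
            {
                "chrom": "0",
                "pos": np.arange(1, genotypes.n_markers + 1),
                "id": genotypes.marker_ids,
                "ref": "A",
                "alt": "B",
            }
        )
    variants = variants.copy().reset_index(drop=True)
    maf = np.where(flip, 1.0 - freq, freq)
    variants["minor_allele"] = np.where(flip, variants["ref"], variants["alt"])
    variants["maf"] = maf
    return out, variants


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker's modal genotype.

    Ties between equally frequent genotype classes break toward the smaller
    code, so the result is deterministic.  A marker with no observed calls is
    an error.
    """
    vals = genotypes.values.copy()
    obs = vals != MISSING
    if not obs.all(axis=0).all():
        counts = np.stack([(np.where(obs, vals, -9) == g).sum(axis=0) for g in (0, 1, 2)])
        empty = obs.sum(axis=0) == 0
        if empty.any():
            j = int(np.flatnonzero(empty)[0])
            raise GenotypeError(f"marker {genotypes.marker_ids[j]!r} has all calls missing")
        mode = counts.argmax(axis=0).astype(np.int8)  # argmax takes first max: ties -> smaller code
        vals = np.where(obs, vals, mode[None, :])
    return GenotypeMatrix(vals, genotypes.sample_ids.copy(), genotypes.marker_ids.copy())


def one_hot_encode(genotypes: GenotypeMatrix) -> EncodedDesign:
    """Expand each marker into three genotype-indicator columns.

    Missing calls must be imputed first; each marker's triple then has exactly
    one enabled bit per individual.
    """
    if (genotypes.values == MISSING).any():
        raise GenotypeError("missing genotypes present: run impute_missing first")
    n, m = genotypes.values.shape
    design = np.zeros((n, 3 * m), dtype=np.float32)
    for g in (0, 1, 2):
        design[:, g::3] = genotypes.values == g
    column_to_marker = np.repeat(np.arange(m), 3)
    return EncodedDesign(design, column_to_marker, genotypes.marker_ids.copy(), "one_hot")


def additive_design(genotypes: GenotypeMatrix) -> EncodedDesign:
    """Additive design: one column per marker with the 0/1/2 coding."""
    if (genotypes.values == MISSING).any():
        raise GenotypeError("missing genotypes present: run impute_missing first")
    return EncodedDesign(
        genotypes.values.astype(np.float32),
        np.arange(genotypes.n_markers),
        genotypes.marker_ids.copy(),
        "additive",
    )


def one_hot_to_additive(design: EncodedDesign) -> np.ndarray:
    """Recover 0/1/2 genotypes from a one-hot design by per-triple argmax."""
    if design.encoding != "one_hot":
        raise ValueError("design is not one-hot encoded")
    n = design.matrix.shape[0]
    m = design.n_markers
    out = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        cols = np.flatnonzero(design.column_to_marker == j)
        out[:, j] = design.matrix[:, cols].argmax(axis=1)
    return out
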