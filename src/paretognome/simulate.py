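"""Seeded case/control genotype simulator.

Generates the data structure the downstream association pipeline assumes:
biallelic markers with a configurable minor-allele-frequency spectrum,
optional linkage-disequilibrium (LD) blocks, and a binary phenotype drawn
from an additive logistic disease model with planted causal markers.

Haplotypes come from a latent Gaussian copula: within each block of
``ld_block_size`` markers the latent variables follow an AR(1) correlation
with parameter ``ld_rho``, thresholded at the allele-frequency quantile so
each marker's marginal allele frequency is exact.  Two independent haplotypes
per individual are summed, so Hardy-Weinberg equilibrium holds marginally.

The disease model is ``logit P(case_i) = beta0 + sum_j beta_j * g_ij`` over
the causal markers; ``beta0`` is solved by bisection so the expected case
fraction matches a target (e.g. the heavy case enrichment of a case/control
cohort, ~88% cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .io import MISSING, GenotypeMatrix, PhenotypeVector, additive_encode

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SolverError(RuntimeError):
    """The intercept solver could not reach the target case fraction."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic case/control dataset.

    Defaults emulate, at desk scale, a cohort with strong case enrichment
    (controls ~11.7% of samples) and common variants, the regime in which the
    consensus ranking workflow is meant to operate.
    """

    n_individuals: int = 2000
    case_fraction: float = 0.883
    n_markers: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 20
    effect_size: float | list = 0.5  # per-allele log-odds
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must be in (0,1)")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_causal > self.n_markers:
            raise ConfigurationError("n_causal exceeds n_markers")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError("ld_rho must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.n_individuals < 2 or self.n_markers < 1:
            raise ConfigurationError("need at least 2 individuals and 1 marker")

    def betas(self) -> np.ndarray:
        b = np.asarray(self.effect_size, dtype=float)
        if b.ndim == 0:
            b = np.full(self.n_causal, float(b))
        if b.shape != (self.n_causal,):
            raise ConfigurationError("effect_size list length must equal n_causal")
        return b


@dataclass
class SyntheticTruth:
    """Planted causal structure of a simulated dataset."""

    causal_indices: np.ndarray
    causal_betas: np.ndarray
    intercept: float = field(default=np.nan)

    def __post_init__(self):
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.causal_betas = np.asarray(self.causal_betas, dtype=float)
        if self.causal_indices.shape != self.causal_betas.shape:
            raise ConfigurationError("causal indices and betas differ in length")
        if len(np.unique(self.causal_indices)) != len(self.causal_indices):
            raise ConfigurationError("causal indices must be unique")


def _haplotypes(rng, n_hap, freqs, block, rho):
    """Latent-Gaussian haplotypes with exact marginal allele frequencies."""
    m = len(freqs)
    z = np.empty((n_hap, m))
    if rho == 0.0 or block == 1:
        z = rng.standard_normal((n_hap, m))
    else:
        # AR(1) within each block, independent across blocks
        start = 0
        while start < m:
            width = min(block, m - start)
            eps = rng.standard_normal((n_hap, width))
            z[:, start] = eps[:, 0]
            scale = np.sqrt(1.0 - rho**2)
            for k in range(1, width):
                z[:, start + k] = rho * z[:, start + k - 1] + scale * eps[:, k]
            start += width
    from scipy.stats import norm

    thresh = norm.ppf(freqs)  # P(z < thresh) = freq exactly
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(config: SimulationConfig):
    """Draw genotypes and a variant table from the configured model.

    Returns ``(GenotypeMatrix, variants DataFrame)`` where the variant table
    carries the ``minor_allele``/``maf`` columns of the additive coding.
    Fully reproducible from ``config.seed``.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_markers)
    h1 = _haplotypes(rng, config.n_individuals, freqs, config.ld_block_size, config.ld_rho)
    h2 = _haplotypes(rng, config.n_individuals, freqs, config.ld_block_size, config.ld_rho)
    values = (h1 + h2).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = MISSING
    width = len(str(config.n_markers))
    marker_ids = np.array(
        [f"snp{j + 1:0{width}d}" for j in range(config.n_markers)], dtype=object
    )
    sample_ids = np.array(
        [f"ind{i + 1:0{len(str(config.n_individuals))}d}" for i in range(config.n_individuals)],
        dtype=object,
    )
    gm = GenotypeMatrix(values, sample_ids, marker_ids)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, config.n_markers + 1) * 1000,
            "id": marker_ids,
            "ref": "A",
            "alt": "C",
        }
    )
    gm, variants = additive_encode(gm, variants)
    return gm, variants


def _solve_intercept(eta, target, tol=1e-6, max_iter=200):
    """Bisection for beta0 with mean(expit(beta0 + eta)) = target."""
    lo, hi = -50.0, 50.0
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise SolverError("target case fraction unattainable for these genotypes")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * 0.01:
            break
    b0 = 0.5 * (lo + hi)
    if abs(f(b0)) > tol:
        raise SolverError("intercept solver did not converge")
    return b0


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: SyntheticTruth,
    target_case_fraction: float,
    seed: int = 0,
) -> tuple[PhenotypeVector, SyntheticTruth]:
    """Draw binary labels from the additive logistic model.

    Missing genotypes at causal markers contribute 0 to the risk score.
    Returns the labels and the realized truth including the solved intercept.
    """
    if not 0 < target_case_fraction < 1:
        raise ConfigurationError("target_case_fraction must be in (0,1)")
    idx = truth.causal_indices
    if len(idx) and (idx.min() < 0 or idx.max() >= genotypes.n_markers):
        raise ConfigurationError("causal index out of range")
    g = genotypes.values[:, idx].astype(float) if len(idx) else np.zeros((genotypes.n_individuals, 0))
    g[g == MISSING] = 0.0
    eta = g @ truth.causal_betas if len(idx) else np.zeros(genotypes.n_individuals)
    b0 = _solve_intercept(eta, target_case_fraction)
    rng = np.random.default_rng(seed)
    labels = (rng.random(genotypes.n_individuals) < expit(b0 + eta)).astype(np.int8)
    realized = SyntheticTruth(idx.copy(), truth.causal_betas.copy(), intercept=b0)
    return PhenotypeVector(labels, genotypes.sample_ids.copy()), realized


def simulate_dataset(config: SimulationConfig):
    """One-call simulation: genotypes, variants, phenotypes, realized truth.

    Causal markers are chosen uniformly without replacement from all markers
    (seeded); phenotype noise uses an independent stream derived from the
    same seed.
    """
    gm, variants = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 1)
    idx = np.sort(rng.choice(config.n_markers, size=config.n_causal, replace=False))
    truth = SyntheticTruth(idx, config.betas())
    phen, realized = simulate_phenotypes(gm, truth, config.case_fraction, seed=config.seed + 2)
    return gm, variants, phen, realized


# ---------------------------------------------------------------------------
# file output


def write_dataset(genotypes, variants, phenotypes, truth, out_dir) -> dict:
    """Write VCF + phenotype TSV + truth TSV; returns the paths.

    The VCF is minimal 4.2 with a single GT FORMAT field and biallelic
    records; it round-trips losslessly through :func:`paretognome.io.read_vcf`
    followed by :func:`additive_encode`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
    }
    vals = genotypes.values
    # write ALT-allele counts: where REF is the minor allele the additive code
    # counts REF copies, so the GT written must be flipped back to ALT dosage
    flip = (variants["minor_allele"] == variants["ref"]).to_numpy()
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_ids))
            + "\n"
        )
        for j, row in enumerate(variants.itertuples(index=False)):
            col = vals[:, j]
            if flip[j]:
                col = np.where(col == MISSING, MISSING, 2 - col)
            gts = "\t".join(gt_strings[int(g)] for g in col)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    with open(paths["phenotypes"], "w") as fh:
        for sid, lab in zip(genotypes.sample_ids, phenotypes.labels):
            fh.write(f"{sid}\t{int(lab)}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("marker_id\tbeta\n")
        for k, j in enumerate(truth.causal_indices):
            fh.write(f"{genotypes.marker_ids[j]}\t{truth.causal_betas[k]:.6g}\n")
    return paths
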