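"""End-to-end workflow orchestration.

Order of stages: (simulate | read) -> additive/one-hot encoding -> allelic
chi-square + Manhattan table -> greedy block selection -> grid-search CV and
final training of the three classifiers -> four importance vectors ->
Pareto front + per-method top-K lists + UpSet counts -> optional gene
annotation, over-representation testing and reference-list intersections.

Every run writes its artifacts plus a ``manifest.json`` with the config
echo, the seed, and SHA-256 checksums of each artifact, so deterministic
stages can be verified byte-for-byte across reruns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import association, pareto, selection
from .io import (
    GenotypeMatrix,
    additive_design,
    additive_encode,
    impute_missing,
    one_hot_encode,
    read_matrix_tsv,
    read_phenotypes,
    read_vcf,
)
from .models import DEFAULT_GRIDS, TrainingConfig, extract_importance, grid_search_cv, train_model
from .simulate import SimulationConfig, simulate_dataset, write_dataset

__all__ = ["RunConfig", "run_all"]

_SIM_KEYS = set(SimulationConfig.__dataclass_fields__)
_TOP_KEYS = {
    "input", "simulation", "encoding", "block_size", "folds", "stop_window",
    "stop_tol", "max_blocks", "grids", "top_k", "fdr_threshold",
    "manhattan_threshold_p", "annotation", "outdir", "seed",
}
_INPUT_KEYS = {"vcf", "genotype_tsv", "phenotypes"}
_ANNOTATION_KEYS = {"intervals_bed", "intervals_gff3", "gmt", "reference_lists", "universe"}


class ConfigError(ValueError):
    """Schema violation in the run configuration."""


class RunConfig:
    """Validated configuration of one pipeline run.

    Built from a plain dict (typically loaded from YAML); unknown keys are
    rejected before any computation, and referenced input files must exist.
    """

    def __init__(self, raw: dict):
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if ("input" in raw) == ("simulation" in raw):
            raise ConfigError("exactly one of 'input' or 'simulation' is required")
        self.simulation = None
        self.input = None
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            unknown = set(sim) - _SIM_KEYS
            if unknown:
                raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
            self.simulation = sim
        else:
            inp = dict(raw["input"])
            unknown = set(inp) - _INPUT_KEYS
            if unknown:
                raise ConfigError(f"unknown input keys: {sorted(unknown)}")
            if "phenotypes" not in inp or not ({"vcf", "genotype_tsv"} & set(inp)):
                raise ConfigError("input needs 'phenotypes' plus 'vcf' or 'genotype_tsv'")
            self.input = inp
        self.encoding = raw.get("encoding", "additive")
        if self.encoding not in ("additive", "one_hot"):
            raise ConfigError("encoding must be 'additive' or 'one_hot'")
        self.block_size = int(raw.get("block_size", 1000))
        self.folds = int(raw.get("folds", 5))
        self.stop_window = int(raw.get("stop_window", 3))
        self.stop_tol = float(raw.get("stop_tol", 0.005))
        self.max_blocks = raw.get("max_blocks")
        self.grids = raw.get("grids") or {}
        unknown = set(self.grids) - set(DEFAULT_GRIDS)
        if unknown:
            raise ConfigError(f"unknown grid keys: {sorted(unknown)}")
        self.top_k = int(raw.get("top_k", 100))
        self.fdr_threshold = float(raw.get("fdr_threshold", 0.05))
        self.manhattan_threshold_p = float(
            raw.get("manhattan_threshold_p", association.DEFAULT_GENOMEWIDE_P)
        )
        self.annotation = None
        if "annotation" in raw and raw["annotation"]:
            anno = dict(raw["annotation"])
            unknown = set(anno) - _ANNOTATION_KEYS
            if unknown:
                raise ConfigError(f"unknown annotation keys: {sorted(unknown)}")
            if not ({"intervals_bed", "intervals_gff3"} & set(anno)):
                raise ConfigError("annotation needs 'intervals_bed' or 'intervals_gff3'")
            self.annotation = anno
        self.outdir = Path(raw.get("outdir", "paretognome_run"))
        self.seed = int(raw.get("seed", 0))
        self._check_paths()
        self.raw = raw

    def _check_paths(self):
        paths = []
        if self.input:
            paths += [v for v in self.input.values()]
        if self.annotation:
            paths += [
                v for k, v in self.annotation.items()
                if k in ("intervals_bed", "intervals_gff3", "gmt")
            ]
            paths += list((self.annotation.get("reference_lists") or {}).values())
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.simulation.get("seed", config.seed)})
        gm, variants, phen, truth = simulate_dataset(sim)
        write_dataset(gm, variants, phen, truth, outdir / "simulated")
        return gm, variants, phen
    if "vcf" in config.input:
        gm, variants = read_vcf(config.input["vcf"])
    else:
        gm = read_matrix_tsv(config.input["genotype_tsv"])
        variants = None
    gm, variants = additive_encode(gm, variants)
    phen = read_phenotypes(config.input["phenotypes"], gm)
    return gm, variants, phen


def run_all(config: RunConfig) -> dict:
    """Execute the full workflow; returns a dict of in-memory results.

    Artifacts and a checksum manifest are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    gm, variants, phen = _load_inputs(config, outdir)
    results["class_counts"] = phen.class_counts()

    # association scan on raw (pre-imputation) genotypes: missing calls are
    # dropped per marker by the allelic counting itself
    assoc = association.allelic_chisq_scan(gm, phen, variants)
    ranked = association.rank_by_p(assoc)
    assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
    association.manhattan_table(assoc, config.manhattan_threshold_p, outdir / "manhattan.tsv")
    results["association"] = assoc
    results["ranked"] = ranked

    gm_imp = impute_missing(gm)
    design = one_hot_encode(gm_imp) if config.encoding == "one_hot" else additive_design(gm_imp)

    ranked_ids = list(ranked["id"])
    curve = selection.incremental_selection(
        design, phen, ranked_ids,
        block_size=config.block_size, folds=config.folds,
        stop_window=config.stop_window, stop_tol=config.stop_tol,
        max_blocks=config.max_blocks, seed=config.seed,
    )
    curve.to_tsv(outdir / "selection_curve.tsv")
    sel_design = selection.selected_design(design, curve, ranked_ids)
    with open(outdir / "selected_markers.txt", "w") as fh:
        fh.write("\n".join(map(str, sel_design.marker_ids)) + "\n")
    results["curve"] = curve
    results["selected_markers"] = list(sel_design.marker_ids)

    X, y = sel_design.matrix, phen.labels
    importances = {}
    cv_reports = {}
    best_params = {}
    for kind in ("logreg", "gbdt", "tabnet"):
        tc = TrainingConfig(
            model_kind=kind, grid=config.grids.get(kind), folds=config.folds, seed=config.seed
        )
        params, report, _ = grid_search_cv(X, y, tc)
        model = train_model(X, y, kind, params, seed=config.seed)
        imp = extract_importance(model, sel_design, kind)
        importances[kind] = pd.Series(imp, index=sel_design.marker_ids)
        cv_reports[kind] = report
        best_params[kind] = params
        importances[kind].rename("score").to_csv(
            outdir / f"importance_{kind}.tsv", sep="\t", header=True, index_label="marker_id"
        )
        report.to_frame().to_csv(outdir / f"cv_report_{kind}.tsv", sep="\t", index=False)
    results["importances"] = importances
    results["cv_reports"] = cv_reports
    results["best_params"] = best_params

    matrix = pareto.assemble_importance_matrix(
        assoc, importances["logreg"], importances["gbdt"], importances["tabnet"]
    )
    matrix.to_csv(outdir / "importance_matrix.tsv", sep="\t")
    front = pareto.pareto_front(matrix)
    front.to_csv(outdir / "pareto_front.tsv", sep="\t")
    lists = {}
    chisq_series = pd.Series(assoc["neg_log10_p"].to_numpy(), index=assoc["id"])
    lists["chisq"], _ = pareto.top_k_list(chisq_series, config.top_k)
    for kind in ("logreg", "gbdt", "tabnet"):
        lists[kind], _ = pareto.top_k_list(importances[kind], config.top_k)
    lists["pareto"] = list(front.index)
    report = pareto.consensus_report(lists)
    report.counts.assign(
        combination=report.counts["combination"].map(lambda c: "+".join(c))
    ).to_csv(outdir / "upset_counts.tsv", sep="\t", index=False)
    results["importance_matrix"] = matrix
    results["pareto_front"] = front
    results["consensus"] = report

    if config.annotation:
        anno_cfg = config.annotation
        if "intervals_bed" in anno_cfg:
            intervals = ann.read_bed(anno_cfg["intervals_bed"])
        else:
            intervals = ann.read_gff3(anno_cfg["intervals_gff3"])
        selected = assoc[assoc["id"].isin(report.union)][["chrom", "pos", "id"]]
        annotations = ann.map_snps_to_genes(selected, intervals)
        pd.DataFrame(
            [
                {
                    "marker_id": a.marker_id,
                    "category": a.category,
                    "genes": ",".join(a.genes),
                    "distances": ",".join(map(str, a.distances)),
                }
                for a in annotations
            ]
        ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        genes = ann.annotation_genes(annotations)
        results["annotations"] = annotations
        results["genes"] = genes
        universe = (
            ann.read_gene_list(anno_cfg["universe"])
            if "universe" in anno_cfg
            else {iv.symbol for iv in intervals}
        )
        if "gmt" in anno_cfg:
            collection = ann.read_gmt(anno_cfg["gmt"])
            enrichment = ann.hypergeometric_enrichment(
                genes, collection, universe, config.fdr_threshold
            )
            enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enrichment
        refs = anno_cfg.get("reference_lists") or {}
        overlaps = {}
        for label, path in refs.items():
            overlaps[label] = ann.intersect_gene_lists(genes, ann.read_gene_list(path), label)
        if overlaps:
            pd.DataFrame(
                [
                    {k: (";".join(v[k]) if k == "overlap" else v[k]) for k in v}
                    for v in overlaps.values()
                ]
            ).to_csv(outdir / "reference_overlaps.tsv", sep="\t", index=False)
        results["reference_overlaps"] = overlaps

    manifest = {
        "seed": config.seed,
        "config": {k: v for k, v in config.raw.items() if k != "outdir"},
        "checksums": {
            p.name: _sha256(p) for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
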