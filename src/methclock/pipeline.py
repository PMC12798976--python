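"""Reproducible end-to-end runs: config validation, stage wiring, manifest.

A run is described by a YAML/dict config (seed, input paths, stage
parameters, output directory).  ``run_pipeline`` executes the requested
stages in their canonical order -- simulate, outliers, train, loocv, ewas,
dma, enrich -- writing every artifact as CSV/JSON plus a ``manifest.json``
that echoes the parameters and records SHA-256 hashes of inputs and
outputs, so an identical config on identical inputs reproduces identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clock, dma as dma_mod, enrichment, ewas as ewas_mod, outliers as out_mod
from .io import (
    read_beta_matrix,
    read_gmt,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_clock_model,
    write_gmt,
    write_probe_annotation,
    write_sample_sheet,
)
from .simulate import SimConfig, generate_dataset, generate_gene_sets
from .transform import TransformParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGE_ORDER = ["simulate", "outliers", "train", "loocv", "ewas", "dma", "enrich"]


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run."""

    output_dir: str
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    inputs: dict = field(default_factory=dict)       # beta / sample_sheet / annotation / gene_sets paths
    simulate: dict = field(default_factory=dict)     # SimConfig overrides
    transform: dict = field(default_factory=lambda: {"asm": 2.0, "offset": 1.0})
    penalty: dict = field(default_factory=dict)      # PenaltyConfig overrides
    outliers: dict = field(default_factory=dict)     # detect_outliers kwargs
    ewas: dict = field(default_factory=lambda: {"p_threshold": 1e-3})
    dma: dict = field(default_factory=lambda: {"min_age": 3.0, "p_adj_threshold": 0.05,
                                               "top_k": 100})
    enrich: dict = field(default_factory=lambda: {"min_overlap": 2})

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}")
        p = self.ewas.get("p_threshold", 1e-3)
        if not 0 < p < 1:
            raise ValueError(f"ewas.p_threshold must lie in (0, 1), got {p}")
        q = self.dma.get("p_adj_threshold", 0.05)
        if not 0 < q < 1:
            raise ValueError(f"dma.p_adj_threshold must lie in (0, 1), got {q}")
        cf = self.outliers.get("cut_fraction", 0.5)
        if not 0 < cf <= 1:
            raise ValueError(f"outliers.cut_fraction must lie in (0, 1], got {cf}")
        TransformParams(**self.transform)  # validates asm/offset


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    manifest = {
        "stages_requested": stages,
        "stages_completed": [],
        "parameters": {
            "seed": config.seed,
            "transform": config.transform,
            "penalty": config.penalty,
            "outliers": config.outliers,
            "ewas": config.ewas,
            "dma": config.dma,
            "enrich": config.enrich,
            "simulate": config.simulate,
        },
        "inputs": {},
        "outputs": {},
    }

    def record_output(name, path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def finalize(status):
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    beta = sheet = annot = gene_sets = None
    for name, key in [("beta", "beta"), ("sample_sheet", "sample_sheet"),
                      ("annotation", "annotation"), ("gene_sets", "gene_sets")]:
        path = config.inputs.get(key)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
    if config.inputs.get("beta"):
        beta = read_beta_matrix(config.inputs["beta"])
    if config.inputs.get("sample_sheet"):
        sheet = read_sample_sheet(config.inputs["sample_sheet"])
    if config.inputs.get("annotation"):
        annot = read_probe_annotation(config.inputs["annotation"])
    if config.inputs.get("gene_sets"):
        gene_sets = read_gmt(config.inputs["gene_sets"])

    tparams = TransformParams(**config.transform)
    pen = clock.PenaltyConfig(seed=config.seed, **config.penalty)
    truth = None
    dma_result = None

    try:
        for stage in stages:
            logger.info("stage %s", stage)
            if stage == "simulate":
                sim = SimConfig(seed=config.seed, **config.simulate)
                beta, sheet, annot, truth = generate_dataset(sim)
                write_beta_matrix(beta, out / "beta.csv")
                write_sample_sheet(sheet, out / "sample_sheet.csv")
                write_probe_annotation(annot, out / "annotation.csv")
                pd.DataFrame({"class": truth.probe_class, "effect": truth.effect}) \
                    .rename_axis("probe_id").to_csv(out / "truth.csv")
                if gene_sets is None:
                    disease_genes = enrichment.map_probes_to_genes(
                        truth.probes_of("disease"), annot)
                    gene_sets = generate_gene_sets(
                        annot, enriched_genes=disease_genes, seed=config.seed)
                    write_gmt(gene_sets, out / "gene_sets.gmt")
                    record_output("gene_sets", out / "gene_sets.gmt")
                for nm in ("beta", "sample_sheet", "annotation", "truth"):
                    record_output(nm, out / f"{nm}.csv")
            elif stage == "outliers":
                rep = out_mod.detect_outliers(beta, sheet, **config.outliers)
                rows = [
                    {"tissue": t, "sample_id": s,
                     "flagged": s in set(tc.flagged_sample_ids),
                     "cut_height": tc.cut_height}
                    for t, tc in rep.by_tissue.items() for s in tc.sample_ids
                ]
                pd.DataFrame(rows).to_csv(out / "outliers.csv", index=False)
                with open(out / "dendrograms.txt", "w") as fh:
                    for tc in rep.by_tissue.values():
                        fh.write(out_mod.format_dendrogram(tc) + "\n\n")
                record_output("outliers", out / "outliers.csv")
                flagged = set(rep.flagged_sample_ids)
                if flagged:
                    keep = [s for s in beta.sample_ids if s not in flagged]
                    beta = beta.subset_samples(keep)
                    sheet = type(sheet)(sheet.data[sheet.data["sample_id"].isin(keep)])
            elif stage == "train":
                age_model = clock.fit_age_clock(beta, sheet, tparams, pen)
                write_clock_model(age_model, out / "age_clock.csv",
                                  out / "age_clock.yaml")
                record_output("age_clock", out / "age_clock.csv")
                if sheet.data["sex"].nunique() > 1:
                    sex_model = clock.fit_sex_clock(beta, sheet, pen)
                    write_clock_model(sex_model, out / "sex_clock.csv",
                                      out / "sex_clock.yaml")
                    record_output("sex_clock", out / "sex_clock.csv")
            elif stage == "loocv":
                ev = clock.loocv_age(beta, sheet, tparams, pen)
                ev.table.to_csv(out / "loocv_age.csv", index=False)
                with open(out / "loocv_age_summary.json", "w") as fh:
                    json.dump({"r": ev.r, "mae": ev.mae,
                               "accuracy20": ev.accuracy20, "n": ev.n}, fh, indent=2)
                record_output("loocv_age", out / "loocv_age.csv")
            elif stage == "ewas":
                meta = sheet.aligned_to(beta)
                res = ewas_mod.screen_numeric(
                    beta, meta["age_years"].to_numpy(),
                    p_threshold=config.ewas.get("p_threshold", 1e-3))
                res.table.to_csv(out / "ewas_age.csv")
                if annot is not None:
                    ewas_mod.region_proportions(res, annot).to_csv(
                        out / "ewas_age_regions.csv")
                    manhattan = annot.indexed().loc[
                        res.table.index.intersection(annot.data["probe_id"]),
                        ["chrom", "pos"]]
                    manhattan = manhattan.join(res.table[["p", "z"]])
                    manhattan.to_csv(out / "ewas_age_manhattan.csv")
                if meta["sex"].nunique() > 1:
                    res_sex = ewas_mod.screen_binary(
                        beta, meta["sex"],
                        p_threshold=config.ewas.get("p_threshold", 1e-3))
                    res_sex.table.to_csv(out / "ewas_sex.csv")
                record_output("ewas_age", out / "ewas_age.csv")
            elif stage == "dma":
                kwargs = {k: v for k, v in config.dma.items() if k != "top_k"}
                kwargs.setdefault("tissue", "liver")
                result = dma_mod.fit_dma(beta, sheet, **kwargs)
                tbl = result.table
                if annot is not None:
                    tbl = tbl.join(annot.indexed()[["gene", "region"]], how="left")
                tbl.to_csv(out / "dma.csv")
                record_output("dma", out / "dma.csv")
                dma_result = result
                if tbl["significant"].any():
                    ref_ids = result.case_sample_ids + result.control_sample_ids
                    bundle = dma_mod.build_heatmap(
                        result, beta.subset_samples(ref_ids),
                        k=config.dma.get("top_k", 100), sheet=sheet)
                    bundle.matrix.to_csv(out / "heatmap_matrix.csv")
                    bundle.col_clusters.rename_axis("sample_id").to_csv(
                        out / "heatmap_clusters.csv")
                    if bundle.annotations is not None:
                        bundle.annotations.to_csv(out / "heatmap_annotations.csv")
                    record_output("heatmap_matrix", out / "heatmap_matrix.csv")
            elif stage == "enrich":
                result = dma_result
                if result is None or annot is None or gene_sets is None:
                    raise ValueError(
                        "enrich stage needs a prior dma stage plus annotation and gene sets")
                background = enrichment.map_probes_to_genes(result.table.index, annot)
                for direction in ("all", "hyper", "hypo"):
                    t = result.table[result.table["significant"]]
                    if direction == "hyper":
                        t = t[t["logFC"] > 0]
                    elif direction == "hypo":
                        t = t[t["logFC"] < 0]
                    if t.empty:
                        continue
                    query = enrichment.map_probes_to_genes(t.index, annot)
                    try:
                        enr = enrichment.hypergeom_ora(
                            query, gene_sets, background,
                            min_overlap=config.enrich.get("min_overlap", 2))
                    except ValueError:
                        continue
                    enr.table.to_csv(out / f"enrichment_{direction}.csv", index=False)
                    record_output(f"enrichment_{direction}",
                                  out / f"enrichment_{direction}.csv")
            manifest["stages_completed"].append(stage)
    except Exception:
        finalize("failed")
        raise
    finalize("complete")
    return manifest
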