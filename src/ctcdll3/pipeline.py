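"""End-to-end orchestration: chains the synthetic generators (or file
inputs), IF gating, patient stratification and the single-cell stages into a
JSON report carrying full provenance (config hash, seed, package version)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cnv, cohort, ifquant, io, scxpr, synth

log = logging.getLogger(__name__)

STAGES = ("simulate_if", "gate", "stratify", "simulate_counts", "qc",
          "score", "venn", "cnv")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration.  Unknown keys are rejected; the full
    config (and its hash) is serialized into every report."""

    stages: tuple[str, ...]
    seed: int = 0
    outdir: str | None = None
    cutoff: float = 25.0
    high_cutoff: float = 75.0
    alpha: float = 0.05
    gating: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    qc_mode: str = "tumor"           # "tumor" or "ctc"
    if_params: dict = field(default_factory=dict)
    sc_params: dict = field(default_factory=dict)
    clinical: list | str | None = None   # records or a table path
    events_path: str | None = None
    mtx_path: str | None = None
    venn_genes: tuple[str, ...] = ("DLL3", "SEZ6", "CD276")

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage selection is empty")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.qc_mode not in ("tumor", "ctc"):
            raise ValueError("qc_mode must be 'tumor' or 'ctc'")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "venn_genes" in d:
            d["venn_genes"] = tuple(d["venn_genes"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_clinical(config: RunConfig) -> pd.DataFrame:
    if config.clinical is None:
        raise ValueError("stratify stage requires a clinical table")
    if isinstance(config.clinical, str):
        df, _ = io.read_table(config.clinical)
        return df
    return pd.DataFrame(config.clinical)


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages and return the report dict.

    Stage failures surface as a structured error naming the stage.  When
    ``outdir`` is set, intermediate tables and ``report.json`` are written
    there; rerunning with the same config gives byte-identical report
    bodies.
    """
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": io.config_hash(config.to_dict()),
            "config": config.to_dict(),
        }
    }
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed,
            "config_hash": report["provenance"]["config_hash"]}

    events = calls = enum = summaries = None
    adata = None
    for stage in config.stages:
        try:
            if stage == "simulate_if":
                params = synth.IFCohortParams(**config.if_params,
                                              seed=config.seed)
                events, truth = synth.simulate_if_cohort(params)
                report["simulate_if"] = {"n_events": int(len(events)),
                                         "n_patients": params.n_patients}
                if outdir:
                    io.write_table(events, outdir / "events.tsv", meta)
                    io.write_table(truth, outdir / "truth_if.tsv", meta)
            elif stage == "gate":
                if events is None:
                    if config.events_path is None:
                        raise ValueError("gate stage needs simulate_if or events_path")
                    events, _ = io.read_table(config.events_path)
                gcfg = ifquant.GatingConfig.from_dict(config.gating)
                calls = ifquant.classify_events(events, gcfg)
                enum = ifquant.enumerate_ctcs(calls, config=gcfg)
                report["gate"] = {
                    "label_counts": {k: int(v) for k, v in
                                     calls["label"].value_counts().items()}}
                if outdir:
                    io.write_table(calls, outdir / "calls.tsv", meta)
                    io.write_table(enum, outdir / "enumeration.tsv", meta)
            elif stage == "stratify":
                if enum is None:
                    raise ValueError("stratify stage needs the gate stage")
                clinical = _load_clinical(config)
                summaries = cohort.summarize_patients(
                    enum, clinical, config.cutoff, config.high_cutoff)
                table = cohort.build_contingency(summaries)
                metrics = cohort.predictive_metrics(table, config.alpha)
                totals = cohort.group_marker_totals(summaries)
                report["stratify"] = {
                    "n_pos": int((summaries["stratum"] == "Pos").sum()),
                    "n_low": int((summaries["stratum"] == "Low").sum()),
                    "contingency": dataclasses.asdict(table),
                    "metrics": metrics.rounded(),
                    "group_totals": totals.to_dict(orient="records"),
                }
                if outdir:
                    io.write_table(summaries, outdir / "patient_summary.tsv", meta)
                    io.write_table(totals, outdir / "group_totals.tsv", meta)
            elif stage == "simulate_counts":
                params = synth.SCCountParams(**config.sc_params,
                                             seed=config.seed)
                adata, _truth = synth.simulate_counts(params)
                report["simulate_counts"] = {"n_cells": int(adata.n_obs),
                                             "n_genes": int(adata.n_vars)}
                if outdir:
                    io.write_mtx(adata, outdir / "counts")
            elif stage == "qc":
                if adata is None:
                    if config.mtx_path is None:
                        raise ValueError("qc stage needs simulate_counts or mtx_path")
                    adata = io.read_mtx(config.mtx_path)
                base = (scxpr.QCThresholds.ctc_mode() if config.qc_mode == "ctc"
                        else scxpr.QCThresholds())
                thr = dataclasses.replace(base, **config.qc)
                adata, cell_flags, gene_flags = scxpr.qc_filter(adata, thr)
                report["qc"] = {
                    "cells_kept": int(cell_flags["pass"].sum()),
                    "cells_total": int(len(cell_flags)),
                    "genes_kept": int(gene_flags["pass"].sum()),
                }
            elif stage == "score":
                if adata is None:
                    raise ValueError("score stage needs a count matrix")
                sigs = scxpr.load_signatures()
                scores = scxpr.ucell_scores(adata, sigs.subtypes)
                assigned = scxpr.assign_subtypes(scores)
                report["score"] = {
                    "subtype_counts": {k: int(v) for k, v in
                                       assigned["subtype"].value_counts().items()},
                    "dll3_positive_fraction": float(
                        scxpr.call_epitope(adata, "DLL3").mean()),
                }
                if outdir:
                    io.write_table(scores.join(assigned).reset_index(),
                                   outdir / "subtype_scores.tsv", meta)
            elif stage == "venn":
                if adata is None:
                    raise ValueError("venn stage needs a count matrix")
                venn = scxpr.coexpression_venn(adata, config.venn_genes)
                report["venn"] = {
                    "regions": {"+".join(sorted(k)): v
                                for k, v in venn.regions.items()},
                    "none": venn.none, "any_positive": venn.any_positive,
                    "total": venn.total,
                }
            elif stage == "cnv":
                if adata is None:
                    raise ValueError("cnv stage needs a count matrix")
                if "population" not in adata.obs:
                    raise ValueError("cnv stage needs a 'population' cell label")
                ref = adata.obs_names[adata.obs["population"] == "reference"]
                window = min(101, int(pd.Series(adata.var["chrom"])
                                      .value_counts().min()) // 2 * 2 - 1)
                profile = cnv.infer_cnv_profile(adata, ref, window=window)
                scores = cnv.total_cnv_score(profile)
                is_tumor, cluster_table = cnv.call_tumor_cells(
                    scores, adata.obs["population"],
                    adata.obs["sample"] if "sample" in adata.obs else None)
                report["cnv"] = {
                    "n_tumor_called": int(is_tumor.sum()),
                    "clusters": cluster_table.reset_index().to_dict(orient="records"),
                }
                if outdir:
                    io.write_table(scores.reset_index(), outdir / "cnv_scores.tsv",
                                   meta)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
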