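"""End-to-end orchestration: simulate -> annotate -> call -> regions ->
enrich -> permutation -> expression trends, from one declarative config.

Every stage writes its outputs under ``outdir`` and the run manifest records
a SHA-256 checksum per file, the seed and the package version, so identical
config + seed reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate, median_by_feature, methylation_class_fractions
from .calling import call_dynamic, call_tissue_hypomethylation, callset_table
from .config import ConfigurationError, PlantedSignal, SimulationConfig, default_planted
from .enrichment import (chromatin_state_enrichment, enrichment_or,
                         enrichment_table, nearest_gene, regions_to_items)
from .expression import cpm, geneset_trend, trend_table
from .io import (write_bed, write_beta_matrix, write_counts,
                 write_gene_models, write_manifest, write_sample_sheet)
from .permutation import permutation_overlap_test
from .regions import call_regions, regions_table, regions_to_bed
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "fetalmeth_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    # caller thresholds (printed defaults)
    sd_max: float = 0.10
    delta: float = 0.20
    w18_tol: float = 0.05
    # region thresholds
    max_gap: int = 1_000
    min_matching: int = 3
    max_nonmatching: int = 3
    # permutation
    n_perm: int = 20_000
    frac_overlap_lom: float = 0.5
    n_decoys: int = 200
    # stage toggles
    run_enrichment: bool = True
    run_permutation: bool = True
    run_expression: bool = True

    def validate(self) -> None:
        if not (0 < self.sd_max <= 1 and 0 < self.delta <= 1
                and 0 <= self.w18_tol <= 1):
            raise ConfigurationError("caller thresholds out of range")
        if self.max_gap < 1 or self.min_matching < 1 or self.max_nonmatching < 0:
            raise ConfigurationError("region thresholds out of range")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            planted_raw = sim_raw.pop("planted", "default")
            if planted_raw == "default":
                planted = default_planted()
            else:
                planted = [PlantedSignal(**p) for p in planted_raw]
            sim = SimulationConfig(planted=planted, **sim_raw)
            sim.seed = raw.get("seed", sim.seed)
            cfg.simulation = sim
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the run manifest (also written as
    summary.json in the output directory)."""
    config.validate()
    sim_cfg = config.simulation
    if sim_cfg is None:
        from .config import default_config
        sim_cfg = default_config(seed=config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = path
        logger.info("stage output %s -> %s (%.1fs)", name, path,
                    time.monotonic() - t0)

    # --- simulate -----------------------------------------------------------
    data = simulate_dataset(sim_cfg, frac_overlap_lom=config.frac_overlap_lom,
                            n_decoys=config.n_decoys)
    write_manifest(data.manifest, outdir / "manifest.tsv")
    write_beta_matrix(data.beta, outdir / "beta.tsv")
    write_sample_sheet(data.meta, outdir / "samples.tsv")
    write_gene_models(data.genes, outdir / "genes.tsv")
    write_bed(data.cgis, outdir / "cgis.bed")
    write_bed(data.peaks, outdir / "peaks.bed")
    write_bed(data.states, outdir / "states.bed")
    write_counts(data.counts, outdir / "counts.tsv")
    data.truth.write(outdir / "truth_probes.tsv", outdir / "truth_blocks.tsv")
    with open(outdir / "gene_sets.json", "w") as fh:
        json.dump(data.gene_sets, fh, indent=1, sort_keys=True)
    for f in ("manifest.tsv", "beta.tsv", "samples.tsv", "genes.tsv",
              "cgis.bed", "peaks.bed", "states.bed", "counts.tsv",
              "truth_probes.tsv", "truth_blocks.tsv", "gene_sets.json"):
        emit(f, outdir / f)

    # --- annotate -----------------------------------------------------------
    labels = annotate(data.manifest, data.cgis, data.genes)
    labels.to_csv(outdir / "labels.tsv", sep="\t")
    emit("labels.tsv", outdir / "labels.tsv")
    med = median_by_feature(data.beta, data.meta, labels)
    med.to_csv(outdir / "median_by_feature.tsv", sep="\t", index=False,
               float_format="%.6g")
    emit("median_by_feature.tsv", outdir / "median_by_feature.tsv")
    frac = methylation_class_fractions(data.beta, data.meta)
    frac.to_csv(outdir / "methylation_class_fractions.tsv", sep="\t",
                index=False, float_format="%.6g")
    emit("methylation_class_fractions.tsv",
         outdir / "methylation_class_fractions.tsv")

    # --- calling ------------------------------------------------------------
    tissues = sorted(data.meta["tissue"].unique())
    callsets = []
    counts_summary = {}
    for tissue in tissues:
        hypo = call_tissue_hypomethylation(
            data.beta, data.meta, tissue, sd_max=config.sd_max,
            delta=config.delta)
        gom, lom = call_dynamic(data.beta, data.meta, tissue,
                                delta=config.delta, w18_tol=config.w18_tol,
                                sd_max=config.sd_max)
        callsets.extend([hypo, gom, lom])
        counts_summary[tissue] = {"hypo": len(hypo), "gom": len(gom),
                                  "lom": len(lom)}
    callset_table(callsets).to_csv(outdir / "calls.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    emit("calls.tsv", outdir / "calls.tsv")

    # --- regions ------------------------------------------------------------
    all_regions = []
    region_counts = {}
    kind_names = {"tissue_hypo": "tHR", "gom": "dDMR_gom", "lom": "dDMR_lom"}
    for cs in callsets:
        match = data.manifest["probe_id"].isin(cs.probes).to_numpy()
        regs = call_regions(data.manifest, match, max_gap=config.max_gap,
                            min_matching=config.min_matching,
                            max_nonmatching=config.max_nonmatching,
                            kind=kind_names[cs.kind], tissue=cs.tissue)
        all_regions.extend(regs)
        region_counts.setdefault(cs.tissue, {})[kind_names[cs.kind]] = len(regs)
    regions_table(all_regions).to_csv(outdir / "regions.tsv", sep="\t",
                                      index=False)
    write_bed(regions_to_bed(all_regions), outdir / "regions.bed")
    emit("regions.tsv", outdir / "regions.tsv")
    emit("regions.bed", outdir / "regions.bed")

    summary: dict = {
        "version": __version__, "seed": config.seed,
        "n_probes": int(len(data.manifest)),
        "calls": counts_summary, "regions": region_counts,
    }

    # --- enrichment ---------------------------------------------------------
    if config.run_enrichment:
        background = pd.Index(data.manifest["probe_id"])
        combined = (labels["cgi_class"] + "/" + labels["genic_class"]).rename(
            "feature")
        enr_rows = []
        for cs in callsets:
            if not len(cs.probes):
                continue
            for res in enrichment_or(cs.probes, background, combined):
                enr_rows.append({"tissue": cs.tissue, "kind": cs.kind,
                                 "axis": "annotation",
                                 **enrichment_table([res]).iloc[0].to_dict()})
            for res in chromatin_state_enrichment(cs.probes, background,
                                                  data.manifest, data.states):
                enr_rows.append({"tissue": cs.tissue, "kind": cs.kind,
                                 "axis": "chromatin_state",
                                 **enrichment_table([res]).iloc[0].to_dict()})
        pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        emit("enrichment.tsv", outdir / "enrichment.tsv")
        lom_regions = [r for r in all_regions if r.kind == "dDMR_lom"]
        if lom_regions:
            ng = nearest_gene(regions_to_items(lom_regions), data.genes)
            ng.to_csv(outdir / "lom_region_nearest_genes.tsv", sep="\t",
                      index=False)
            emit("lom_region_nearest_genes.tsv",
                 outdir / "lom_region_nearest_genes.tsv")

    # --- permutation overlap ------------------------------------------------
    if config.run_permutation:
        lom_regions = [r for r in all_regions if r.kind == "dDMR_lom"]
        if lom_regions:
            perm = permutation_overlap_test(
                lom_regions, data.peaks, data.manifest,
                n_perm=config.n_perm, seed=config.seed + 1)
            with open(outdir / "permutation.json", "w") as fh:
                json.dump(perm.to_dict(), fh, indent=1, sort_keys=True)
            emit("permutation.json", outdir / "permutation.json")
            summary["permutation"] = perm.to_dict()
        else:
            logger.warning("no LOM regions called; permutation stage skipped")

    # --- expression trends --------------------------------------------------
    if config.run_expression:
        cpm_matrix = cpm(data.counts)
        summaries = []
        for set_name, genes in sorted(data.gene_sets.items()):
            if not genes:
                continue
            for tissue in tissues:
                summaries.append(geneset_trend(cpm_matrix, data.meta, genes,
                                               tissue, set_name=set_name))
        trend_table(summaries).to_csv(outdir / "expression_trends.tsv",
                                      sep="\t", index=False,
                                      float_format="%.6g")
        emit("expression_trends.tsv", outdir / "expression_trends.tsv")

    summary["outputs"] = {name: _sha256(path) for name, path in
                          sorted(outputs.items())}
    summary["runtime_s"] = round(time.monotonic() - t0, 2)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
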