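"""End-to-end pipeline driver.

Chains simulate -> de -> harmonize -> match -> enrich -> chromatin,
writing every artifact as TSV/JSON under an output directory together
with a :class:`RunManifest`.  Each stage failure aborts with the stage
name while preserving upstream outputs.  A single global seed fans out to
per-stage seeds by stable hashing, so re-running with the same config and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromatin import classify_concordance, overrepresentation, upset_intersections
from .config import SimulationConfig, StageCorrSpec, ThresholdConfig
from .de import (ConsensusDEGTable, consensus_degs, normalize, run_caller,
                 top_variant_pca, volcano_table)
from .enrichment import common_gene_nuclear_ora, gsea_preranked, ora, pathway_wilcoxon
from .errors import StageError, ValidationError
from .harmonize import stage_differential
from .io import (FLOAT_FORMAT, write_calls, write_counts_tsv, write_gmt,
                 write_probe_expression, write_probe_map, write_truth)
from .stagematch import build_report
from .stats import derive_seed
from .synth import (simulate_acetylation_datasets, simulate_count_experiment,
                    simulate_geneset_collection, simulate_staged_cohort)

log = logging.getLogger(__name__)

DEFAULT_CALLERS = ("nb_exact", "lognorm_t", "perm_mean")


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs; YAML-loadable."""

    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    staged: StageCorrSpec = field(default_factory=StageCorrSpec)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    callers: tuple = DEFAULT_CALLERS
    moderation: str = "none"
    n_sets: int = 100
    set_size_range: tuple = (15, 80)
    n_enriched: int = 5
    n_acetyl_datasets: int = 3
    acetyl_coverage: float = 0.6
    acetyl_concordance_prob: float = 0.9
    gsea_n_perm: int = 500

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sim = SimulationConfig(**data.pop("simulation", {}))
        staged_raw = data.pop("staged", {})
        if "n_samples_per_stage" in staged_raw:
            staged_raw["n_samples_per_stage"] = dict(staged_raw["n_samples_per_stage"])
        staged = StageCorrSpec(**staged_raw)
        thresholds = ThresholdConfig(**data.pop("thresholds", {}))
        for key in ("callers", "set_size_range"):
            if key in data:
                data[key] = tuple(data[key])
        unknown = set(data) - {f.name for f in
                               cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, staged=staged, thresholds=thresholds, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def write(self, path):
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=1))


def _write(frame: pd.DataFrame, path, index_label=None):
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index=index_label is not None, index_label=index_label)


def run_pipeline(cfg: PipelineConfig, outdir) -> RunManifest:
    """Run the full synthetic pipeline; returns the manifest (also written)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.simulation.validate()
    cfg.staged.validate()
    cfg.thresholds.validate()
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed,
                           version=__version__,
                           thresholds=asdict(cfg.thresholds))

    def stage(name):
        log.info("pipeline stage: %s", name)
        return name

    # -- simulate ----------------------------------------------------------
    name = stage("simulate")
    try:
        sim = cfg.simulation
        sim = SimulationConfig(**{**asdict(sim), "seed": derive_seed(cfg.seed, "counts")})
        cm, truth = simulate_count_experiment(sim)
        expr, pmap, truth = simulate_staged_cohort(
            truth, cfg.staged, seed=derive_seed(cfg.seed, "staged"))
        collection = simulate_geneset_collection(
            truth.universe, cfg.n_sets, cfg.set_size_range, cfg.n_enriched, truth,
            keywords=cfg.thresholds.correlation_keywords + cfg.thresholds.nuclear_keywords,
            seed=derive_seed(cfg.seed, "genesets"))
        calls = simulate_acetylation_datasets(
            truth, cfg.n_acetyl_datasets, cfg.acetyl_coverage,
            cfg.acetyl_concordance_prob, seed=derive_seed(cfg.seed, "acetyl"))
        write_counts_tsv(cm, outdir / "counts.tsv", outdir / "samples.tsv")
        write_probe_expression(expr, outdir / "probe_expression.tsv",
                               outdir / "cohort_samples.tsv")
        write_probe_map(pmap, outdir / "probe_map.tsv")
        write_gmt(collection, outdir / "gene_sets.gmt")
        write_calls(calls, outdir / "acetylation_calls.tsv")
        write_truth(truth, outdir / "truth.json")
        manifest.stage_counts["simulate"] = {
            "n_genes": len(truth.universe), "n_de_genes": int(len(truth.de_genes)),
            "n_probes": int(len(pmap.table)), "n_sets": len(collection),
            "n_acetyl_datasets": len(calls)}
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- de ----------------------------------------------------------------
    name = stage("de")
    try:
        results = [run_caller(cm, cid, seed=derive_seed(cfg.seed, f"caller:{cid}"))
                   for cid in cfg.callers]
        degs = consensus_degs(results, cfg.thresholds)
        _write(degs.table, outdir / "deg_consensus.tsv", index_label="gene_id")
        _write(volcano_table(degs), outdir / "volcano.tsv", index_label="gene_id")
        norm = normalize(cm)
        _, coords, explained = top_variant_pca(norm, k=cfg.thresholds.pca_top)
        _write(coords.iloc[:, :2], outdir / "pca_coordinates.tsv",
               index_label="sample_id")
        manifest.stage_counts["de"] = {
            "n_members": int(degs.table["member"].sum()),
            "n_up": int((degs.table["direction"] == "up").sum()),
            "n_down": int((degs.table["direction"] == "down").sum()),
            "pc1_explained": round(float(explained[0]), 6)}
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- harmonize ---------------------------------------------------------
    name = stage("harmonize")
    try:
        profile = stage_differential(expr, pmap, cfg.thresholds,
                                     moderation=cfg.moderation)
        _write(profile.table, outdir / "stage_profile.tsv")
        _write(profile.excluded, outdir / "exclusion_report.tsv")
        manifest.stage_counts["harmonize"] = {
            "n_genes_reported": int(profile.table["gene_id"].nunique()),
            "n_genes_excluded": int(profile.excluded["gene_id"].nunique()),
            "n_unmapped_probes": profile.n_unmapped_probes,
            "variant": profile.variant}
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- match -------------------------------------------------------------
    name = stage("match")
    try:
        report = build_report(degs, profile, collection,
                              cfg.thresholds.correlation_keywords)
        _write(report.to_frame(), outdir / "stage_correlations.tsv")
        if report.keyword_table is not None:
            _write(report.keyword_table, outdir / "keyword_correlations.tsv")
        cohort_gene_expr = _cohort_gene_expression(expr, pmap)
        from .stagematch import samplewise_correlation
        mat, groups = samplewise_correlation(norm, cohort_gene_expr)
        _write(mat, outdir / "samplewise_correlation.tsv", index_label="sample_id")
        _write(groups.to_frame("group"), outdir / "samplewise_groups.tsv",
               index_label="sample_id")
        manifest.stage_counts["match"] = {
            "assigned_stage": report.assigned_stage,
            "ambiguous": bool(report.ambiguous),
            **{f"r_{s}": round(c.r, 6) for s, c in report.stages.items()}}
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- enrich ------------------------------------------------------------
    name = stage("enrich")
    try:
        members = list(degs.members)
        universe = list(degs.universe)
        ora_table = ora(members, universe, collection,
                        alpha=cfg.thresholds.ora_alpha) if members else pd.DataFrame()
        _write(ora_table, outdir / "ora.tsv")
        merged_lfc = degs.table.loc[degs.members, "consensus_log2fc"]
        wil = pathway_wilcoxon(merged_lfc, collection, cfg.thresholds) \
            if members else pd.DataFrame()
        _write(wil, outdir / "pathway_wilcoxon.tsv")
        gsea = gsea_preranked(degs.table["consensus_log2fc"], collection,
                              min_size=cfg.thresholds.gsea_min,
                              max_size=cfg.thresholds.gsea_max,
                              n_perm=cfg.gsea_n_perm,
                              seed=derive_seed(cfg.seed, "gsea"))
        _write(gsea.table, outdir / "gsea.tsv")
        _write(gsea.top(10), outdir / "gsea_top.tsv")
        common = common_gene_nuclear_ora(degs, profile, collection,
                                         stage=report.assigned_stage or "proAD",
                                         thresholds=cfg.thresholds)
        _write(common.ora_up, outdir / "common_nuclear_ora_up.tsv")
        _write(common.ora_down, outdir / "common_nuclear_ora_down.tsv")
        manifest.stage_counts["enrich"] = {
            "n_ora_significant": int(ora_table["significant"].sum())
            if len(ora_table) else 0,
            "n_wilcoxon_reported": int(len(wil)),
            "n_gsea_sets": int(len(gsea.table)),
            "n_common_up": len(common.common_up),
            "n_common_down": len(common.common_down)}
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- chromatin ---------------------------------------------------------
    name = stage("chromatin")
    try:
        classification = classify_concordance(calls)
        _write(classification.classes.to_frame("acetylation_class"),
               outdir / "acetylation_classes.tsv", index_label="gene_id")
        upset = upset_intersections(classification, degs)
        _write(upset, outdir / "upset_counts.tsv")
        enr = overrepresentation(classification, degs, universe=degs.universe,
                                 alpha=cfg.thresholds.ora_alpha)
        _write(enr, outdir / "acetylation_enrichment.tsv")
        manifest.stage_counts["chromatin"] = {
            **{f"class_{k}": v for k, v in classification.class_sizes().items()},
            "n_significant_pairs": int(enr["significant"].sum())}
    except Exception as exc:
        raise StageError(name, exc) from exc

    manifest.write(outdir / "manifest.json")
    return manifest


def _cohort_gene_expression(expr, pmap) -> pd.DataFrame:
    """Mean probe intensity per gene (for the sample-wise correlation)."""
    merged = expr.expression.join(pmap.table, how="inner")
    return merged.groupby("gene_id").mean()
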