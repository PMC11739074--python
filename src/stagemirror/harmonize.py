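"""Probe-to-gene harmonization of the staged expression cohort.

Microarray probes are collapsed to gene level by taking the arithmetic
mean of probe log-fold-changes; genes whose probes disagree in logFC sign
(at least two probes with strictly opposite nonzero signs — a zero logFC
is sign-free) are excluded entirely and reported.  Per-stage differential
expression against the normal group is computed probe-wise first (Welch
t-test, or a pooled-variance moderated variant), then collapsed:

* gene logFC  = mean of probe logFCs,
* gene p      = min probe p with a Bonferroni factor equal to the probe
  count (capped at 1) — a documented stand-in for a probe-aware model,
* gene FDR    = Benjamini–Hochberg across genes, separately per stage.

A gene is flagged differential in a stage when its FDR is strictly below
the cut-off (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import STAGE_NAMES, ThresholdConfig
from .errors import ValidationError
from .stats import bh_adjust

MODERATION_PRIOR_DF = 4.0  # d0: weight of the pooled variance prior


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene mapping; unmapped probes carry NA."""

    table: pd.DataFrame  # index probe_id; column gene_id (NA = unmapped)

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"probe mapped more than once: {dups[:5]}")
        if self.table.empty:
            raise ValidationError("empty probe map")

    @property
    def mapped(self) -> pd.Series:
        return self.table["gene_id"].dropna()


@dataclass
class StagedExpressionSet:
    """Probe x sample log-scale intensities with a stage label per sample."""

    expression: pd.DataFrame  # probes x samples
    stage: pd.Series          # per sample, drawn from STAGE_NAMES

    def __post_init__(self):
        if not self.expression.columns.equals(pd.Index(self.stage.index)):
            self.stage = self.stage.reindex(self.expression.columns)
        if self.stage.isna().any():
            missing = self.stage.index[self.stage.isna()].tolist()
            raise ValidationError(f"samples without a stage label: {missing}")
        bad = sorted(set(self.stage) - set(STAGE_NAMES))
        if bad:
            raise ValidationError(
                f"unknown stage label(s) {bad}; allowed: {list(STAGE_NAMES)}")
        if "normal" not in set(self.stage):
            raise ValidationError("the 'normal' reference stage is absent")

    def stages_present(self) -> list[str]:
        present = set(self.stage)
        return [s for s in STAGE_NAMES if s != "normal" and s in present]


@dataclass
class GeneLevelStageProfile:
    """Gene-level per-stage differential expression versus normal."""

    table: pd.DataFrame     # columns gene_id, stage, logfc, pvalue, fdr, n_probes, significant
    excluded: pd.DataFrame  # columns gene_id, stage, reason, probe_logfcs
    n_unmapped_probes: int = 0
    variant: str = "welch"

    def stage_frame(self, stage: str) -> pd.DataFrame:
        sub = self.table[self.table["stage"] == stage]
        if sub.empty:
            raise ValidationError(f"stage {stage!r} absent from the profile")
        return sub.set_index("gene_id")

    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.table["stage"]))


def summarize_probes(probe_table: pd.DataFrame, pmap: ProbeMap):
    """Collapse probe-level logFCs to gene level.

    Parameters
    ----------
    probe_table : DataFrame indexed by probe_id with column ``logfc`` and
        optionally ``pvalue``.
    pmap : ProbeMap

    Returns
    -------
    (gene_table, report) : gene-level DataFrame (logfc = mean of probes,
    pvalue = Bonferroni-min if present, n_probes) indexed by gene_id, and a
    report dict with the excluded-gene DataFrame and the unmapped count.
    Genes with strictly opposite nonzero probe logFC signs are excluded.
    """
    if pmap.mapped.empty:
        raise ValidationError("probe map contains no mapped probes")
    merged = probe_table.join(pmap.table, how="left")
    n_unmapped = int(merged["gene_id"].isna().sum())
    merged = merged.dropna(subset=["gene_id"])

    grouped = merged.groupby("gene_id", sort=True)
    pos = grouped["logfc"].agg(lambda v: bool((v > 0).any()))
    neg = grouped["logfc"].agg(lambda v: bool((v < 0).any()))
    discordant = pos & neg

    gene_logfc = grouped["logfc"].mean()
    n_probes = grouped["logfc"].size()
    cols = {"logfc": gene_logfc, "n_probes": n_probes}
    if "pvalue" in merged.columns:
        cols["pvalue"] = (grouped["pvalue"].min() * n_probes).clip(upper=1.0)
    gene_table = pd.DataFrame(cols)

    excl_rows = []
    for gene in gene_table.index[discordant]:
        lfcs = merged.loc[merged["gene_id"] == gene, "logfc"]
        excl_rows.append({"gene_id": gene, "reason": "discordant_probe_logfc",
                          "probe_logfcs": ";".join(f"{v:.4g}" for v in lfcs)})
    excluded = pd.DataFrame(excl_rows, columns=["gene_id", "reason", "probe_logfcs"])
    gene_table = gene_table[~discordant]
    return gene_table, {"excluded": excluded, "n_unmapped_probes": n_unmapped}


def _probe_stats(x_stage: np.ndarray, x_normal: np.ndarray, moderation: str):
    """Per-probe logFC and p-value for stage vs normal."""
    lfc = x_stage.mean(axis=1) - x_normal.mean(axis=1)
    n1, n2 = x_stage.shape[1], x_normal.shape[1]
    if moderation == "none":
        res = sps.ttest_ind(x_stage, x_normal, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        p = np.where(np.isnan(p), np.where(np.isclose(lfc, 0.0), 1.0, 0.0), p)
    elif moderation == "pooled":
        v1 = x_stage.var(axis=1, ddof=1)
        v2 = x_normal.var(axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        d0 = MODERATION_PRIOR_DF
        s2_mod = (d0 * s2.mean() + df * s2) / (d0 + df)
        t = lfc / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(np.abs(t), df=d0 + df)
    else:
        raise ValidationError(f"unknown moderation mode {moderation!r}; use 'none' or 'pooled'")
    return lfc, p


def stage_differential(expr: StagedExpressionSet, pmap: ProbeMap,
                       thresholds: ThresholdConfig | None = None,
                       moderation: str = "none",
                       stages: list[str] | None = None) -> GeneLevelStageProfile:
    """Per-stage gene-level differential expression versus normal."""
    thresholds = (thresholds or ThresholdConfig()).validate()
    stages = stages if stages is not None else expr.stages_present()
    present = set(expr.stage)
    for stage in stages:
        if stage not in present:
            raise ValidationError(f"stage {stage!r} has no samples in the data")
    normal_mask = (expr.stage == "normal").to_numpy()
    if normal_mask.sum() < 2:
        raise ValidationError("need at least 2 normal samples")
    x = expr.expression.to_numpy(dtype=float)

    rows, excl_frames, n_unmapped = [], [], 0
    for stage in stages:
        mask = (expr.stage == stage).to_numpy()
        if mask.sum() < 2:
            raise ValidationError(f"stage {stage!r} needs at least 2 samples")
        lfc, p = _probe_stats(x[:, mask], x[:, normal_mask], moderation)
        probe_table = pd.DataFrame({"logfc": lfc, "pvalue": p},
                                   index=expr.expression.index)
        gene_table, report = summarize_probes(probe_table, pmap)
        n_unmapped = report["n_unmapped_probes"]
        excl = report["excluded"].copy()
        excl["stage"] = stage
        excl_frames.append(excl)
        gene_table = gene_table.copy()
        gene_table["fdr"] = bh_adjust(gene_table["pvalue"].to_numpy())
        gene_table["significant"] = gene_table["fdr"] < thresholds.fdr_stage
        gene_table["stage"] = stage
        rows.append(gene_table.reset_index())

    table = pd.concat(rows, ignore_index=True)[
        ["gene_id", "stage", "logfc", "pvalue", "fdr", "n_probes", "significant"]]
    excluded = pd.concat(excl_frames, ignore_index=True)[
        ["gene_id", "stage", "reason", "probe_logfcs"]]
    return GeneLevelStageProfile(table=table, excluded=excluded,
                                 n_unmapped_probes=n_unmapped,
                                 variant="welch" if moderation == "none" else "moderated_pooled")
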