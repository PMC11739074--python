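"""Configuration objects: analysis thresholds and simulation parameters.

Every threshold that the analysis applies lives in :class:`ThresholdConfig`
with the study's published value as default; all comparisons are strict
inequalities exactly as printed (FDR ``< 0.1``, ``|log2FC| > 0.5``, set
size ``> 10`` ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: Closed vocabulary of disease-stage labels: normal controls plus
#: possible / probable / definitive Alzheimer's disease (early,
#: intermediate, late neuropathological phases).
STAGE_NAMES = ("normal", "posAD", "proAD", "defAD")

#: Keywords restricting the stage correlation to chromatin/transcription
#: gene sets (case-insensitive substring match on set names).
CORRELATION_KEYWORDS = ("Transcription", "Chromatin", "Acetylation", "Methylation", "Histone")

#: Keywords selecting nuclear-process terms in the common-gene analysis.
NUCLEAR_KEYWORDS = ("transcription", "chromatin", "chromosome", "histone", "DNA")


@dataclass
class ThresholdConfig:
    """Analysis thresholds; defaults are the study settings."""

    fdr_deg: float = 0.1            # consensus DEG: FDR < 0.1 in every caller
    lfc_deg: float = 0.5            # consensus DEG: |log2FC| > 0.5
    fdr_stage: float = 0.1          # staged-cohort DE: FDR < 0.1
    ora_alpha: float = 0.05         # ORA: BH-adjusted p < 0.05
    wilcoxon_alpha: float = 0.05    # per-pathway Wilcoxon: p < 0.05
    wilcoxon_min_genes: int = 10    # report sets with strictly more DEG members
    gsea_min: int = 15
    gsea_max: int = 500
    common_lfc: float = 0.1         # common-gene rule: same sign, |logFC| > 0.1
    pca_top: int = 300
    correlation_keywords: tuple = CORRELATION_KEYWORDS
    nuclear_keywords: tuple = NUCLEAR_KEYWORDS

    def validate(self) -> "ThresholdConfig":
        for name in ("fdr_deg", "lfc_deg", "fdr_stage", "ora_alpha",
                     "wilcoxon_alpha", "common_lfc"):
            if not getattr(self, name) > 0:
                raise ConfigError(name, "must be strictly positive")
        for name in ("wilcoxon_min_genes", "gsea_min", "gsea_max", "pca_top"):
            if not getattr(self, name) > 0:
                raise ConfigError(name, "must be strictly positive")
        if self.gsea_min > self.gsea_max:
            raise ConfigError("gsea_min", "must not exceed gsea_max")
        if not self.correlation_keywords:
            raise ConfigError("correlation_keywords", "must be non-empty")
        if not self.nuclear_keywords:
            raise ConfigError("nuclear_keywords", "must be non-empty")
        return self


@dataclass
class SimulationConfig:
    """Parameters of the two-condition negative-binomial count simulation.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 2000 genes, 6 samples per condition, 10% of genes perturbed at
    |log2FC| = 2 with NB dispersion 0.05.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    frac_de: float = 0.1
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    library_size_mean: int = 1_000_000
    gene_length_range: tuple = (200, 10_000)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_genes < 1:
            raise ConfigError("n_genes", "must be a positive integer")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group", "must be a positive integer")
        if not (0 <= self.frac_de < 1):
            raise ConfigError("frac_de", "must lie in [0, 1)")
        if self.frac_de > 0 and self.frac_de * self.n_genes < 1:
            raise ConfigError("frac_de", "frac_de * n_genes must be >= 1")
        if not self.lfc_magnitude > 0:
            raise ConfigError("lfc_magnitude", "must be strictly positive")
        if not self.nb_dispersion > 0:
            raise ConfigError("nb_dispersion", "must be strictly positive")
        if not self.library_size_mean > 0:
            raise ConfigError("library_size_mean", "must be strictly positive")
        low, high = self.gene_length_range
        if not (0 < low < high):
            raise ConfigError("gene_length_range", "requires 0 < low < high")
        if self.seed < 0:
            raise ConfigError("seed", "must be non-negative")
        return self


def _default_target_r():
    return {"posAD": -0.3, "proAD": 0.6, "defAD": 0.0}


def _default_stage_n():
    return {s: 20 for s in STAGE_NAMES}


@dataclass
class StageCorrSpec:
    """Parameters of the staged probe-level cohort simulation.

    ``target_r`` plants the Pearson correlation between each stage's
    gene-level log2FC vector (stage vs normal) and the cell-model truth
    log2FCs, evaluated over the planted DE genes.  Defaults mirror the
    qualitative stage pattern the pipeline is designed to detect:
    negative for early disease, positive for intermediate, null for late.
    """

    stage_names: tuple = STAGE_NAMES
    target_r: dict = field(default_factory=_default_target_r)
    n_samples_per_stage: dict = field(default_factory=_default_stage_n)
    probes_per_gene: int = 2          # mean of 1 + Poisson(probes_per_gene - 1)
    frac_discordant_genes: float = 0.05
    noise_sd: float = 0.3             # per-sample log2-intensity noise
    stage_effect_sd: float = 0.5      # scale of planted gene-level stage effects

    def validate(self) -> "StageCorrSpec":
        if "normal" not in self.stage_names:
            raise ConfigError("stage_names", "the 'normal' reference stage is required")
        for stage in self.stage_names:
            if stage != "normal" and stage not in self.target_r:
                raise ConfigError("target_r", f"no target correlation for stage {stage!r}")
        for stage, r in self.target_r.items():
            if not (-1.0 <= r <= 1.0):
                raise ConfigError("target_r", f"{stage}: correlation {r} outside [-1, 1]")
        for stage in self.stage_names:
            if self.n_samples_per_stage.get(stage, 0) < 1:
                raise ConfigError("n_samples_per_stage", f"stage {stage!r} needs >= 1 sample")
        if self.probes_per_gene < 1:
            raise ConfigError("probes_per_gene", "must be a positive integer")
        if not (0 <= self.frac_discordant_genes < 1):
            raise ConfigError("frac_discordant_genes", "must lie in [0, 1)")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd", "must be strictly positive")
        if not self.stage_effect_sd > 0:
            raise ConfigError("stage_effect_sd", "must be strictly positive")
        return self
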