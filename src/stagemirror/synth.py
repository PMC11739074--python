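"""Seeded synthetic data with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of the study's inputs so
the whole analysis is testable without downloads:

* a two-condition negative-binomial count experiment with planted DE
  (variance mu + phi*mu**2, log-normal per-sample library factors),
* a staged probe-level cohort whose gene-level stage-vs-normal logFC
  vectors have an exactly planted Pearson correlation with the cell-model
  truth over the DE genes, plus a controllable fraction of genes carrying
  one sign-flipped (discordant) probe,
* gene-set collections with planted enriched sets and keyword-labelled
  names,
* per-dataset acetylation call tables with a planted probability of
  agreeing with the true DE direction.

Everything is driven by numpy Generators from explicit seeds: identical
(config, seed) reproduces identical objects bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import AcetylationCallTable
from .config import SimulationConfig, StageCorrSpec
from .de import CountMatrix
from .enrichment import GeneSetCollection
from .errors import ConfigError, GenerationError, ValidationError
from .harmonize import ProbeMap, StagedExpressionSet

LIBRARY_FACTOR_SD = 0.15      # log-normal spread of per-sample library sizes
BASELINE_INTENSITY_MEAN = 7.0  # log2-scale microarray baseline
BASELINE_INTENSITY_SD = 1.0
PROBE_OFFSET_SD = 0.25
NULL_STAGE_LFC_SD = 0.05      # background stage drift of non-DE genes
DISCORDANT_EFFECT_FLOOR = 0.75  # min |logFC| planted on discordant-gene probes
ACETYL_MARKS = ("H3K27ac", "H3K9ac", "H3K122ac")


@dataclass
class SyntheticTruth:
    """Planted ground truth threading through every synthetic artifact."""

    universe: list
    de_lfc: pd.Series                      # gene -> signed true log2FC (DE genes only)
    stage_r: dict = field(default_factory=dict)        # stage -> realized planted r
    stage_lfc: pd.DataFrame | None = None  # genes x stages expected gene-level logFC
    enriched_sets: list = field(default_factory=list)
    discordant_genes: list = field(default_factory=list)
    acetylation_calls: dict = field(default_factory=dict)  # dataset -> Series

    @property
    def de_genes(self) -> pd.Index:
        return self.de_lfc.index

    def direction(self, gene: str) -> str:
        lfc = self.de_lfc.get(gene, 0.0)
        return "up" if lfc > 0 else ("down" if lfc < 0 else "none")


# ---------------------------------------------------------------------------
# count experiment


def simulate_count_experiment(cfg: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Two-condition NB count experiment with planted log2 fold changes.

    Planted genes (a ``frac_de`` fraction, half up, half down) have
    expected log2FC of +/- ``lfc_magnitude`` in the treatment condition;
    counts are NB with variance mu + phi*mu**2 around per-sample expected
    means built from log-normal relative abundances and library factors.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1],
                           size=cfg.n_genes)
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    abundance /= abundance.sum()

    n_de = int(round(cfg.frac_de * cfg.n_genes))
    beta = np.zeros(cfg.n_genes)
    de_idx = np.array([], dtype=int)
    if n_de:
        de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        beta[de_idx] = signs * cfg.lfc_magnitude

    n = cfg.n_per_group
    samples = [f"ctrl_{i + 1:02d}" for i in range(n)] + [f"tau_{i + 1:02d}" for i in range(n)]
    condition = pd.Series(["control"] * n + ["tau"] * n, index=samples, name="condition")
    lib = cfg.library_size_mean * rng.lognormal(mean=0.0, sigma=LIBRARY_FACTOR_SD,
                                                size=2 * n)
    mu = np.empty((cfg.n_genes, 2 * n))
    mu[:, :n] = np.outer(abundance, lib[:n])
    mu[:, n:] = np.outer(abundance * 2.0**beta, lib[n:])

    r = 1.0 / cfg.nb_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples),
                     lengths_bp=pd.Series(lengths, index=genes, name="length_bp"),
                     condition=condition, reference="control")
    de_series = pd.Series(beta[de_idx], index=[genes[i] for i in de_idx],
                          name="true_log2fc").sort_index()
    truth = SyntheticTruth(universe=genes, de_lfc=de_series)
    return cm, truth


# ---------------------------------------------------------------------------
# staged cohort


def _plant_correlated(target_r: float, t_std: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector with exact sample correlation target_r to t_std."""
    n = len(t_std)
    eps = rng.standard_normal(n)
    eps = eps - eps.mean()
    eps = eps - (eps @ t_std) / (t_std @ t_std) * t_std  # orthogonalize
    sd = eps.std()
    if sd == 0:
        raise GenerationError("degenerate noise vector while planting correlation")
    eps /= sd
    return target_r * t_std + np.sqrt(max(0.0, 1.0 - target_r**2)) * eps


def simulate_staged_cohort(truth: SyntheticTruth, spec: StageCorrSpec,
                           seed: int = 0):
    """Probe-level staged cohort with planted stage-vs-truth correlations.

    Per non-normal stage, the gene-level expected logFC vector over the
    planted DE genes has *exactly* the target Pearson correlation with the
    truth log2FCs (noise is orthogonalized before mixing).  A
    ``frac_discordant_genes`` fraction of non-DE genes receives one extra
    probe with flipped logFC sign; both that probe and the gene's regular
    probes are planted at |logFC| >= 0.75 so the discordance is detectable
    at desk-scale sample sizes.

    Returns (StagedExpressionSet, ProbeMap, truth) with ``truth.stage_lfc``,
    ``truth.stage_r`` and ``truth.discordant_genes`` filled in.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    genes = list(truth.universe)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    stages = [s for s in spec.stage_names if s != "normal"]

    # gene-level expected stage effects
    effects = pd.DataFrame(
        rng.normal(0.0, NULL_STAGE_LFC_SD, size=(n_genes, len(stages))),
        index=genes, columns=stages)
    de = truth.de_genes
    realized = {}
    if len(de):
        t = truth.de_lfc.to_numpy()
        if len(de) < 3 or np.std(t) == 0:
            raise GenerationError(
                "planting stage correlations needs >= 3 DE genes with varying log2FC")
        t_std = (t - t.mean()) / t.std()
        for stage in stages:
            r = spec.target_r[stage]
            z = _plant_correlated(r, t_std, rng) * spec.stage_effect_sd
            effects.loc[de, stage] = z
            realized[stage] = float(np.corrcoef(z, t)[0, 1]) if np.std(z) > 0 else 0.0
            if abs(realized[stage] - r) > 1e-6:
                raise GenerationError(
                    f"stage {stage}: realized correlation {realized[stage]:.4f} "
                    f"missed target {r}")
    else:
        realized = {stage: float("nan") for stage in stages}

    # discordant genes: non-DE pool, detectable effect floor on all probes
    n_disc = int(round(spec.frac_discordant_genes * n_genes))
    non_de = [g for g in genes if g not in set(de)]
    if n_disc > len(non_de):
        raise GenerationError(
            f"frac_discordant_genes needs {n_disc} non-DE genes; only {len(non_de)}")
    discordant = sorted(rng.choice(non_de, size=n_disc, replace=False)) if n_disc else []
    sign0 = lambda v: np.where(v >= 0, 1.0, -1.0)
    for g in discordant:
        e = effects.loc[g].to_numpy()
        effects.loc[g] = sign0(e) * np.maximum(np.abs(e), DISCORDANT_EFFECT_FLOOR)

    # probe layout
    n_probes = 1 + rng.poisson(spec.probes_per_gene - 1, size=n_genes)
    probe_gene, flipped = [], []
    for i, g in enumerate(genes):
        probe_gene.extend([g] * int(n_probes[i]))
        flipped.extend([False] * int(n_probes[i]))
    for g in discordant:                       # one extra sign-flipped probe
        probe_gene.append(g)
        flipped.append(True)
    probe_ids = [f"P{i:06d}" for i in range(len(probe_gene))]
    flipped = np.array(flipped)

    # probe-level stage effects
    probe_eff = effects.loc[probe_gene].to_numpy()
    if flipped.any():
        flip_mag = rng.uniform(DISCORDANT_EFFECT_FLOOR, 2 * DISCORDANT_EFFECT_FLOOR,
                               size=(int(flipped.sum()), len(stages)))
        probe_eff[flipped] = -sign0(probe_eff[flipped]) * flip_mag

    baseline = rng.normal(BASELINE_INTENSITY_MEAN, BASELINE_INTENSITY_SD, size=n_genes)
    probe_base = baseline[[gene_pos[g] for g in probe_gene]] + \
        rng.normal(0.0, PROBE_OFFSET_SD, size=len(probe_gene))

    # samples
    all_stages = [s for s in spec.stage_names]
    cols, stage_labels = [], []
    blocks = []
    for si, stage in enumerate(all_stages):
        ns = spec.n_samples_per_stage[stage]
        names = [f"{stage}_{i + 1:03d}" for i in range(ns)]
        cols.extend(names)
        stage_labels.extend([stage] * ns)
        eff = np.zeros(len(probe_gene)) if stage == "normal" \
            else probe_eff[:, stages.index(stage)]
        noise = rng.normal(0.0, spec.noise_sd, size=(len(probe_gene), ns))
        blocks.append(probe_base[:, None] + eff[:, None] + noise)
    expr = pd.DataFrame(np.hstack(blocks), index=probe_ids, columns=cols)
    stage_series = pd.Series(stage_labels, index=cols, name="stage")

    pmap = ProbeMap(table=pd.DataFrame({"gene_id": probe_gene}, index=pd.Index(probe_ids, name="probe_id")))
    truth.stage_lfc = effects
    truth.stage_r = realized
    truth.discordant_genes = list(discordant)
    return StagedExpressionSet(expression=expr, stage=stage_series), pmap, truth


# ---------------------------------------------------------------------------
# gene sets


def simulate_geneset_collection(genes, n_sets: int, size_range: tuple,
                                n_enriched: int, truth: SyntheticTruth,
                                keywords=None, keyword_frac: float = 0.3,
                                enriched_de_frac: float = 0.9,
                                seed: int = 0) -> GeneSetCollection:
    """Gene-set collection with planted enriched sets and keyword labels.

    The first ``n_enriched`` sets draw ``enriched_de_frac`` of their
    members from the planted DE genes (detectable by ORA downstream);
    a ``keyword_frac`` fraction of set names embeds a keyword from
    ``keywords`` (round-robin) so keyword-restricted analyses have
    matching sets.  Set names land in ``truth.enriched_sets``.
    """
    genes = list(genes)
    if n_enriched > n_sets:
        raise ValidationError(f"n_enriched={n_enriched} exceeds n_sets={n_sets}")
    lo, hi = size_range
    if not (2 <= lo <= hi <= len(genes)):
        raise ConfigError("size_range", f"({lo}, {hi}) must lie within [2, {len(genes)}]")
    rng = np.random.default_rng(seed)
    de = [g for g in truth.de_genes if g in set(genes)]
    non_de = [g for g in genes if g not in set(de)]

    n_kw = int(round(keyword_frac * n_sets)) if keywords else 0
    sets, descriptions = {}, {}
    enriched_names = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched and de:
            n_from_de = min(int(round(enriched_de_frac * size)), len(de))
            members = list(rng.choice(de, size=n_from_de, replace=False))
            rest = [g for g in non_de if g not in set(members)]
            members += list(rng.choice(rest, size=size - n_from_de, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        if keywords and i < n_kw:
            kw = keywords[i % len(keywords)]
            name = f"SET_{i:04d}_{kw.upper()}_REGULATION"
        else:
            name = f"SET_{i:04d}_PROCESS"
        sets[name] = frozenset(members)
        descriptions[name] = "planted_enriched" if i < n_enriched else "background"
        if i < n_enriched:
            enriched_names.append(name)
    truth.enriched_sets = enriched_names
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# ---------------------------------------------------------------------------
# acetylation call tables


def simulate_acetylation_datasets(truth: SyntheticTruth, n_datasets: int = 3,
                                  coverage: float = 0.6,
                                  concordance_prob: float = 0.9,
                                  seed: int = 0) -> list[AcetylationCallTable]:
    """Per-dataset acetylation direction calls with planted concordance.

    Each dataset calls an independent ``coverage`` fraction of the
    universe.  A called DE gene agrees with its true DE direction with
    probability ``concordance_prob`` (independently per dataset); called
    non-DE genes are up/down with equal probability.
    """
    if n_datasets < 1:
        raise ConfigError("n_datasets", "must be >= 1")
    if not (0 < coverage <= 1):
        raise ConfigError("coverage", "must lie in (0, 1]")
    if not (0 < concordance_prob <= 1):
        raise ConfigError("concordance_prob", "must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.universe)
    de_set = set(truth.de_genes)
    true_dir = np.array([truth.direction(g) for g in genes])

    tables = []
    truth.acetylation_calls = {}
    for d in range(n_datasets):
        called = rng.random(len(genes)) < coverage
        agree = rng.random(len(genes)) < concordance_prob
        coin = rng.random(len(genes)) < 0.5
        directions = np.where(
            np.isin(genes, list(de_set)),
            np.where(agree, true_dir, np.where(true_dir == "up", "down", "up")),
            np.where(coin, "up", "down"))
        calls = pd.Series(directions[called], index=pd.Index(genes[called], name="gene_id"))
        dataset_id = f"acetyl_{d + 1}"
        tables.append(AcetylationCallTable(dataset_id=dataset_id, calls=calls,
                                           mark=ACETYL_MARKS[d % len(ACETYL_MARKS)]))
        truth.acetylation_calls[dataset_id] = calls
    return tables
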