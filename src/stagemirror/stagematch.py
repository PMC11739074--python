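"""Stage matching: how well the cell-model DEG signature mirrors each
disease stage of the cohort.

For every stage the consensus DEG log2FCs are correlated (Pearson) with
the stage-vs-normal gene-level logFCs over their common genes; the
direction-concordance percentage counts common genes whose logFC signs
agree (genes with a logFC of exactly zero on either side are dropped from
the denominator, since their sign is undefined).  The stage with maximal
correlation is assigned, with an ambiguity flag when the top two are
within 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import ConsensusDEGTable, NormalizedMatrix
from .enrichment import GeneSetCollection
from .errors import UndefinedCorrelationError, ValidationError
from .harmonize import GeneLevelStageProfile

ASSIGN_TIE_TOLERANCE = 0.02  # |r1 - r2| below this flags the assignment ambiguous


@dataclass
class StageCorrelation:
    stage: str
    r: float
    p: float
    n_common: int
    concordance_pct: float


@dataclass
class CorrelationReport:
    stages: dict                          # stage -> StageCorrelation
    keyword_table: pd.DataFrame | None = None
    samplewise: pd.DataFrame | None = None
    samplewise_groups: pd.Series | None = None
    assigned_stage: str | None = None
    ambiguous: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s.stage, "r": s.r, "p": s.p, "n_common": s.n_common,
              "concordance_pct": s.concordance_pct} for s in self.stages.values()])


def _paired_logfcs(degs: ConsensusDEGTable, profile: GeneLevelStageProfile,
                   stage: str, genes=None, members_only: bool = True):
    """Aligned (cell-model, stage) log2FC vectors over common genes."""
    stage_lfc = profile.stage_frame(stage)["logfc"]
    base = degs.table["consensus_log2fc"]
    pool = degs.members if members_only else degs.universe
    if genes is not None:
        pool = pool.intersection(pd.Index(genes))
    common = pool.intersection(stage_lfc.index)
    return base.reindex(common), stage_lfc.reindex(common)


def correlate_stage(degs: ConsensusDEGTable, profile: GeneLevelStageProfile,
                    stage: str, genes=None,
                    members_only: bool = True) -> StageCorrelation:
    """Pearson correlation and direction concordance for one stage.

    Restricted to consensus DEG members present in the (non-excluded)
    stage profile; ``genes`` optionally restricts further, and
    ``members_only=False`` widens to all shared genes.
    """
    x, y = _paired_logfcs(degs, profile, stage, genes, members_only)
    n = len(x)
    if n < 3:
        raise ValidationError(
            f"only {n} common genes between DEGs and stage {stage!r}; need >= 3")
    xv, yv = x.to_numpy(), y.to_numpy()
    if np.allclose(xv, xv[0]) or np.allclose(yv, yv[0]):
        raise UndefinedCorrelationError(
            f"zero variance in a logFC vector for stage {stage!r}")
    res = sps.pearsonr(xv, yv)
    nonzero = (xv != 0) & (yv != 0)
    if nonzero.sum() == 0:
        pct = float("nan")
    else:
        pct = 100.0 * float((np.sign(xv[nonzero]) == np.sign(yv[nonzero])).sum()
                            / nonzero.sum())
    return StageCorrelation(stage=stage, r=float(res.statistic),
                            p=float(res.pvalue), n_common=n, concordance_pct=pct)


def keyword_restricted_correlation(degs: ConsensusDEGTable,
                                   profile: GeneLevelStageProfile, stage: str,
                                   collection: GeneSetCollection,
                                   keywords) -> pd.DataFrame:
    """Stage correlation restricted, per keyword, to genes of matching sets.

    Keyword matching is case-insensitive substring on set names; keywords
    with fewer than 3 common genes are reported as not computable
    (r and p NaN), never as r = 0.
    """
    matches = collection.match_keywords(keywords)
    if not any(matches.values()):
        raise ValidationError(f"no gene set matches any of the keywords {list(keywords)}")
    rows = []
    for kw in keywords:
        names = matches[kw]
        genes = frozenset().union(*(collection.sets[n] for n in names)) if names else frozenset()
        try:
            sc = correlate_stage(degs, profile, stage, genes=genes)
            rows.append({"keyword": kw, "n_sets": len(names), "r": sc.r,
                         "p": sc.p, "n_common": sc.n_common, "computable": True})
        except (ValidationError, UndefinedCorrelationError):
            rows.append({"keyword": kw, "n_sets": len(names), "r": np.nan,
                         "p": np.nan, "n_common": 0, "computable": False})
    return pd.DataFrame(rows)


def samplewise_correlation(cell_norm: NormalizedMatrix,
                           cohort_expr: pd.DataFrame,
                           common_genes=None) -> tuple[pd.DataFrame, pd.Series]:
    """Sample x sample Pearson matrix across the two datasets.

    Cell-model samples contribute log2(RPM+1); the cohort contributes its
    gene-level log-scale expression.  Genes are centered within each
    dataset before correlating (removes platform offsets), and the matrix
    is computed over the genes common to both.
    Returns (matrix, group labels per sample).
    """
    cell = np.log2(cell_norm.rpm + 1.0)
    common = cell.index.intersection(cohort_expr.index)
    if common_genes is not None:
        common = common.intersection(pd.Index(common_genes))
    if len(common) < 3:
        raise ValidationError(f"only {len(common)} common genes; need >= 3")
    a = cell.loc[common]
    b = cohort_expr.loc[common]
    a = a.sub(a.mean(axis=1), axis=0)
    b = b.sub(b.mean(axis=1), axis=0)
    combined = pd.concat([a, b], axis=1)
    sds = combined.std(axis=0, ddof=0)
    flat = sds.index[sds == 0].tolist()
    if flat:
        raise UndefinedCorrelationError(
            f"constant sample(s) after centering: {flat[:5]}")
    mat = pd.DataFrame(np.corrcoef(combined.to_numpy().T),
                       index=combined.columns, columns=combined.columns)
    np.fill_diagonal(mat.values, 1.0)
    groups = pd.Series(["cell_model"] * a.shape[1] + ["cohort"] * b.shape[1],
                       index=combined.columns, name="group")
    return mat, groups


def assign_stage(stages: dict) -> tuple[str, bool]:
    """Stage with maximal r; flags ambiguity when the runner-up is close.

    ``stages`` maps stage name to :class:`StageCorrelation` (or any object
    with an ``r`` attribute).  Returns (stage, ambiguous).
    """
    usable = {s: c.r for s, c in stages.items() if np.isfinite(c.r)}
    if not usable:
        raise ValidationError("no stage with a computable correlation")
    ordered = sorted(usable.items(), key=lambda kv: (-kv[1], kv[0]))
    best, r_best = ordered[0]
    ambiguous = len(ordered) > 1 and (r_best - ordered[1][1]) < ASSIGN_TIE_TOLERANCE
    return best, ambiguous


def build_report(degs: ConsensusDEGTable, profile: GeneLevelStageProfile,
                 collection: GeneSetCollection | None = None,
                 keywords=None) -> CorrelationReport:
    """Full correlation report over every stage in the profile."""
    stages = {}
    for stage in profile.stages():
        stages[stage] = correlate_stage(degs, profile, stage)
    kw_table = None
    if collection is not None and keywords:
        best_stage, _ = assign_stage(stages)
        kw_table = keyword_restricted_correlation(degs, profile, best_stage,
                                                  collection, keywords)
    assigned, ambiguous = assign_stage(stages)
    return CorrelationReport(stages=stages, keyword_table=kw_table,
                             assigned_stage=assigned, ambiguous=ambiguous)
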