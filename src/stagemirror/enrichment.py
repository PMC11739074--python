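"""Enrichment statistics: ORA, per-pathway Wilcoxon, preranked GSEA, and
the common-gene nuclear-term analysis.

Three significance conventions coexist deliberately and are preserved per
call site rather than unified:

* gene-ontology ORA uses a right-tail hypergeometric test with BH < 0.05;
* the per-pathway Wilcoxon table reports sets with unadjusted p < 0.05 and
  strictly more than 10 DEG members;
* the common-gene analysis uses unadjusted p < 0.05.

The Wilcoxon variant compares the log2FCs of in-set DEGs against
out-of-set DEGs (two-sample rank-sum); a one-sample signed-rank-vs-zero
mode exists behind ``mode="one_sample"`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ThresholdConfig
from .de import ConsensusDEGTable
from .errors import ValidationError
from .harmonize import GeneLevelStageProfile
from .stats import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed) with free-text descriptions."""

    sets: dict                      # name -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
        self.sets = {name: frozenset(m) for name, m in self.sets.items()}

    def __len__(self):
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def match_keywords(self, keywords) -> dict:
        """keyword -> list of set names matching by case-insensitive substring."""
        return {kw: [n for n in self.sets if kw.lower() in n.lower()]
                for kw in keywords}

    def restrict_to(self, universe) -> "GeneSetCollection":
        uni = frozenset(universe)
        kept = {n: m & uni for n, m in self.sets.items() if m & uni}
        return GeneSetCollection(sets=kept, descriptions=dict(self.descriptions))

    def filter_by_size(self, min_size: int, max_size: int) -> "GeneSetCollection":
        kept = {n: m for n, m in self.sets.items() if min_size <= len(m) <= max_size}
        return GeneSetCollection(sets=kept, descriptions=dict(self.descriptions))


# ---------------------------------------------------------------------------
# over-representation analysis


def ora(query, universe, collection: GeneSetCollection,
        alpha: float = 0.05, adjust: bool = True) -> pd.DataFrame:
    """Right-tail hypergeometric over-representation analysis.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set|, n=|query|);
    enrichment = (k/n)/(K/N).  Sets are intersected with the universe
    before testing.  With ``adjust`` the significance flag is BH < alpha,
    otherwise unadjusted p < alpha.
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query or not universe:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValidationError(f"query genes outside the universe: {extra[:10]}")
    n, big_n = len(query), len(universe)
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        if not inset:
            continue
        big_k = len(inset)
        k = len(inset & query)
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p": min(p, 1.0),
                     "enrichment": (k / n) / (big_k / big_n)})
    result = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "enrichment"])
    if result.empty:
        result["fdr"] = result["significant"] = []
        return result
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = (result["fdr"] if adjust else result["p"]) < alpha
    return result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-pathway Wilcoxon


def pathway_wilcoxon(deg_logfcs: pd.Series, collection: GeneSetCollection,
                     thresholds: ThresholdConfig | None = None,
                     mode: str = "two_sample") -> pd.DataFrame:
    """Wilcoxon test per pathway over the merged up+down DEG set.

    Only sets with strictly more than ``wilcoxon_min_genes`` DEG members
    are tested.  ``two_sample`` (default) is a rank-sum of in-set vs
    out-of-set DEG log2FCs; ``one_sample`` is a signed-rank of in-set
    log2FCs against zero.
    """
    thresholds = (thresholds or ThresholdConfig()).validate()
    if deg_logfcs.empty:
        raise ValidationError("the merged DEG set is empty")
    if mode not in ("two_sample", "one_sample"):
        raise ValidationError(f"unknown mode {mode!r}")
    rows = []
    for name, members in collection.sets.items():
        in_mask = deg_logfcs.index.isin(members)
        n_in = int(in_mask.sum())
        if n_in <= thresholds.wilcoxon_min_genes:
            continue
        x = deg_logfcs.to_numpy()[in_mask]
        if mode == "two_sample":
            y = deg_logfcs.to_numpy()[~in_mask]
            if len(y) == 0:
                continue
            method = "exact" if min(len(x), len(y)) <= 25 and \
                len(np.unique(np.concatenate([x, y]))) == len(x) + len(y) else "asymptotic"
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        else:
            if np.allclose(x, 0):
                p = 1.0
            else:
                p = float(sps.wilcoxon(x, alternative="two-sided").pvalue)
        rows.append({"set": name, "n_genes": n_in, "median_logfc": float(np.median(x)),
                     "p": p})
    result = pd.DataFrame(rows, columns=["set", "n_genes", "median_logfc", "p"])
    if result.empty:
        log.warning("no gene set has more than %d DEG members", thresholds.wilcoxon_min_genes)
        result["significant"] = []
        return result
    result["significant"] = result["p"] < thresholds.wilcoxon_alpha
    return result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(hits: np.ndarray, weights: np.ndarray):
    """Signed extreme of the weighted Kolmogorov–Smirnov running sum.

    ``hits`` is a boolean vector over the ranked gene list; ``weights``
    the (already exponentiated) ranking statistic magnitudes.
    Returns (es, index of the extreme position).
    """
    n = len(hits)
    nh = int(hits.sum())
    if nh == 0 or nh == n:
        return 0.0, 0
    wr = np.where(hits, weights, 0.0)
    total = wr.sum()
    if total == 0:  # all hit weights zero: fall back to unweighted hits
        wr = hits.astype(float)
        total = wr.sum()
    step = wr / total - (~hits) / (n - nh)
    cum = np.cumsum(step)
    i = int(np.argmax(np.abs(cum)))
    return float(cum[i]), i


def _rank_genes(ranked: pd.Series) -> pd.Series:
    """Descending by log2FC, ties broken by gene id (determinism)."""
    frame = ranked.rename("score").rename_axis("gene_id").reset_index()
    frame = frame.sort_values(["score", "gene_id"],
                              ascending=[False, True], kind="mergesort")
    return frame.set_index("gene_id")["score"]


@dataclass
class GSEAResult:
    table: pd.DataFrame          # set, size, es, nes, p
    leading_edges: dict          # set -> list of genes

    def top(self, n: int = 10) -> pd.DataFrame:
        """Top-n positive and top-n negative sets by NES."""
        t = self.table.dropna(subset=["nes"])
        up = t[t["nes"] > 0].nlargest(n, "nes")
        down = t[t["nes"] < 0].nsmallest(n, "nes")
        return pd.concat([up, down]).reset_index(drop=True)


def gsea_preranked(ranked: pd.Series, collection: GeneSetCollection,
                   min_size: int = 15, max_size: int = 500,
                   n_perm: int = 1000, seed: int = 0,
                   weight: float = 1.0) -> GSEAResult:
    """Preranked GSEA with the weighted running-sum statistic.

    Genes are ranked by log2FC (descending, ties by id); the enrichment
    score is the signed extreme of the running sum with hit increments
    proportional to |log2FC|**weight.  The null is a gene-label
    permutation (random same-size sets, seeded); p uses the add-one
    estimator over same-sign null scores and NES divides by the mean
    |null ES| of the same sign.
    """
    if n_perm < 100:
        log.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    scores = _rank_genes(ranked)
    order_genes = scores.index.to_numpy()
    weights = np.abs(scores.to_numpy()) ** weight
    n = len(order_genes)
    gene_pos = {g: i for i, g in enumerate(order_genes)}

    filtered = {name: members & frozenset(order_genes)
                for name, members in collection.sets.items()}
    filtered = {name: m for name, m in filtered.items()
                if min_size <= len(m) <= max_size}
    if not filtered:
        raise ValidationError(
            f"no gene set within [{min_size}, {max_size}] after intersection")

    rng = np.random.default_rng(seed)
    rows, edges = [], {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(filtered):
        members = filtered[name]
        hits = np.zeros(n, dtype=bool)
        hits[[gene_pos[g] for g in members]] = True
        es, i_ext = _running_es(hits, weights)

        nh = int(hits.sum())
        if nh not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                h = np.zeros(n, dtype=bool)
                h[rng.choice(n, size=nh, replace=False)] = True
                null[b], _ = _running_es(h, weights)
            null_cache[nh] = null
        null = null_cache[nh]
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        mean_same = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / mean_same if n_same and mean_same > 0 else np.nan

        hit_idx = np.flatnonzero(hits)
        if es >= 0:
            edge = order_genes[hit_idx[hit_idx <= i_ext]]
        else:
            edge = order_genes[hit_idx[hit_idx >= i_ext]]
        edges[name] = list(edge)
        rows.append({"set": name, "size": nh, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(rows).sort_values(
        ["p", "set"], kind="mergesort").reset_index(drop=True)
    return GSEAResult(table=table, leading_edges=edges)


# ---------------------------------------------------------------------------
# common genes between the cell model and a disease stage


@dataclass
class CommonGeneResult:
    common_up: list
    common_down: list
    ora_up: pd.DataFrame
    ora_down: pd.DataFrame


def common_gene_nuclear_ora(degs: ConsensusDEGTable, profile: GeneLevelStageProfile,
                            collection: GeneSetCollection, stage: str = "proAD",
                            thresholds: ThresholdConfig | None = None) -> CommonGeneResult:
    """Nuclear-term ORA on genes shared between the cell model and a stage.

    Common-up genes are consensus up-DEGs whose stage logFC exceeds +0.1
    (same direction); common-down symmetric.  Up and down lists are tested
    separately with unadjusted p < 0.05, then filtered to sets whose names
    contain a nuclear keyword (transcription, chromatin, chromosome,
    histone, DNA; case-insensitive).
    """
    thresholds = (thresholds or ThresholdConfig()).validate()
    stage_lfc = profile.stage_frame(stage)["logfc"]
    cut = thresholds.common_lfc

    def common(direction, cond):
        genes = degs.direction_set(direction)
        lfc = stage_lfc.reindex(genes).dropna()
        return sorted(lfc.index[cond(lfc)])

    common_up = common("up", lambda v: v > cut)
    common_down = common("down", lambda v: v < -cut)

    universe = frozenset(degs.universe)
    matches = collection.match_keywords(thresholds.nuclear_keywords)
    nuclear_names = sorted({n for names in matches.values() for n in names})
    nuclear = GeneSetCollection(
        sets={n: collection.sets[n] for n in nuclear_names},
        descriptions=dict(collection.descriptions)) if nuclear_names else None

    def run(genes):
        if not genes or nuclear is None:
            return pd.DataFrame(columns=["set", "k", "K", "n", "N", "p",
                                         "enrichment", "fdr", "significant",
                                         "log10_p"])
        res = ora(genes, universe, nuclear,
                  alpha=thresholds.ora_alpha, adjust=False)
        res["log10_p"] = np.log10(res["p"].clip(lower=1e-300))
        return res

    return CommonGeneResult(common_up=common_up, common_down=common_down,
                            ora_up=run(common_up), ora_down=run(common_down))
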