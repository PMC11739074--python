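"""Consensus differential expression on a two-condition count experiment.

The analysis normalizes raw counts to RPM/RPKM, runs several lightweight
differential-expression callers behind one registry interface, and calls a
gene a consensus DEG only when *every* caller reports FDR < 0.1 **and** the
consensus |log2FC| exceeds 0.5 — the intersection rule that defines the
DEG set for all downstream stages.

The built-in callers are deliberately simple, pluggable equivalents of the
heavyweight count-model packages:

``nb_exact``
    Negative-binomial conditional exact test with a pooled
    method-of-moments common dispersion (variance ``mu + phi*mu**2``).
``lognorm_t``
    Welch t-test on ``log2(RPM + 0.5)``.
``perm_mean``
    Permutation test on the difference of group means of
    ``log2(RPM + 0.5)``; exhaustive over all group relabelings when there
    are at most 10_000, otherwise 10_000 seeded Monte-Carlo draws.

External caller results (e.g. real edgeR/DESeq output re-imported as TSV)
can replace any built-in caller: `consensus_degs` only needs per-gene
(log2fc, pvalue, fdr) tables over a shared gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ThresholdConfig
from .errors import ValidationError
from .stats import bh_adjust

log = logging.getLogger(__name__)

LOG2FC_PSEUDOCOUNT = 0.5  # added to group-mean RPM before the log-ratio
PERM_MAX_EXACT = 10_000
PERM_N_DRAWS = 10_000


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-gene lengths and sample labels.

    ``condition`` must have exactly two levels for differential expression;
    ``reference`` names the baseline level (default: lexicographically
    first), so log2FC > 0 means higher expression in the non-reference
    condition.
    """

    counts: pd.DataFrame          # genes x samples, non-negative integers
    lengths_bp: pd.Series         # per gene, positive
    condition: pd.Series          # per sample
    reference: str | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if not self.counts.columns.equals(pd.Index(self.condition.index)):
            self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise ValidationError(f"samples without a condition label: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.lengths_bp.index.equals(self.counts.index):
            self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.lengths_bp.isna().any() or (self.lengths_bp <= 0).any():
            raise ValidationError("every gene needs a positive length_bp")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def condition_levels(self) -> tuple[str, str]:
        """(reference, treatment) pair; requires exactly two levels."""
        levels = sorted(self.condition.unique())
        if len(levels) != 2:
            raise ValidationError(f"expected exactly two condition levels, got {levels}")
        ref = self.reference if self.reference is not None else levels[0]
        if ref not in levels:
            raise ValidationError(f"reference level {ref!r} not among {levels}")
        trt = levels[1] if ref == levels[0] else levels[0]
        return ref, trt


@dataclass
class NormalizedMatrix:
    """RPM (reads per million) and RPKM (per kilobase per million)."""

    rpm: pd.DataFrame
    rpkm: pd.DataFrame


@dataclass
class DECallerResult:
    """Per-gene statistics from one caller: log2fc, pvalue, BH fdr."""

    caller_id: str
    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, fdr


@dataclass
class ConsensusDEGTable:
    """Per-gene consensus over callers.

    ``member`` is True iff FDR < fdr_deg in every caller and the consensus
    |log2FC| (mean over callers) exceeds lfc_deg; ``direction`` is the sign
    of the consensus log2FC for members, ``none`` otherwise.
    """

    table: pd.DataFrame  # index gene_id; consensus_log2fc, fdr_<caller>..., member, direction
    caller_ids: tuple
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)

    @property
    def members(self) -> pd.Index:
        return self.table.index[self.table["member"]]

    def direction_set(self, direction: str) -> pd.Index:
        return self.table.index[self.table["direction"] == direction]

    @property
    def universe(self) -> pd.Index:
        return self.table.index


# ---------------------------------------------------------------------------
# normalization


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """RPM and RPKM normalization.

    rpm[g,s]  = counts[g,s] * 1e6 / colsum(s)
    rpkm[g,s] = rpm[g,s] * 1e3 / length_bp(g)
    """
    colsum = cm.counts.sum(axis=0)
    zero = colsum.index[colsum == 0].tolist()
    if zero:
        raise ValidationError(f"zero column sum in sample(s) {zero}")
    rpm = cm.counts * 1e6 / colsum
    rpkm = rpm.mul(1e3 / cm.lengths_bp, axis=0)
    return NormalizedMatrix(rpm=rpm.astype(float), rpkm=rpkm.astype(float))


def _group_masks(cm: CountMatrix) -> tuple[np.ndarray, np.ndarray]:
    ref, trt = cm.condition_levels()
    a = (cm.condition == ref).to_numpy()
    b = (cm.condition == trt).to_numpy()
    if a.sum() < 2 or b.sum() < 2:
        raise ValidationError("each condition needs at least 2 samples")
    return a, b


def _log2fc(cm: CountMatrix) -> np.ndarray:
    """Shared log2FC estimator: pseudocount-stabilized ratio of mean RPM."""
    rpm = normalize(cm).rpm.to_numpy()
    a, b = _group_masks(cm)
    mean_ref = rpm[:, a].mean(axis=1)
    mean_trt = rpm[:, b].mean(axis=1)
    return np.log2((mean_trt + LOG2FC_PSEUDOCOUNT) / (mean_ref + LOG2FC_PSEUDOCOUNT))


# ---------------------------------------------------------------------------
# callers


def _caller_lognorm_t(cm: CountMatrix, seed=None) -> pd.DataFrame:
    x = np.log2(normalize(cm).rpm.to_numpy() + LOG2FC_PSEUDOCOUNT)
    a, b = _group_masks(cm)
    res = sps.ttest_ind(x[:, b], x[:, a], axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance genes: t is 0/0; identical groups are null by definition
    mean_eq = np.isclose(x[:, b].mean(axis=1), x[:, a].mean(axis=1))
    p = np.where(np.isnan(p), np.where(mean_eq, 1.0, 0.0), p)
    return pd.DataFrame({"log2fc": _log2fc(cm), "pvalue": p}, index=cm.gene_ids)


def _perm_labelings(n: int, n_b: int, rng: np.random.Generator | None):
    """0/1 matrix of group-B membership, exhaustive or Monte-Carlo."""
    from math import comb

    if comb(n, n_b) <= PERM_MAX_EXACT:
        rows = [np.isin(np.arange(n), idx) for idx in combinations(range(n), n_b)]
        return np.array(rows, dtype=float), True
    if rng is None:
        rng = np.random.default_rng(0)
    rows = np.zeros((PERM_N_DRAWS, n))
    for i in range(PERM_N_DRAWS):
        rows[i, rng.choice(n, size=n_b, replace=False)] = 1.0
    return rows, False


def _caller_perm_mean(cm: CountMatrix, seed=None) -> pd.DataFrame:
    x = np.log2(normalize(cm).rpm.to_numpy() + LOG2FC_PSEUDOCOUNT)
    a, b = _group_masks(cm)
    n = x.shape[1]
    rng = np.random.default_rng(seed if seed is not None else 0)
    mask_b, exhaustive = _perm_labelings(n, int(b.sum()), rng)
    mask_a = 1.0 - mask_b
    # L x genes matrix of permuted statistics
    stat = (mask_b @ x.T) / b.sum() - (mask_a @ x.T) / a.sum()
    obs = x[:, b].mean(axis=1) - x[:, a].mean(axis=1)
    extreme = np.abs(stat) >= np.abs(obs)[None, :] - 1e-12
    if exhaustive:
        p = extreme.mean(axis=0)  # observed labeling is one of the rows
    else:
        p = (1.0 + extreme.sum(axis=0)) / (stat.shape[0] + 1.0)
    return pd.DataFrame({"log2fc": _log2fc(cm), "pvalue": p}, index=cm.gene_ids)


def _common_dispersion(counts: np.ndarray, sf: np.ndarray, groups) -> float:
    """Pooled method-of-moments dispersion for var = mu + phi*mu^2.

    On size-factor-normalized counts z = K/s, Var(z) = mu*mean(1/s) + phi*mu^2
    within a group; phi is averaged over well-expressed genes and both groups.
    """
    ests = []
    for g in groups:
        z = counts[:, g] / sf[g]
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        c = np.mean(1.0 / sf[g])
        ok = m > 1
        if ok.any():
            ests.append((v[ok] - m[ok] * c) / m[ok] ** 2)
    if not ests:
        return 1e-8
    phi = float(np.mean(np.concatenate(ests)))
    return max(phi, 1e-8)


def _nb_cond_exact_p(k_a: int, k: int, mu_a: float, mu_b: float,
                     phi_a: float, phi_b: float) -> float:
    """Two-sided conditional exact NB p-value.

    Conditions on the total k = k_a + k_b; sums the probabilities of all
    splits no more likely than the observed one.
    """
    if k == 0:
        return 1.0
    # restrict to a window around the conditional mean for large totals
    if k > 20_000:
        frac = mu_a / (mu_a + mu_b)
        center = k * frac
        sd = np.sqrt(k * frac * (1 - frac) * 10)  # generous overdispersion margin
        lo = int(max(0, min(center - 40 * sd, k_a - 5)))
        hi = int(min(k, max(center + 40 * sd, k_a + 5)))
    else:
        lo, hi = 0, k
    a = np.arange(lo, hi + 1)
    n_a, n_b = 1.0 / phi_a, 1.0 / phi_b
    pa = n_a / (n_a + mu_a)
    pb = n_b / (n_b + mu_b)
    probs = sps.nbinom.pmf(a, n_a, pa) * sps.nbinom.pmf(k - a, n_b, pb)
    total = probs.sum()
    if total <= 0:
        return 1.0
    p_obs = probs[k_a - lo]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-10)].sum() / total))


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (composition-robust), mean-scaled to 1.

    Falls back to library-size ratios when too few genes are expressed in
    every sample for the gene-wise geometric reference.
    """
    every = (counts > 0).all(axis=1)
    if every.sum() >= 50:
        logc = np.log(counts[every])
        ref = logc.mean(axis=1, keepdims=True)  # log geometric mean per gene
        sf = np.exp(np.median(logc - ref, axis=0))
    else:
        sf = counts.sum(axis=0)
    return sf / sf.mean()


def _caller_nb_exact(cm: CountMatrix, seed=None) -> pd.DataFrame:
    counts = cm.counts.to_numpy(dtype=float)
    colsum = counts.sum(axis=0)
    if (colsum == 0).any():
        raise ValidationError("zero column sum")
    sf = _size_factors(counts)
    a, b = _group_masks(cm)
    phi = _common_dispersion(counts, sf, (a, b))
    k_a = counts[:, a].sum(axis=1)
    k_b = counts[:, b].sum(axis=1)
    s_a, s_b = sf[a].sum(), sf[b].sum()
    q = (k_a + k_b) / (s_a + s_b)
    mu_a, mu_b = q * s_a, q * s_b
    # dispersion of a sum of per-sample NBs sharing phi
    phi_a = phi * (sf[a] ** 2).sum() / s_a**2
    phi_b = phi * (sf[b] ** 2).sum() / s_b**2
    k_tot = (k_a + k_b).astype(int)
    p = np.ones(len(counts))
    for i in range(len(counts)):
        if k_tot[i] > 0:
            p[i] = _nb_cond_exact_p(int(round(k_a[i])), k_tot[i],
                                    mu_a[i], mu_b[i], phi_a, phi_b)
    return pd.DataFrame({"log2fc": _log2fc(cm), "pvalue": p}, index=cm.gene_ids)


CALLERS = {
    "nb_exact": _caller_nb_exact,
    "lognorm_t": _caller_lognorm_t,
    "perm_mean": _caller_perm_mean,
}


def run_caller(cm: CountMatrix, caller_id: str, seed: int | None = None) -> DECallerResult:
    """Run one registered caller; FDR is BH over all genes."""
    if caller_id not in CALLERS:
        raise ValidationError(
            f"unknown caller {caller_id!r}; registered callers: {sorted(CALLERS)}")
    table = CALLERS[caller_id](cm, seed=seed)
    table = table.copy()
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())
    return DECallerResult(caller_id=caller_id, table=table)


# ---------------------------------------------------------------------------
# consensus


def consensus_degs(results: list[DECallerResult],
                   thresholds: ThresholdConfig | None = None) -> ConsensusDEGTable:
    """Intersection consensus: FDR < threshold in EVERY caller and
    consensus |log2FC| (mean of caller log2FCs) above the fold-change cut."""
    if not results:
        raise ValidationError("at least one caller result is required")
    thresholds = (thresholds or ThresholdConfig()).validate()
    universe = results[0].table.index
    for res in results[1:]:
        if not res.table.index.equals(universe):
            missing = universe.symmetric_difference(res.table.index).tolist()
            raise ValidationError(
                f"caller {res.caller_id!r} covers a different gene universe; "
                f"mismatched genes: {missing[:10]}")
    lfc = np.mean([r.table["log2fc"].to_numpy() for r in results], axis=0)
    fdr_cols = {f"fdr_{r.caller_id}": r.table["fdr"].to_numpy() for r in results}
    max_fdr = np.max(np.stack(list(fdr_cols.values())), axis=0)
    member = (max_fdr < thresholds.fdr_deg) & (np.abs(lfc) > thresholds.lfc_deg)
    direction = np.where(member, np.where(lfc > 0, "up", "down"), "none")
    table = pd.DataFrame({"consensus_log2fc": lfc, **fdr_cols,
                          "member": member, "direction": direction}, index=universe)
    return ConsensusDEGTable(table=table,
                             caller_ids=tuple(r.caller_id for r in results),
                             thresholds=thresholds)


def volcano_table(degs: ConsensusDEGTable) -> pd.DataFrame:
    """Plot-ready volcano table: log2FC against -log10 of the worst FDR."""
    fdr_cols = [c for c in degs.table.columns if c.startswith("fdr_")]
    worst = degs.table[fdr_cols].max(axis=1)
    return pd.DataFrame({
        "log2fc": degs.table["consensus_log2fc"],
        "neg_log10_fdr": -np.log10(worst.clip(lower=1e-300)),
        "member": degs.table["member"],
    })


# ---------------------------------------------------------------------------
# PCA on most-variant genes


def top_variant_pca(norm: NormalizedMatrix, k: int = 300):
    """Top-k most variant genes (on log2(RPM+1)) and PCA sample coordinates.

    Variance ties are broken by gene id for determinism; each principal
    component's sign is fixed so its largest-|loading| gene loads positive.

    Returns
    -------
    (genes, coords, explained) : selected gene ids, sample x PC coordinate
    DataFrame, and the explained-variance ratio per component.
    """
    if k < 2:
        raise ValidationError("k must be at least 2")
    x = np.log2(norm.rpm + 1.0)
    if x.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if k > x.shape[0]:
        log.warning("k=%d exceeds the %d-gene universe; using all genes", k, x.shape[0])
        k = x.shape[0]
    variances = x.var(axis=1, ddof=1)
    # stable sort of the id-sorted series => variance ties break by gene id
    genes = variances.sort_index().sort_values(
        ascending=False, kind="mergesort").index[:k]
    mat = x.loc[genes].to_numpy().T  # samples x genes
    mat = mat - mat.mean(axis=0)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    # deterministic sign: largest-|loading| gene positive on each PC
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    coords = pd.DataFrame(u * s, index=norm.rpm.columns,
                          columns=[f"PC{j + 1}" for j in range(len(s))])
    denom = (s**2).sum()
    explained = s**2 / denom if denom > 0 else np.zeros_like(s)
    return genes, coords, explained
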