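"""Tri-state histone-acetylation concordance and its overlap with DEGs.

Each acetylation dataset calls a subset of genes 'up' or 'down'.  Across
datasets a gene is classified

* ``down``     — every dataset reporting a change calls it down,
* ``up``       — every dataset reporting a change calls it up,
* ``any``      — at least two datasets disagree on the direction,
* ``uncalled`` — no dataset reports a change.

Absence from a dataset never breaks concordance: only datasets reporting
a change count.  The classes are intersected with the DEG direction sets
as exclusive intersections (upset-style counts that partition each DEG
direction set), and over-representation of each (direction x class) pair
is tested against a genome-wide universe with a right-tail hypergeometric
test, BH-adjusted across the tested pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import ConsensusDEGTable
from .errors import ValidationError
from .stats import bh_adjust

DIRECTIONS = ("up", "down")
CLASSES = ("down", "up", "any", "uncalled")


@dataclass
class AcetylationCallTable:
    """Per-dataset gene -> acetylation-direction calls."""

    dataset_id: str
    calls: pd.Series              # gene_id -> 'up' | 'down'
    mark: str = ""                # free text, e.g. 'H3K27ac'

    def __post_init__(self):
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"dataset {self.dataset_id!r}: multiple calls for gene(s) {dups[:5]}")
        bad = self.calls[~self.calls.isin(DIRECTIONS)]
        if len(bad):
            gene, val = bad.index[0], bad.iloc[0]
            raise ValidationError(
                f"dataset {self.dataset_id!r}, gene {gene!r}: "
                f"direction {val!r} not in {DIRECTIONS}")


@dataclass
class ConcordanceClassification:
    """Per-gene tri-state class with supporting dataset ids.

    Only genes called in at least one dataset appear in ``classes``;
    :meth:`lookup` returns ``uncalled`` for anything else.
    """

    classes: pd.Series            # gene_id -> 'down' | 'up' | 'any'
    support: dict                 # gene_id -> tuple of dataset ids

    def lookup(self, genes) -> pd.Series:
        out = self.classes.reindex(pd.Index(genes))
        return out.fillna("uncalled")

    def class_sizes(self) -> dict:
        counts = self.classes.value_counts()
        return {c: int(counts.get(c, 0)) for c in ("down", "up", "any")}


def classify_concordance(tables: list[AcetylationCallTable]) -> ConcordanceClassification:
    """Classify genes by acetylation-direction concordance across datasets."""
    if not tables:
        raise ValidationError("at least one acetylation call table is required")
    ids = [t.dataset_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate dataset ids: {ids}")
    calls = pd.DataFrame({t.dataset_id: t.calls for t in tables})
    calls = calls.dropna(how="all")
    has_up = (calls == "up").any(axis=1)
    has_down = (calls == "down").any(axis=1)
    cls = np.where(has_up & has_down, "any", np.where(has_up, "up", "down"))
    classes = pd.Series(cls, index=calls.index).sort_index()
    support = {gene: tuple(calls.columns[calls.loc[gene].notna()])
               for gene in classes.index}
    return ConcordanceClassification(classes=classes, support=support)


def upset_intersections(classification: ConcordanceClassification,
                        degs: ConsensusDEGTable) -> pd.DataFrame:
    """Exclusive-intersection counts of DEG directions vs acetylation class.

    For each DEG direction the four classes (down/up/any/uncalled)
    partition the direction set; percentages are over that direction's
    total and sum to 100.
    """
    rows = []
    for direction in DIRECTIONS:
        genes = degs.direction_set(direction)
        total = len(genes)
        cls = classification.lookup(genes)
        for c in CLASSES:
            count = int((cls == c).sum())
            rows.append({"deg_direction": direction, "acetylation_class": c,
                         "count": count,
                         "pct_of_degs": 100.0 * count / total if total else np.nan})
    return pd.DataFrame(rows)


def overrepresentation(classification: ConcordanceClassification,
                       degs: ConsensusDEGTable, universe=None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each (direction x class) pair.

    For DEG direction d (query, size n) and acetylation class c (size K in
    the universe, size N): k = overlap, p = P(X >= k), enrichment =
    (k/n)/(K/N); BH across all tested pairs.  The universe defaults to the
    DE-tested gene universe (the genome-wide baseline of the analysis).
    """
    universe = pd.Index(universe) if universe is not None else degs.universe
    if universe.has_duplicates:
        raise ValidationError("universe contains duplicate gene ids")
    uni = frozenset(universe)
    stray = [g for g in degs.universe if g not in uni]
    if stray:
        raise ValidationError(f"DEG genes outside the universe: {stray[:10]}")
    stray = [g for g in classification.classes.index if g not in uni]
    if stray:
        raise ValidationError(f"classified genes outside the universe: {stray[:10]}")
    big_n = len(uni)
    cls_all = classification.lookup(universe)
    rows = []
    for direction in DIRECTIONS:
        genes = degs.direction_set(direction)
        n = len(genes)
        cls_deg = classification.lookup(genes)
        for c in ("down", "up", "any"):
            big_k = int((cls_all == c).sum())
            k = int((cls_deg == c).sum())
            p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n)) if n and big_k else 1.0
            enrichment = ((k / n) / (big_k / big_n)) if n and big_k else 0.0
            rows.append({"deg_direction": direction, "acetylation_class": c,
                         "overlap": k, "n_degs": n, "class_size": big_k,
                         "universe_size": big_n,
                         "pct_of_degs": 100.0 * k / n if n else np.nan,
                         "enrichment": enrichment, "p": min(p, 1.0)})
    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    result["significant"] = result["fdr"] < alpha
    return result
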