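from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from conftest import make_deg_table, make_stage_profile
from stagemirror import (GeneSetCollection, ThresholdConfig,
                         common_gene_nuclear_ora, gsea_preranked, ora,
                         pathway_wilcoxon)
from stagemirror.errors import ValidationError


def enumeration_ora_p(universe, geneset, query):
    """Independent right-tail oracle: enumerate all C(N, n) draws of |query|
    genes from the universe and count draws overlapping the set at least as
    much as the observed query."""
    universe, geneset, query = list(universe), set(geneset), set(query)
    k_obs = len(geneset & query)
    hits = total = 0
    for draw in combinations(universe, len(query)):
        total += 1
        if len(geneset & set(draw)) >= k_obs:
            hits += 1
    return hits / total


def brute_force_es(ranked_scores, hits, weight=1.0):
    """O(N) loop oracle for the weighted running-sum enrichment score."""
    scores = np.abs(np.asarray(ranked_scores, dtype=float)) ** weight
    nr = scores[hits].sum()
    n, nh = len(scores), int(np.sum(hits))
    cum, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            cum += scores[i] / nr
        else:
            cum -= 1.0 / (n - nh)
        if abs(cum) > abs(best):
            best = cum
    return best


# ---------------------------------------------------------------------------
# ORA


def test_ora_worked_case_matches_enumeration():
    universe = [f"g{i}" for i in range(10)]
    geneset = universe[:3]                       # K = 3
    query = universe[1:5]                        # n = 4, overlap k = 2
    col = GeneSetCollection(sets={"S": frozenset(geneset)})
    res = ora(query, universe, col)
    assert res.loc[0, "k"] == 2
    assert res.loc[0, "p"] == pytest.approx(1 / 3, abs=1e-12)
    assert res.loc[0, "p"] == pytest.approx(
        enumeration_ora_p(universe, geneset, query), abs=1e-12)


def test_ora_degenerate_cases():
    universe = [f"g{i}" for i in range(8)]
    col = GeneSetCollection(sets={"S": frozenset(universe[:3])})
    # no overlap -> p = 1
    res = ora(universe[3:5], universe, col)
    assert res.loc[0, "k"] == 0 and res.loc[0, "p"] == pytest.approx(1.0)
    assert res.loc[0, "enrichment"] == 0.0
    # query = universe -> k = K, p = 1
    res = ora(universe, universe, col)
    assert res.loc[0, "p"] == pytest.approx(1.0)


def test_ora_p_monotone_in_overlap():
    universe = [f"g{i}" for i in range(20)]
    col = GeneSetCollection(sets={"S": frozenset(universe[:8])})
    ps = []
    for k in range(5):
        query = universe[:k] + universe[8:8 + (5 - k)]  # size 5, overlap k
        ps.append(ora(query, universe, col).loc[0, "p"])
    assert all(np.diff(ps) <= 1e-12)


def test_ora_validation():
    with pytest.raises(ValidationError):
        ora([], ["g1"], GeneSetCollection(sets={"S": frozenset(["g1"])}))
    with pytest.raises(ValidationError, match="outside"):
        ora(["gX"], ["g1"], GeneSetCollection(sets={"S": frozenset(["g1"])}))


# ---------------------------------------------------------------------------
# per-pathway Wilcoxon


def _deg_lfcs(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(0, 1, n), index=[f"g{i:03d}" for i in range(n)])


def test_sets_at_the_size_threshold_are_omitted():
    lfcs = _deg_lfcs()
    col = GeneSetCollection(sets={
        "TEN": frozenset(lfcs.index[:10]),      # exactly 10 -> omitted
        "ELEVEN": frozenset(lfcs.index[:11]),   # strictly more -> kept
    })
    res = pathway_wilcoxon(lfcs, col)
    assert set(res["set"]) == {"ELEVEN"}


def test_null_pathway_pvalues_are_uniform():
    rng = np.random.default_rng(1)
    ps = []
    for rep in range(200):
        lfcs = pd.Series(rng.normal(0, 1, 120),
                         index=[f"g{i:03d}" for i in range(120)])
        members = rng.choice(lfcs.index, 20, replace=False)
        col = GeneSetCollection(sets={"S": frozenset(members)})
        ps.append(pathway_wilcoxon(lfcs, col).loc[0, "p"])
    assert np.mean(ps) == pytest.approx(0.5, abs=0.06)


def test_shifted_pathway_is_detected():
    rng = np.random.default_rng(2)
    detected = 0
    for rep in range(100):
        lfcs = pd.Series(rng.normal(0, 1, 230),
                         index=[f"g{i:03d}" for i in range(230)])
        members = lfcs.index[:30]
        lfcs[members] += 1.0
        col = GeneSetCollection(sets={"S": frozenset(members)})
        res = pathway_wilcoxon(lfcs, col)
        detected += int(res.loc[0, "p"] < 0.05)
    assert detected >= 95


def test_rank_statistic_is_monotone_transform_invariant():
    lfcs = _deg_lfcs(80, seed=3)
    col = GeneSetCollection(sets={"S": frozenset(lfcs.index[:20])})
    p1 = pathway_wilcoxon(lfcs, col).loc[0, "p"]
    p2 = pathway_wilcoxon(np.exp(lfcs) - 5, col).loc[0, "p"]  # strictly monotone
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_all_sets_too_small_yields_empty_result():
    lfcs = _deg_lfcs(30)
    col = GeneSetCollection(sets={"S": frozenset(lfcs.index[:5])})
    assert pathway_wilcoxon(lfcs, col).empty


# ---------------------------------------------------------------------------
# GSEA


def test_singleton_at_top_scores_one():
    genes = [f"g{i:03d}" for i in range(50)]
    ranked = pd.Series(np.linspace(3, -3, 50), index=genes)
    col = GeneSetCollection(sets={"TOP": frozenset([genes[0]])})
    res = gsea_preranked(ranked, col, min_size=1, max_size=500,
                         n_perm=200, seed=0)
    assert res.table.loc[0, "es"] == pytest.approx(1.0)
    assert res.leading_edges["TOP"] == [genes[0]]


def test_streaming_es_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(4)
    for rep in range(50):
        n = int(rng.integers(30, 150))
        genes = [f"g{i:04d}" for i in range(n)]
        scores = rng.normal(0, 2, n)
        ranked = pd.Series(scores, index=genes)
        size = int(rng.integers(3, max(4, n // 4)))
        members = rng.choice(genes, size, replace=False)
        col = GeneSetCollection(sets={"S": frozenset(members)})
        res = gsea_preranked(ranked, col, min_size=1, max_size=500,
                             n_perm=100, seed=rep)
        order = ranked.rename("s").rename_axis("g").reset_index() \
            .sort_values(["s", "g"], ascending=[False, True])
        hits = order["g"].isin(set(members)).to_numpy()
        expected = brute_force_es(order["s"].to_numpy(), hits)
        assert res.table.loc[0, "es"] == pytest.approx(expected, abs=1e-12)


def test_permutation_p_respects_add_one_bounds():
    rng = np.random.default_rng(5)
    genes = [f"g{i:03d}" for i in range(100)]
    ranked = pd.Series(rng.normal(0, 1, 100), index=genes)
    col = GeneSetCollection(sets={
        "A": frozenset(genes[:20]), "B": frozenset(rng.choice(genes, 25, replace=False))})
    res = gsea_preranked(ranked, col, min_size=1, max_size=500,
                         n_perm=199, seed=1)
    assert (res.table["p"] >= 1 / 200 - 1e-12).all()
    assert (res.table["p"] <= 1.0).all()


def test_es_invariant_under_positive_scaling():
    rng = np.random.default_rng(6)
    genes = [f"g{i:03d}" for i in range(60)]
    ranked = pd.Series(rng.normal(0, 1, 60), index=genes)
    col = GeneSetCollection(sets={"S": frozenset(genes[5:25])})
    a = gsea_preranked(ranked, col, min_size=1, max_size=500, n_perm=100, seed=0)
    b = gsea_preranked(ranked * 3.5, col, min_size=1, max_size=500,
                       n_perm=100, seed=0)
    assert a.table.loc[0, "es"] == pytest.approx(b.table.loc[0, "es"], abs=1e-12)


def test_size_filter_and_empty_collection_error():
    genes = [f"g{i:03d}" for i in range(40)]
    ranked = pd.Series(np.arange(40, dtype=float), index=genes)
    col = GeneSetCollection(sets={"SMALL": frozenset(genes[:5])})
    with pytest.raises(ValidationError):
        gsea_preranked(ranked, col, min_size=15, max_size=500, n_perm=100)


# ---------------------------------------------------------------------------
# common-gene nuclear ORA


def test_common_gene_direction_and_threshold_rules():
    cell = pd.Series({"gU1": 1.0, "gU2": 0.9, "gU3": 0.8, "gD1": -1.0,
                      "gN": 0.1})
    degs = make_deg_table(cell)
    profile = make_stage_profile({"proAD": pd.Series(
        {"gU1": 0.15, "gU2": 0.05, "gU3": -0.4, "gD1": -0.2, "gN": 0.5})})
    sets = GeneSetCollection(sets={
        "GO_CHROMATIN_REMODELING": frozenset(["gU1", "gD1"]),
        "GO_LIPID_METABOLISM": frozenset(["gU2", "gU3"]),
    })
    result = common_gene_nuclear_ora(degs, profile, sets, stage="proAD")
    # +0.15 passes |logFC| > 0.1 same-direction; +0.05 and -0.4 do not
    assert result.common_up == ["gU1"]
    assert result.common_down == ["gD1"]
    # only nuclear-keyword sets are reported
    assert set(result.ora_up["set"]) <= {"GO_CHROMATIN_REMODELING"}


def test_common_gene_missing_stage_raises():
    cell = pd.Series({"g1": 1.0, "g2": -1.0})
    degs = make_deg_table(cell)
    profile = make_stage_profile({"posAD": pd.Series({"g1": 0.5, "g2": -0.5})})
    sets = GeneSetCollection(sets={"GO_DNA_REPAIR": frozenset(["g1"])})
    with pytest.raises(ValidationError, match="proAD"):
        common_gene_nuclear_ora(degs, profile, sets, stage="proAD")


def test_planted_enriched_sets_recovered_end_to_end(small_experiment):
    from stagemirror import simulate_geneset_collection
    _, truth = small_experiment
    col = simulate_geneset_collection(truth.universe, n_sets=60,
                                      size_range=(15, 50), n_enriched=5,
                                      truth=truth, seed=77)
    res = ora(list(truth.de_genes), truth.universe, col, alpha=0.05)
    sig = set(res.loc[res["significant"], "set"])
    recovered = len(sig & set(truth.enriched_sets)) / len(truth.enriched_sets)
    assert recovered >= 0.8
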