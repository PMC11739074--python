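from itertools import product

import numpy as np
import pandas as pd
import pytest

from stagemirror import (SimulationConfig, StageCorrSpec,
                         classify_concordance, normalize, ora,
                         simulate_acetylation_datasets,
                         simulate_count_experiment,
                         simulate_geneset_collection, simulate_staged_cohort)
from stagemirror.errors import ConfigError, GenerationError, ValidationError


# ---------------------------------------------------------------------------
# count experiment


def test_identical_seed_gives_identical_experiment():
    cfg = SimulationConfig(n_genes=200, n_per_group=4, seed=7)
    cm1, t1 = simulate_count_experiment(cfg)
    cm2, t2 = simulate_count_experiment(cfg)
    assert cm1.counts.equals(cm2.counts)
    assert cm1.lengths_bp.equals(cm2.lengths_bp)
    assert t1.de_lfc.equals(t2.de_lfc)


def test_null_simulation_has_no_planted_genes():
    cfg = SimulationConfig(n_genes=300, n_per_group=5, frac_de=0.0, seed=3)
    cm, truth = simulate_count_experiment(cfg)
    assert len(truth.de_genes) == 0
    # group means differ only by sampling noise: median |log2 ratio| is small
    rpm = normalize(cm).rpm.to_numpy()
    lfc = np.log2((rpm[:, 5:].mean(1) + 0.5) / (rpm[:, :5].mean(1) + 0.5))
    assert abs(np.median(lfc)) < 0.2


def test_planted_up_genes_average_the_requested_log2fc():
    """Monte-Carlo self-consistency: mean observed log2FC of planted
    up-genes within +/-0.3 of +2 across 10 seeds."""
    means = []
    for seed in range(10):
        cfg = SimulationConfig(n_genes=2000, n_per_group=6, lfc_magnitude=2.0,
                               nb_dispersion=0.05, seed=seed)
        cm, truth = simulate_count_experiment(cfg)
        rpm = normalize(cm).rpm
        up = truth.de_lfc.index[truth.de_lfc > 0]
        obs = np.log2((rpm.loc[up].iloc[:, 6:].mean(1) + 0.5)
                      / (rpm.loc[up].iloc[:, :6].mean(1) + 0.5))
        means.append(float(obs.mean()))
    assert abs(np.mean(means) - 2.0) < 0.3


@pytest.mark.parametrize("field,kwargs", [
    ("n_genes", {"n_genes": 0}),
    ("frac_de", {"frac_de": 1.2}),
    ("frac_de", {"n_genes": 5, "frac_de": 0.01}),   # frac_de*n_genes < 1
    ("nb_dispersion", {"nb_dispersion": 0.0}),
    ("gene_length_range", {"gene_length_range": (500, 100)}),
])
def test_invalid_config_names_the_field(field, kwargs):
    with pytest.raises(ConfigError) as err:
        SimulationConfig(**kwargs).validate()
    assert err.value.field == field


# ---------------------------------------------------------------------------
# staged cohort


def test_planted_stage_correlations_are_exact_at_the_expected_level(small_experiment):
    _, truth = small_experiment
    spec = StageCorrSpec()
    _, _, truth = simulate_staged_cohort(truth, spec, seed=5)
    de = truth.de_genes
    t = truth.de_lfc.to_numpy()
    for stage, target in spec.target_r.items():
        z = truth.stage_lfc.loc[de, stage].to_numpy()
        assert np.corrcoef(z, t)[0, 1] == pytest.approx(target, abs=1e-6)
        assert truth.stage_r[stage] == pytest.approx(target, abs=1e-6)


def test_perfect_target_makes_stage_lfc_proportional_to_truth(small_experiment):
    _, truth = small_experiment
    spec = StageCorrSpec(target_r={"posAD": 1.0, "proAD": 0.5, "defAD": 0.0})
    _, _, truth = simulate_staged_cohort(truth, spec, seed=6)
    de = truth.de_genes
    z = truth.stage_lfc.loc[de, "posAD"].to_numpy()
    t = truth.de_lfc.to_numpy()
    assert np.corrcoef(z, t)[0, 1] == pytest.approx(1.0, abs=1e-9)


def test_no_discordant_genes_means_no_flipped_probes(small_experiment):
    _, truth = small_experiment
    spec = StageCorrSpec(frac_discordant_genes=0.0)
    expr, pmap, truth = simulate_staged_cohort(truth, spec, seed=8)
    assert truth.discordant_genes == []
    # every probe of a gene shares the planted per-stage sign
    merged = pmap.table.copy()
    for stage in ("posAD", "proAD", "defAD"):
        eff = truth.stage_lfc[stage]
        # probes inherit the gene effect exactly -> no opposite signs possible
        assert eff.reindex(merged["gene_id"]).notna().all()


def test_probe_map_covers_every_probe(small_cohort):
    expr, pmap, truth = small_cohort
    assert set(expr.expression.index) == set(pmap.table.index)
    assert pmap.table["gene_id"].notna().all()
    assert set(pmap.table["gene_id"]) <= set(truth.universe)


def test_staged_cohort_determinism(small_experiment):
    _, truth = small_experiment
    spec = StageCorrSpec(n_samples_per_stage={s: 5 for s in spec_stages()})
    e1, m1, _ = simulate_staged_cohort(truth, spec, seed=11)
    e2, m2, _ = simulate_staged_cohort(truth, spec, seed=11)
    assert e1.expression.equals(e2.expression)
    assert m1.table.equals(m2.table)


def spec_stages():
    return ("normal", "posAD", "proAD", "defAD")


def test_degenerate_truth_raises_generation_error():
    from stagemirror.synth import SyntheticTruth
    truth = SyntheticTruth(universe=["g0", "g1", "g2"],
                           de_lfc=pd.Series({"g0": 2.0, "g1": 2.0}))
    with pytest.raises(GenerationError):
        simulate_staged_cohort(truth, StageCorrSpec(), seed=0)


# ---------------------------------------------------------------------------
# gene sets


def test_geneset_sizes_and_planted_enrichment(small_experiment):
    _, truth = small_experiment
    col = simulate_geneset_collection(truth.universe, n_sets=40,
                                      size_range=(15, 40), n_enriched=3,
                                      truth=truth, seed=4)
    sizes = [len(m) for m in col.sets.values()]
    assert all(15 <= s <= 40 for s in sizes)
    assert len(truth.enriched_sets) == 3
    # planted sets are recoverable by ORA on the true DE genes
    res = ora(list(truth.de_genes), truth.universe, col, alpha=0.05)
    sig = set(res.loc[res["significant"], "set"])
    assert set(truth.enriched_sets) <= sig


def test_null_collection_shows_no_systematic_enrichment(small_experiment):
    _, truth = small_experiment
    col = simulate_geneset_collection(truth.universe, n_sets=40,
                                      size_range=(10, 30), n_enriched=0,
                                      truth=truth, seed=9)
    res = ora(list(truth.de_genes), truth.universe, col, alpha=0.05)
    assert int(res["significant"].sum()) <= 2  # chance level at BH 0.05


def test_keyworded_names_appear(small_experiment):
    _, truth = small_experiment
    col = simulate_geneset_collection(truth.universe, n_sets=20,
                                      size_range=(5, 10), n_enriched=0,
                                      truth=truth, keywords=("Histone",),
                                      keyword_frac=0.5, seed=2)
    matches = col.match_keywords(("Histone",))
    assert len(matches["Histone"]) == 10


def test_geneset_argument_validation(small_experiment):
    _, truth = small_experiment
    with pytest.raises(ValidationError):
        simulate_geneset_collection(truth.universe, n_sets=2, size_range=(5, 10),
                                    n_enriched=3, truth=truth)
    with pytest.raises(ConfigError):
        simulate_geneset_collection(truth.universe, n_sets=2,
                                    size_range=(1, 10), n_enriched=0, truth=truth)


# ---------------------------------------------------------------------------
# acetylation datasets


def test_perfect_concordance_and_full_coverage(small_experiment):
    _, truth = small_experiment
    tables = simulate_acetylation_datasets(truth, n_datasets=3, coverage=1.0,
                                           concordance_prob=1.0, seed=5)
    classes = classify_concordance(tables)
    for gene in truth.de_genes:
        want = truth.direction(gene)
        for t in tables:
            assert t.calls[gene] == want
        assert classes.classes[gene] == want
    # no DE gene can be discordant
    de_classes = classes.lookup(truth.de_genes)
    assert (de_classes != "any").all()


def test_single_dataset_never_produces_any_class(small_experiment):
    _, truth = small_experiment
    tables = simulate_acetylation_datasets(truth, n_datasets=1, coverage=0.7,
                                           concordance_prob=0.8, seed=6)
    classes = classify_concordance(tables)
    assert (classes.classes != "any").all()


def test_any_fraction_matches_call_pattern_enumeration():
    """Fraction of DE genes classified 'any' under (coverage c, concordance p,
    3 datasets) must match exhaustive enumeration of the per-dataset call
    pattern space {absent, match, flip}^3."""
    cfg = SimulationConfig(n_genes=2000, frac_de=0.5, seed=13)
    _, truth = simulate_count_experiment(cfg)
    c, p = 0.6, 0.9
    tables = simulate_acetylation_datasets(truth, n_datasets=3, coverage=c,
                                           concordance_prob=p, seed=14)
    classes = classify_concordance(tables)
    observed = float((classes.lookup(truth.de_genes) == "any").mean())

    probs = {"absent": 1 - c, "match": c * p, "flip": c * (1 - p)}
    expected = sum(
        np.prod([probs[s] for s in pattern])
        for pattern in product(probs, repeat=3)
        if "match" in pattern and "flip" in pattern)
    assert observed == pytest.approx(expected, abs=0.04)


def test_acetylation_parameter_validation(small_experiment):
    _, truth = small_experiment
    with pytest.raises(ConfigError):
        simulate_acetylation_datasets(truth, n_datasets=0)
    with pytest.raises(ConfigError):
        simulate_acetylation_datasets(truth, coverage=0.0)
    with pytest.raises(ConfigError):
        simulate_acetylation_datasets(truth, concordance_prob=1.5)


def test_all_emitted_genes_come_from_the_universe(small_cohort, small_experiment):
    _, truth = small_experiment
    tables = simulate_acetylation_datasets(truth, seed=1)
    uni = set(truth.universe)
    for t in tables:
        assert set(t.calls.index) <= uni
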