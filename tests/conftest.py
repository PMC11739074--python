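import numpy as np
import pandas as pd
import pytest

from stagemirror import (ConsensusDEGTable, CountMatrix, SimulationConfig,
                         StageCorrSpec, ThresholdConfig,
                         simulate_count_experiment, simulate_staged_cohort)
from stagemirror.harmonize import GeneLevelStageProfile


def make_count_matrix(counts, lengths, condition, reference=None):
    """CountMatrix from plain nested lists / dicts, for hand-built cases."""
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(len(counts))] \
        if not isinstance(counts.index[0], str) else counts.index
    return CountMatrix(
        counts=counts,
        lengths_bp=pd.Series(lengths, index=counts.index),
        condition=pd.Series(condition, index=counts.columns),
        reference=reference,
    )


def make_deg_table(log2fc: pd.Series, member=None,
                   thresholds: ThresholdConfig | None = None) -> ConsensusDEGTable:
    """Consensus DEG table straight from a log2FC vector (single 'truth'
    caller with fdr 0 for members, 1 otherwise)."""
    thresholds = thresholds or ThresholdConfig()
    if member is None:
        member = np.abs(log2fc.to_numpy()) > thresholds.lfc_deg
    member = np.asarray(member, dtype=bool)
    direction = np.where(member, np.where(log2fc.to_numpy() > 0, "up", "down"), "none")
    table = pd.DataFrame({
        "consensus_log2fc": log2fc,
        "fdr_truth": np.where(member, 0.0, 1.0),
        "member": member,
        "direction": direction,
    }, index=log2fc.index)
    return ConsensusDEGTable(table=table, caller_ids=("truth",), thresholds=thresholds)


def make_stage_profile(stage_lfc: dict, pvalue=0.001) -> GeneLevelStageProfile:
    """Gene-level stage profile from {stage: Series(gene -> logfc)}."""
    rows = []
    for stage, series in stage_lfc.items():
        for gene, lfc in series.items():
            rows.append({"gene_id": gene, "stage": stage, "logfc": float(lfc),
                         "pvalue": pvalue, "fdr": pvalue, "n_probes": 1,
                         "significant": True})
    table = pd.DataFrame(rows)
    excluded = pd.DataFrame(columns=["gene_id", "stage", "reason", "probe_logfcs"])
    return GeneLevelStageProfile(table=table, excluded=excluded)


@pytest.fixture(scope="session")
def small_experiment():
    """One seeded 500-gene experiment with truth, shared across tests."""
    cfg = SimulationConfig(n_genes=500, n_per_group=6, seed=101)
    return simulate_count_experiment(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_experiment):
    _, truth = small_experiment
    spec = StageCorrSpec()
    return simulate_staged_cohort(truth, spec, seed=202)
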