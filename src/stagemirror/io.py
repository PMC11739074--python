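"""Readers and writers for the pipeline's plain-text formats.

All tabular files are UTF-8, tab-delimited, with a mandatory header row;
lines starting with ``#`` are comments.  Formats:

counts TSV        gene_id, length_bp, then one column per sample
sample sheet TSV  sample_id, condition   (or sample_id, stage)
probe expr TSV    probe_id, then one column per sample
probe map TSV     probe_id, gene_id
acetylation TSV   dataset_id, gene_id, direction        (direction: up|down)
GMT               set name TAB description TAB gene ids...
truth JSON        the generator's planted ground truth

Every writer's output round-trips through its reader bit-exactly (floats
are written with repr-faithful precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import AcetylationCallTable
from .de import CountMatrix
from .enrichment import GeneSetCollection
from .errors import ParseError, ValidationError
from .harmonize import ProbeMap, StagedExpressionSet
from .synth import SyntheticTruth

FLOAT_FORMAT = "%.10g"


def _read_tsv(path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, None, "file not found")
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                           dtype={0: str} if index_col == 0 else None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(path, None, f"cannot parse: {exc}") from exc


def _write_tsv(frame: pd.DataFrame, path, index_label=None):
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index=index_label is not None, index_label=index_label)


# ---------------------------------------------------------------------------
# counts + sample sheet


def read_counts_tsv(counts_path, samples_path, reference=None) -> CountMatrix:
    raw = _read_tsv(counts_path, index_col=0)
    if "length_bp" not in raw.columns:
        raise ParseError(counts_path, 1, "missing 'length_bp' column")
    lengths = raw["length_bp"]
    counts = raw.drop(columns=["length_bp"])
    arr = counts.to_numpy()
    neg = np.argwhere(arr < 0)
    if len(neg):
        g, s = neg[0]
        raise ParseError(counts_path, None,
                         f"negative count at gene {counts.index[g]!r}, "
                         f"sample {counts.columns[s]!r}")
    if not np.allclose(arr, np.round(arr)):
        raise ParseError(counts_path, None, "counts must be integers")
    sheet = _read_tsv(samples_path, index_col=0)
    if "condition" not in sheet.columns:
        raise ParseError(samples_path, 1, "missing 'condition' column")
    try:
        return CountMatrix(counts=counts.astype(np.int64), lengths_bp=lengths,
                           condition=sheet["condition"], reference=reference)
    except ValidationError as exc:
        raise ParseError(counts_path, None, str(exc)) from exc


def write_counts_tsv(cm: CountMatrix, counts_path, samples_path):
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths_bp)
    _write_tsv(out, counts_path, index_label="gene_id")
    _write_tsv(cm.condition.to_frame("condition"), samples_path,
               index_label="sample_id")


# ---------------------------------------------------------------------------
# staged probe expression


def read_probe_expression(expr_path, samples_path) -> StagedExpressionSet:
    expr = _read_tsv(expr_path, index_col=0)
    sheet = _read_tsv(samples_path, index_col=0)
    if "stage" not in sheet.columns:
        raise ParseError(samples_path, 1, "missing 'stage' column")
    try:
        return StagedExpressionSet(expression=expr, stage=sheet["stage"])
    except ValidationError as exc:
        raise ParseError(samples_path, None, str(exc)) from exc


def write_probe_expression(expr: StagedExpressionSet, expr_path, samples_path):
    _write_tsv(expr.expression, expr_path, index_label="probe_id")
    _write_tsv(expr.stage.to_frame("stage"), samples_path, index_label="sample_id")


# ---------------------------------------------------------------------------
# probe map


def read_probe_map(path) -> ProbeMap:
    table = _read_tsv(path, index_col=0)
    if "gene_id" not in table.columns:
        raise ParseError(path, 1, "missing 'gene_id' column")
    try:
        return ProbeMap(table=table[["gene_id"]])
    except ValidationError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_probe_map(pmap: ProbeMap, path):
    _write_tsv(pmap.table, path, index_label="probe_id")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    if not path.exists():
        raise ParseError(path, None, "file not found")
    sets, descriptions = {}, {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(path, lineno,
                             "GMT line needs name, description and >= 1 gene")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ParseError(path, lineno, f"duplicate set name {name!r}")
        if not genes:
            raise ParseError(path, lineno, f"set {name!r} has no genes")
        sets[name] = frozenset(genes)
        descriptions[name] = desc
    if not sets:
        raise ParseError(path, None, "no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path):
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        genes = sorted(collection.sets[name])
        lines.append("\t".join([name, desc] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# acetylation calls


def read_calls(paths) -> list[AcetylationCallTable]:
    """One or several (dataset_id, gene_id, direction) TSVs -> call tables."""
    frames = []
    for path in ([paths] if isinstance(paths, (str, Path)) else list(paths)):
        frame = _read_tsv(path)
        for col in ("dataset_id", "gene_id", "direction"):
            if col not in frame.columns:
                raise ParseError(path, 1, f"missing {col!r} column")
        frames.append(frame)
    merged = pd.concat(frames, ignore_index=True)
    tables = []
    for dataset_id, sub in merged.groupby("dataset_id", sort=True):
        calls = pd.Series(sub["direction"].to_numpy(),
                          index=pd.Index(sub["gene_id"], name="gene_id"))
        mark = str(sub["mark"].iloc[0]) if "mark" in sub.columns else ""
        tables.append(AcetylationCallTable(dataset_id=str(dataset_id),
                                           calls=calls, mark=mark))
    return tables


def write_calls(tables: list[AcetylationCallTable], path):
    rows = []
    for t in tables:
        for gene, direction in t.calls.items():
            rows.append({"dataset_id": t.dataset_id, "gene_id": gene,
                         "direction": direction, "mark": t.mark})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# truth JSON


def write_truth(truth: SyntheticTruth, path):
    payload = {
        "universe": list(truth.universe),
        "de_lfc": {g: float(v) for g, v in truth.de_lfc.items()},
        "stage_r": {k: (None if v != v else float(v)) for k, v in truth.stage_r.items()},
        "stage_lfc": (None if truth.stage_lfc is None
                      else {c: truth.stage_lfc[c].round(10).to_dict()
                            for c in truth.stage_lfc.columns}),
        "enriched_sets": list(truth.enriched_sets),
        "discordant_genes": list(truth.discordant_genes),
        "acetylation_calls": {d: s.to_dict() for d, s in truth.acetylation_calls.items()},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    stage_lfc = None
    if payload.get("stage_lfc"):
        stage_lfc = pd.DataFrame(payload["stage_lfc"]).reindex(payload["universe"])
    return SyntheticTruth(
        universe=payload["universe"],
        de_lfc=pd.Series(payload["de_lfc"], name="true_log2fc").sort_index(),
        stage_r={k: (float("nan") if v is None else v)
                 for k, v in payload.get("stage_r", {}).items()},
        stage_lfc=stage_lfc,
        enriched_sets=payload.get("enriched_sets", []),
        discordant_genes=payload.get("discordant_genes", []),
        acetylation_calls={d: pd.Series(v) for d, v in
                           payload.get("acetylation_calls", {}).items()},
    )
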