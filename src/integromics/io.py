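"""Readers and writers for the plain-text formats the pipeline touches.

All files are tab-separated UTF-8 text with "." as the decimal mark; this is
pinned for bit-exact round trips. Supported formats: expression matrices
(features x samples TSV), GMT gene-set collections, TargetScan-style target
prediction tables, survival tables, and network node/edge tables + GraphML.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    STAGE_ORDINALS,
    ExpressionMatrix,
    GeneSet,
    StageDesign,
    SurvivalRecord,
    TargetPrediction,
)

_FLOAT_FMT = "%.17g"  # full double precision so write/read round-trips exactly


def read_expression_matrix(path, kind: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header sample ids).

    Missing cells (empty / NA) are kept as NaN and flagged; non-numeric text
    raises with the offending row and column named.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in header:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id in header {sid!r}")
        seen.add(sid)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.columns = header
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        missing = cells.isin(["", "NA", "NaN", "nan"])
        numeric = pd.to_numeric(cells.where(~missing), errors="coerce")
        bad = numeric.isna() & ~missing
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} "
                f"at feature {row!r}, sample {col!r}"
            )
        parsed[col] = numeric
    return ExpressionMatrix(parsed, kind=kind)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV; round-trips through :func:`read_expression_matrix`."""
    matrix.data.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature")


def read_stage_design(path, stages=None) -> StageDesign:
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str, "stage": str})
    return StageDesign.from_frame(frame, stages=stages)


def write_stage_design(design: StageDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Parse a standard GMT file: name, description, then members, tab-separated.

    The description field is stored as the set's collection when non-empty.
    Duplicate members within a line are deduplicated.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            sets.append(
                GeneSet(name=name, members=frozenset(members), collection=description)
            )
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.collection}\t{members}\n")


def read_target_predictions(
    path,
    mirna_col: str = "mirna",
    family_col: str = "family",
    gene_col: str = "gene",
    score_col: str = "total_context_score",
) -> list[TargetPrediction]:
    """Read a TargetScan-style prediction table.

    Duplicate (miRNA, gene) rows are collapsed to the most negative
    (strongest predicted repression) total context score.
    """
    table = pd.read_csv(path, sep="\t")
    for col in (mirna_col, family_col, gene_col, score_col):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(table) == 0:
        return []
    collapsed = (
        table.sort_values(score_col, kind="stable")
        .drop_duplicates(subset=[mirna_col, gene_col], keep="first")
        .sort_index()
    )
    return [
        TargetPrediction(
            mirna=str(r[mirna_col]),
            family=str(r[family_col]),
            gene=str(r[gene_col]),
            total_context_score=float(r[score_col]),
        )
        for _, r in collapsed.iterrows()
    ]


def write_target_predictions(predictions: list[TargetPrediction], path) -> None:
    pd.DataFrame(
        [
            {
                "mirna": p.mirna,
                "family": p.family,
                "gene": p.gene,
                "total_context_score": p.total_context_score,
            }
            for p in predictions
        ],
        columns=["mirna", "family", "gene", "total_context_score"],
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_survival_table(path, sep: str = "\t") -> list[SurvivalRecord]:
    """Read a survival table (time in months, binary event, age, stage, marker).

    Roman stage labels I-IV are mapped to ordinals; integer stages 1-4 pass
    through. Non-positive times and unknown stage labels raise.
    """
    table = pd.read_csv(path, sep=sep)
    required = {"time", "event", "age", "stage", "marker"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in table.iterrows():
        stage_raw = str(row["stage"]).strip()
        if stage_raw in STAGE_ORDINALS:
            stage = STAGE_ORDINALS[stage_raw]
        elif stage_raw in {"1", "2", "3", "4"}:
            stage = int(stage_raw)
        else:
            raise ValueError(f"{path}: unknown stage label {stage_raw!r} in row {i}")
        subject = str(row["subject_id"]) if "subject_id" in table.columns else f"S{i}"
        records.append(
            SurvivalRecord(
                subject_id=subject,
                time=float(row["time"]),
                event=int(row["event"]),
                age=float(row["age"]),
                stage=stage,
                marker=float(row["marker"]),
            )
        )
    return records


def write_survival_table(records: list[SurvivalRecord], path) -> None:
    inv = {v: k for k, v in STAGE_ORDINALS.items()}
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "time": r.time,
                "event": r.event,
                "age": r.age,
                "stage": inv[r.stage],
                "marker": r.marker,
            }
            for r in records
        ],
        columns=["subject_id", "time", "event", "age", "stage", "marker"],
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_network_edgelist(graph: nx.Graph, path) -> dict[str, str]:
    """Write a network as TSV edge + node tables and GraphML.

    ``path`` is the edge-list path; ``<path-stem>.nodes.tsv`` and
    ``<path-stem>.graphml`` are written next to it. Returns the paths used.
    """
    path = str(path)
    stem, _ = os.path.splitext(path)
    node_path = stem + ".nodes.tsv"
    graphml_path = stem + ".graphml"

    edge_rows = [
        {
            "source": u,
            "target": v,
            "weight": data.get("weight", np.nan),
            "sign": data.get("sign", 0),
            "relation": data.get("relation", ""),
        }
        for u, v, data in graph.edges(data=True)
    ]
    pd.DataFrame(
        edge_rows, columns=["source", "target", "weight", "sign", "relation"]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    node_rows = [
        {
            "node": n,
            "type": data.get("type", ""),
            "group": data.get("group", ""),
            "direction": data.get("direction", ""),
        }
        for n, data in graph.nodes(data=True)
    ]
    pd.DataFrame(node_rows, columns=["node", "type", "group", "direction"]).to_csv(
        node_path, sep="\t", index=False
    )
    nx.write_graphml(graph, graphml_path)
    return {"edges": path, "nodes": node_path, "graphml": graphml_path}


def read_network_edgelist(path) -> nx.DiGraph:
    """Read back the TSV pair written by :func:`write_network_edgelist`."""
    path = str(path)
    stem, _ = os.path.splitext(path)
    node_path = stem + ".nodes.tsv"
    graph = nx.DiGraph()
    nodes = pd.read_csv(node_path, sep="\t", keep_default_na=False)
    for _, r in nodes.iterrows():
        graph.add_node(
            r["node"], type=r["type"], group=r["group"], direction=r["direction"]
        )
    edges = pd.read_csv(path, sep="\t", keep_default_na=False)
    for _, r in edges.iterrows():
        graph.add_edge(
            r["source"],
            r["target"],
            weight=float(r["weight"]),
            sign=int(r["sign"]),
            relation=r["relation"],
        )
    return graph
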