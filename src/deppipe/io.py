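"""Readers and writers for the pipeline's TSV dialect.

All files are tab-delimited UTF-8 with a header row. Missing abundance
cells are encoded as the empty string or the literal ``NA``
(case-sensitive); any other non-numeric cell is an error, so silent data
loss from typos is impossible.

Layouts::

    matrix       protein_id [gene_symbol] <sample_1> ... <sample_n>
    metadata     sample_id  group
    edge list    node_a  node_b  [score]
    annotations  id  ontology  category
    disease      gene  disease_id  disease_name  channel  score
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceDataset,
    AnnotationTable,
    ConsistencyError,
    DiseaseAssociation,
    FormatError,
    PpiNetwork,
)

logger = logging.getLogger(__name__)

MISSING_TOKENS = ("", "NA")


def _parse_cell(token: str, where: str) -> float:
    if token in MISSING_TOKENS:
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric cell {token!r} at {where}") from None


def read_abundance_matrix(
    matrix_path: str | Path, metadata_path: str | Path
) -> AbundanceDataset:
    """Read a log-abundance matrix TSV plus its sample->group metadata.

    The matrix must have a ``protein_id`` first column, an optional
    ``gene_symbol`` second column, then one column per sample; sample
    order in the file is preserved. Raises on duplicate ids, samples
    missing from either file, or a group count other than two.
    """
    with open(matrix_path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FormatError(f"{matrix_path}: empty matrix file")
    header = rows[0]
    if not header or header[0] != "protein_id":
        raise FormatError(f"{matrix_path}: first column must be 'protein_id'")
    has_symbols = len(header) > 1 and header[1] == "gene_symbol"
    first_sample = 2 if has_symbols else 1
    sample_ids = header[first_sample:]
    if not sample_ids:
        raise FormatError(f"{matrix_path}: no sample columns")

    protein_ids: list[str] = []
    gene_symbols: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(f"{matrix_path}:{lineno}: ragged row")
        protein_ids.append(row[0])
        if has_symbols:
            gene_symbols.append(row[1])
        data.append(
            [
                _parse_cell(tok, f"{matrix_path}:{lineno}:{sample_ids[j]}")
                for j, tok in enumerate(row[first_sample:])
            ]
        )

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if list(meta.columns[:2]) != ["sample_id", "group"]:
        raise FormatError(f"{metadata_path}: expected columns sample_id, group")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{metadata_path}: duplicate sample ids")
    group_of = dict(zip(meta["sample_id"], meta["group"]))
    missing_meta = set(sample_ids) - set(group_of)
    if missing_meta:
        raise ConsistencyError(
            f"samples absent from metadata: {sorted(missing_meta)}"
        )
    extra_meta = set(group_of) - set(sample_ids)
    if extra_meta:
        raise ConsistencyError(f"metadata samples absent from matrix: {sorted(extra_meta)}")

    return AbundanceDataset(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        group_of=group_of,
        values=np.array(data, dtype=float),
        gene_symbols=gene_symbols if has_symbols else None,
    )


def write_abundance_matrix(
    dataset: AbundanceDataset, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a dataset back to the matrix + metadata TSV pair (NA = missing)."""
    with open(matrix_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["protein_id"]
        if dataset.gene_symbols is not None:
            header.append("gene_symbol")
        w.writerow(header + list(dataset.sample_ids))
        for i, pid in enumerate(dataset.protein_ids):
            row = [pid]
            if dataset.gene_symbols is not None:
                row.append(dataset.gene_symbols[i])
            row += [
                "NA" if np.isnan(v) else repr(float(v)) for v in dataset.values[i]
            ]
            w.writerow(row)
    with open(metadata_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group"])
        for s in dataset.sample_ids:
            w.writerow([s, dataset.group_of[s]])


def read_edge_list(path: str | Path) -> PpiNetwork:
    """Read a STRING-export-style scored edge list.

    Duplicate pairs (in either order) collapse keeping the maximum
    score; self-loops are dropped with a warning but keep their node.
    An empty file yields an empty, valid network.
    """
    net = PpiNetwork()
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        return net
    start = 1 if rows[0] and rows[0][0] in ("node_a", "protein_a") else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or (len(row) == 1 and not row[0]):
            continue
        if len(row) < 2:
            raise FormatError(f"{path}:{lineno}: need at least two columns")
        a, b = row[0], row[1]
        score = float(row[2]) if len(row) > 2 and row[2] != "" else 1.0
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
            net.add_node(a)
            continue
        net.add_edge(a, b, score)
    return net


def write_edge_list(network: PpiNetwork, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_a", "node_b", "score"])
        for a, b, score in network.edges:
            w.writerow([a, b, repr(float(score))])


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read (id, ontology, category) records; exact duplicates dropped."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        names=["id", "ontology", "category"], header=0,
    )
    if df.empty:
        return AnnotationTable()
    return AnnotationTable(records=df)


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def read_disease_table(path: str | Path) -> list[DiseaseAssociation]:
    """Read gene-disease association records, preserving file order."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["gene", "disease_id", "disease_name", "channel", "score"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    return [
        DiseaseAssociation(
            gene=r.gene,
            disease_id=r.disease_id,
            disease_name=r.disease_name,
            channel=r.channel,
            score=float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def write_disease_table(
    records: list[DiseaseAssociation], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "disease_id", "disease_name", "channel", "score"])
        for r in records:
            w.writerow([r.gene, r.disease_id, r.disease_name, r.channel, repr(float(r.score))])
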