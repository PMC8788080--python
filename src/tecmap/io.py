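"""Readers and writers for the pipeline's tabular and graph formats.

Canonical table dialect is TSV (tab-separated, decimal point, UTF-8),
matching the download conventions of expression atlases.  Gene and column
order is always preserved, never silently sorted.  Floats are written with
12 significant digits so write/read round-trips are value-preserving at
that precision.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd
import skbio

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet, Stage

FLOAT_FORMAT = "%.12g"


def read_expression(path, stage: Stage | str, lengths_path=None) -> ExpressionMatrix:
    """Read a gene x column expression TSV.

    First column holds gene ids, the header row holds column ids, and the
    body must be numeric and non-negative.  ``lengths_path`` optionally
    points to a two-column TSV (gene_id, length_kb).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError:
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad][0]
                raise ValueError(
                    f"non-numeric cell at gene {row!r}, column {col!r} in {path}"
                ) from None
        raise
    lengths = read_gene_lengths(lengths_path) if lengths_path is not None else None
    return ExpressionMatrix(data=frame, stage=Stage(stage), gene_lengths=lengths)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


def read_gene_lengths(path) -> pd.Series:
    """Two-column TSV (gene_id, length_kb) -> Series of lengths in kb."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValueError(f"gene length file {path} needs columns gene_id, length_kb")
    s = pd.Series(frame.iloc[:, 1].astype(float).to_numpy(), index=frame.iloc[:, 0].astype(str))
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in length file: {dup!r}")
    return s


def write_gene_lengths(lengths: pd.Series, path) -> None:
    frame = pd.DataFrame({"gene_id": lengths.index, "length_kb": lengths.to_numpy()})
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t")
    frame["gene_id"] = frame["gene_id"].astype(str)
    return GeneAnnotation(frame)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.frame.to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write any result table as TSV with 12-significant-digit floats."""
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: one set per line (name, description, members)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} at line {lineno}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")


def ensure_writable(path) -> Path:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    return path
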