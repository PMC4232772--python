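"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices, sample designs, probe annotations, ground truth and
gene sets travel as TSV; proteins as FASTA; cluster trees as Newick. All
writers round-trip losslessly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_sets import GeneSet
from .matrix import ExpressionMatrix
from .pqnscan import ProteinRecord

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_design_table",
    "write_design_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_fasta",
    "write_fasta",
    "read_gene_set",
    "write_gene_set",
]


def read_expression_table(
    path: str | Path, design: Mapping[str, str] | None = None, *, scale: str = "log2"
) -> ExpressionMatrix:
    """Read a feature-by-sample expression TSV.

    First column holds feature ids, header row holds sample ids, the body
    is numeric. ``design`` supplies the sample -> state map; when omitted
    every sample is labeled with its own id (sufficient for operations that
    ignore states).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression table")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature id(s): {dup[:5]}")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        for col in non_numeric:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = df.index.get_loc(bad.index[0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r} (line {line})"
            )
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    state_of = dict(design) if design is not None else {s: s for s in df.columns}
    return ExpressionMatrix(df, state_of, scale)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def read_design_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, state) TSV into a sample -> state map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: design table needs columns (sample, state)")
    sample_col, state_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dup[:5]}")
    return dict(zip(df[sample_col], df[state_col]))


def write_design_table(state_of: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(state_of), "state": [state_of[s] for s in state_of]}
    ).to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (probe, gene) TSV into a probe -> gene map.

    A probe appearing with two different genes is ambiguous and rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation table needs columns (probe, gene)")
    probe_col, gene_col = df.columns[:2]
    conflicts = df.groupby(probe_col)[gene_col].nunique()
    multi = conflicts[conflicts > 1].index.tolist()
    if multi:
        raise ValueError(
            f"{path}: probe(s) mapped to multiple genes (e.g. {multi[:3]}); "
            "ambiguous mappings are rejected"
        )
    return dict(zip(df[probe_col], df[gene_col]))


def write_annotation_table(annotation: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"probe": list(annotation), "gene": [annotation[p] for p in annotation]}
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA, in file order, upper-cased.

    Empty files, empty sequences and non-standard residues are errors.
    """
    path = Path(path)
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_gene_set(path: str | Path) -> GeneSet:
    """Read a 3-column (gene, direction, set) TSV written by write_gene_set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty gene set table")
    name = df["set"].iloc[0]
    return GeneSet(name=name, members=dict(zip(df["gene"], df["direction"])))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    rows = sorted(gene_set.members.items())
    pd.DataFrame(
        {
            "gene": [g for g, _ in rows],
            "direction": [d for _, d in rows],
            "set": gene_set.name,
        }
    ).to_csv(path, sep="\t", index=False)
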