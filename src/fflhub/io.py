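"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV for matrices and edge tables, FASTA for
sequences (via Biopython), SIF and GraphML for networks (via networkx),
JSON for truth files, summaries and the run report.  JSON is written with
sorted keys and a trailing newline so reruns are byte-comparable.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError
from .seedmatch import NucSequence

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
    "read_table_tsv",
    "write_table_tsv",
    "read_fasta",
    "write_fasta",
    "write_sif",
    "write_graphml",
    "read_json",
    "write_json",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene × sample matrix: first column gene ids, header sample ids."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index.name = "gene_id"
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise SchemaError(f"{path}: duplicate gene or sample identifiers")
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def read_phenotype_tsv(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t")
    if list(table.columns[:2]) != ["sample_id", "group"]:
        raise SchemaError(f"{path}: expected columns sample_id, group")
    return table.set_index("sample_id")["group"]


def write_phenotype_tsv(phenotype: pd.Series, path) -> None:
    frame = phenotype.rename("group").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_fasta(path) -> list[NucSequence]:
    return [
        NucSequence(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences, path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sif(graph, path, relation: str = "pp") -> None:
    """Cytoscape SIF: one `source relation target` line per edge.

    For directed regulatory networks the per-edge ``etype`` attribute is
    used as the relation when present.
    """
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{data.get('etype', relation)}\t{b}\n")
        for v in sorted((v for v in graph.nodes if graph.degree(v) == 0), key=str):
            fh.write(f"{v}\n")


def write_graphml(graph, path) -> None:
    # GraphML holds scalar attributes only; container-valued graph metadata
    # (e.g. per-class edge counts) lives in the JSON summaries instead
    out = graph.copy()
    for key in [k for k, v in out.graph.items() if isinstance(v, (dict, list, tuple))]:
        del out.graph[key]
    nx.write_graphml(out, str(path))


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
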