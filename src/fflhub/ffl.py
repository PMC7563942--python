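"""miRNA-TF-gene feed-forward-loop (FFL) network assembly and mining.

The FFL network is a directed tripartite graph over three node roles —
miRNAs, transcription factors (TFs) and (hub) genes — built from three
regulatory tables:

* miRNA→gene predictions (miRWalk-style), screened in two tiers: first by
  binding evidence (binding region ``3UTR``, binding gap 1, prediction
  score ≥ 0.95 inclusive), then by consensus — the (miRNA, gene) pair must
  be reported by all three of TargetScan, miRDB and miRTarBase;
* TF→gene edges (ChIPBase/ChEA-style) restricted to TFs flagged as
  disease-associated (the flag models the manual ARDS/ALI literature
  curation step);
* miRNA→TF repression edges (StarBase-style), deduplicated but not
  binding-filtered, since those exports carry no binding columns.

A feed-forward loop is a closed triad (m, t, g) where the miRNA represses
both the TF and the gene while the TF also regulates the gene, i.e. the
edges m→t, m→g and t→g all exist.  Triads are ranked by the sum of the
total degrees of their three nodes in the merged network, and the maximal
one is the "top higher-order subnetwork".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import NoFFLError, SchemaError, TypeConflictError, ValidationError

__all__ = [
    "tier1_filter",
    "tier2_consensus",
    "tf_screen",
    "assemble",
    "enumerate_ffl",
    "top_subnetwork",
    "summarize",
    "FFLTriad",
    "MIRWALK_DBS",
]

logger = logging.getLogger(__name__)

MIRWALK_DBS = frozenset({"TargetScan", "miRDB", "miRTarBase"})

_TIER1_COLUMNS = ("source", "target", "source_db", "score", "binding_region", "binding_gap")


@dataclass(frozen=True, order=True)
class FFLTriad:
    """A closed miRNA→TF→gene loop with its merged-network degree sum."""

    mirna: str
    tf: str
    gene: str
    degree_sum: int = 0


def _require(edges: pd.DataFrame, columns) -> None:
    missing = set(columns) - set(edges.columns)
    if missing:
        raise SchemaError(f"regulatory table missing columns: {sorted(missing)}")


def tier1_filter(
    edges: pd.DataFrame,
    min_score: float = 0.95,
    region: str = "3UTR",
    gap: int = 1,
) -> pd.DataFrame:
    """First-tier binding screen on miRNA→gene rows.

    Keeps rows with ``binding_region == region``, ``binding_gap == gap``
    and ``score >= min_score`` (inclusive — a score of exactly 0.95
    passes).
    """
    _require(edges, _TIER1_COLUMNS)
    keep = (
        (edges["binding_region"] == region)
        & (edges["binding_gap"] == gap)
        & (edges["score"] >= min_score)
    )
    return edges.loc[keep].reset_index(drop=True)


def tier2_consensus(
    edges: pd.DataFrame, required_dbs: frozenset = MIRWALK_DBS
) -> pd.DataFrame:
    """Second-tier consensus: keep pairs predicted by all source databases.

    Rows are grouped by (source, target); a pair survives only when its
    evidence rows span every database in ``required_dbs``.  The output has
    one consolidated row per surviving pair, carrying the maximum score
    and the database count.
    """
    _require(edges, ("source", "target", "source_db"))
    unknown = set(edges["source_db"]) - set(required_dbs)
    if unknown:
        raise ValidationError(f"unknown source_db labels: {sorted(unknown)}")
    if edges.empty:
        return pd.DataFrame(columns=["source", "target", "score", "n_dbs"])
    grouped = edges.groupby(["source", "target"], sort=True).agg(
        dbs=("source_db", lambda s: frozenset(s)),
        score=("score", "max") if "score" in edges.columns else ("source_db", "size"),
    )
    keep = grouped[grouped["dbs"].map(lambda d: required_dbs <= d)]
    out = keep.reset_index()
    out["n_dbs"] = out["dbs"].map(len)
    return out.drop(columns=["dbs"])


def tf_screen(tf_edges: pd.DataFrame) -> pd.DataFrame:
    """Keep TF→gene edges whose TF carries the disease-association flag."""
    _require(tf_edges, ("source", "target", "disease_flag"))
    flags = tf_edges["disease_flag"].astype(bool)
    return tf_edges.loc[flags].reset_index(drop=True)


def assemble(
    mirna_gene: pd.DataFrame,
    tf_gene: pd.DataFrame,
    mirna_tf: pd.DataFrame,
) -> nx.DiGraph:
    """Merge the three filtered tables into one typed directed network.

    Node roles are inferred from table positions (miRNA = sources of the
    two miRNA tables, TF = sources of the TF table and targets of the
    miRNA→TF table, gene = targets of the gene-directed tables).  Edges
    are deduplicated within each interaction class.  TF→gene rows whose
    target is itself a TF (TF-TF regulation) are outside the three-class
    loop definition and are dropped with a logged count; any other
    identifier claimed by two roles raises :class:`TypeConflictError`.

    Per-class edge counts before and after deduplication are stored in
    ``graph.graph``.
    """
    for table in (mirna_gene, tf_gene, mirna_tf):
        _require(table, ("source", "target"))
    mirnas = set(mirna_gene["source"]) | set(mirna_tf["source"])
    tfs = set(tf_gene["source"]) | set(mirna_tf["target"])
    tf_tf_mask = tf_gene["target"].isin(tfs)
    n_tf_tf = int(tf_tf_mask.sum())
    if n_tf_tf:
        logger.warning("ignoring %d TF-TF edge(s) in the TF table", n_tf_tf)
        tf_gene = tf_gene.loc[~tf_tf_mask]
    genes = set(mirna_gene["target"]) | set(tf_gene["target"])
    for role_a, role_b, label in (
        (mirnas, tfs, "miRNA/TF"),
        (mirnas, genes, "miRNA/gene"),
        (tfs, genes, "TF/gene"),
    ):
        clash = role_a & role_b
        if clash:
            raise TypeConflictError(f"ids with conflicting roles ({label}): {sorted(clash)}")

    graph = nx.DiGraph()
    for node_set, kind in ((mirnas, "mirna"), (tfs, "tf"), (genes, "gene")):
        graph.add_nodes_from(sorted(node_set), kind=kind)
    raw_counts, dedup_counts = {}, {}
    for table, etype in (
        (mirna_gene, "mirna-gene"),
        (tf_gene, "tf-gene"),
        (mirna_tf, "mirna-tf"),
    ):
        pairs = list(table[["source", "target"]].itertuples(index=False, name=None))
        raw_counts[etype] = len(pairs)
        unique = sorted(set(pairs))
        dedup_counts[etype] = len(unique)
        graph.add_edges_from(unique, etype=etype)
    graph.graph["edge_counts_raw"] = raw_counts
    graph.graph["edge_counts"] = dedup_counts
    graph.graph["n_tf_tf_dropped"] = n_tf_tf
    return graph


def enumerate_ffl(network: nx.DiGraph) -> list[FFLTriad]:
    """All closed (miRNA, TF, gene) triads with m→t, m→g and t→g edges.

    Each triad carries the sum of the total (in + out) degrees of its
    three nodes in the merged network.  The list is sorted by ids.
    """
    degree = dict(network.degree())
    triads = []
    for m, kind in network.nodes(data="kind"):
        if kind != "mirna":
            continue
        succ = list(network.successors(m))
        tf_succ = [t for t in succ if network.nodes[t]["kind"] == "tf"]
        gene_succ = [g for g in succ if network.nodes[g]["kind"] == "gene"]
        for t in tf_succ:
            for g in gene_succ:
                if network.has_edge(t, g):
                    triads.append(
                        FFLTriad(m, t, g, degree[m] + degree[t] + degree[g])
                    )
    return sorted(triads, key=lambda tr: (tr.mirna, tr.tf, tr.gene))


def top_subnetwork(triads: list[FFLTriad]) -> FFLTriad:
    """The triad with the largest degree sum (ties: lexicographically first ids)."""
    if not triads:
        raise NoFFLError("no feed-forward loop found")
    return min(triads, key=lambda tr: (-tr.degree_sum, tr.mirna, tr.tf, tr.gene))


def summarize(network: nx.DiGraph) -> tuple[pd.DataFrame, dict]:
    """Per-node regulatory fan-in/fan-out table and the argmax highlights.

    The table has one row per node with its role and the counts relevant
    to that role (genes targeted and TFs repressed for miRNAs; TF
    regulators and miRNA repressors for genes; targets and repressors for
    TFs).  The highlights dict names the miRNA targeting the most genes,
    the miRNA repressing the most TFs, and the gene regulated by the most
    TFs.
    """
    rows = []
    for node, kind in sorted(network.nodes(data="kind")):
        out_edges = network.out_edges(node, data="etype")
        in_edges = network.in_edges(node, data="etype")
        rows.append(
            {
                "node": node,
                "kind": kind,
                "n_genes_targeted": sum(1 for *_, e in out_edges if e == "mirna-gene"),
                "n_tfs_repressed": sum(1 for *_, e in out_edges if e == "mirna-tf"),
                "n_tf_regulators": sum(1 for *_, e in in_edges if e == "tf-gene"),
                "n_mirna_repressors": sum(1 for *_, e in in_edges if e == "mirna-gene"),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "node",
            "kind",
            "n_genes_targeted",
            "n_tfs_repressed",
            "n_tf_regulators",
            "n_mirna_repressors",
        ],
    )
    highlights: dict = {}
    if not table.empty:
        mirnas = table[table["kind"] == "mirna"]
        genes = table[table["kind"] == "gene"]
        if not mirnas.empty:
            top_tgt = mirnas.sort_values(["n_genes_targeted", "node"], ascending=[False, True]).iloc[0]
            top_rep = mirnas.sort_values(["n_tfs_repressed", "node"], ascending=[False, True]).iloc[0]
            highlights["mirna_most_genes"] = (top_tgt["node"], int(top_tgt["n_genes_targeted"]))
            highlights["mirna_most_tfs"] = (top_rep["node"], int(top_rep["n_tfs_repressed"]))
        if not genes.empty:
            top_reg = genes.sort_values(["n_tf_regulators", "node"], ascending=[False, True]).iloc[0]
            highlights["gene_most_tf_regulators"] = (top_reg["node"], int(top_reg["n_tf_regulators"]))
    return table, highlights
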