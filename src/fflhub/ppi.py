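"""Score-filtered protein-protein interaction graphs over DEGs.

Consumes a STRING-style scored edge list (``node_a``, ``node_b``,
``combined_score`` in [0, 1]) exported for the screened DEGs, keeps only
high-confidence pairs (combined score strictly above 0.9 by default, the
conventional "highest confidence" cut-off), and builds a simple undirected
graph restricted to a node whitelist — normally the DEG identifiers.

Cleaning rules: self-pairs are dropped, duplicate pairs (in either endpoint
order) collapse to a single edge keeping the maximum score, and whitelisted
nodes without any surviving interaction are retained as degree-0 nodes so
that every DEG has a defined centrality rank.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = ["filter_edges", "build_graph", "EDGE_COLUMNS"]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("node_a", "node_b", "combined_score")


def _check_schema(edges: pd.DataFrame) -> None:
    missing = set(EDGE_COLUMNS) - set(edges.columns)
    if missing:
        raise SchemaError(f"edge table missing columns: {sorted(missing)}")


def filter_edges(edges: pd.DataFrame, min_score: float = 0.9) -> pd.DataFrame:
    """Keep interaction pairs with combined score strictly above ``min_score``.

    The comparison is strict: a score exactly at the threshold is dropped.
    Scores must be finite and within [0, 1].
    """
    _check_schema(edges)
    scores = edges["combined_score"].to_numpy(float)
    if not np.all(np.isfinite(scores)) or scores.min(initial=0.0) < 0.0 or scores.max(initial=0.0) > 1.0:
        raise ValidationError("combined_score values must be finite and in [0, 1]")
    return edges.loc[scores > min_score].reset_index(drop=True)


def build_graph(edges: pd.DataFrame, node_whitelist: Iterable) -> nx.Graph:
    """Undirected simple graph over whitelisted nodes.

    Only edges with both endpoints in the whitelist are used; self-loops
    are dropped; duplicate pairs keep the maximum score.  Whitelist nodes
    without edges stay in the graph as isolated nodes.
    """
    _check_schema(edges)
    whitelist = set(node_whitelist)
    if not whitelist:
        logger.warning("empty node whitelist: returning empty graph")
        return nx.Graph()
    graph = nx.Graph()
    graph.add_nodes_from(sorted(whitelist, key=str))
    for a, b, score in edges[list(EDGE_COLUMNS)].itertuples(index=False):
        if a == b or a not in whitelist or b not in whitelist:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], float(score))
        else:
            graph.add_edge(a, b, score=float(score))
    return graph
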