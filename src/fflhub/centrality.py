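"""Six node-centrality measures for hub-gene calling on PPI networks.

The hub-calling recipe ranks every node of a score-filtered PPI graph by six
measures popularised by the CytoHubba Cytoscape plugin — maximal clique
centrality (MCC), edge percolated component (EPC), closeness (harmonic
form), betweenness, bottleneck and radiality — takes the top *k* (k = 10 by
default) under each measure, and calls the intersection of the six top-k
sets the hub genes.

All measures are implemented here directly on :class:`networkx.Graph`
adjacency (only maximal-clique enumeration is delegated to networkx).  The
graph is treated as undirected, simple and unweighted; edge confidence
scores play no role once the graph has been score-filtered.

Definitions
-----------
MCC(v)
    Sum over all maximal cliques ``C`` with ``v ∈ C`` and ``|C| ≥ 2`` of
    ``(|C| − 1)!``.  An isolated node (whose only maximal clique is the
    singleton ``{v}``) scores 0.
EPC(v)
    Monte-Carlo estimate of the expected number of *other* nodes that stay
    in ``v``'s connected component under random edge percolation: each
    replicate draws a threshold ``τ ~ U(0,1)`` and an independent
    ``u_e ~ U(0,1)`` per edge, keeping edges with ``u_e ≥ τ``.
closeness(v)
    Harmonic centrality ``Σ_{w≠v} 1/d(v,w)``; unreachable pairs contribute
    zero.
betweenness(v)
    Unnormalised shortest-path betweenness, endpoints excluded:
    ``Σ_{s<t, s,t≠v} σ_st(v)/σ_st``.
bottleneck(v)
    For every root ``s``, a breadth-first shortest-path tree is grown over
    ``s``'s component with the deterministic parent rule "smallest node id
    among candidates".  ``v ≠ s`` collects one point for root ``s`` iff the
    node count of ``v``'s subtree strictly exceeds ``n_s / 4`` where ``n_s``
    is the tree size.  The score is the total number of points.
radiality(v)
    Within ``v``'s component (size ``n_c``, diameter ``Δ``):
    ``Σ_{w≠v} (Δ + 1 − d(v,w)) / (n_c − 1)``; 0 for singleton components.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "mcc",
    "epc",
    "closeness",
    "betweenness",
    "bottleneck",
    "radiality",
    "all_centralities",
    "top_k",
    "hub_intersection",
    "HubResult",
    "MEASURES",
]

MEASURES = ("mcc", "epc", "closeness", "betweenness", "bottleneck", "radiality")


def _id_key(v):
    """Total order over heterogeneous node ids (type name, then repr)."""
    return (type(v).__name__, str(v))


def _sorted_ids(nodes):
    """Natural id order when comparable, otherwise the :func:`_id_key` order."""
    nodes = list(nodes)
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=_id_key)


def _min_id(nodes):
    nodes = list(nodes)
    try:
        return min(nodes)
    except TypeError:
        return min(nodes, key=_id_key)


def _bfs_levels(adj: Mapping[Hashable, list], source: Hashable) -> dict:
    """Unweighted shortest-path distances from ``source``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def _sorted_adj(graph: nx.Graph) -> dict:
    return {v: _sorted_ids(graph.neighbors(v)) for v in graph.nodes}


def mcc(graph: nx.Graph) -> dict:
    """Maximal clique centrality: Σ (|C|−1)! over maximal cliques C ∋ v, |C| ≥ 2."""
    scores = dict.fromkeys(graph.nodes, 0)
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def epc(graph: nx.Graph, reps: int = 1000, seed=None) -> dict:
    """Edge percolated component by seeded Monte-Carlo.

    Per replicate a global threshold τ ~ U(0,1) is drawn together with one
    uniform per edge; edges whose uniform is ≥ τ survive.  EPC(v) is the
    mean, over replicates, of the number of other nodes sharing v's
    surviving component.
    """
    if reps < 1:
        raise InvalidConfigError(f"epc needs reps >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    n, m = len(nodes), len(edges)
    totals = np.zeros(n)
    if n == 0:
        return {}
    taus = rng.random(reps)
    unis = rng.random((reps, m)) if m else np.zeros((reps, 0))
    parent = np.empty(n, dtype=np.int64)
    for r in range(reps):
        parent[:] = np.arange(n)

        def find(x):
            root = x
            while parent[root] != root:
                root = parent[root]
            while parent[x] != root:
                parent[x], x = root, parent[x]
            return root

        keep = unis[r] >= taus[r]
        for j in np.flatnonzero(keep):
            a, b = edges[j]
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        roots = np.fromiter((find(i) for i in range(n)), dtype=np.int64, count=n)
        sizes = np.bincount(roots, minlength=n)
        totals += sizes[roots] - 1
    return {v: totals[index[v]] / reps for v in nodes}


def closeness(graph: nx.Graph) -> dict:
    """Harmonic closeness Σ 1/d(v,w); unreachable pairs contribute 0."""
    adj = _sorted_adj(graph)
    scores = {}
    for v in graph.nodes:
        dist = _bfs_levels(adj, v)
        scores[v] = sum(1.0 / d for w, d in dist.items() if w != v)
    return scores


def betweenness(graph: nx.Graph) -> dict:
    """Unnormalised betweenness (Brandes accumulation), endpoints excluded."""
    scores = dict.fromkeys(graph.nodes, 0.0)
    adj = _sorted_adj(graph)
    for s in graph.nodes:
        stack = []
        preds = {v: [] for v in graph.nodes}
        sigma = dict.fromkeys(graph.nodes, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append(u)
        delta = dict.fromkeys(graph.nodes, 0.0)
        while stack:
            w = stack.pop()
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                scores[w] += delta[w]
    # every unordered pair was visited from both endpoints
    return {v: s / 2.0 for v, s in scores.items()}


def bottleneck(graph: nx.Graph) -> dict:
    """BottleNeck centrality over deterministic BFS shortest-path trees."""
    scores = dict.fromkeys(graph.nodes, 0)
    adj = _sorted_adj(graph)
    for s in graph.nodes:
        dist = _bfs_levels(adj, s)
        tree_nodes = list(dist)
        n_s = len(tree_nodes)
        if n_s == 1:
            continue
        # parent = smallest-id neighbour one BFS level up
        children = {v: [] for v in tree_nodes}
        for v in tree_nodes:
            if v == s:
                continue
            parent = _min_id(u for u in adj[v] if dist[u] == dist[v] - 1)
            children[parent].append(v)
        subtree = dict.fromkeys(tree_nodes, 1)
        for v in sorted(tree_nodes, key=dist.get, reverse=True):
            if v != s:
                parent = _min_id(u for u in adj[v] if dist[u] == dist[v] - 1)
                subtree[parent] += subtree[v]
        threshold = n_s / 4.0
        for v in tree_nodes:
            if v != s and subtree[v] > threshold:
                scores[v] += 1
    return scores


def radiality(graph: nx.Graph) -> dict:
    """Radiality relative to the diameter of each node's component."""
    adj = _sorted_adj(graph)
    scores = dict.fromkeys(graph.nodes, 0.0)
    for comp in nx.connected_components(graph):
        comp = _sorted_ids(comp)
        if len(comp) == 1:
            continue
        dists = {v: _bfs_levels(adj, v) for v in comp}
        diameter = max(max(d.values()) for d in dists.values())
        denom = len(comp) - 1
        for v in comp:
            scores[v] = sum(
                diameter + 1 - d for w, d in dists[v].items() if w != v
            ) / denom
    return scores


def all_centralities(
    graph: nx.Graph, epc_reps: int = 1000, seed=None
) -> dict:
    """All six measures as ``{measure: {node: score}}``."""
    return {
        "mcc": mcc(graph),
        "epc": epc(graph, reps=epc_reps, seed=seed),
        "closeness": closeness(graph),
        "betweenness": betweenness(graph),
        "bottleneck": bottleneck(graph),
        "radiality": radiality(graph),
    }


def top_k(scores: Mapping[Hashable, float], k: int = 10) -> list:
    """Top-k node ids by (score descending, node id ascending).

    Ties are broken by node id so the list always has exactly
    ``min(k, n)`` entries and Venn arithmetic over the six lists stays
    well defined.
    """
    if k < 1:
        raise InvalidConfigError(f"top_k needs k >= 1, got {k}")
    try:
        ordered = sorted(scores, key=lambda v: (-scores[v], v))
    except TypeError:
        ordered = sorted(scores, key=lambda v: (-scores[v],) + _id_key(v))
    return ordered[:k]


@dataclass
class HubResult:
    """Per-measure top-k rankings and their intersection (the hub call)."""

    top: dict  # measure -> ordered node list
    intersection: list  # sorted node ids present in all six lists
    k: int
    venn_counts: dict = field(default_factory=dict)  # region label -> node count

    def __post_init__(self):
        for measure, nodes in self.top.items():
            missing = set(self.intersection) - set(nodes)
            if missing:
                raise ValueError(f"intersection not within top-{self.k} of {measure}")


def hub_intersection(
    graph: nx.Graph, k: int = 10, epc_reps: int = 1000, seed=None
) -> HubResult:
    """Call hub genes as the intersection of the six top-k centrality lists.

    ``venn_counts`` maps each non-empty Venn region (measures joined by
    ``&``) to the number of nodes falling exactly in that region.
    """
    scores = all_centralities(graph, epc_reps=epc_reps, seed=seed)
    tops = {m: top_k(scores[m], k=k) for m in MEASURES}
    sets = {m: set(tops[m]) for m in MEASURES}
    members = set().union(*sets.values()) if sets else set()
    inter = _sorted_ids(set.intersection(*sets.values())) if sets else []
    venn: dict = {}
    for v in members:
        label = "&".join(m for m in MEASURES if v in sets[m])
        venn[label] = venn.get(label, 0) + 1
    return HubResult(top=tops, intersection=inter, k=k, venn_counts=venn)
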