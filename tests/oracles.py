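"""Independent brute-force oracles used to validate the implementation.

Every function here recomputes a quantity by the most direct route
available — exhaustive enumeration, naive definitions, closed forms —
sharing no code with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats


# ---------------------------------------------------------------- centralities


def mcc_oracle(graph: nx.Graph) -> dict:
    """MCC by enumerating every node subset and testing clique maximality."""
    nodes = list(graph.nodes)
    scores = dict.fromkeys(nodes, 0)
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if not all(graph.has_edge(a, b) for a, b in combinations(subset, 2)):
                continue
            members = set(subset)
            extendable = any(
                members <= set(graph.neighbors(v)) for v in graph.nodes if v not in members
            )
            if extendable:
                continue
            for v in subset:
                scores[v] += math.factorial(r - 1)
    return scores


def closeness_oracle(graph: nx.Graph) -> dict:
    out = {}
    for v in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, v)
        out[v] = sum(1.0 / d for w, d in lengths.items() if w != v)
    return out


def betweenness_oracle(graph: nx.Graph) -> dict:
    """Betweenness by explicitly enumerating all shortest paths per pair."""
    scores = dict.fromkeys(graph.nodes, 0.0)
    nodes = list(graph.nodes)
    for s, t in combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in graph.nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in paths if v in p)
            if on:
                scores[v] += on / len(paths)
    return scores


def bottleneck_oracle(graph: nx.Graph) -> dict:
    """BottleNeck recomputed with an explicit recursive descendant count."""
    scores = dict.fromkeys(graph.nodes, 0)
    for s in graph.nodes:
        dist = nx.single_source_shortest_path_length(graph, s)
        tree = {v: min((u for u in graph.neighbors(v) if dist.get(u) == dist[v] - 1))
                for v in dist if v != s}
        n_s = len(dist)

        def descendants(v):
            kids = [w for w, p in tree.items() if p == v]
            return 1 + sum(descendants(w) for w in kids)

        for v in dist:
            if v != s and descendants(v) > n_s / 4.0:
                scores[v] += 1
    return scores


def radiality_oracle(graph: nx.Graph) -> dict:
    scores = dict.fromkeys(graph.nodes, 0.0)
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_nodes() == 1:
            continue
        diam = nx.diameter(sub)
        for v in sub.nodes:
            lengths = nx.single_source_shortest_path_length(sub, v)
            scores[v] = sum(diam + 1 - d for w, d in lengths.items() if w != v) / (
                sub.number_of_nodes() - 1
            )
    return scores


def epc_exact(graph: nx.Graph) -> tuple[dict, dict]:
    """Exact EPC mean and per-replicate variance by edge-subset enumeration.

    Conditional on the percolation threshold τ, each edge survives
    independently with probability (1 − τ); integrating the probability of
    a specific surviving edge set S over τ gives the Beta integral
    ``∫ (1−τ)^k τ^(m−k) dτ = k!(m−k)!/(m+1)!`` with ``k = |S|``.  Summing
    component co-membership over all 2^m subsets yields E[X_v] and E[X_v²]
    for X_v = "number of other nodes connected to v", hence the exact
    Monte-Carlo standard error for any replicate count.
    """
    nodes = list(graph.nodes)
    edges = list(graph.edges)
    m = len(edges)
    mean = dict.fromkeys(nodes, 0.0)
    second = dict.fromkeys(nodes, 0.0)
    for mask in range(2 ** m):
        k = bin(mask).count("1")
        prob = math.factorial(k) * math.factorial(m - k) / math.factorial(m + 1)
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from(e for j, e in enumerate(edges) if mask >> j & 1)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                mean[v] += prob * (size - 1)
                second[v] += prob * (size - 1) ** 2
    var = {v: second[v] - mean[v] ** 2 for v in nodes}
    return mean, var


# ------------------------------------------------------------------ statistics


def welch_formula(x, y) -> tuple[float, float, float]:
    """Welch statistic, Satterthwaite df and p evaluated from the formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx_, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx_ + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def wilcoxon_exact_oracle(x, y) -> float:
    """Exact two-sided rank-sum p via the Mann-Whitney U pair-count statistic."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    mu = len(x) * len(y) / 2.0
    total = hits = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def hclust_scipy_oracle(values: np.ndarray):
    """Complete-linkage merge heights on 1 − Pearson distance via scipy."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist

    dist = pdist(values, metric="correlation")
    return linkage(dist, method="complete")


# ----------------------------------------------------------------- FFL mining


def tier_filter_rowscan(rows) -> set:
    """(miRNA, gene) pairs passing both screening tiers, by naive row scan.

    ``rows`` is an iterable of dicts with keys source, target, source_db,
    score, binding_region, binding_gap.
    """
    per_pair_dbs: dict = {}
    for row in rows:
        if (
            row["binding_region"] == "3UTR"
            and row["binding_gap"] == 1
            and row["score"] >= 0.95
        ):
            per_pair_dbs.setdefault((row["source"], row["target"]), set()).add(
                row["source_db"]
            )
    return {
        pair
        for pair, dbs in per_pair_dbs.items()
        if {"TargetScan", "miRDB", "miRTarBase"} <= dbs
    }


def ffl_triple_scan(mirna_tf_pairs, mirna_gene_pairs, tf_gene_pairs) -> set:
    """All closed triads by scanning the full miRNA × TF × gene product."""
    mirnas = {m for m, _ in mirna_tf_pairs} | {m for m, _ in mirna_gene_pairs}
    tfs = {t for _, t in mirna_tf_pairs} | {t for t, _ in tf_gene_pairs}
    genes = {g for _, g in mirna_gene_pairs} | {g for _, g in tf_gene_pairs}
    mt, mg, tg = set(mirna_tf_pairs), set(mirna_gene_pairs), set(tf_gene_pairs)
    return {
        (m, t, g)
        for m in mirnas
        for t in tfs
        for g in genes
        if (m, t) in mt and (m, g) in mg and (t, g) in tg
    }


# ----------------------------------------------------------------- seed sites


def seed_sites_bruteforce(mirna_rna: str, utr_rna: str) -> list:
    """Position-by-position site scan written directly from the definitions.

    Returns (type, start, end) tuples, 0-based half-open.
    """
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    out = []
    for i in range(len(utr_rna) - 5):
        ok = True
        for k in range(6):
            if comp[mirna_rna[1 + k]] != utr_rna[i + 5 - k]:
                ok = False
                break
        if not ok:
            continue
        has_m8 = i - 1 >= 0 and comp[mirna_rna[7]] == utr_rna[i - 1]
        has_a1 = i + 6 < len(utr_rna) and utr_rna[i + 6] == "A"
        if has_m8 and has_a1:
            out.append(("8mer", i - 1, i + 7))
        elif has_m8:
            out.append(("7mer-m8", i - 1, i + 6))
        elif has_a1:
            out.append(("7mer-A1", i, i + 7))
        else:
            out.append(("6mer", i, i + 6))
    return out
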