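"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the four kinds of input the analysis consumes —
a two-group log2 expression matrix with phenotype labels, a STRING-style
scored PPI edge list, three regulatory tables (miRNA→gene with binding
evidence, TF→gene with a disease-curation flag, miRNA→TF), and a
miRNA/3'UTR FASTA pair — each with known planted structure recorded in a
:class:`SyntheticTruth`, so that differential-expression calling, hub
intersection, the two-tier miRNA screen, FFL enumeration and seed matching
can all be tested end to end without any downloads.

Default condition sizes mirror the emulated study: 13 case vs 21 control
samples, ~10% of 2000 genes differentially expressed, a 60-node PPI
network hiding a 5-node high-confidence clique, and a regulatory space of
8 miRNAs × 21 TFs × a handful of hub genes.

Generative choices the emulated study never describes (it used archived
microarray and database exports) are documented stand-ins: baseline log2
intensities are Normal(8, 2), per-gene noise standard deviations are drawn
from U(0.5·noise_sd, 1.5·noise_sd), PPI background topology is a
Barabási-Albert preferential-attachment graph, high-confidence (planted
clique) interaction scores come from U(0.92, 1.0) and background scores
from U(0.40, 0.95).

Every generator receives its randomness from an independent substream of
the single configured seed, so generating one table never perturbs the
others, and identical configurations give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .seedmatch import NucSequence, reverse_complement

__all__ = ["SimConfig", "SyntheticTruth", "gen_expression", "gen_ppi", "gen_regnet", "gen_sequences"]

logger = logging.getLogger(__name__)

# substream tags: one fixed lane per generated table
_STREAM = {"expression": 0, "ppi": 1, "regnet": 2, "sequences": 3}

DECOY_CRITERIA = ("region", "gap", "score", "consensus", "tf_flag")


@dataclass
class SimConfig:
    """Condition sizes and effect settings for all synthetic inputs."""

    # expression matrix
    n_genes: int = 2000
    n_samples_a: int = 13  # case group (disease + background condition)
    n_samples_b: int = 21  # control group (background condition only)
    de_fraction: float = 0.1
    effect_size: float = 1.5  # log2-units shift planted in the case group
    noise_sd: float = 0.5  # log2-units; per-gene sds drawn around this
    # PPI graph
    n_nodes: int = 60
    attach_m: int = 1  # preferential-attachment edges per new node
    hub_clique_size: int = 5
    # regulatory tables
    n_mirnas: int = 8
    n_tfs: int = 21
    n_targets: int = 4
    n_planted_ffls: int = 5
    n_decoys: int = 20
    # sequences
    mirna_len: int = 22
    utr_len: int = 500
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_a": self.n_samples_a,
            "n_samples_b": self.n_samples_b,
            "n_nodes": self.n_nodes,
            "attach_m": self.attach_m,
            "hub_clique_size": self.hub_clique_size,
            "n_mirnas": self.n_mirnas,
            "n_tfs": self.n_tfs,
            "n_targets": self.n_targets,
            "n_planted_ffls": self.n_planted_ffls,
            "n_decoys": self.n_decoys,
        }
        for name, value in counts.items():
            if value < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise InvalidConfigError(f"de_fraction must be in [0,1], got {self.de_fraction}")
        if self.hub_clique_size > self.n_nodes:
            raise InvalidConfigError("hub_clique_size cannot exceed n_nodes")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream for one generated table."""
        return np.random.default_rng([int(self.seed), _STREAM[stream]])


@dataclass
class SyntheticTruth:
    """Planted structure: the oracle for downstream recovery tests."""

    de_genes: dict = field(default_factory=dict)  # gene id -> +1/-1 effect sign
    hub_nodes: list = field(default_factory=list)  # planted clique node ids
    true_ffls: list = field(default_factory=list)  # (mirna, tf, gene) triples
    decoy_edges: list = field(default_factory=list)  # dicts with violated criterion
    seed_sites: list = field(default_factory=list)  # planted UTR sites

    def as_dict(self) -> dict:
        d = asdict(self)
        d["true_ffls"] = [list(t) for t in self.true_ffls]
        return d


def gen_expression(config: SimConfig):
    """Two-group log2 expression matrix with planted shifts.

    Returns ``(matrix, phenotype, truth)``: a gene × sample DataFrame, a
    sample→group Series with labels ``case``/``control``, and the truth
    carrying the planted genes with their effect signs.  A fraction
    ``de_fraction`` of genes (rounded) is shifted by ``±effect_size`` in
    the case group; the sign per gene is random and recorded.
    """
    config.validate()
    if config.n_samples_a < 2 or config.n_samples_b < 2:
        raise InvalidConfigError("each group needs at least 2 samples")
    rng = config.rng("expression")
    n = config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n)]
    cases = [f"case{i + 1:02d}" for i in range(config.n_samples_a)]
    ctrls = [f"ctrl{i + 1:02d}" for i in range(config.n_samples_b)]
    baseline = rng.normal(8.0, 2.0, size=n)
    gene_sd = rng.uniform(0.5 * config.noise_sd, 1.5 * config.noise_sd, size=n)
    n_de = round(config.de_fraction * n)
    de_idx = np.sort(rng.choice(n, size=n_de, replace=False)) if n_de else np.array([], int)
    signs = rng.choice([-1, 1], size=n_de)
    n_samples = config.n_samples_a + config.n_samples_b
    values = baseline[:, None] + rng.normal(0.0, 1.0, size=(n, n_samples)) * gene_sd[:, None]
    values[de_idx, : config.n_samples_a] += signs[:, None] * config.effect_size
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cases + ctrls)
    phenotype = pd.Series(
        ["case"] * len(cases) + ["control"] * len(ctrls),
        index=pd.Index(cases + ctrls, name="sample_id"),
        name="group",
    )
    truth = SyntheticTruth(de_genes={genes[i]: int(s) for i, s in zip(de_idx, signs)})
    return matrix, phenotype, truth


def gen_ppi(config: SimConfig, node_ids: list | None = None):
    """Scored PPI edge list hiding a high-confidence clique.

    Background topology is Barabási-Albert preferential attachment with
    ``attach_m`` edges per incoming node; the ``hub_clique_size`` earliest
    nodes (the preferential-attachment hubs, lowest ids) are additionally
    connected all-to-all.  Clique edges score U(0.92, 1.0) — all above the
    0.9 confidence cut — while background edges score U(0.40, 0.95), so a
    minority of background edges also survive filtering and the clique
    must be recovered against realistic clutter.

    Returns ``(edges, truth)`` with ``truth.hub_nodes`` the clique ids.
    """
    config.validate()
    if config.hub_clique_size < 2:
        raise InvalidConfigError("hub_clique_size must be >= 2")
    if config.attach_m >= config.n_nodes:
        raise InvalidConfigError("attach_m must be smaller than n_nodes")
    rng = config.rng("ppi")
    if node_ids is None:
        node_ids = [f"n{i + 1:03d}" for i in range(config.n_nodes)]
    elif len(node_ids) != config.n_nodes:
        raise InvalidConfigError("node_ids length must equal n_nodes")
    graph = nx.barabasi_albert_graph(
        config.n_nodes, config.attach_m, seed=int(rng.integers(2**31))
    )
    clique = set(range(config.hub_clique_size))
    edges = {frozenset(e) for e in graph.edges}
    edges |= {
        frozenset((i, j))
        for i in clique
        for j in clique
        if i < j
    }
    rows = []
    for pair in sorted(tuple(sorted(e)) for e in edges):
        i, j = pair
        in_clique = i in clique and j in clique
        score = rng.uniform(0.92, 1.0) if in_clique else rng.uniform(0.40, 0.95)
        rows.append((node_ids[i], node_ids[j], round(float(score), 6)))
    table = pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])
    truth = SyntheticTruth(hub_nodes=[node_ids[i] for i in sorted(clique)])
    return table, truth


def _closure_triads(m_t: set, m_g: set, t_g: set) -> set:
    """Brute-force FFL closure over three directed pair sets."""
    return {
        (m, t, g)
        for (m, t) in m_t
        for (m2, g) in m_g
        if m2 == m
        for (t2, g2) in t_g
        if t2 == t and g2 == g
    }


def gen_regnet(config: SimConfig, gene_ids: list | None = None):
    """Three regulatory tables with planted FFLs and single-violation decoys.

    Each planted (miRNA, TF, gene) triple contributes its three edges; the
    miRNA→gene edge carries binding region ``3UTR``, binding gap 1 and a
    score ≥ 0.95, and appears under all three miRWalk source databases, so
    it passes both screening tiers.  Planted triples are sampled so the
    edge union closes over exactly the planted triads (no emergent loops).

    Each decoy edge violates exactly one criterion — binding region,
    binding gap, score, three-database consensus, or the TF disease flag —
    cycling through the five kinds; the violated criterion is recorded per
    decoy in the truth, making filter tests diagnostic per criterion.

    Returns ``({"mirna_gene": ..., "tf_gene": ..., "mirna_tf": ...}, truth)``.
    """
    config.validate()
    if config.n_planted_ffls > config.n_mirnas * config.n_tfs * config.n_targets:
        raise InvalidConfigError("n_planted_ffls exceeds the triple space")
    if 0 < config.n_decoys < 5:
        logger.warning(
            "n_decoys=%d < 5: not every violation criterion will be exercised",
            config.n_decoys,
        )
    rng = config.rng("regnet")
    mirnas = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(config.n_targets)]
    elif len(gene_ids) != config.n_targets:
        raise InvalidConfigError("gene_ids length must equal n_targets")

    # --- plant FFL triples, rejecting candidates that close emergent loops
    planted: list[tuple] = []
    m_t: set = set()
    m_g: set = set()
    t_g: set = set()
    attempts = 0
    while len(planted) < config.n_planted_ffls:
        attempts += 1
        if attempts > 200 * max(1, config.n_planted_ffls):
            raise InvalidConfigError(
                "could not plant emergent-free FFLs; enlarge the id spaces"
            )
        m = mirnas[rng.integers(config.n_mirnas)]
        t = tfs[rng.integers(config.n_tfs)]
        g = gene_ids[rng.integers(config.n_targets)]
        if (m, g) in m_g:  # keep miRNA→gene pairs unique across triples
            continue
        cand_mt, cand_mg, cand_tg = m_t | {(m, t)}, m_g | {(m, g)}, t_g | {(t, g)}
        if _closure_triads(cand_mt, cand_mg, cand_tg) != set(planted) | {(m, t, g)}:
            continue
        planted.append((m, t, g))
        m_t, m_g, t_g = cand_mt, cand_mg, cand_tg

    dbs = sorted(["TargetScan", "miRDB", "miRTarBase"])
    mg_rows, tg_rows, mt_rows = [], [], []
    for m, g in sorted(m_g):
        for db in dbs:
            mg_rows.append(
                (m, g, db, round(float(rng.uniform(0.95, 1.0)), 4), "3UTR", 1)
            )
    # pairs shared by several planted triples are emitted once
    for t, g in sorted(t_g):
        tg_rows.append((t, g, str(rng.choice(["ChIPBase", "ChEA"])), True))
    for m, t in sorted(m_t):
        mt_rows.append((m, t, "StarBase", round(float(rng.uniform(0.5, 1.0)), 4)))

    # --- decoys: each violates exactly one criterion
    decoys = []
    used_mg = set(m_g)
    used_tg = set(t_g)
    for k in range(config.n_decoys):
        criterion = DECOY_CRITERIA[k % len(DECOY_CRITERIA)]
        if criterion == "tf_flag":
            for _ in range(1000):
                t = tfs[rng.integers(config.n_tfs)]
                g = gene_ids[rng.integers(config.n_targets)]
                if (t, g) not in used_tg:
                    break
            else:
                raise InvalidConfigError("decoy TF→gene pair space exhausted")
            used_tg.add((t, g))
            tg_rows.append((t, g, str(rng.choice(["ChIPBase", "ChEA"])), False))
            decoys.append({"table": "tf_gene", "source": t, "target": g, "violates": criterion})
            continue
        for _ in range(1000):
            m = mirnas[rng.integers(config.n_mirnas)]
            g = gene_ids[rng.integers(config.n_targets)]
            if (m, g) not in used_mg:
                break
        else:
            raise InvalidConfigError("decoy miRNA→gene pair space exhausted")
        used_mg.add((m, g))
        region, gap = "3UTR", 1
        score_lo, score_hi = 0.95, 1.0
        row_dbs = dbs
        if criterion == "region":
            region = str(rng.choice(["CDS", "5UTR"]))
        elif criterion == "gap":
            gap = int(rng.integers(2, 5))
        elif criterion == "score":
            score_lo, score_hi = 0.50, 0.9499
        elif criterion == "consensus":
            row_dbs = sorted(str(d) for d in rng.choice(dbs, size=2, replace=False))
        for db in row_dbs:
            mg_rows.append(
                (m, g, db, round(float(rng.uniform(score_lo, score_hi)), 4), region, gap)
            )
        decoys.append({"table": "mirna_gene", "source": m, "target": g, "violates": criterion})

    tables = {
        "mirna_gene": pd.DataFrame(
            mg_rows,
            columns=["source", "target", "source_db", "score", "binding_region", "binding_gap"],
        ).sort_values(["source", "target", "source_db"], ignore_index=True),
        "tf_gene": pd.DataFrame(
            tg_rows, columns=["source", "target", "source_db", "disease_flag"]
        ).sort_values(["source", "target"], ignore_index=True),
        "mirna_tf": pd.DataFrame(
            mt_rows, columns=["source", "target", "source_db", "score"]
        ).sort_values(["source", "target"], ignore_index=True),
    }
    truth = SyntheticTruth(true_ffls=sorted(planted), decoy_edges=decoys)
    return tables, truth


def gen_sequences(config: SimConfig, mirna_id: str = "miR-sim", utr_id: str = "UTR-sim"):
    """A random miRNA and a random 3'UTR with one planted 8mer seed site.

    The UTR receives, at a random offset, the reverse complement of miRNA
    nucleotides 2-8 followed by an A (the canonical 8mer geometry); the
    planted offset and type are recorded in the truth.
    """
    config.validate()
    if config.mirna_len < 8:
        raise InvalidConfigError("mirna_len must be >= 8")
    if config.utr_len < 20:
        raise InvalidConfigError("utr_len must be >= 20")
    rng = config.rng("sequences")
    alphabet = np.array(list("ACGU"))
    mirna_seq = "".join(rng.choice(alphabet, size=config.mirna_len))
    mirna = NucSequence(id=mirna_id, seq=mirna_seq, alphabet="RNA")
    utr_chars = rng.choice(alphabet, size=config.utr_len)
    core = reverse_complement(
        NucSequence(id="_seed", seq=mirna_seq[1:8], alphabet="RNA")
    ).seq
    site = core + "A"  # 8mer: rc(nt 2-8) then the position-1 A
    start = int(rng.integers(1, config.utr_len - len(site) - 1))
    utr_chars[start : start + len(site)] = list(site)
    utr = NucSequence(id=utr_id, seq="".join(utr_chars), alphabet="RNA")
    truth = SyntheticTruth(
        seed_sites=[{"utr_id": utr_id, "site_type": "8mer", "start": start, "end": start + 8}]
    )
    return mirna, utr, truth
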