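"""End-to-end orchestration: simulate → DEGs → PPI → hubs → FFL → seed match.

:func:`run_all` runs the whole in-silico procedure on one directory: it
either generates a fully synthetic input set (expression matrix, scored
PPI export, regulatory tables, FASTA pair — with the planted truth written
alongside) or consumes user-supplied files, then screens DEGs, builds the
score-filtered PPI graph over them, calls hub genes by six-centrality
intersection, applies the two-tier miRNA screen plus TF curation flag,
assembles the miRNA-TF-gene network, enumerates feed-forward loops, ranks
the top triad by degree, and scans the UTR for seed sites.

Every stage writes its intermediate to disk and the machine-readable run
report is recomputed from those files, so the report never contains an
in-memory-only number.  The report carries no timestamps: two runs with
the same configuration produce byte-identical reports.

In synthetic mode the generated tables are wired together the way the
emulated study's inputs were: the PPI export covers (planted) disease
genes, the regulatory tables are fetched for the planted hub genes, and
the FASTA pair corresponds to the first planted loop's miRNA and target
UTR.  Mirroring the study's flow — regulatory tables are only queried for
called hub genes — the FFL stage restricts gene-directed edges to the hub
genes the pipeline actually called.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import centrality as ct
from . import diffexpr, ffl, io, ppi, seedmatch
from .errors import InvalidConfigError, NoFFLError, PipelineError
from .simulate import SimConfig, SyntheticTruth, gen_expression, gen_ppi, gen_regnet, gen_sequences

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and paths for one pipeline run.

    Threshold defaults are the emulated study's printed values: DEG alpha
    0.05 (strict <), PPI combined score > 0.9 (strict), tier-1 binding
    score ≥ 0.95 with binding gap 1 in the 3'UTR, and top-10 rankings per
    centrality measure.
    """

    alpha: float = 0.05
    min_ppi_score: float = 0.9
    tier1_min_score: float = 0.95
    tier1_region: str = "3UTR"
    tier1_gap: int = 1
    epc_reps: int = 1000
    top_k: int = 10
    deg_method: str = "welch"  # or "geo2r-compat"
    allow_gu: bool = False
    restrict_ffl_to_hubs: bool = True
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # optional user-supplied inputs; when None, synthetic inputs are generated
    inputs: dict | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidConfigError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 <= self.min_ppi_score <= 1.0:
            raise InvalidConfigError("min_ppi_score must be in [0,1]")
        if self.top_k < 1 or self.epc_reps < 1:
            raise InvalidConfigError("top_k and epc_reps must be >= 1")
        if self.deg_method not in ("welch", "geo2r-compat"):
            raise InvalidConfigError(f"unknown deg_method {self.deg_method!r}")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


_INPUT_FILES = {
    "expression": "expression.tsv",
    "phenotype": "phenotype.tsv",
    "ppi_edges": "ppi_edges.tsv",
    "mirna_gene": "mirna_gene.tsv",
    "tf_gene": "tf_gene.tsv",
    "mirna_tf": "mirna_tf.tsv",
    "mirna_fasta": "mirna.fasta",
    "utr_fasta": "utrs.fasta",
}


def simulate_inputs(config: RunConfig, outdir: Path) -> dict:
    """Generate the coherent synthetic input set and write it to ``outdir``.

    The PPI node universe is drawn from the planted disease genes (the
    clique, i.e. the intended hubs, gets the lexicographically smallest
    ids), and the regulatory tables target the planted hub genes.
    Returns the paths dict in the shape expected by :func:`run_all`.
    """
    sim = config.sim
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, phenotype, truth_expr = gen_expression(sim)
    planted = sorted(truth_expr.de_genes)
    if len(planted) >= sim.n_nodes:
        node_ids = planted[: sim.n_nodes]
    else:  # not enough planted genes: pad the PPI universe with null genes
        others = [g for g in matrix.index if g not in truth_expr.de_genes]
        node_ids = sorted(planted + others[: sim.n_nodes - len(planted)])
    edges, truth_ppi = gen_ppi(sim, node_ids=node_ids)
    regnet_sim = dataclasses.replace(sim, n_targets=sim.hub_clique_size)
    tables, truth_reg = gen_regnet(regnet_sim, gene_ids=truth_ppi.hub_nodes)
    mirna, utr, truth_seq = gen_sequences(sim)

    paths = {k: outdir / v for k, v in _INPUT_FILES.items()}
    io.write_expression_tsv(matrix, paths["expression"])
    io.write_phenotype_tsv(phenotype, paths["phenotype"])
    io.write_table_tsv(edges, paths["ppi_edges"])
    io.write_table_tsv(tables["mirna_gene"], paths["mirna_gene"])
    io.write_table_tsv(tables["tf_gene"], paths["tf_gene"])
    io.write_table_tsv(tables["mirna_tf"], paths["mirna_tf"])
    io.write_fasta([mirna], paths["mirna_fasta"])
    io.write_fasta([utr], paths["utr_fasta"])

    truth = SyntheticTruth(
        de_genes=truth_expr.de_genes,
        hub_nodes=truth_ppi.hub_nodes,
        true_ffls=truth_reg.true_ffls,
        decoy_edges=truth_reg.decoy_edges,
        seed_sites=truth_seq.seed_sites,
    )
    io.write_json(truth.as_dict(), outdir / "truth.json")
    return {k: str(v) for k, v in paths.items()}


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage in order, writing intermediates and the run report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Stage failures propagate with the stage name prepended; previously
    written outputs stay on disk next to a ``FAILED`` marker naming the
    stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "fflhub",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "alpha": config.alpha,
            "min_ppi_score": config.min_ppi_score,
            "tier1_min_score": config.tier1_min_score,
            "tier1_region": config.tier1_region,
            "tier1_gap": config.tier1_gap,
            "epc_reps": config.epc_reps,
            "top_k": config.top_k,
            "deg_method": config.deg_method,
            "allow_gu": config.allow_gu,
            "restrict_ffl_to_hubs": config.restrict_ffl_to_hubs,
            "synthetic": config.inputs is None,
            "sim": dataclasses.asdict(config.sim) if config.inputs is None else None,
        },
        "stages": {},
    }
    stage = "simulate"
    try:
        if config.inputs is None:
            t0 = time.perf_counter()
            inputs = simulate_inputs(config, outdir / "inputs")
            logger.info("stage simulate: %.2fs", time.perf_counter() - t0)
        else:
            missing = set(_INPUT_FILES) - set(config.inputs)
            if missing:
                raise InvalidConfigError(f"inputs dict missing: {sorted(missing)}")
            inputs = config.inputs

        # ---- differential expression -------------------------------------
        stage = "degs"
        t0 = time.perf_counter()
        matrix = io.read_expression_tsv(inputs["expression"])
        phenotype = io.read_phenotype_tsv(inputs["phenotype"])
        deg_table = diffexpr.run_deg(
            matrix, phenotype, alpha=config.alpha, method=config.deg_method
        )
        io.write_table_tsv(deg_table.reset_index(), outdir / "deg_table.tsv")
        deg_table = io.read_table_tsv(outdir / "deg_table.tsv").set_index("gene_id")
        summary = diffexpr.deg_summary(deg_table, alpha=config.alpha)
        io.write_json(summary, outdir / "deg_summary.json")
        report["stages"]["degs"] = summary
        deg_ids = deg_table.index[deg_table["p_value"] < config.alpha]
        # heatmap-style panel: top-10 up and top-10 down DEGs, row-zscored,
        # clustered with Pearson distance / complete linkage
        panel_ids = [
            g
            for direction in ("up", "down")
            for g in deg_table[deg_table["direction"] == direction]
            .sort_values(["p_value", "log2fc"])
            .head(10)
            .index
        ]
        if len(panel_ids) >= 2:
            dend = diffexpr.hclust_pearson_complete(
                diffexpr.row_zscore(matrix.loc[panel_ids])
            )
            report["stages"]["degs"]["heatmap_panel"] = panel_ids
            report["stages"]["degs"]["heatmap_leaf_order"] = dend.leaf_order
        else:
            report["stages"]["degs"]["heatmap_panel"] = panel_ids
            report["stages"]["degs"]["heatmap_leaf_order"] = panel_ids
        logger.info("stage degs: %.2fs (%d DEGs)", time.perf_counter() - t0, len(deg_ids))

        # ---- PPI graph ----------------------------------------------------
        stage = "ppi"
        t0 = time.perf_counter()
        raw_edges = io.read_table_tsv(inputs["ppi_edges"])
        kept = ppi.filter_edges(raw_edges, min_score=config.min_ppi_score)
        exported = set(raw_edges["node_a"]) | set(raw_edges["node_b"])
        whitelist = [g for g in deg_ids if g in exported]
        graph = ppi.build_graph(kept, whitelist)
        io.write_sif(graph, outdir / "ppi_network.sif")
        io.write_graphml(graph, outdir / "ppi_network.graphml")
        report["stages"]["ppi"] = {
            "n_input_edges": int(len(raw_edges)),
            "n_filtered_edges": int(len(kept)),
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
        }
        logger.info("stage ppi: %.2fs", time.perf_counter() - t0)

        # ---- centralities and hub call -------------------------------------
        stage = "hubs"
        t0 = time.perf_counter()
        scores = ct.all_centralities(
            graph, epc_reps=config.epc_reps, seed=[config.seed, 100]
        )
        nodes = sorted(graph.nodes, key=str)
        cent = pd.DataFrame({"node": nodes})
        for measure in ct.MEASURES:
            cent[measure] = [scores[measure][v] for v in nodes]
            order = ct.top_k(scores[measure], k=max(1, len(nodes)))
            rank = {v: i + 1 for i, v in enumerate(order)}
            cent[f"{measure}_rank"] = [rank[v] for v in nodes]
        io.write_table_tsv(cent, outdir / "centralities.tsv")
        tops = {
            m: ct.top_k(scores[m], k=config.top_k) for m in ct.MEASURES
        }
        hubs = sorted(set.intersection(*(set(t) for t in tops.values()))) if nodes else []
        io.write_json({"top_k": tops, "k": config.top_k, "hubs": hubs}, outdir / "hubs.json")
        # rank-based group comparison of each called hub gene's expression
        hub_wilcoxon = {}
        for gene in hubs:
            if gene in matrix.index:
                case_vals = matrix.loc[gene, phenotype == phenotype.unique()[0]]
                ctrl_vals = matrix.loc[gene, phenotype != phenotype.unique()[0]]
                hub_wilcoxon[gene] = diffexpr.wilcoxon_ranksum(case_vals, ctrl_vals)
        report["stages"]["hubs"] = {
            "per_measure_top_k": tops,
            "hubs": hubs,
            "wilcoxon_p": hub_wilcoxon,
        }
        logger.info("stage hubs: %.2fs (hubs: %s)", time.perf_counter() - t0, hubs)

        # ---- regulatory network and FFL mining ------------------------------
        stage = "ffl"
        t0 = time.perf_counter()
        mirna_gene = io.read_table_tsv(inputs["mirna_gene"])
        tf_gene = io.read_table_tsv(inputs["tf_gene"])
        mirna_tf = io.read_table_tsv(inputs["mirna_tf"])
        if config.restrict_ffl_to_hubs:
            mirna_gene = mirna_gene[mirna_gene["target"].isin(hubs)]
            tf_gene = tf_gene[tf_gene["target"].isin(hubs)]
        tier1 = ffl.tier1_filter(
            mirna_gene,
            min_score=config.tier1_min_score,
            region=config.tier1_region,
            gap=config.tier1_gap,
        )
        tier2 = ffl.tier2_consensus(tier1)
        tf_kept = ffl.tf_screen(tf_gene)
        mirna_tf_kept = mirna_tf.drop_duplicates(subset=["source", "target"])
        network = ffl.assemble(tier2, tf_kept, mirna_tf_kept)
        triads = ffl.enumerate_ffl(network)
        io.write_sif(network, outdir / "ffl_network.sif")
        io.write_graphml(network, outdir / "ffl_network.graphml")
        triad_table = pd.DataFrame(
            [dataclasses.asdict(t) for t in triads],
            columns=["mirna", "tf", "gene", "degree_sum"],
        )
        io.write_table_tsv(triad_table, outdir / "ffl_triads.tsv")
        try:
            top = ffl.top_subnetwork(triads)
            top_payload = dataclasses.asdict(top)
        except NoFFLError:
            top_payload = None
        node_stats, highlights = ffl.summarize(network)
        io.write_table_tsv(node_stats, outdir / "ffl_node_stats.tsv")
        ffl_summary = {
            "n_nodes": network.number_of_nodes(),
            "n_edges": network.number_of_edges(),
            "per_class_counts": network.graph.get("edge_counts", {}),
            "per_class_counts_raw": network.graph.get("edge_counts_raw", {}),
            "n_triads": len(triads),
            "top_triad": top_payload,
            "degree_definition": "sum of total (in+out) degrees of the triad's "
            "three nodes in the merged network",
            "highlights": {k: list(v) for k, v in highlights.items()},
        }
        io.write_json(ffl_summary, outdir / "ffl_summary.json")
        report["stages"]["ffl"] = ffl_summary
        logger.info("stage ffl: %.2fs (%d triads)", time.perf_counter() - t0, len(triads))

        # ---- seed matching ---------------------------------------------------
        stage = "seedmatch"
        t0 = time.perf_counter()
        mirnas = io.read_fasta(inputs["mirna_fasta"])
        utrs = io.read_fasta(inputs["utr_fasta"])
        site_rows = []
        for utr in utrs:
            for site in seedmatch.find_seed_sites(mirnas[0], utr, allow_gu=config.allow_gu):
                site_rows.append(
                    {
                        "utr_id": site.utr_id,
                        "site_type": site.site_type,
                        "start_1based": site.start_1based,
                        "end_1based": site.end_1based,
                        "matched_seq": site.matched_seq,
                    }
                )
        sites = pd.DataFrame(
            site_rows,
            columns=["utr_id", "site_type", "start_1based", "end_1based", "matched_seq"],
        )
        io.write_table_tsv(sites, outdir / "seed_sites.tsv")
        report["stages"]["seedmatch"] = {
            "mirna": mirnas[0].id,
            "n_sites": int(len(sites)),
            "sites": site_rows,
        }
        logger.info("stage seedmatch: %.2fs", time.perf_counter() - t0)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"[stage {stage}] {exc}") from exc

    io.write_json(report, outdir / "report.json")
    return report
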