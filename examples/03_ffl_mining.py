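"""Mine miRNA-TF-gene feed-forward loops from regulatory tables.

Generates miRWalk/ChIPBase/StarBase-style tables with planted loops and
single-violation decoys, applies the two-tier miRNA screen (binding region
3UTR, binding gap 1, score >= 0.95; then three-database consensus) and the
TF disease-curation flag, assembles the tripartite network, and ranks the
closed triads by the total degree of their members.
"""

from fflhub import ffl
from fflhub.simulate import SimConfig, gen_regnet

cfg = SimConfig(n_planted_ffls=5, n_decoys=20, seed=3)
tables, truth = gen_regnet(cfg)

tier1 = ffl.tier1_filter(tables["mirna_gene"])
tier2 = ffl.tier2_consensus(tier1)
print(f"miRNA-gene rows: {len(tables['mirna_gene'])} -> tier1 {len(tier1)} "
      f"-> tier2 consensus pairs {len(tier2)}")

network = ffl.assemble(
    tier2,
    ffl.tf_screen(tables["tf_gene"]),
    tables["mirna_tf"].drop_duplicates(["source", "target"]),
)
print(f"network: {network.number_of_nodes()} nodes, "
      f"{network.number_of_edges()} edges by class {network.graph['edge_counts']}")

triads = ffl.enumerate_ffl(network)
print(f"closed feed-forward loops: {len(triads)} (planted: {len(truth.true_ffls)})")
top = ffl.top_subnetwork(triads)
print(f"top triad by degree: {top.mirna} -| {top.tf} -> {top.gene} "
      f"(degree sum {top.degree_sum})")
# Every loop passing the filters is a planted one: each decoy edge was
# built to violate exactly one screening criterion.
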