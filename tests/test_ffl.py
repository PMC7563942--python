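"""Two-tier miRNA screen, TF curation, FFL assembly and triad mining."""

import numpy as np
import pandas as pd
import pytest

from fflhub import ffl
from fflhub.errors import NoFFLError, SchemaError, TypeConflictError, ValidationError
from fflhub.simulate import SimConfig, gen_regnet

import oracles

MG_COLS = ["source", "target", "source_db", "score", "binding_region", "binding_gap"]


def mg_frame(rows):
    return pd.DataFrame(rows, columns=MG_COLS)


class TestTier1:
    def test_inclusive_score_threshold(self):
        edges = mg_frame([
            ("m1", "g1", "TargetScan", 0.95, "3UTR", 1),
            ("m1", "g2", "TargetScan", 0.9499, "3UTR", 1),
        ])
        kept = ffl.tier1_filter(edges)
        assert list(kept["target"]) == ["g1"]

    def test_region_and_gap_criteria(self):
        edges = mg_frame([
            ("m1", "g1", "miRDB", 0.99, "CDS", 1),
            ("m1", "g2", "miRDB", 0.99, "3UTR", 2),
            ("m1", "g3", "miRDB", 0.99, "3UTR", 1),
        ])
        assert list(ffl.tier1_filter(edges)["target"]) == ["g3"]

    def test_missing_column_rejected(self):
        with pytest.raises(SchemaError):
            ffl.tier1_filter(pd.DataFrame({"source": [], "target": []}))

    def test_idempotent_and_order_invariant(self, rng):
        rows = [
            (f"m{i % 4}", f"g{i % 7}",
             ["TargetScan", "miRDB", "miRTarBase"][i % 3],
             float(rng.uniform(0.8, 1.0)),
             ["3UTR", "CDS"][i % 2], int(rng.integers(1, 3)))
            for i in range(40)
        ]
        edges = mg_frame(rows)
        once = ffl.tier1_filter(edges)
        pd.testing.assert_frame_equal(ffl.tier1_filter(once), once)
        shuffled = edges.sample(frac=1, random_state=0).reset_index(drop=True)
        again = ffl.tier1_filter(shuffled)
        key = lambda df: sorted(map(tuple, df.to_numpy()))
        assert key(once) == key(again)


class TestTier2:
    def test_two_of_three_databases_dropped(self):
        edges = mg_frame([
            ("m1", "g1", "TargetScan", 0.99, "3UTR", 1),
            ("m1", "g1", "miRDB", 0.99, "3UTR", 1),
        ])
        assert ffl.tier2_consensus(edges).empty

    def test_full_consensus_consolidated(self):
        edges = mg_frame([
            ("m1", "g1", db, 0.95 + i / 100, "3UTR", 1)
            for i, db in enumerate(["TargetScan", "miRDB", "miRTarBase"])
        ])
        out = ffl.tier2_consensus(edges)
        assert len(out) == 1
        assert out.loc[0, "n_dbs"] == 3
        assert out.loc[0, "score"] == pytest.approx(0.97)

    def test_unknown_database_rejected(self):
        edges = mg_frame([("m1", "g1", "PicTar", 0.99, "3UTR", 1)])
        with pytest.raises(ValidationError):
            ffl.tier2_consensus(edges)

    def test_matches_set_intersection_oracle(self, rng):
        rows = []
        for i in range(120):
            rows.append((
                f"m{rng.integers(5)}", f"g{rng.integers(8)}",
                ["TargetScan", "miRDB", "miRTarBase"][int(rng.integers(3))],
                1.0, "3UTR", 1,
            ))
        edges = mg_frame(rows)
        out = ffl.tier2_consensus(edges)
        per_db = {
            db: {(r[0], r[1]) for r in rows if r[2] == db}
            for db in ("TargetScan", "miRDB", "miRTarBase")
        }
        expected = set.intersection(*per_db.values())
        assert set(zip(out["source"], out["target"])) == expected


class TestTfScreen:
    def test_flag_filtering_and_count(self, rng):
        flags = rng.random(30) < 0.5
        table = pd.DataFrame({
            "source": [f"t{i}" for i in range(30)],
            "target": ["g1"] * 30,
            "disease_flag": flags,
        })
        kept = ffl.tf_screen(table)
        assert len(kept) == int(flags.sum())
        assert kept["disease_flag"].all()


def build_simple_network():
    mg = pd.DataFrame({"source": ["m1", "m1"], "target": ["g1", "g2"]})
    tg = pd.DataFrame({"source": ["t1"], "target": ["g1"], "disease_flag": [True]})
    mt = pd.DataFrame({"source": ["m1"], "target": ["t1"]})
    return ffl.assemble(mg, tg, mt)


class TestAssemble:
    def test_empty_inputs_empty_network(self):
        empty = pd.DataFrame(columns=["source", "target"])
        net = ffl.assemble(empty, empty.assign(disease_flag=[]), empty)
        assert net.number_of_nodes() == 0
        assert net.number_of_edges() == 0

    def test_counts_match_set_union_oracle(self, rng):
        mg = pd.DataFrame({
            "source": [f"m{rng.integers(3)}" for _ in range(20)],
            "target": [f"g{rng.integers(4)}" for _ in range(20)],
        })
        tg = pd.DataFrame({
            "source": [f"t{rng.integers(3)}" for _ in range(20)],
            "target": [f"g{rng.integers(4)}" for _ in range(20)],
            "disease_flag": True,
        })
        mt = pd.DataFrame({
            "source": [f"m{rng.integers(3)}" for _ in range(20)],
            "target": [f"t{rng.integers(3)}" for _ in range(20)],
        })
        net = ffl.assemble(mg, tg, mt)
        mg_set = set(zip(mg["source"], mg["target"]))
        tg_set = set(zip(tg["source"], tg["target"]))
        mt_set = set(zip(mt["source"], mt["target"]))
        assert net.number_of_edges() == len(mg_set | tg_set | mt_set)
        nodes = {x for pair in mg_set | tg_set | mt_set for x in pair}
        assert net.number_of_nodes() == len(nodes)
        assert net.graph["edge_counts"] == {
            "mirna-gene": len(mg_set), "tf-gene": len(tg_set), "mirna-tf": len(mt_set)
        }

    def test_type_conflict_detected(self):
        mg = pd.DataFrame({"source": ["m1"], "target": ["t1"]})  # gene id == TF id
        tg = pd.DataFrame({"source": ["t1"], "target": ["g1"], "disease_flag": [True]})
        mt = pd.DataFrame({"source": ["m1"], "target": ["t1"]})
        with pytest.raises(TypeConflictError):
            ffl.assemble(mg, tg, mt)

    def test_tf_tf_edges_dropped_with_count(self):
        mg = pd.DataFrame({"source": ["m1"], "target": ["g1"]})
        tg = pd.DataFrame({
            "source": ["t1", "t1"], "target": ["g1", "t2"], "disease_flag": True
        })
        mt = pd.DataFrame({"source": ["m1"], "target": ["t2"]})
        net = ffl.assemble(mg, tg, mt)
        assert net.graph["n_tf_tf_dropped"] == 1
        assert not net.has_edge("t1", "t2")


class TestEnumerate:
    def test_simple_loop_found(self):
        net = build_simple_network()
        triads = ffl.enumerate_ffl(net)
        assert [(t.mirna, t.tf, t.gene) for t in triads] == [("m1", "t1", "g1")]
        # m1: deg 3 (g1, g2, t1); t1: deg 2; g1: deg 2
        assert triads[0].degree_sum == 7

    def test_missing_tf_gene_edge_breaks_triad(self):
        mg = pd.DataFrame({"source": ["m1"], "target": ["g1"]})
        tg = pd.DataFrame({"source": ["t1"], "target": ["g2"], "disease_flag": [True]})
        mt = pd.DataFrame({"source": ["m1"], "target": ["t1"]})
        assert ffl.enumerate_ffl(ffl.assemble(mg, tg, mt)) == []

    def test_no_mirna_tf_edges_no_triads(self):
        mg = pd.DataFrame({"source": ["m1"], "target": ["g1"]})
        tg = pd.DataFrame({"source": ["t1"], "target": ["g1"], "disease_flag": [True]})
        mt = pd.DataFrame(columns=["source", "target"])
        assert ffl.enumerate_ffl(ffl.assemble(mg, tg, mt)) == []

    def test_matches_bruteforce_on_synthetic(self):
        cfg = SimConfig(n_mirnas=6, n_tfs=8, n_targets=5, n_planted_ffls=7,
                        n_decoys=0, seed=5)
        tables, truth = gen_regnet(cfg)
        tier2 = ffl.tier2_consensus(ffl.tier1_filter(tables["mirna_gene"]))
        net = ffl.assemble(tier2, ffl.tf_screen(tables["tf_gene"]),
                           tables["mirna_tf"].drop_duplicates(["source", "target"]))
        mine = {(t.mirna, t.tf, t.gene) for t in ffl.enumerate_ffl(net)}
        brute = oracles.ffl_triple_scan(
            set(zip(tables["mirna_tf"]["source"], tables["mirna_tf"]["target"])),
            set(zip(tier2["source"], tier2["target"])),
            set(zip(tables["tf_gene"]["source"], tables["tf_gene"]["target"])),
        )
        assert mine == brute == set(map(tuple, truth.true_ffls))


class TestTopSubnetwork:
    def test_single_triad_is_top(self):
        triads = [ffl.FFLTriad("m1", "t1", "g1", 5)]
        assert ffl.top_subnetwork(triads) == triads[0]

    def test_degree_then_lexicographic(self):
        triads = [
            ffl.FFLTriad("m2", "t1", "g1", 9),
            ffl.FFLTriad("m1", "t9", "g9", 9),
            ffl.FFLTriad("m3", "t0", "g0", 7),
        ]
        assert ffl.top_subnetwork(triads).mirna == "m1"

    def test_empty_rejected(self):
        with pytest.raises(NoFFLError):
            ffl.top_subnetwork([])

    def test_planted_high_degree_triad_wins(self):
        # one miRNA-TF-gene trio wired to many extra partners
        mg = pd.DataFrame({
            "source": ["mBig"] * 4 + ["mSmall"],
            "target": ["gBig", "g2", "g3", "g4", "gSmall"],
        })
        tg = pd.DataFrame({
            "source": ["tBig"] * 4 + ["tSmall"],
            "target": ["gBig", "g2", "g3", "g4", "gSmall"],
            "disease_flag": True,
        })
        mt = pd.DataFrame({
            "source": ["mBig", "mSmall"], "target": ["tBig", "tSmall"]
        })
        triads = ffl.enumerate_ffl(ffl.assemble(mg, tg, mt))
        top = ffl.top_subnetwork(triads)
        assert (top.mirna, top.tf) == ("mBig", "tBig")


class TestSummarize:
    def test_empty_network(self):
        table, highlights = ffl.summarize(ffl.assemble(
            pd.DataFrame(columns=["source", "target"]),
            pd.DataFrame(columns=["source", "target", "disease_flag"]),
            pd.DataFrame(columns=["source", "target"]),
        ))
        assert table.empty
        assert highlights == {}

    def test_counts_match_adjacency_oracle(self):
        cfg = SimConfig(n_mirnas=5, n_tfs=6, n_targets=4, n_planted_ffls=6,
                        n_decoys=0, seed=9)
        tables, _ = gen_regnet(cfg)
        net = ffl.assemble(
            ffl.tier2_consensus(ffl.tier1_filter(tables["mirna_gene"])),
            ffl.tf_screen(tables["tf_gene"]),
            tables["mirna_tf"].drop_duplicates(["source", "target"]),
        )
        table, highlights = ffl.summarize(net)
        for _, row in table.iterrows():
            v = row["node"]
            assert row["n_genes_targeted"] == sum(
                1 for _, _, e in net.out_edges(v, data="etype") if e == "mirna-gene"
            )
            assert row["n_tf_regulators"] == sum(
                1 for _, _, e in net.in_edges(v, data="etype") if e == "tf-gene"
            )
        best_gene, best_count = highlights["gene_most_tf_regulators"]
        genes = table[table["kind"] == "gene"]
        assert best_count == genes["n_tf_regulators"].max()
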