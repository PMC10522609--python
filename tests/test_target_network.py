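"""Tests for network construction, node strengths, selection and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitranet.diffexpr import SignedMiRNASet
from mitranet.target_network import (
    InteractionRecord,
    build_network,
    export_network,
    node_strengths,
    passes_threshold,
    read_edgelist,
    read_interactions,
    select_targets,
)

from conftest import brute_force_strengths


def _write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


class TestThresholds:
    @pytest.mark.parametrize("score,kept", [(80.0, False), (80.01, True),
                                            (79.99, False), (100.0, True)])
    def test_mirdb_strict(self, score, kept):
        assert passes_threshold("mirdb", score) is kept

    @pytest.mark.parametrize("score,kept", [(-1.2, False), (-1.21, True),
                                            (-1.19, False), (-5.0, True)])
    def test_mirsvr_strict(self, score, kept):
        assert passes_threshold("mirsvr", score) is kept

    def test_validated_always_kept(self):
        assert passes_threshold("validated", None)


class TestReadInteractions:
    def test_mirdb_threshold_applied(self, tmp_path):
        path = tmp_path / "mirdb.tsv"
        _write_tsv(path, ["mirna", "gene", "score"],
                   [["miR-1", "G1", 80.0], ["miR-1", "G2", 80.01],
                    ["miR-2", "G3", 95.5]])
        recs = read_interactions(path, "mirdb")
        assert {(r.mirna_id, r.gene_id) for r in recs} == {
            ("rno-mir-1", "G2"), ("rno-mir-2", "G3")}

    def test_mirsvr_threshold_applied(self, tmp_path):
        path = tmp_path / "mirsvr.tsv"
        _write_tsv(path, ["mirna", "gene", "mirsvr_score"],
                   [["miR-1", "G1", -1.2], ["miR-1", "G2", -1.21]])
        recs = read_interactions(path, "mirsvr")
        assert [(r.gene_id, r.score) for r in recs] == [("G2", -1.21)]

    def test_validated_rows_kept_without_score(self, tmp_path):
        path = tmp_path / "validated.tsv"
        _write_tsv(path, ["mirna", "gene", "evidence"],
                   [["miR-1", "G1", "reporter_assay"]])
        recs = read_interactions(path, "validated")
        assert recs[0].score is None and recs[0].source == "validated"

    def test_malformed_and_missing_score_rows_skipped(self, tmp_path, caplog):
        path = tmp_path / "mirdb.tsv"
        _write_tsv(path, ["mirna", "gene", "score"],
                   [["miR-1", "", 90.0], ["miR-2", "G2", "n/a"],
                    ["miR-3", "G3", 90.0]])
        with caplog.at_level("WARNING"):
            recs = read_interactions(path, "mirdb")
        assert len(recs) == 1 and recs[0].gene_id == "G3"
        assert "malformed" in caplog.text and "invalid score" in caplog.text

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_interactions(tmp_path / "x.tsv", "targetscan")

    def test_custom_thresholds(self, tmp_path):
        path = tmp_path / "mirdb.tsv"
        _write_tsv(path, ["mirna", "gene", "score"], [["miR-1", "G1", 75.0]])
        assert len(read_interactions(path, "mirdb", mirdb_min=70.0)) == 1


def _rec(m, g, source="validated", score=None):
    return InteractionRecord(m, g, source, score)


class TestBuildNetwork:
    def test_empty_interactions_give_mirna_only_network(self, signed_small):
        net = build_network(signed_small, [])
        assert net.mirnas == signed_small.up | signed_small.down
        assert net.genes == set()

    def test_up_mirna_edge_weight_plus_one(self):
        signed = SignedMiRNASet(up={"rno-mir-1"})
        net = build_network(signed, [_rec("rno-mir-1", "G1")])
        assert net.edges[("rno-mir-1", "G1")].weight == 1

    def test_down_mirna_edge_weight_minus_one(self):
        signed = SignedMiRNASet(down={"rno-mir-1"})
        net = build_network(signed, [_rec("rno-mir-1", "G1")])
        assert net.edges[("rno-mir-1", "G1")].weight == -1

    def test_duplicate_pair_across_sources_collapses_with_provenance(self):
        signed = SignedMiRNASet(up={"rno-mir-1"})
        recs = [_rec("rno-mir-1", "G1", "validated"),
                _rec("rno-mir-1", "G1", "mirdb", 90.0),
                _rec("rno-mir-1", "G1", "mirsvr", -2.0)]
        net = build_network(signed, recs)
        assert len(net.edges) == 1
        assert net.edges[("rno-mir-1", "G1")].sources == {"validated", "mirdb", "mirsvr"}

    def test_non_signed_mirna_interactions_dropped(self):
        signed = SignedMiRNASet(up={"rno-mir-1"})
        net = build_network(signed, [_rec("rno-mir-2", "G1")])
        assert net.genes == set()

    def test_empty_signed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_network(SignedMiRNASet(), [])


class TestNodeStrengths:
    def test_seven_up_regulators_predict_downregulation(self):
        signed = SignedMiRNASet(up={f"rno-mir-{i}" for i in range(7)})
        recs = [_rec(f"rno-mir-{i}", "G1") for i in range(7)]
        table = node_strengths(build_network(signed, recs))
        row = table.iloc[0]
        assert row.node_strength == 7
        assert row.predicted_direction == "down"
        assert bool(row.unidirectional)

    def test_balanced_regulators_cancel(self):
        signed = SignedMiRNASet(up={"u1", "u2", "u3"}, down={"d1", "d2", "d3"})
        recs = [_rec(m, "G1") for m in ("u1", "u2", "u3", "d1", "d2", "d3")]
        row = node_strengths(build_network(signed, recs)).iloc[0]
        assert row.node_strength == 0
        assert row.predicted_direction == "ambiguous"
        assert not row.unidirectional

    def test_sorted_by_abs_strength_then_gene_id(self):
        signed = SignedMiRNASet(up={"u1", "u2"}, down={"d1", "d2"})
        recs = [_rec("u1", "B"), _rec("u2", "B"),  # +2
                _rec("d1", "A"), _rec("d2", "A"),  # -2
                _rec("u1", "C")]                   # +1
        table = node_strengths(build_network(signed, recs))
        assert table.gene_id.tolist() == ["A", "B", "C"]

    def test_matches_brute_force_on_random_fixture(self, rng, signed_small):
        mirnas = sorted(signed_small.up | signed_small.down)
        recs = []
        for _ in range(400):
            m = mirnas[rng.integers(len(mirnas))]
            g = f"G{rng.integers(60):03d}"
            src = ("validated", "mirdb", "mirsvr")[rng.integers(3)]
            score = {"validated": None, "mirdb": 90.0, "mirsvr": -2.0}[src]
            recs.append(_rec(m, g, src, score))
        table = node_strengths(build_network(signed_small, recs))
        expected = brute_force_strengths(recs, signed_small)
        assert dict(zip(table.gene_id, table.node_strength)) == expected

    def test_direction_flip_negates_strengths(self, rng, signed_small):
        mirnas = sorted(signed_small.up | signed_small.down)
        recs = [_rec(mirnas[rng.integers(len(mirnas))], f"G{rng.integers(40):03d}")
                for _ in range(200)]
        fwd = node_strengths(build_network(signed_small, recs))
        flipped = SignedMiRNASet(up=signed_small.down, down=signed_small.up)
        rev = node_strengths(build_network(flipped, recs))
        f = dict(zip(fwd.gene_id, fwd.node_strength))
        r = dict(zip(rev.gene_id, rev.node_strength))
        assert f.keys() == r.keys()
        assert all(r[g] == -s for g, s in f.items())

    def test_abs_strength_bounded_by_degree(self, rng, signed_small):
        mirnas = sorted(signed_small.up | signed_small.down)
        recs = [_rec(mirnas[rng.integers(len(mirnas))], f"G{rng.integers(30):03d}")
                for _ in range(150)]
        net = build_network(signed_small, recs)
        degree: dict[str, int] = {}
        for _, g in net.edges:
            degree[g] = degree.get(g, 0) + 1
        for row in node_strengths(net).itertuples():
            assert abs(row.node_strength) <= degree[row.gene_id]
            assert (abs(row.node_strength) == degree[row.gene_id]) == row.unidirectional

    def test_subset_restriction_never_increases_counts(self, rng, signed_small):
        mirnas = sorted(signed_small.up | signed_small.down)
        recs = [_rec(mirnas[rng.integers(len(mirnas))], f"G{rng.integers(30):03d}")
                for _ in range(150)]
        full = node_strengths(build_network(signed_small, recs)).set_index("gene_id")
        sub_signed = SignedMiRNASet(up=set(sorted(signed_small.up)[:4]),
                                    down=set(sorted(signed_small.down)[:2]))
        sub = node_strengths(build_network(sub_signed, recs)).set_index("gene_id")
        for g in sub.index:
            assert sub.loc[g, "n_up_regulators"] <= full.loc[g, "n_up_regulators"]
            assert sub.loc[g, "n_down_regulators"] <= full.loc[g, "n_down_regulators"]


class TestSelectTargets:
    @pytest.fixture
    def tiered_table(self):
        signed = SignedMiRNASet(up={f"u{i}" for i in range(8)})
        ups = sorted(f"u{i}" for i in range(8))
        recs = []
        for i in range(4):  # tier-1 genes at strength 7
            recs += [_rec(m, f"T1_{i}") for m in ups[:7]]
        for i in range(10):  # tier-2 genes, unidirectional at 6
            recs += [_rec(m, f"T2_{i}") for m in ups[:6]]
        for i in range(20):  # background at 1..4
            recs += [_rec(m, f"BG_{i}") for m in ups[: 1 + i % 4]]
        return node_strengths(build_network(signed, recs))

    def test_tier1_is_all_genes_at_max_strength(self, tiered_table):
        sel = select_targets(tiered_table, unidirectional_strength=6)
        assert (sel.tier == "tier1").sum() == 4
        assert set(sel.loc[sel.tier == "tier1", "node_strength"]) == {7}

    def test_tier2_unidirectional_at_specified_strength(self, tiered_table):
        sel = select_targets(tiered_table, unidirectional_strength=6)
        assert (sel.tier == "tier2").sum() == 10

    def test_tier3_seeded_random_sample(self, tiered_table):
        sel1 = select_targets(tiered_table, unidirectional_strength=6,
                              n_random_strong=4, strong_floor=2, seed=7)
        sel2 = select_targets(tiered_table, unidirectional_strength=6,
                              n_random_strong=4, strong_floor=2, seed=7)
        t3 = set(sel1.loc[sel1.tier == "tier3", "gene_id"])
        assert len(t3) == 4
        assert t3 == set(sel2.loc[sel2.tier == "tier3", "gene_id"])
        assert all(g.startswith("BG_") for g in t3)

    def test_zero_random_gives_empty_tier3(self, tiered_table):
        sel = select_targets(tiered_table, unidirectional_strength=6)
        assert (sel.tier == "tier3").sum() == 0

    def test_tiers_disjoint(self, tiered_table):
        sel = select_targets(tiered_table, unidirectional_strength=6,
                             n_random_strong=4, strong_floor=1, seed=1)
        assert sel.gene_id.is_unique

    def test_unreachable_unidirectional_strength_warns_empty_tier2(self, tiered_table, caplog):
        with caplog.at_level("WARNING"):
            sel = select_targets(tiered_table, unidirectional_strength=99)
        assert (sel.tier == "tier2").sum() == 0
        assert "exceeds max" in caplog.text

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_targets(pd.DataFrame(columns=["gene_id", "node_strength"]))


class TestExport:
    @pytest.fixture
    def small_net(self):
        signed = SignedMiRNASet(up={"rno-mir-1"}, down={"rno-mir-2"})
        recs = [_rec("rno-mir-1", "G1", "validated"),
                _rec("rno-mir-1", "G2", "mirdb", 90.0),
                _rec("rno-mir-2", "G1", "mirsvr", -2.0)]
        return build_network(signed, recs)

    def test_sif_lines(self, small_net, tmp_path):
        path = tmp_path / "net.sif"
        export_network(small_net, path, "sif")
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert "rno-mir-1\t1\tG1" in lines
        assert "rno-mir-2\t-1\tG1" in lines

    def test_empty_network_edge_list_is_header_only(self, tmp_path):
        from mitranet.target_network import TargetNetwork
        path = tmp_path / "net.tsv"
        export_network(TargetNetwork(mirna_direction={"rno-mir-1": "up"}), path, "tsv")
        assert path.read_text().splitlines() == [
            "mirna\tgene\tweight\tmirna_direction\tsources"]

    def test_edgelist_round_trip_preserves_strengths(self, small_net, tmp_path):
        path = tmp_path / "net.tsv"
        export_network(small_net, path, "tsv")
        back = read_edgelist(path)
        assert back.edges.keys() == small_net.edges.keys()
        assert node_strengths(back).equals(node_strengths(small_net))

    def test_graphml_node_attributes(self, small_net, tmp_path):
        import networkx as nx
        path = tmp_path / "net.graphml"
        strengths = node_strengths(small_net)
        export_network(small_net, path, "graphml", strengths=strengths)
        g = nx.read_graphml(path)
        gene_node = g.nodes["G2"]
        assert gene_node["strength"] == 1
        assert gene_node["predicted_direction"] == "down"
        assert g.nodes["rno-mir-1"]["direction"] == "up"

    def test_unknown_format_rejected(self, small_net, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(small_net, tmp_path / "x", "gexf")


class TestRecordValidation:
    def test_validated_with_score_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord("m", "g", "validated", 50.0)

    def test_prediction_without_score_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord("m", "g", "mirdb", None)

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            InteractionRecord("m", "g", "targetscan", 1.0)
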