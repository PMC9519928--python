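import numpy as np
import pandas as pd
import pytest

from mpm.entities_io import (AssociationTable, EntityRegistry, ParseError,
                             read_association_table, read_edge_list,
                             read_ontology, read_score_table,
                             write_score_table)


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestEdgeList:
    @pytest.mark.parametrize("relation,expected", [
        ("binding", {("A", "B"), ("B", "A")}),
        ("inhibits", {("A", "B")}),
        ("activates", {("A", "B")}),
        ("regulates", {("A", "B")}),
        ("catalyzes", {("A", "B")}),
    ])
    def test_relation_direction_rules(self, tmp_path, relation, expected):
        path = write_tsv(tmp_path / "e.tsv", ["source", "target", "relation"],
                         [("A", "B", relation)])
        net = read_edge_list(path)
        ids = {net.pcg_registry.id(s): s for s in range(net.n_pcgs)}
        edges = {(net.pcg_registry.id(s), net.pcg_registry.id(t)) for s, t in net.edges}
        assert edges == expected
        if relation == "binding":
            assert net.out_degree()[net.pcg_registry.index("A")] == 1

    def test_ordered_pair_dedup_matches_set_union(self, tmp_path):
        # brute-force oracle: the union of per-row edge sets
        rows = [("A", "B", "binding"), ("A", "B", "regulates")]
        oracle = set()
        for s, t, rel in rows:
            oracle.add((s, t))
            if rel == "binding":
                oracle.add((t, s))
        path = write_tsv(tmp_path / "e.tsv", ["source", "target", "relation"], rows)
        net = read_edge_list(path)
        edges = {(net.pcg_registry.id(s), net.pcg_registry.id(t)) for s, t in net.edges}
        assert edges == oracle == {("A", "B"), ("B", "A")}

    def test_unknown_relation_names_line(self, tmp_path):
        path = write_tsv(tmp_path / "e.tsv", ["source", "target", "relation"],
                         [("A", "B", "binding"), ("B", "C", "eats")])
        with pytest.raises(ParseError, match=r":3"):
            read_edge_list(path)

    def test_empty_file_errors(self, tmp_path):
        path = write_tsv(tmp_path / "e.tsv", ["source", "target", "relation"], [])
        with pytest.raises(ParseError, match="empty"):
            read_edge_list(path)

    def test_degree_conservation_and_idempotence(self, tmp_path):
        rows = [("A", "B", "binding"), ("B", "C", "inhibits"), ("C", "A", "regulates"),
                ("A", "C", "catalyzes")]
        path = write_tsv(tmp_path / "e.tsv", ["source", "target", "relation"], rows)
        net1 = read_edge_list(path)
        net2 = read_edge_list(path)
        assert net1.in_degree().sum() == net1.out_degree().sum() == len(net1.edges)
        assert net1.edges == net2.edges
        assert net1.pcg_registry.index_to_id == net2.pcg_registry.index_to_id


class TestRegistry:
    def test_round_trip_bijection(self):
        reg = EntityRegistry.from_ids("miRNA", ["m2", "m1", "m3"])
        for i in range(len(reg)):
            assert reg.index(reg.id(i)) == i
        assert reg.add("m1") == reg.index("m1")  # idempotent add
        with pytest.raises(KeyError):
            reg.index("absent")


class TestAssociationTable:
    def test_binary_mode_assigns_unit_weight(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", ["mirna_id", "pcg_id"],
                         [("m1", "g1"), ("m1", "g2")])
        table = read_association_table(path, "miRNA", "PCG", "binary")
        assert table.records == {("m1", "g1"): 1.0, ("m1", "g2"): 1.0}

    def test_scores_in_range_pass_through(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", ["disease_id", "pcg_id", "score"],
                         [("d1", "g1", 0.1), ("d1", "g2", 0.9)])
        table = read_association_table(path, "disease", "PCG", "score")
        assert table.records[("d1", "g1")] == pytest.approx(0.1)
        assert table.records[("d1", "g2")] == pytest.approx(0.9)

    def test_out_of_range_scores_min_max_rescaled(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", ["disease_id", "pcg_id", "score"],
                         [("d1", "g1", 1), ("d1", "g2", 3), ("d1", "g3", 5)])
        table = read_association_table(path, "disease", "PCG", "score")
        # hand min-max: (x - 1) / 4
        assert table.records[("d1", "g1")] == pytest.approx(0.0)
        assert table.records[("d1", "g2")] == pytest.approx(0.5)
        assert table.records[("d1", "g3")] == pytest.approx(1.0)

    def test_duplicates_collapse_to_max(self):
        table = AssociationTable("disease", "PCG")
        table.add("d1", "g1", 0.2)
        table.add("d1", "g1", 0.7)
        table.add("d1", "g1", 0.4)
        assert table.records[("d1", "g1")] == 0.7

    def test_score_mode_requires_score_column(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", ["disease_id", "pcg_id"],
                         [("d1", "g1")])
        with pytest.raises(ParseError, match="score"):
            read_association_table(path, "disease", "PCG", "score")

    def test_non_numeric_score_errors(self, tmp_path):
        path = write_tsv(tmp_path / "a.tsv", ["disease_id", "pcg_id", "score"],
                         [("d1", "g1", "high")])
        with pytest.raises(ParseError, match="non-numeric"):
            read_association_table(path, "disease", "PCG", "score")


class TestOntology:
    def test_parent_by_code_prefix(self, tmp_path):
        path = write_tsv(tmp_path / "o.tsv", ["disease_id", "tree_code"],
                         [("d1", "C04.557"), ("cat", "C04")])
        tree = read_ontology(path)
        assert tree.code_to_node["C04"] == "cat"
        assert tree.codes("d1") == ["C04.557"]

    def test_multi_code_disease_keeps_all_positions(self, tmp_path):
        path = write_tsv(tmp_path / "o.tsv", ["disease_id", "tree_code"],
                         [("d1", "C04.557"), ("d1", "C15.378")])
        tree = read_ontology(path)
        assert tree.codes("d1") == ["C04.557", "C15.378"]

    def test_orphan_prefix_synthesised(self, tmp_path):
        # closure oracle: every proper prefix of every code must own a node
        path = write_tsv(tmp_path / "o.tsv", ["disease_id", "tree_code"],
                         [("d1", "C04.557.123")])
        tree = read_ontology(path)
        for prefix in ("C04", "C04.557"):
            assert tree.code_to_node[prefix] == prefix  # implicit category node

    def test_malformed_code_errors(self, tmp_path):
        path = write_tsv(tmp_path / "o.tsv", ["disease_id", "tree_code"],
                         [("d1", "C04..557")])
        with pytest.raises(ParseError, match="malformed"):
            read_ontology(path)


class TestScoreTable:
    def test_rank_follows_score_then_ids(self, tmp_path):
        df = pd.DataFrame({"miRNA_id": ["m2", "m1", "m1"],
                           "disease_id": ["d1", "d1", "d2"],
                           "score": [0.1, 0.5, 0.5]})
        path = tmp_path / "s.tsv"
        write_score_table(df, path)
        out = read_score_table(path)
        assert list(out["rank"]) == [1, 2, 3]
        # tie 0.5/0.5 resolved by (miRNA_id, disease_id)
        assert list(out["disease_id"][:2]) == ["d1", "d2"]
        assert out.iloc[2]["miRNA_id"] == "m2"

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"miRNA_id": ["m1", "m2"], "disease_id": ["d1", "d2"],
                           "score": [0.9, 0.1]})
        path = tmp_path / "s.tsv"
        write_score_table(df, path)
        back = read_score_table(path)
        assert list(back["score"]) == [0.9, 0.1]
        assert list(back["rank"]) == [1, 2]

    def test_invalid_scores_rejected(self, tmp_path):
        df = pd.DataFrame({"miRNA_id": ["m1"], "disease_id": ["d1"],
                           "score": [np.nan]})
        with pytest.raises(ValueError):
            write_score_table(df, tmp_path / "s.tsv")
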