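"""Tests for category summaries, network construction and centrality."""

import networkx as nx
import pandas as pd
import pytest

from ampkscan.network import (
    build_network,
    category_counts,
    export_graph,
    rank_central_nodes,
    read_annotations,
    read_associations,
)


def ann_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "category", "evidence"])


def assoc_frame(pairs):
    return pd.DataFrame(
        [(a, b, "association") for a, b in pairs],
        columns=["protein_a", "protein_b", "type"],
    )


class TestCategoryCounts:
    def test_unannotated_falls_into_uncategorized(self):
        df = category_counts(["a", "b"], ann_frame([("a", "transcription", "")]))
        props = dict(zip(df["category"], df["proportion"]))
        assert props == {"transcription": 0.5, "uncategorized": 0.5}

    def test_fractional_split_of_multi_category_protein(self):
        df = category_counts(
            ["a"], ann_frame([("a", "transcription", ""), ("a", "translation", "")])
        )
        weights = dict(zip(df["category"], df["weight"]))
        assert weights == {"transcription": 0.5, "translation": 0.5}

    def test_empty_annotations_all_uncategorized(self):
        df = category_counts(["a", "b", "c"], None)
        assert df["category"].tolist() == ["uncategorized"]
        assert df["proportion"].tolist() == [1.0]

    def test_proportions_sum_to_one_fractional(self):
        ann = ann_frame(
            [("a", "transcription", ""), ("a", "translation", ""), ("b", "cell migration", "")]
        )
        df = category_counts(["a", "b", "c"], ann)
        assert df["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_count_in_each_policy(self):
        ann = ann_frame([("a", "transcription", ""), ("a", "translation", "")])
        df = category_counts(["a"], ann, policy="each")
        assert set(df["weight"]) == {1.0}
        assert df["n_proteins"].sum() == 2

    def test_unknown_annotation_protein_warns(self, caplog):
        with caplog.at_level("WARNING"):
            category_counts(["a"], ann_frame([("ghost", "transcription", "")]))
        assert "not scanned targets" in caplog.text

    def test_bad_policy(self):
        with pytest.raises(ValueError):
            category_counts(["a"], None, policy="majority")


class TestBuildNetwork:
    def test_nodes_and_edges(self):
        g = build_network(["a", "b", "c"], associations=assoc_frame([("a", "b"), ("b", "c")]))
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.number_of_edges() == 2

    def test_self_loop_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_network(["a"], associations=assoc_frame([("a", "a")]))
        assert g.number_of_edges() == 0
        assert "self-association" in caplog.text

    def test_duplicate_pair_in_both_orders_single_edge(self):
        g = build_network(["a", "b"], associations=assoc_frame([("a", "b"), ("b", "a")]))
        assert g.number_of_edges() == 1

    def test_non_target_edges_excluded_by_default(self):
        g = build_network(["a"], associations=assoc_frame([("a", "x"), ("x", "y")]))
        assert set(g.nodes) == {"a"}

    def test_include_neighbors_flags_non_targets(self):
        g = build_network(
            ["a"], associations=assoc_frame([("a", "x")]), include_neighbors=True
        )
        assert g.nodes["x"]["is_target"] is False
        assert g.nodes["a"]["is_target"] is True
        assert g.has_edge("a", "x")

    def test_node_attributes(self):
        ann = ann_frame([("a", "translation", ""), ("a", "transcription", "")])
        g = build_network(["a"], ann, tiers={"a": "strict"})
        assert g.nodes["a"]["tier"] == "strict"
        assert g.nodes["a"]["categories"] == "transcription;translation"


class TestRankCentralNodes:
    def test_star_hub_first(self):
        pairs = [("h", leaf) for leaf in ["l1", "l2", "l3", "l4"]]
        g = build_network(["h", "l1", "l2", "l3", "l4"], associations=assoc_frame(pairs))
        assert rank_central_nodes(g)[0] == ("h", 4)

    def test_path_center_first(self):
        g = build_network(["a", "b", "c"], associations=assoc_frame([("a", "b"), ("b", "c")]))
        assert rank_central_nodes(g)[0] == ("b", 2)

    def test_lexicographic_tie_break(self):
        g = build_network(["b", "a"], associations=assoc_frame([("a", "b")]))
        assert rank_central_nodes(g) == [("a", 1), ("b", 1)]

    def test_category_restricted_degree(self):
        ann = ann_frame([(p, "cat", "") for p in ("a", "b")] + [("c", "other", "")])
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        g = build_network(["a", "b", "c"], ann, assoc_frame(pairs))
        ranking = rank_central_nodes(g, category="cat")
        # inside "cat" only the a-b edge counts
        assert ranking == [("a", 1), ("b", 1)]

    def test_unknown_category_empty_with_warning(self, caplog):
        g = build_network(["a"], ann_frame([("a", "cat", "")]))
        with caplog.at_level("WARNING"):
            assert rank_central_nodes(g, category="nope") == []
        assert "no protein carries" in caplog.text

    def test_ranking_is_permutation_with_correct_degrees(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")]
        g = build_network(list("abcd"), associations=assoc_frame(pairs))
        ranking = rank_central_nodes(g)
        assert sorted(n for n, _ in ranking) == list("abcd")
        for node, degree in ranking:
            assert degree == sum(1 for a, b in pairs if node in (a, b))


class TestExportGraph:
    def test_sif_single_edge(self, tmp_path):
        g = build_network(["a", "b"], associations=assoc_frame([("a", "b")]))
        path = tmp_path / "net.sif"
        export_graph(g, path, "sif")
        assert path.read_text() == "a\tassociation\tb\n"

    def test_sif_isolated_node_listed(self, tmp_path):
        g = build_network(["a", "b"], associations=assoc_frame([]))
        path = tmp_path / "net.sif"
        export_graph(g, path, "sif")
        assert path.read_text() == "a\nb\n"

    def test_graphml_round_trip_preserves_network(self, tmp_path):
        ann = ann_frame([("a", "translation", "")])
        g = build_network(["a", "b"], ann, assoc_frame([("a", "b")]), tiers={"a": "strict"})
        path = tmp_path / "net.graphml"
        export_graph(g, path, "graphml")
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        assert back.nodes["a"]["categories"] == "translation"
        assert back.nodes["a"]["tier"] == "strict"

    def test_empty_network_graphml_valid(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_graph(build_network([]), path, "graphml")
        assert nx.read_graphml(path).number_of_nodes() == 0

    def test_tsv_edge_list(self, tmp_path):
        g = build_network(["a", "b"], associations=assoc_frame([("a", "b")]))
        path = tmp_path / "net.tsv"
        export_graph(g, path, "tsv")
        df = pd.read_csv(path, sep="\t")
        assert df.values.tolist() == [["a", "b", "association"]]

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_graph(build_network([]), tmp_path / "x", "gexf")


class TestTableReaders:
    def test_read_annotations(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("protein_id\tcategory\tevidence\na\ttranscription\tlit\n")
        df = read_annotations(path)
        assert df.values.tolist() == [["a", "transcription", "lit"]]

    def test_read_associations_default_type(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        path.write_text("protein_a\tprotein_b\na\tb\n")
        df = read_associations(path)
        assert df["type"].tolist() == ["association"]

    def test_malformed_association_row_line_number(self, tmp_path):
        path = tmp_path / "assoc.tsv"
        path.write_text("protein_a\tprotein_b\ttype\na\tb\tpp\nc\n")
        with pytest.raises(ValueError, match=r"line\(s\) \[3\]"):
            read_associations(path)
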