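import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppifunc.network import (
    InteractionRecord,
    ParseError,
    ProteinNetwork,
    TableDialect,
    build_network,
    compute_weights,
    edge_weights,
    node_weights,
    read_interaction_table,
    refine,
    refine_network,
    weight_threshold,
)

from conftest import random_network


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadInteractionTable:
    def test_parses_rows_including_self_pairs(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("protein_a\tprotein_b\nP1\tP2\nP2\tP2\n")
        records = read_interaction_table(path)
        assert records == [InteractionRecord("P1", "P2"), InteractionRecord("P2", "P2")]

    def test_optional_experiment_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("protein_a\tprotein_b\texperiment\nYAL014c\tYAL030w\tTwo hybrid\n")
        (rec,) = read_interaction_table(path)
        assert rec.experiment_type == "Two hybrid"
        assert rec.function_a == ""

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("protein_a\tprotein_b\n")
        assert read_interaction_table(path) == []

    def test_comment_lines_ignored_and_ids_trimmed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("# exported\nprotein_a\tprotein_b\n A \tB\n")
        (rec,) = read_interaction_table(path)
        assert (rec.protein_a, rec.protein_b) == ("A", "B")

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("protein_a\tprotein_b\nP1\tP2\nP3\n")
        with pytest.raises(ParseError, match=":3:"):
            read_interaction_table(path)

    def test_custom_dialect_maps_columns(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("ida\tidb\nA\tB\n")
        (rec,) = read_interaction_table(path, TableDialect(protein_a="ida", protein_b="idb"))
        assert (rec.protein_a, rec.protein_b) == ("A", "B")


class TestBuildNetwork:
    def test_dedupe_and_self_loop_drop(self):
        net = build_network(
            [InteractionRecord("A", "B"), InteractionRecord("B", "A"), InteractionRecord("C", "C")]
        )
        assert net.proteins == {"A", "B"}
        assert net.edges == {("A", "B")}

    def test_duplicates_collapse_to_one_edge(self):
        net = build_network([InteractionRecord("A", "B")] * 10)
        assert net.n_edges == 1

    def test_g5_construction(self, g5):
        assert g5.proteins == set("ABCDE")
        assert g5.n_edges == 5


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class TestNodeWeights:
    def test_g5_degree_over_mean(self, g5):
        assert node_weights(g5) == {"A": 1.0, "B": 1.0, "C": 1.5, "D": 1.0, "E": 0.5}

    def test_g5_raw_degree(self, g5):
        assert node_weights(g5, "raw_degree") == {"A": 2, "B": 2, "C": 3, "D": 2, "E": 1}

    def test_single_edge_gives_unit_weights(self):
        net = ProteinNetwork.from_edges([("A", "B")])
        assert node_weights(net) == {"A": 1.0, "B": 1.0}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            node_weights(ProteinNetwork())

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_over_mean_averages_to_one(self, seed):
        net = random_network(seed, n=15, p=0.25)
        nw = node_weights(net)
        if net.n_edges:  # edgeless networks have all-zero weights by convention
            assert math.isclose(sum(nw.values()) / len(nw), 1.0)


class TestEdgeWeights:
    def test_g5_jaccard_values(self, g5):
        ew = edge_weights(g5)
        assert ew[("A", "B")] == 1.0  # shared {C}; union minus endpoints {C}
        assert ew[("A", "C")] == 0.5  # shared {B}; union minus endpoints {B, D}
        assert ew[("C", "D")] == 0.0

    def test_common_neighbor_count_scheme(self, g5):
        ew = edge_weights(g5, "common_neighbor_count")
        assert ew[("A", "B")] == 1 and ew[("C", "D")] == 0

    def test_missing_pair_lookup_raises(self, g5):
        weights = compute_weights(g5)
        with pytest.raises(KeyError, match="A.*E|E.*A"):
            weights.edge_weight_of("A", "E")

    def test_brute_force_oracle_all_graphs_up_to_6_nodes(self):
        """Jaccard and count weights match a naive triple loop on every
        graph with at most six nodes (the graph atlas enumeration)."""
        from networkx.generators.atlas import graph_atlas_g

        checked = 0
        for g in graph_atlas_g():
            if g.number_of_nodes() > 6:
                break
            if g.number_of_edges() == 0:
                continue
            net = ProteinNetwork.from_edges((f"n{u}", f"n{v}") for u, v in g.edges)
            jac = edge_weights(net, "jaccard_cn")
            cnt = edge_weights(net, "common_neighbor_count")
            for u, v in net.edges:
                common = sum(
                    1 for w in net.proteins if net.has_edge(u, w) and net.has_edge(v, w)
                )
                union = {
                    w
                    for w in net.proteins
                    if (net.has_edge(u, w) or net.has_edge(v, w)) and w not in (u, v)
                }
                assert cnt[(u, v)] == common
                expected = common / len(union) if union else 0.0
                assert math.isclose(jac[(u, v)], expected)
            checked += 1
        assert checked > 150

    @pytest.mark.parametrize("seed", range(10))
    def test_jaccard_bounds_and_unit_condition(self, seed):
        net = random_network(seed, n=14, p=0.3)
        if net.n_edges == 0:
            return
        ew = edge_weights(net)
        for (u, v), w in ew.items():
            assert 0.0 <= w <= 1.0
            coincide = (net.neighbors(u) - {u, v}) == (net.neighbors(v) - {u, v}) and (
                net.neighbors(u) - {u, v}
            )
            assert (w == 1.0) == bool(coincide)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

class TestWeightThreshold:
    def test_unit_mean_unit_sigma(self):
        values = [0.0, 2.0] * 5  # alpha 1, sigma 1, damping factor 1/2
        assert weight_threshold(values, 1) == pytest.approx(1.5)
        assert weight_threshold(values, 2) == pytest.approx(2.0)
        assert weight_threshold(values, 3) == pytest.approx(2.5)

    def test_constant_values_collapse_to_mean(self):
        for k in (1, 2, 3):
            assert weight_threshold([0.7] * 4, k) == pytest.approx(0.7)

    def test_g5_jaccard_distribution(self, g5):
        ew = edge_weights(g5)  # {1.0, 0.5, 0.5, 0, 0}: alpha 0.4, sigma sqrt(0.14)
        sigma = math.sqrt(0.14)
        expected = 0.4 + sigma * (1 - 1 / (1 + 0.14))
        assert weight_threshold(ew.values(), 1) == pytest.approx(expected)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            weight_threshold([], 1)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_levels_ordered_when_dispersed(self, values):
        import statistics

        th = [weight_threshold(values, k) for k in (1, 2, 3)]
        if statistics.pstdev(values) > 1e-9:  # below that the k-term underflows
            assert th[0] < th[1] < th[2]
        else:
            assert th[0] == pytest.approx(th[1]) == pytest.approx(th[2])


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

class TestRefine:
    def test_constant_weight_graph_is_noop(self):
        # a 6-cycle: all degrees and all edge weights identical -> sigma 0,
        # thresholds collapse to the mean and ties survive
        cyc = ProteinNetwork.from_edges(
            [(f"n{i}", f"n{(i + 1) % 6}") for i in range(6)]
        )
        weights = compute_weights(cyc)
        refined = refine_network(cyc, weights, "high")
        assert refined.proteins == cyc.proteins
        assert refined.edges == cyc.edges

    def test_g5_lowest_weight_node_removed_first(self, g5):
        weights = compute_weights(g5)
        assert weights.threshold("node", "low") > 0.5
        result = refine(g5, weights, "low")
        assert "E" not in result.node_pruned.proteins

    def test_star_prunes_all_leaves(self):
        star = ProteinNetwork.from_edges([("c", f"l{i}") for i in range(4)])
        weights = compute_weights(star)
        assert weights.node_weight["c"] == pytest.approx(2.5)
        assert weights.node_weight["l0"] == pytest.approx(0.625)
        for level in ("low", "medium", "high"):
            refined = refine_network(star, weights, level)
            assert refined.proteins == {"c"}
            assert refined.n_edges == 0

    @pytest.mark.parametrize("seed", range(15))
    def test_refined_levels_nest(self, seed):
        """Node thresholds are monotone in level, so the surviving protein
        sets nest high within medium within low, and every refined graph
        is a subgraph of its input. Edge sets need not nest across levels
        because each level's edge table is recomputed on its own
        node-pruned sub-network."""
        net = random_network(seed, n=20, p=0.25)
        if net.n_edges == 0:
            return
        weights = compute_weights(net)
        low = refine(net, weights, "low")
        med = refine(net, weights, "medium")
        high = refine(net, weights, "high")
        assert high.refined.proteins <= med.refined.proteins <= low.refined.proteins
        for r in (low, med, high):
            assert r.refined.subgraph_of(r.node_pruned)
            assert r.node_pruned.subgraph_of(net)

    def test_unknown_level_rejected(self, g5):
        with pytest.raises(ValueError, match="extreme"):
            refine_network(g5, compute_weights(g5), "extreme")

    def test_edge_pruning_keeps_all_surviving_proteins(self):
        # the triangular prism is 3-regular (no node pruning); its rung
        # edges have no common neighbours and fall below the edge cutoff,
        # while all six proteins must remain
        rungs = {("a1", "b1"), ("a2", "b2"), ("a3", "b3")}
        triangles = {("a1", "a2"), ("a1", "a3"), ("a2", "a3"),
                     ("b1", "b2"), ("b1", "b3"), ("b2", "b3")}
        net = ProteinNetwork.from_edges(triangles | rungs)
        weights = compute_weights(net)
        result = refine(net, weights, "low")
        assert result.node_pruned.proteins == net.proteins  # regular: no node prune
        assert result.refined.proteins == net.proteins
        assert result.refined.edges == triangles
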