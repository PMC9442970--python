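from collections import Counter

import numpy as np
import pytest

from motifmod.motifs import (
    classify_subgraph,
    code_type,
    count_by_code,
    enumerate_all_three_node,
    enumerate_three_node_subgraphs,
    enumerate_two_node_subgraphs,
    generate_nonredundant_codes,
)
from motifmod.network import CompositeNetwork, ConfigurationError, LayerSpec

from conftest import brute_force_three_node, brute_force_two_node, random_composite_network


def _net(layers, edges):
    net = CompositeNetwork(layers=layers)
    for u, v, l in edges:
        net.add_edge(u, v, l)
    return net


class TestCatalogue:
    def test_single_undirected_letter_gives_one_triangle_class(self):
        assert generate_nonredundant_codes(set(), {"P"}) == ["PPP"]

    def test_single_directed_letter_gives_cycle_and_transitive(self):
        codes = generate_nonredundant_codes({"R"}, set())
        assert len(codes) == 2
        assert sorted(code_type(c, {"R"}) for c in codes) == ["CIR", "FFL"]

    def test_two_undirected_letters_collapse_to_multisets(self):
        codes = generate_nonredundant_codes(set(), {"P", "C"})
        assert codes == ["CCC", "CCP", "CPP", "PPP"]

    def test_overlapping_letter_sets_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_nonredundant_codes({"R"}, {"R"})

    def test_catalogue_oracle_count(self):
        # brute force: distinct canonical classes among all raw assignments
        # equals the catalogue size for a mixed letter alphabet
        codes = generate_nonredundant_codes({"R", "M"}, {"P"})
        types = Counter(code_type(c, {"R", "M"}) for c in codes)
        # every one of the seven 3-node types must be realizable
        assert set(types) == {"COM", "COP", "COR", "FFL", "CIR", "FBU", "FB2U"}


class TestThreeNodeEnumeration:
    def test_single_triangle_found_once(self):
        net = _net([LayerSpec("P", False)],
                   [("a", "b", "P"), ("b", "c", "P"), ("a", "c", "P"),
                    ("c", "d", "P")])
        inst = enumerate_three_node_subgraphs(net, "PPP")
        assert len(inst) == 1
        assert set(inst[0].nodes) == {"a", "b", "c"}

    def test_cor_instance(self):
        net = _net([LayerSpec("R", True), LayerSpec("P", False)],
                   [("a", "b", "R"), ("a", "c", "R"), ("b", "c", "P")])
        inst = enumerate_all_three_node(net)
        assert len(inst) == 1
        assert inst[0].topo_type == "COR"

    def test_cycle_is_not_transitive(self):
        net = _net([LayerSpec("R", True)],
                   [("a", "b", "R"), ("b", "c", "R"), ("c", "a", "R")])
        inst = enumerate_all_three_node(net)
        assert len(inst) == 1
        assert inst[0].topo_type == "CIR"
        ffl_code = next(
            c for c in generate_nonredundant_codes({"R"}, set())
            if code_type(c, {"R"}) == "FFL"
        )
        assert enumerate_three_node_subgraphs(net, ffl_code) == []

    def test_undeclared_code_letter_rejected(self, toy_net):
        with pytest.raises(ConfigurationError):
            enumerate_three_node_subgraphs(toy_net, "XXX")

    def test_non_induced_matching_multiplicity(self):
        # triple with a parallel P and C edge on one pair matches twice
        net = _net(
            [LayerSpec("P", False), LayerSpec("C", False)],
            [("a", "b", "P"), ("b", "c", "P"), ("a", "c", "P"), ("a", "c", "C")],
        )
        counts = count_by_code(enumerate_all_three_node(net))
        assert counts["PPP"] == 1
        assert counts["CPP"] == 1


class TestTwoNodeEnumeration:
    def test_dd_pair(self):
        net = _net([LayerSpec("R", True), LayerSpec("M", True)],
                   [("a", "b", "R"), ("b", "a", "M")])
        inst = enumerate_two_node_subgraphs(net)
        assert [i.code for i in inst] == ["DD"]

    def test_du_pair_is_2fb(self):
        net = _net([LayerSpec("R", True), LayerSpec("P", False)],
                   [("a", "b", "R"), ("a", "b", "P")])
        inst = enumerate_two_node_subgraphs(net)
        assert [(i.code, i.topo_type) for i in inst] == [("DU", "2FB")]

    def test_lone_directed_edge_yields_nothing(self):
        net = _net([LayerSpec("R", True)], [("a", "b", "R")])
        assert enumerate_two_node_subgraphs(net) == []


class TestClassification:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("A", "C", "R"), ("B", "C", "R"), ("A", "B", "P")], "COP"),
            ([("A", "B", "P"), ("B", "C", "P"), ("A", "C", "P")], "COM"),
            ([("A", "B", "R"), ("B", "C", "R"), ("A", "C", "P")], "FBU"),
            ([("A", "B", "R"), ("A", "C", "R"), ("B", "C", "P")], "COR"),
            ([("A", "B", "R"), ("A", "C", "R"), ("B", "C", "R")], "FFL"),
            ([("A", "B", "R"), ("B", "C", "P"), ("A", "C", "P")], "FB2U"),
        ],
    )
    def test_types_from_edge_patterns(self, edges, expected):
        net = _net([LayerSpec("R", True), LayerSpec("P", False)], edges)
        inst = enumerate_all_three_node(net)
        assert len(inst) == 1
        assert inst[0].topo_type == expected
        assert classify_subgraph(inst[0]) == expected

    def test_classification_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        layers = [LayerSpec("R", True), LayerSpec("P", False)]
        net = random_composite_network(rng, 12, layers, density=0.3)
        before = Counter(i.topo_type for i in enumerate_all_three_node(net))
        mapping = {n: f"x{k}" for k, n in enumerate(sorted(net.nodes, reverse=True))}
        relabeled = CompositeNetwork(layers=layers)
        for spec in layers:
            for u, v in net.edges[spec.letter]:
                relabeled.add_edge(mapping[u], mapping[v], spec.letter)
        after = Counter(i.topo_type for i in enumerate_all_three_node(relabeled))
        assert before == after


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_three_node_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        layers = [LayerSpec("R", True), LayerSpec("M", True),
                  LayerSpec("P", False), LayerSpec("C", False)]
        net = random_composite_network(rng, int(rng.integers(6, 15)), layers, 0.2)
        ours = {frozenset(i.edges) for i in enumerate_all_three_node(net)}
        assert ours == brute_force_three_node(net)

    @pytest.mark.parametrize("seed", range(4))
    def test_two_node_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        layers = [LayerSpec("R", True), LayerSpec("M", True),
                  LayerSpec("P", False)]
        net = random_composite_network(rng, 10, layers, 0.3)
        dd, du = brute_force_two_node(net)
        inst = enumerate_two_node_subgraphs(net)
        assert {frozenset(i.edges) for i in inst if i.code == "DD"} == dd
        assert {frozenset(i.edges) for i in inst if i.code == "DU"} == du

    def test_every_three_node_instance_has_exactly_one_type(self):
        rng = np.random.default_rng(5)
        layers = [LayerSpec("R", True), LayerSpec("P", False)]
        net = random_composite_network(rng, 14, layers, 0.25)
        for inst in enumerate_all_three_node(net):
            assert inst.topo_type in {"COP", "COR", "FFL", "CIR", "FBU", "FB2U", "COM"}

    def test_adding_an_edge_never_decreases_counts(self):
        rng = np.random.default_rng(11)
        layers = [LayerSpec("R", True), LayerSpec("P", False)]
        net = random_composite_network(rng, 10, layers, 0.25)
        before = count_by_code(enumerate_all_three_node(net))
        nodes = sorted(net.nodes)
        for _ in range(20):
            u, v = rng.choice(nodes, size=2, replace=False)
            if (u, v) not in net.edges["R"]:
                net.add_edge(u, v, "R")
                break
        after = count_by_code(enumerate_all_three_node(net))
        assert all(after[c] >= k for c, k in before.items())
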