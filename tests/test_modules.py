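import math
import random

import networkx as nx
import pytest

import drugnet as dn
from drugnet.entities import AssociationSet, Catalogs
from drugnet.exceptions import ParameterError
from drugnet.modules import D_MODULE, P_MODULE, TopologicalModule, write_module


@pytest.fixture
def chain3():
    return dn.load_network([("A", "B"), ("B", "C")])


class TestCommonModule:
    def test_identical_seeds_level_zero(self, chain3):
        mod = dn.common_module({"A"}, {"A"}, 0, chain3)
        assert mod.members == {"A"}

    def test_intersection_of_expanded_balls(self, chain3):
        mod = dn.common_module({"A"}, {"C"}, 1, chain3)
        assert mod.members == {"B"}

    def test_disjoint_seeds_without_expansion_empty(self, chain3):
        assert dn.common_module({"A"}, {"C"}, 0, chain3).members == frozenset()

    def test_level_out_of_range_rejected(self, chain3):
        with pytest.raises(ParameterError):
            dn.common_module({"A"}, {"C"}, 5, chain3)

    def test_members_monotone_in_level(self):
        g = nx.gnp_random_graph(40, 0.08, seed=3)
        net = dn.load_network([(f"n{a}", f"n{b}") for a, b in g.edges])
        rng = random.Random(3)
        nodes = sorted(net.nodes)
        for _ in range(10):
            s1 = frozenset(rng.sample(nodes, 3))
            s2 = frozenset(rng.sample(nodes, 3))
            prev = frozenset()
            for v in (0, 1, 2):
                members = dn.common_module(s1, s2, v, net).members
                assert prev <= members
                prev = members


def brute_force_module_distance(members, genes, k, graph, base=1.0 / 6.0):
    """Oracle: exact-distance indicator over every (module, gene) pair."""
    if not members:
        return 0.0
    hits = 0
    for t in members:
        lengths = nx.single_source_shortest_path_length(graph, t)
        for g in genes:
            if lengths.get(g, math.inf) == k:
                hits += 1
    return (base ** (k + 1)) * hits / (len(members) * len(genes))


class TestModuleEntityDistance:
    @pytest.mark.parametrize(
        "members,genes,k,expected",
        [
            ({"B"}, {"B"}, 0, 1 / 6),     # single exact intersection
            ({"B"}, {"C"}, 1, 1 / 36),    # distance exactly 1
            ({"B"}, {"C"}, 0, 0.0),       # same input misses at k = 0
            (set(), {"B"}, 1, 0.0),       # empty-module convention
            ({"A", "B"}, {"B"}, 0, 1 / 12),  # one of two pairs intersects
        ],
    )
    def test_chain_examples(self, chain3, cfg, members, genes, k, expected):
        mod = TopologicalModule(frozenset(members), level=0)
        got = dn.module_entity_distance(mod, genes, k, chain3, cfg)
        assert got == pytest.approx(expected, abs=1e-15)

    def test_k_out_of_range_rejected(self, chain3, cfg):
        mod = TopologicalModule(frozenset("B"), level=0)
        with pytest.raises(ParameterError):
            dn.module_entity_distance(mod, {"B"}, 3, chain3, cfg)

    def test_matches_brute_force_on_random_graphs(self, cfg):
        for seed in range(10):
            g = nx.gnp_random_graph(50, 0.06, seed=seed)
            g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
            net = dn.load_network(list(g.edges))
            rng = random.Random(seed)
            nodes = sorted(net.nodes)
            members = frozenset(rng.sample(nodes, 6))
            genes = frozenset(rng.sample(nodes, 4))
            mod = TopologicalModule(members, level=1)
            for k in (0, 1, 2):
                assert dn.module_entity_distance(mod, genes, k, net, cfg) == pytest.approx(
                    brute_force_module_distance(members, genes, k, g), abs=1e-12
                )

    def test_exact_distance_buckets_are_disjoint(self, cfg):
        # summed hit counts over k never exceed the number of (t, g) pairs
        g = nx.gnp_random_graph(40, 0.1, seed=9)
        net = dn.load_network([(f"n{a}", f"n{b}") for a, b in g.edges])
        rng = random.Random(9)
        nodes = sorted(net.nodes)
        members = frozenset(rng.sample(nodes, 8))
        genes = frozenset(rng.sample(nodes, 5))
        mod = TopologicalModule(members, level=2)
        scale = len(members) * len(genes)
        pair_count = 0
        for k in (0, 1, 2):
            value = dn.module_entity_distance(mod, genes, k, net, cfg)
            pair_count += round(value * scale / cfg.weight(k))
        assert pair_count <= scale


class TestBestKnownModuleDistance:
    @pytest.fixture
    def setting(self, chain3):
        catalogs = Catalogs(
            drugs={"d1": frozenset("AB"), "d2": frozenset("BC")},
            diseases={"p1": frozenset("AC"), "p2": frozenset("AB")},
        )
        assoc = AssociationSet([("d1", "p1"), ("d2", "p1"), ("d1", "p2")])
        return catalogs, assoc

    def test_maximum_over_candidates_matches_enumeration(self, chain3, cfg, setting):
        catalogs, assoc = setting
        for v in (0, 1, 2):
            for k in (0, 1, 2):
                got = dn.best_known_module_distance(
                    "d2", "p1", D_MODULE, v, k, catalogs, assoc, chain3, cfg,
                    exclude="d2",
                )
                mod = dn.common_module(
                    catalogs.drugs["d2"], catalogs.drugs["d1"], v, chain3
                )
                want = dn.module_entity_distance(
                    mod, catalogs.diseases["p1"], k, chain3, cfg
                )
                assert got == want

    def test_no_remaining_candidates_scores_zero(self, chain3, cfg, setting):
        catalogs, assoc = setting
        got = dn.best_known_module_distance(
            "p2", "d1", P_MODULE, 1, 1, catalogs, assoc, chain3, cfg, exclude=None
        )
        # p-module side: candidates are d1's known diseases p1 and p2
        assert got >= 0.0
        only_self = dn.best_known_module_distance(
            "p1", "d2", P_MODULE, 1, 1, catalogs, assoc, chain3, cfg, exclude="p1"
        )
        assert only_self == 0.0

    def test_combined_score_zero_if_either_side_zero(self, cfg):
        assert dn.combine_geometric(0.0, 0.7, cfg.combine_weights) == 0.0
        assert dn.combine_geometric(0.7, 0.0, cfg.combine_weights) == 0.0


def test_module_export_lists_members_sorted(tmp_path):
    mod = TopologicalModule(frozenset({"B", "A"}), level=1, seed_entities=("d1", "d2"))
    out = tmp_path / "mod.txt"
    write_module(mod, out)
    lines = out.read_text().splitlines()
    assert lines[1:] == ["A", "B"]
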