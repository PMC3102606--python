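"""Connected-subgraph enumeration, candidate scoring, disjoint selection."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rme.discovery import (
    CandidateModule,
    DiscoveryConfig,
    enumerate_connected,
    run_discovery,
    score_candidates,
    select_disjoint,
)
from rme.matrix import module_stats
from rme.significance import SignificanceBreakdown
from rme.simulate import FrequencySpec, SimulationParams, simulate_dataset
from rme.winnow import ExclusivityGraph

from conftest import make_matrix


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return ExclusivityGraph(g)


def brute_force_connected(g: nx.Graph, seed, max_size):
    """Oracle: test every subset containing the seed for connectivity."""
    nodes = sorted(g.nodes)
    out = set()
    for size in range(2, max_size + 1):
        for combo in combinations(nodes, size):
            if seed in combo and nx.is_connected(g.subgraph(combo)):
                out.add(frozenset(combo))
    return out


class TestEnumerateConnected:
    def test_path_graph(self):
        g = graph_from_edges([("a", "b"), ("b", "c")])
        sets = enumerate_connected(g, "a", 3)
        assert set(sets) == {frozenset("ab"), frozenset("abc")}

    def test_triangle(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        sets = enumerate_connected(g, "a", 3)
        assert set(sets) == {frozenset("ab"), frozenset("ac"), frozenset("abc")}

    def test_max_size_two_gives_incident_edges(self):
        g = graph_from_edges([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])
        sets = enumerate_connected(g, "c", 2)
        assert set(sets) == {frozenset("ac"), frozenset("bc"), frozenset("cd")}

    def test_isolated_seed_yields_nothing(self):
        g = nx.Graph()
        g.add_node("a")
        assert enumerate_connected(ExclusivityGraph(g), "a", 4) == []

    def test_deterministic_canonical_order(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        once = enumerate_connected(g, "c", 4)
        again = enumerate_connected(g, "c", 4)
        assert once == again
        assert once == sorted(once, key=lambda s: (len(s), tuple(sorted(s))))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        n=st.integers(2, 6),
        edge_bits=st.integers(0, 2**15 - 1),
        max_size=st.integers(2, 6),
    )
    def test_matches_brute_force_on_small_graphs(self, n, edge_bits, max_size):
        nodes = [chr(ord("a") + i) for i in range(n)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for idx, (u, v) in enumerate(combinations(nodes, 2)):
            if edge_bits >> idx & 1:
                g.add_edge(u, v)
        seed = nodes[0]
        got = set(enumerate_connected(ExclusivityGraph(g), seed, max_size))
        assert got == brute_force_connected(g, seed, max_size)


def stub_candidate(genes, d):
    """CandidateModule with only the fields selection relies on."""
    genes = frozenset(genes)
    breakdown = SignificanceBreakdown(
        d_prime=d, gene_identity_bits=0, sample_count_bits=0, gene_count_bits=0,
        sort_bits=0, d=d, significance=2.0**-d if d > 0 else 1.0, p_null=0.01,
    )
    from rme.matrix import ModuleStats

    stats = ModuleStats(genes, 1.0, 1.0, 1)
    return CandidateModule(genes=genes, seed=min(genes), stats=stats, breakdown=breakdown)


class TestSelectDisjoint:
    def test_largest_bin_wins_and_all_overlaps_are_discarded(self):
        # abc is emitted first despite ab's higher d (largest size bin first);
        # both ab and cd overlap abc's genes and are therefore discarded.
        cands = [
            stub_candidate("abc", 60.0),
            stub_candidate("ab", 80.0),
            stub_candidate("cd", 55.0),
        ]
        out = select_disjoint(cands)
        assert [c.sorted_genes() for c in out] == [("a", "b", "c")]

    def test_disjoint_smaller_module_survives_selection(self):
        cands = [
            stub_candidate("abc", 60.0),
            stub_candidate("ab", 80.0),
            stub_candidate("de", 55.0),
        ]
        out = select_disjoint(cands)
        assert [c.sorted_genes() for c in out] == [("a", "b", "c"), ("d", "e")]

    def test_single_candidate(self):
        cands = [stub_candidate("xy", 51.0)]
        assert select_disjoint(cands) == cands

    def test_two_disjoint_same_size_emitted_by_score(self):
        cands = [stub_candidate("ab", 55.0), stub_candidate("cd", 70.0)]
        out = select_disjoint(cands)
        assert [c.sorted_genes() for c in out] == [("c", "d"), ("a", "b")]

    def test_tie_broken_lexicographically(self):
        cands = [stub_candidate("cd", 60.0), stub_candidate("ab", 60.0)]
        out = select_disjoint(cands)
        assert out[0].sorted_genes() == ("a", "b")

    def test_output_pairwise_disjoint(self):
        cands = [
            stub_candidate(s, d)
            for s, d in [("abc", 90), ("bcd", 80), ("de", 70), ("ef", 60), ("fa", 55)]
        ]
        out = select_disjoint(cands)
        seen = set()
        for c in out:
            assert not (c.genes & seen)
            seen |= c.genes


class TestScoreCandidates:
    def test_empty_candidate_list(self, tiny_matrix):
        assert score_candidates(tiny_matrix, [], n_total=10) == []

    def test_duplicates_collapsed_and_threshold_applied(self):
        rng = np.random.default_rng(2)
        rows = np.zeros((100, 30), dtype=int)
        for i in range(100):  # perfect exclusive pair on g0, g1
            rows[i, i % 2] = 1
        rows[:, 2:] = (rng.random((100, 28)) < 0.02).astype(int)
        m = make_matrix(rows.tolist())
        pair = frozenset(["g0", "g1"])
        cfg = DiscoveryConfig(d_threshold=10.0)
        out = score_candidates(
            m, [("g0", pair), ("g1", pair)], n_total=30, config=cfg
        )
        assert len(out) == 1
        assert out[0].genes == pair
        assert out[0].d >= 10.0


class TestRunDiscovery:
    def test_planted_module_recovered_and_first(self):
        params = SimulationParams(k=145, n=300, module_size=3, coverage=1.0)
        matrix, truth = simulate_dataset(params, random_seed=42)
        modules = run_discovery(matrix)
        assert modules, "no module reported"
        assert modules[0].genes == truth.module_genes
        assert modules[0].stats.exclusivity == 1.0

    def test_pure_null_reports_nothing(self):
        for seed in range(3):
            background = __import__("rme").sample_background(
                145, 300, FrequencySpec(mode="large_panel"), random_seed=seed
            )
            assert run_discovery(background) == []

    def test_deterministic_given_config(self):
        params = SimulationParams(k=145, n=300, module_size=2, coverage=0.9)
        matrix, _ = simulate_dataset(params, random_seed=5)
        a = run_discovery(matrix)
        b = run_discovery(matrix)
        assert [m.genes for m in a] == [m.genes for m in b]
        assert [m.d for m in a] == [m.d for m in b]

    def test_too_few_recurrent_genes_is_informative_empty(self, tiny_matrix, caplog):
        sparse = make_matrix([[0] * 3] * 19 + [[1, 0, 0]])
        with caplog.at_level("WARNING"):
            assert run_discovery(sparse, config=DiscoveryConfig(min_recurrence=0.5)) == []
        assert "recurrence" in caplog.text

    def test_reported_modules_satisfy_contract(self):
        params = SimulationParams(k=145, n=300, module_size=4, coverage=1.0)
        matrix, truth = simulate_dataset(params, random_seed=8)
        cfg = DiscoveryConfig()
        modules = run_discovery(matrix, config=cfg)
        seen = set()
        for mod in modules:
            assert mod.d >= cfg.d_threshold
            assert not (mod.genes & seen)
            seen |= mod.genes
            assert module_stats(matrix, mod.genes).coverage == mod.stats.coverage
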