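import logging
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grn_softmem.graph import (
    EdgeListParseError,
    SignedDigraph,
    extract_recurrent_core,
    giant_component,
    network_stats,
    read_edge_list,
    write_edge_list,
)

from conftest import random_graph_tuples


def write_lines(tmp_path, lines):
    p = tmp_path / "net.tsv"
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return p


class TestEdgeListIO:
    def test_basic_parse(self, tmp_path):
        p = write_lines(tmp_path, ["a\tb\t+", "b\ta\t-"])
        g = read_edge_list(p)
        assert g.n_nodes == 2 and g.n_edges == 2
        assert g.repression_fraction == 0.5

    def test_empty_file(self, tmp_path):
        p = write_lines(tmp_path, ["# comment only"])
        g = read_edge_list(p)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_duplicate_collapses_last_wins(self, tmp_path, caplog):
        p = write_lines(tmp_path, ["a\tb\t+", "a\tb\t-"])
        with caplog.at_level(logging.WARNING):
            g = read_edge_list(p)
        assert g.n_edges == 1
        assert g.sign("a", "b") == -1
        assert any("duplicate" in r.message for r in caplog.records)

    @pytest.mark.parametrize("bad", ["a\tb", "a\tb\tmaybe", "only-one-field"])
    def test_malformed_rows_raise_with_line_number(self, tmp_path, bad):
        p = write_lines(tmp_path, ["a\tb\t+", bad])
        with pytest.raises(EdgeListParseError, match=":2"):
            read_edge_list(p)

    @pytest.mark.parametrize(
        "token,sign",
        [("+", 1), ("-", -1), ("+1", 1), ("-1", -1), ("activation", 1),
         ("repression", -1)],
    )
    def test_sign_tokens(self, tmp_path, token, sign):
        p = write_lines(tmp_path, [f"a\tb\t{token}"])
        assert read_edge_list(p).sign("a", "b") == sign

    def test_round_trip(self, tmp_path):
        g = SignedDigraph(["x", "iso"], [("x", "y", 1), ("y", "x", -1), ("y", "y", -1)])
        p = tmp_path / "round.tsv"
        write_edge_list(g, p)
        assert read_edge_list(p) == g


class TestNetworkStats:
    @pytest.mark.parametrize(
        "n,m,expected_2dp,truncated",
        [(3236, 8366, 5.17, 5.17), (70, 317, 9.06, 9.05)],
    )
    def test_published_mean_degrees(self, n, m, expected_2dp, truncated):
        """The two published node/edge rows give mean degrees 5.17 and 9.05
        (the latter under truncation, 9.0571... -> 9.05)."""
        from grn_softmem import SurrogateSpec, random_signed_digraph

        g = random_signed_digraph(SurrogateSpec(n, m, seed=0))
        stats = network_stats(g)
        assert (stats.n_nodes, stats.n_edges) == (n, m)
        assert round(stats.mean_degree, 2) == expected_2dp
        assert math.floor(stats.mean_degree * 100) / 100 == truncated

    def test_counts_from_graph(self):
        g = SignedDigraph(edges=[("a", "a", 1)])
        s = network_stats(g)
        assert s.n_nodes == 1 and s.n_edges == 1
        assert s.mean_degree == 2.0

    def test_empty_graph(self):
        s = network_stats(SignedDigraph())
        assert s.mean_degree == 0.0 and s.repression_fraction == 0.0


def brute_force_cycle_nodes(g: SignedDigraph) -> set:
    """Oracle: nodes on at least one simple directed cycle, via exhaustive
    cycle enumeration."""
    G = g.to_networkx()
    members = set()
    for cycle in nx.simple_cycles(G):
        members.update(cycle)
    return members


class TestRecurrentCore:
    def test_cycle_plus_dangler(self, three_cycle):
        three_cycle.add_edge("c", "d", 1)
        core = extract_recurrent_core(three_cycle)
        assert set(core.nodes) == {"a", "b", "c"}
        assert core.n_edges == 3

    def test_dag_gives_empty(self):
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "c", -1), ("a", "c", 1)])
        assert extract_recurrent_core(g).n_nodes == 0

    def test_self_loop_is_recurrent(self):
        g = SignedDigraph(edges=[("a", "a", -1), ("a", "b", 1)])
        assert set(extract_recurrent_core(g).nodes) == {"a"}

    def test_idempotent(self, surrogate):
        core = extract_recurrent_core(surrogate)
        assert extract_recurrent_core(core) == core

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_cycle_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        m = int(rng.integers(1, min(n * n, 3 * n) + 1))
        g = SignedDigraph(range(n), random_graph_tuples(rng, n, m))
        assert set(extract_recurrent_core(g).nodes) == brute_force_cycle_nodes(g)

    def test_random_20_node_matches_oracle(self):
        rng = np.random.default_rng(99)
        g = SignedDigraph(range(20), random_graph_tuples(rng, 20, 60))
        assert set(extract_recurrent_core(g).nodes) == brute_force_cycle_nodes(g)


class TestGiantComponent:
    def test_two_disjoint_cycles(self):
        g = SignedDigraph(
            edges=[("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1),
                   ("x", "y", 1), ("y", "z", 1), ("z", "x", 1)]
        )
        assert set(giant_component(g).nodes) == {"a", "b", "c", "d"}

    def test_connected_graph_is_itself(self, three_cycle):
        assert giant_component(three_cycle) == three_cycle

    def test_tie_break_lexicographic(self):
        g = SignedDigraph(
            edges=[("d", "e", 1), ("e", "f", 1), ("f", "d", 1),
                   ("a", "b", 1), ("b", "c", 1), ("c", "a", 1)]
        )
        assert set(giant_component(g).nodes) == {"a", "b", "c"}

    def test_strong_mode(self):
        # a -> b -> a strongly connected; c attached only weakly
        g = SignedDigraph(edges=[("a", "b", 1), ("b", "a", 1), ("b", "c", 1)])
        assert set(giant_component(g, mode="strong").nodes) == {"a", "b"}
        assert set(giant_component(g, mode="weak").nodes) == {"a", "b", "c"}

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            giant_component(SignedDigraph())
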