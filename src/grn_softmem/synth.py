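"""Random signed digraphs emulating bacterial regulatory-network statistics.

The generators here play three roles: (i) surrogates for the E. coli
transcriptional network, whose published summary statistics (70 nodes / 317
edges / 41% repression for the recurrent core; 3236 / 8366 / 24% for the
whole graph) are matched by construction, (ii) the null model for motif
z-scores — a uniform directed graph with exactly ``m`` distinct edges (no
multi-edges, self-loops allowed), and (iii) controlled fixtures such as delay
chains and motif-enriched graphs used to validate the memory benchmarks.

Sign counts are exact (``round(f * m)`` repressing edges), not Bernoulli per
edge, so sweeps over the repression fraction are noiseless in composition.
All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ACTIVATION, REPRESSION, SignedDigraph, extract_recurrent_core

__all__ = [
    "SurrogateSpec",
    "random_signed_digraph",
    "ecoli_core_surrogate",
    "randomize_signs",
    "delay_chain",
    "motif_enriched_graph",
    "ECOLI_CORE_NODES",
    "ECOLI_CORE_EDGES",
    "ECOLI_CORE_REPRESSION",
    "ECOLI_WHOLE_NODES",
    "ECOLI_WHOLE_EDGES",
    "ECOLI_WHOLE_REPRESSION",
]

# Published E. coli (EcoCyc-derived) network statistics used as surrogate
# targets throughout the package.
ECOLI_CORE_NODES = 70
ECOLI_CORE_EDGES = 317
ECOLI_CORE_REPRESSION = 0.41
ECOLI_WHOLE_NODES = 3236
ECOLI_WHOLE_EDGES = 8366
ECOLI_WHOLE_REPRESSION = 0.24


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters of a uniform random signed digraph.

    ``n_edges`` distinct ordered pairs are drawn uniformly without
    replacement from all permitted pairs; exactly ``round(repression_fraction
    * n_edges)`` of them carry sign -1.
    """

    n_nodes: int
    n_edges: int
    repression_fraction: float = 0.0
    allow_self_loops: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 0 or self.n_edges < 0:
            raise ValueError("n_nodes and n_edges must be non-negative")
        if not 0.0 <= self.repression_fraction <= 1.0:
            raise ValueError("repression_fraction must lie in [0, 1]")
        cap = self.n_nodes**2 if self.allow_self_loops else self.n_nodes * (
            self.n_nodes - 1
        )
        if self.n_edges > cap:
            raise ValueError(
                f"{self.n_edges} edges infeasible on {self.n_nodes} nodes "
                f"(max {cap} with allow_self_loops={self.allow_self_loops})"
            )


def _node_labels(n: int) -> list[str]:
    width = max(1, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


def sample_edge_codes(
    n: int, m: int, allow_self_loops: bool, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``m`` distinct ordered pairs, encoded as ``i * n + j``.

    Rejection sampling of integer codes; uniform over all m-subsets of the
    permitted pair space, returned sorted.  Self-pairs are excluded from the
    code space (and re-mapped) when ``allow_self_loops`` is False.
    """
    space = n * n if allow_self_loops else n * (n - 1)
    if m > space:
        raise ValueError(f"cannot place {m} distinct edges in a space of {space}")
    chosen: set[int] = set()
    while len(chosen) < m:
        batch = rng.integers(0, space, size=m - len(chosen))
        chosen.update(int(c) for c in batch)
    codes = np.fromiter(chosen, dtype=np.int64, count=m)
    codes.sort()
    if not allow_self_loops:
        # map code -> off-diagonal pair (i, j), j skipping the diagonal
        i = codes // (n - 1)
        r = codes % (n - 1)
        j = np.where(r < i, r, r + 1)
        codes = i * n + j
        codes.sort()
    return codes


def _signs_for_edges(m: int, repression_fraction: float, rng: np.random.Generator):
    n_neg = int(round(repression_fraction * m))
    signs = np.full(m, ACTIVATION, dtype=np.int64)
    if n_neg:
        signs[rng.permutation(m)[:n_neg]] = REPRESSION
    return signs


def _graph_from_codes(n: int, codes: np.ndarray, signs: np.ndarray) -> SignedDigraph:
    labels = _node_labels(n)
    g = SignedDigraph(labels)
    for c, s in zip(codes.tolist(), signs.tolist()):
        g.add_edge(labels[c // n], labels[c % n], int(s))
    return g


def _random_signed_digraph(
    n: int,
    m: int,
    repression_fraction: float,
    allow_self_loops: bool,
    rng: np.random.Generator,
) -> SignedDigraph:
    codes = sample_edge_codes(n, m, allow_self_loops, rng)
    signs = _signs_for_edges(m, repression_fraction, rng)
    return _graph_from_codes(n, codes, signs)


def random_signed_digraph(spec: SurrogateSpec) -> SignedDigraph:
    """Uniform random signed digraph per ``spec`` (the motif null model)."""
    rng = np.random.default_rng(spec.seed)
    return _random_signed_digraph(
        spec.n_nodes,
        spec.n_edges,
        spec.repression_fraction,
        spec.allow_self_loops,
        rng,
    )


def ecoli_core_surrogate(
    seed: int,
    n_nodes: int = ECOLI_CORE_NODES,
    n_edges: int = ECOLI_CORE_EDGES,
    repression_fraction: float = ECOLI_CORE_REPRESSION,
    max_retries: int = 1000,
) -> SignedDigraph:
    """A fully recurrent, weakly connected surrogate of the E. coli core.

    Draws uniform random graphs with the published core statistics (70 nodes,
    317 edges, 41% repression) and resamples until every node lies on a cycle
    and the graph is weakly connected, so the whole graph is a single
    reservoir.  Deterministic given ``seed``.
    """
    import networkx as nx

    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max_retries):
        rng = np.random.default_rng(child)
        g = _random_signed_digraph(n_nodes, n_edges, repression_fraction, True, rng)
        if extract_recurrent_core(g).n_nodes != n_nodes:
            continue
        if not nx.is_weakly_connected(g.to_networkx()):
            continue
        return g
    raise RuntimeError(
        f"no fully recurrent connected graph found in {max_retries} draws "
        f"(n={n_nodes}, m={n_edges})"
    )


def randomize_signs(
    g: SignedDigraph, repression_fraction: float, seed: int
) -> SignedDigraph:
    """Re-draw edge signs, keeping topology and an exact repression count.

    Exactly ``round(repression_fraction * m)`` edges are set to -1, chosen
    uniformly among all edges.
    """
    if g.n_edges == 0:
        raise ValueError("cannot randomize signs of an edgeless graph")
    if not 0.0 <= repression_fraction <= 1.0:
        raise ValueError("repression_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = list(g.edges())
    signs = _signs_for_edges(len(edges), repression_fraction, rng)
    return SignedDigraph(
        g.nodes, ((u, v, int(s)) for (u, v, _), s in zip(edges, signs))
    )


def delay_chain(length: int) -> SignedDigraph:
    """An activating chain v1 -> v2 -> ... -> vL with a self-loop on v1.

    The self-loop keeps the chain inside its own recurrent core, so the
    fixture behaves as a near-delay-line reservoir with L-step memory.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    nodes = [f"v{i}" for i in range(1, length + 1)]
    g = SignedDigraph(nodes)
    g.add_edge(nodes[0], nodes[0], ACTIVATION)
    for a, b in zip(nodes, nodes[1:]):
        g.add_edge(a, b, ACTIVATION)
    return g


def motif_enriched_graph(
    spec: SurrogateSpec,
    extra_self_loops: int = 0,
    extra_mutual: int = 0,
    extra_ffl: int = 0,
    seed: int = 0,
    max_retries: int = 10_000,
) -> SignedDigraph:
    """Random base graph with extra planted memory-motif instances.

    Plants exactly ``extra_self_loops`` new self-loops and ``extra_mutual``
    new reciprocal pairs (sites already carrying the motif are rejected and
    resampled), and ``extra_ffl`` feedforward triples (x -> y, y -> z,
    x -> z; triples with all three edges present are rejected, so the census
    rises by at least the planted number — added edges may create incidental
    FFLs).  Planted edges are activating.  The final edge count is whatever
    the plantings produce.
    """
    rng = np.random.default_rng(seed)
    g = random_signed_digraph(spec)
    nodes = list(g.nodes)
    n = len(nodes)

    loop_free = [u for u in nodes if not g.has_edge(u, u)]
    if extra_self_loops > len(loop_free):
        raise ValueError("not enough loop-free nodes to plant self-loops")
    for i in rng.permutation(len(loop_free))[:extra_self_loops]:
        g.add_edge(loop_free[i], loop_free[i], ACTIVATION)

    planted = 0
    for _ in range(max_retries):
        if planted == extra_mutual:
            break
        i, j = rng.choice(n, size=2, replace=False)
        u, v = nodes[i], nodes[j]
        if g.has_edge(u, v) and g.has_edge(v, u):
            continue
        g.add_edge(u, v, ACTIVATION)
        g.add_edge(v, u, ACTIVATION)
        planted += 1
    else:
        raise RuntimeError("could not plant the requested mutual pairs")

    planted = 0
    for _ in range(max_retries):
        if planted == extra_ffl:
            break
        i, j, k = rng.choice(n, size=3, replace=False)
        x, y, z = nodes[i], nodes[j], nodes[k]
        if g.has_edge(x, y) and g.has_edge(y, z) and g.has_edge(x, z):
            continue
        g.add_edge(x, y, ACTIVATION)
        g.add_edge(y, z, ACTIVATION)
        g.add_edge(x, z, ACTIVATION)
        planted += 1
    else:
        raise RuntimeError("could not plant the requested feedforward loops")

    return g
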