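"""Signed directed graphs for transcriptional networks.

A gene regulatory network is represented as a :class:`SignedDigraph`: an
ordered set of nodes (gene/regulator labels) plus directed edges carrying a
regulatory sign, +1 for activation and -1 for repression.  At most one edge
may exist per ordered (source, target) pair; self-edges (autoregulation) are
allowed.  The module also provides edge-list I/O in a simple TSV dialect,
extraction of the recurrent core (the cycle-supporting subgraph that acts as
the dynamical reservoir), giant-component selection, and summary statistics.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Hashable, Iterable, Iterator
from dataclasses import asdict, dataclass

import networkx as nx

__all__ = [
    "ACTIVATION",
    "REPRESSION",
    "SignedDigraph",
    "NetworkStats",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "network_stats",
    "extract_recurrent_core",
    "giant_component",
]

log = logging.getLogger(__name__)

ACTIVATION = 1
REPRESSION = -1

#: accepted third-column tokens in edge-list files
_SIGN_TOKENS = {
    "+": ACTIVATION,
    "-": REPRESSION,
    "+1": ACTIVATION,
    "-1": REPRESSION,
    "1": ACTIVATION,
    "activation": ACTIVATION,
    "repression": REPRESSION,
}

_SIGN_TO_TOKEN = {ACTIVATION: "+", REPRESSION: "-"}


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class SignedDigraph:
    """A directed graph whose edges carry a regulatory sign (+1 or -1).

    Nodes keep their insertion order, which fixes the matrix index mapping
    used when a graph is turned into a reservoir weight matrix.  Adding an
    edge whose (source, target) pair already exists replaces the stored sign
    (last write wins).
    """

    __slots__ = ("_order", "_succ", "_pred", "_n_repress")

    def __init__(
        self,
        nodes: Iterable[Hashable] = (),
        edges: Iterable[tuple[Hashable, Hashable, int]] = (),
    ) -> None:
        self._order: dict[Hashable, None] = {}
        self._succ: dict[Hashable, dict[Hashable, int]] = {}
        self._pred: dict[Hashable, dict[Hashable, int]] = {}
        self._n_repress = 0
        for u in nodes:
            self.add_node(u)
        for u, v, s in edges:
            self.add_edge(u, v, s)

    # -- construction -----------------------------------------------------

    def add_node(self, u: Hashable) -> None:
        if u not in self._order:
            self._order[u] = None
            self._succ[u] = {}
            self._pred[u] = {}

    def add_edge(self, u: Hashable, v: Hashable, sign: int) -> bool:
        """Add edge u -> v; returns True if an existing edge was replaced."""
        if sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        self.add_node(u)
        self.add_node(v)
        replaced = v in self._succ[u]
        if replaced and self._succ[u][v] == REPRESSION:
            self._n_repress -= 1
        self._succ[u][v] = sign
        self._pred[v][u] = sign
        if sign == REPRESSION:
            self._n_repress += 1
        return replaced

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> tuple[Hashable, ...]:
        return tuple(self._order)

    def edges(self) -> Iterator[tuple[Hashable, Hashable, int]]:
        for u in self._order:
            for v, s in self._succ[u].items():
                yield u, v, s

    @property
    def n_nodes(self) -> int:
        return len(self._order)

    @property
    def n_edges(self) -> int:
        return sum(len(d) for d in self._succ.values())

    @property
    def repression_fraction(self) -> float:
        m = self.n_edges
        return self._n_repress / m if m else 0.0

    def has_node(self, u: Hashable) -> bool:
        return u in self._order

    def has_edge(self, u: Hashable, v: Hashable) -> bool:
        return u in self._succ and v in self._succ[u]

    def sign(self, u: Hashable, v: Hashable) -> int:
        return self._succ[u][v]

    def successors(self, u: Hashable) -> tuple[Hashable, ...]:
        return tuple(self._succ[u])

    def predecessors(self, v: Hashable) -> tuple[Hashable, ...]:
        return tuple(self._pred[v])

    def self_loop_nodes(self) -> tuple[Hashable, ...]:
        return tuple(u for u in self._order if u in self._succ[u])

    # -- derived graphs ---------------------------------------------------

    def subgraph(self, nodes: Iterable[Hashable]) -> "SignedDigraph":
        """Induced subgraph, preserving the parent's node order."""
        keep = set(nodes)
        missing = keep - set(self._order)
        if missing:
            raise KeyError(f"nodes not in graph: {sorted(map(str, missing))[:5]}")
        sub = SignedDigraph(u for u in self._order if u in keep)
        for u in sub.nodes:
            for v, s in self._succ[u].items():
                if v in keep:
                    sub.add_edge(u, v, s)
        return sub

    def copy(self) -> "SignedDigraph":
        return SignedDigraph(self.nodes, self.edges())

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self._order)
        G.add_edges_from((u, v, {"sign": s}) for u, v, s in self.edges())
        return G

    # -- dunder -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return set(self._order) == set(other._order) and set(self.edges()) == set(
            other.edges()
        )

    def __hash__(self) -> None:  # mutable container
        raise TypeError("SignedDigraph is unhashable")

    def __repr__(self) -> str:
        return (
            f"<SignedDigraph n={self.n_nodes} m={self.n_edges} "
            f"repression={self.repression_fraction:.2f}>"
        )


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of a signed digraph."""

    n_nodes: int
    n_edges: int
    mean_degree: float
    repression_fraction: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def read_edge_list(path) -> SignedDigraph:
    """Read a TSV edge list ``source<TAB>target<TAB>sign``.

    Lines starting with ``#`` and blank lines are ignored.  Accepted sign
    tokens: ``+ - +1 -1 1 activation repression`` (case-insensitive).
    Duplicate (source, target) rows collapse, last sign wins, with a warning.
    """
    g = SignedDigraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                # "# node <id>" records an isolated node (see write_edge_list)
                stripped = line.lstrip()
                if stripped.startswith("# node "):
                    g.add_node(stripped[len("# node "):].strip())
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            src, tgt, token = fields[0], fields[1], fields[2].strip().lower()
            if token not in _SIGN_TOKENS:
                raise EdgeListParseError(
                    f"{path}:{lineno}: unknown sign token {fields[2]!r}"
                )
            if g.add_edge(src, tgt, _SIGN_TOKENS[token]):
                log.warning(
                    "%s:%d: duplicate edge (%s -> %s); last sign wins",
                    path,
                    lineno,
                    src,
                    tgt,
                )
    return g


def write_edge_list(g: SignedDigraph, path) -> None:
    """Write ``g`` in the same TSV dialect accepted by :func:`read_edge_list`.

    Isolated nodes are recorded as ``# node <id>`` comment lines so that a
    round trip preserves the node set.
    """
    with open(path, "w", encoding="utf-8") as fh:
        connected = {u for u, v, _ in g.edges()} | {v for _, v, _ in g.edges()}
        for u in g.nodes:
            if u not in connected:
                fh.write(f"# node {u}\n")
        for u, v, s in g.edges():
            fh.write(f"{u}\t{v}\t{_SIGN_TO_TOKEN[s]}\n")


def network_stats(g: SignedDigraph) -> NetworkStats:
    """Node/edge counts, mean total degree 2m/n, and repression fraction."""
    n, m = g.n_nodes, g.n_edges
    mean_degree = 2.0 * m / n if n else 0.0
    return NetworkStats(n, m, mean_degree, g.repression_fraction)


def extract_recurrent_core(g: SignedDigraph) -> SignedDigraph:
    """Induced subgraph on all nodes that lie on at least one directed cycle.

    A node participates in a cycle iff it belongs to a strongly connected
    component of size >= 2 or carries a self-loop.  This is the maximal
    subgraph able to sustain recurrent (reservoir) dynamics; an acyclic input
    yields the empty graph.
    """
    keep: set[Hashable] = set()
    G = g.to_networkx()
    for comp in nx.strongly_connected_components(G):
        if len(comp) > 1:
            keep |= comp
    for u in g.nodes:
        if g.has_edge(u, u):
            keep.add(u)
    return g.subgraph(keep)


def giant_component(g: SignedDigraph, mode: str = "weak") -> SignedDigraph:
    """Induced subgraph on the largest connected component.

    ``mode`` selects weak (default) or strong connectivity.  Size ties are
    broken by the component containing the lexicographically smallest node id
    (compared as strings).
    """
    if g.n_nodes == 0:
        raise ValueError("giant_component of an empty graph is undefined")
    if mode not in ("weak", "strong"):
        raise ValueError(f"mode must be 'weak' or 'strong', got {mode!r}")
    G = g.to_networkx()
    comps = (
        nx.weakly_connected_components(G)
        if mode == "weak"
        else nx.strongly_connected_components(G)
    )
    best = min(comps, key=lambda c: (-len(c), min(str(u) for u in c)))
    return g.subgraph(best)
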