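"""Census and null-model statistics of the three memory motifs.

The memory motifs are the smallest circuits carrying feedback or feedforward
structure in a regulatory network:

* **self-loops** — edges (v, v), single-gene autoregulation;
* **mutual regulation** — unordered pairs {i, j} with both i -> j and
  j -> i present;
* **feedforward loops (FFLs)** — ordered triples (x, y, z) of distinct
  nodes with x -> y, y -> z and x -> z all present (a fully reciprocal
  triangle therefore contributes 6).

Counting is sign-blind.  Enrichment is quantified against a uniform null —
random digraphs with the same number of nodes and distinct edges, self-loops
allowed — via the z-score (N_real - <N>_rand) / sigma_rand, with the sample
(n-1) standard deviation over the ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import SignedDigraph
from .synth import sample_edge_codes

__all__ = [
    "MotifCensus",
    "MotifStat",
    "MotifZScores",
    "count_self_loops",
    "count_mutual_regulation",
    "count_ffl",
    "census",
    "null_motif_moments",
    "motif_zscores",
    "expected_motif_counts",
    "normalized_motif_counts",
]

MOTIF_NAMES = ("self_loops", "mutual_regulation", "ffl")


@dataclass(frozen=True)
class MotifCensus:
    """Counts of the three memory motifs in one graph."""

    self_loops: int
    mutual_regulation: int
    ffl: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.self_loops, self.mutual_regulation, self.ffl)


@dataclass(frozen=True)
class MotifStat:
    """One motif's real count against the randomized ensemble."""

    real: int
    null_mean: float
    null_sd: float
    zscore: float
    degenerate: bool = False  # sigma_rand == 0; zscore reported as +/-inf


@dataclass(frozen=True)
class MotifZScores:
    self_loops: MotifStat
    mutual_regulation: MotifStat
    ffl: MotifStat
    n_rand: int = 0


def _edge_codes(g: SignedDigraph) -> tuple[int, np.ndarray]:
    index = {u: i for i, u in enumerate(g.nodes)}
    n = g.n_nodes
    codes = np.fromiter(
        (index[u] * n + index[v] for u, v, _ in g.edges()),
        dtype=np.int64,
        count=g.n_edges,
    )
    codes.sort()
    return n, codes


def _census_from_codes(n: int, codes: np.ndarray, count_ffls: bool = True):
    """(self-loops, mutual pairs, FFL triples) from sorted pair codes."""
    if len(codes) == 0:
        return 0, 0, 0
    i = codes // n
    j = codes % n
    self_loops = int(np.count_nonzero(i == j))

    off = i != j
    rev = j * n + i
    # count each reciprocal pair once via i < j
    mutual = int(np.count_nonzero(np.isin(rev[off & (i < j)], codes)))

    ffl = 0
    if count_ffls:
        succ: dict[int, set[int]] = {}
        pred: dict[int, set[int]] = {}
        for a, b in zip(i[off].tolist(), j[off].tolist()):
            succ.setdefault(a, set()).add(b)
            pred.setdefault(b, set()).add(a)
        for a, b in zip(i[off].tolist(), j[off].tolist()):
            sa = succ.get(a)
            pb = pred.get(b)
            if sa and pb:
                inter = sa & pb
                ffl += len(inter) - (1 if b in inter else 0) - (1 if a in inter else 0)
    return self_loops, mutual, ffl


def census(g: SignedDigraph) -> MotifCensus:
    """Exact memory-motif census of ``g``."""
    n, codes = _edge_codes(g)
    s, m, f = _census_from_codes(n, codes)
    return MotifCensus(self_loops=s, mutual_regulation=m, ffl=f)


def count_self_loops(g: SignedDigraph) -> int:
    return census(g).self_loops


def count_mutual_regulation(g: SignedDigraph) -> int:
    return census(g).mutual_regulation


def count_ffl(g: SignedDigraph) -> int:
    return census(g).ffl


def null_motif_moments(
    n: int,
    m: int,
    n_rand: int = 1000,
    seed: int = 0,
    include_ffl: bool = True,
) -> dict[str, tuple[float, float]]:
    """Ensemble mean and sample s.d. of each motif count under the null.

    The null is the uniform digraph with exactly ``m`` distinct edges on
    ``n`` nodes, self-loops allowed.  FFL counting dominates the cost on
    large graphs and can be switched off.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2 for a sample s.d.")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_rand, 3))
    for r in range(n_rand):
        codes = sample_edge_codes(n, m, True, rng)
        counts[r] = _census_from_codes(n, codes, count_ffls=include_ffl)
    out = {}
    for idx, name in enumerate(MOTIF_NAMES):
        if name == "ffl" and not include_ffl:
            continue
        col = counts[:, idx]
        out[name] = (float(col.mean()), float(col.std(ddof=1)))
    return out


def _stat(real: int, mean: float, sd: float) -> MotifStat:
    if sd == 0.0:
        z = math.inf if real > mean else (-math.inf if real < mean else 0.0)
        return MotifStat(real, mean, sd, z, degenerate=True)
    return MotifStat(real, mean, sd, (real - mean) / sd)


def motif_zscores(
    g: SignedDigraph, n_rand: int = 1000, seed: int = 0
) -> MotifZScores:
    """Motif z-scores of ``g`` against ``n_rand`` matched random graphs."""
    real = census(g)
    moments = null_motif_moments(g.n_nodes, g.n_edges, n_rand=n_rand, seed=seed)
    stats = {
        name: _stat(count, *moments[name])
        for name, count in zip(MOTIF_NAMES, real.as_tuple())
    }
    return MotifZScores(
        self_loops=stats["self_loops"],
        mutual_regulation=stats["mutual_regulation"],
        ffl=stats["ffl"],
        n_rand=n_rand,
    )


def expected_motif_counts(n: int, m: int) -> dict[str, float]:
    """Closed-form null expectations (uniform m-subset of the n^2 pairs)."""
    N = n * n
    if m == 0 or n == 0:
        return dict.fromkeys(MOTIF_NAMES, 0.0)
    e_self = n * m / N
    e_mut = (n * (n - 1) / 2) * (m * (m - 1)) / (N * (N - 1)) if m >= 2 else 0.0
    e_ffl = (
        n * (n - 1) * (n - 2) * (m * (m - 1) * (m - 2)) / (N * (N - 1) * (N - 2))
        if m >= 3 and n >= 3
        else 0.0
    )
    return {"self_loops": e_self, "mutual_regulation": e_mut, "ffl": e_ffl}


def normalized_motif_counts(
    g: SignedDigraph, n_rand: int = 1000, seed: int = 0
) -> dict[str, float]:
    """Real count divided by the null-ensemble mean, per motif.

    A sampled null mean of zero is replaced by the analytic expectation of
    :func:`expected_motif_counts` to avoid division by zero.
    """
    real = census(g)
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_rand, 3))
    for r in range(n_rand):
        codes = sample_edge_codes(g.n_nodes, g.n_edges, True, rng)
        counts[r] = _census_from_codes(g.n_nodes, codes)
    means = counts.mean(axis=0)
    analytic = expected_motif_counts(g.n_nodes, g.n_edges)
    out = {}
    for idx, name in enumerate(MOTIF_NAMES):
        denom = means[idx] if means[idx] > 0 else analytic[name]
        real_count = real.as_tuple()[idx]
        out[name] = real_count / denom if denom > 0 else 0.0
    return out
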