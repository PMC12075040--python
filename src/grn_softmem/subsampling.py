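"""Sub-reservoir sampling by iterated random node removal, and outlier filtering.

Starting from a fully recurrent core, each run repeatedly deletes one
uniformly chosen node, re-extracts the recurrent core (nodes on directed
cycles) and keeps the giant weakly connected component, recording every
intermediate graph down to a minimum size.  Concatenating many runs yields a
library of sub-reservoirs spanning a wide size range, used to relate local
motif content and network size to memory performance.

The companion :func:`performance_filter` implements the score-outlier rule
used when plotting size-performance clouds: keep values within a given
number of standard deviations of the library mean (1.25 by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import SignedDigraph, extract_recurrent_core, giant_component, write_edge_list
from .motifs import census

__all__ = [
    "SubReservoir",
    "SubReservoirLibrary",
    "sample_subreservoirs",
    "performance_filter",
    "save_library",
]


@dataclass(frozen=True)
class SubReservoir:
    """One sampled sub-reservoir with its provenance (run, removal step)."""

    graph: SignedDigraph
    run: int
    step: int


@dataclass
class SubReservoirLibrary:
    members: list[SubReservoir] = field(default_factory=list)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def sizes(self) -> np.ndarray:
        return np.array([m.graph.n_nodes for m in self.members])


def sample_subreservoirs(
    core: SignedDigraph,
    n_runs: int = 100,
    min_size: int = 3,
    seed: int = 0,
    record_initial: bool = False,
) -> SubReservoirLibrary:
    """Library of pruned sub-reservoirs from ``n_runs`` random removal runs.

    ``core`` must already be its own recurrent core.  A snapshot is recorded
    after every removal+prune step while the surviving graph has at least
    ``min_size`` nodes; duplicates across runs are retained.  Sizes are
    strictly decreasing within a run.  ``record_initial`` additionally stores
    the unpruned parent once per run (step 0).
    """
    if core.n_nodes == 0:
        raise ValueError("core is empty")
    if extract_recurrent_core(core) != core:
        raise ValueError("input graph is not fully recurrent (not its own core)")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    rng = np.random.default_rng(seed)
    lib = SubReservoirLibrary(seed=seed)
    for run in range(n_runs):
        g = core
        if record_initial:
            lib.members.append(SubReservoir(graph=g, run=run, step=0))
        step = 0
        while g.n_nodes > 0:
            victim = g.nodes[int(rng.integers(g.n_nodes))]
            pruned = extract_recurrent_core(
                g.subgraph(u for u in g.nodes if u != victim)
            )
            if pruned.n_nodes == 0:
                break
            g = giant_component(pruned, mode="weak")
            step += 1
            if g.n_nodes < min_size:
                break
            lib.members.append(SubReservoir(graph=g, run=run, step=step))
    return lib


def performance_filter(values, width: float = 1.25) -> np.ndarray:
    """Mask of values within ``width`` sample standard deviations of the mean.

    With zero spread every value is kept.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        return np.ones(v.size, dtype=bool)
    return np.abs(v - v.mean()) <= width * sd


def save_library(lib: SubReservoirLibrary, directory) -> Path:
    """Persist a library as numbered TSV edge lists plus a manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "run", "step", "n_nodes", "n_edges", "self_loops", "mutual", "ffl"]
        )
        for i, member in enumerate(lib.members):
            path = directory / f"subreservoir_{i:05d}.tsv"
            write_edge_list(member.graph, path)
            c = census(member.graph)
            writer.writerow(
                [
                    i,
                    member.run,
                    member.step,
                    member.graph.n_nodes,
                    member.graph.n_edges,
                    c.self_loops,
                    c.mutual_regulation,
                    c.ffl,
                ]
            )
    return manifest
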