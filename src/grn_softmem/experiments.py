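"""Headline experiments: spectral-radius and repression sweeps, motif-memory
and size-performance analyses over sub-reservoir libraries.

Each experiment takes a network (or a library of sub-reservoirs), a grid,
and a realization count, derives per-realization sub-seeds deterministically
from a master seed, and returns a tidy :class:`pandas.DataFrame` carrying
full provenance columns (seed, gamma, washout, protocol sizes).  Numbers,
not figures, are the product; plotting is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import SignedDigraph
from .lyapunov import MLEConfig, max_lyapunov, mle_input
from .motifs import census, normalized_motif_counts
from .reservoir import build_reservoir
from .subsampling import SubReservoirLibrary, performance_filter
from .synth import randomize_signs
from .tasks import (
    TaskProtocol,
    critical_memory_capacity,
    delayed_and_task,
    narma10_task,
)

__all__ = [
    "ExperimentConfig",
    "sweep_spectral_radius",
    "sweep_repression",
    "motif_memory_analysis",
    "size_performance",
    "pareto_front",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment knobs; grids default to the headline sweeps."""

    rho_grid: tuple = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))
    repression_grid: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    rho: float = 0.95
    n_realizations: int = 50
    k_max: int = 30
    protocol: TaskProtocol = field(default_factory=TaskProtocol)
    mle: MLEConfig = field(default_factory=MLEConfig)
    mle_drive: str = "zero"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rho_grid or not self.repression_grid:
            raise ValueError("grids must be non-empty")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def _realization_seed(master: int, *key: int) -> int:
    """Deterministic 31-bit sub-seed for one grid point / realization."""
    state = np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0]
    return int(state % (2**31))


def _provenance(cfg: ExperimentConfig) -> dict:
    p = cfg.protocol
    return {
        "gamma": p.gamma,
        "washout": p.washout,
        "n_series": p.n_series,
        "series_length": p.series_length,
        "master_seed": cfg.seed,
    }


def sweep_spectral_radius(
    g: SignedDigraph, cfg: ExperimentConfig | None = None
) -> pd.DataFrame:
    """Mean +/- s.d. of the Lyapunov exponent and k* across a rho grid.

    Each realization redraws the recurrent weight magnitudes, the input
    weights, and the task inputs.
    """
    cfg = cfg or ExperimentConfig()
    rows = []
    for pi, rho in enumerate(cfg.rho_grid):
        lams = np.empty(cfg.n_realizations)
        kstars = np.empty(cfg.n_realizations)
        for r in range(cfg.n_realizations):
            seed = _realization_seed(cfg.seed, 0, pi, r)
            sys = build_reservoir(g, rho=float(rho), n_inputs=1, seed=seed)
            mle_cfg = replace(cfg.mle, seed=seed)
            lams[r] = max_lyapunov(
                sys, mle_input(sys, mle_cfg, kind=cfg.mle_drive), mle_cfg
            )
            proto = replace(cfg.protocol, seed=seed)
            kstars[r] = critical_memory_capacity(
                sys, k_max=cfg.k_max, protocol=proto
            ).score
        rows.append(
            {
                "rho": float(rho),
                "lambda_mean": lams.mean(),
                "lambda_sd": lams.std(ddof=1) if len(lams) > 1 else 0.0,
                "kstar_mean": kstars.mean(),
                "kstar_sd": kstars.std(ddof=1) if len(kstars) > 1 else 0.0,
                "n": cfg.n_realizations,
                **_provenance(cfg),
            }
        )
    return pd.DataFrame(rows)


def _resign_weights(
    sys, repression_fraction: float, rng: np.random.Generator
):
    """Same reservoir with edge signs redrawn at an exact repression count.

    The weight magnitudes (and hence the overall scale set by normalizing
    the *natural* signing) are kept fixed, so the effective gain of the
    re-signed matrix varies with the sign balance — unbalanced signings lose
    the cancellation that keeps the balanced network near criticality.
    """
    from .reservoir import ReservoirSystem

    rows, cols = np.nonzero(sys.W)
    m = len(rows)
    n_neg = int(round(repression_fraction * m))
    signs = np.ones(m)
    if n_neg:
        signs[rng.permutation(m)[:n_neg]] = -1.0
    W = np.zeros_like(sys.W)
    W[rows, cols] = np.abs(sys.W[rows, cols]) * signs
    return ReservoirSystem(
        W=W, W_in=sys.W_in, rho=sys.rho, node_order=sys.node_order, seed=sys.seed
    )


def sweep_repression(
    g: SignedDigraph,
    cfg: ExperimentConfig | None = None,
    tasks: tuple[str, ...] = ("narma", "kstar"),
    renormalize: bool = False,
) -> pd.DataFrame:
    """NARMA-10 error and k* as edge signs are re-randomized across a
    repression-fraction grid.

    Per realization, one reservoir is built from the input network (its
    natural signs) and normalized to ``cfg.rho``; each grid fraction then
    re-signs those fixed-magnitude weights, so the sign balance genuinely
    changes the operating regime.  With ``renormalize=True`` every re-signed
    matrix is instead rescaled back to ``cfg.rho`` (isolating composition
    from gain).  The unmodified network's own scores are appended as a
    reference row (``reference`` column True, ``repression_fraction`` equal
    to the input graph's actual fraction).
    """
    cfg = cfg or ExperimentConfig()

    def scores(sys, proto) -> dict:
        out = {}
        if "narma" in tasks:
            out["narma_nrmse"] = narma10_task(sys, proto).score
        if "kstar" in tasks:
            out["kstar"] = critical_memory_capacity(
                sys, k_max=cfg.k_max, protocol=proto
            ).score
        return out

    grid = [float(f) for f in cfg.repression_grid]
    accum: dict[int, dict[str, list[float]]] = {
        pi: {} for pi in range(len(grid) + 1)
    }
    for r in range(cfg.n_realizations):
        base_seed = _realization_seed(cfg.seed, 1, r)
        base = build_reservoir(g, rho=cfg.rho, n_inputs=1, seed=base_seed)
        for pi, f in enumerate(grid):
            if renormalize:
                seed = _realization_seed(cfg.seed, 1, r, pi)
                gf = randomize_signs(g, f, seed=seed)
                sys = build_reservoir(gf, rho=cfg.rho, n_inputs=1, seed=base_seed)
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(1, r, pi))
                )
                sys = _resign_weights(base, f, rng)
            proto = replace(cfg.protocol, seed=_realization_seed(cfg.seed, 6, r, pi))
            for name, val in scores(sys, proto).items():
                accum[pi].setdefault(name, []).append(val)
        proto = replace(cfg.protocol, seed=_realization_seed(cfg.seed, 6, r, len(grid)))
        for name, val in scores(base, proto).items():
            accum[len(grid)].setdefault(name, []).append(val)

    rows = []
    fractions = grid + [g.repression_fraction]
    for pi, f in enumerate(fractions):
        row = {
            "repression_fraction": f,
            "rho": cfg.rho,
            "n": cfg.n_realizations,
            "reference": pi == len(grid),
            **_provenance(cfg),
        }
        for name, vals in accum[pi].items():
            arr = np.asarray(vals)
            row[f"{name}_mean"] = arr.mean()
            row[f"{name}_sd"] = arr.std(ddof=1) if len(arr) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_task_scores(
    graph: SignedDigraph,
    cfg: ExperimentConfig,
    key: int,
    member_index: int,
    tasks: tuple[str, ...],
) -> dict:
    accum: dict[str, list[float]] = {t: [] for t in tasks}
    for r in range(cfg.n_realizations):
        seed = _realization_seed(cfg.seed, key, member_index, r)
        proto = replace(cfg.protocol, seed=seed)
        if "kstar" in tasks or "narma" in tasks:
            sys = build_reservoir(graph, rho=cfg.rho, n_inputs=1, seed=seed)
            if "kstar" in tasks:
                accum["kstar"].append(
                    critical_memory_capacity(sys, k_max=cfg.k_max, protocol=proto).score
                )
            if "narma" in tasks:
                accum["narma"].append(narma10_task(sys, proto).score)
        if "dand" in tasks:
            sys2 = build_reservoir(graph, rho=cfg.rho, n_inputs=2, seed=seed)
            proto_d = replace(proto, series_length=600)
            accum["dand"].append(delayed_and_task(sys2, proto_d).score)
    return {t: float(np.mean(v)) for t, v in accum.items()}


def motif_memory_analysis(
    library: SubReservoirLibrary,
    cfg: ExperimentConfig | None = None,
    n_null: int = 1000,
) -> pd.DataFrame:
    """Per sub-reservoir: motif census (raw and null-normalized) and mean k*."""
    if len(library) == 0:
        raise ValueError("library is empty")
    cfg = cfg or ExperimentConfig()
    rows = []
    for mi, member in enumerate(library):
        g = member.graph
        c = census(g)
        seed = _realization_seed(cfg.seed, 2, mi)
        norm = normalized_motif_counts(g, n_rand=n_null, seed=seed)
        scores = _mean_task_scores(g, cfg, 3, mi, tasks=("kstar",))
        rows.append(
            {
                "member": mi,
                "run": member.run,
                "step": member.step,
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "self_loops": c.self_loops,
                "mutual_regulation": c.mutual_regulation,
                "ffl": c.ffl,
                "self_loops_norm": norm["self_loops"],
                "mutual_regulation_norm": norm["mutual_regulation"],
                "ffl_norm": norm["ffl"],
                "kstar_mean": scores["kstar"],
                "n": cfg.n_realizations,
                **_provenance(cfg),
            }
        )
    return pd.DataFrame(rows)


def threshold_split(
    df: pd.DataFrame, motif: str, thresholds: tuple[int, ...] = (28, 55)
) -> dict[int, np.ndarray]:
    """k* distributions of sub-reservoirs with fewer than each motif-count
    threshold (the distribution-comparison view of the motif-memory data)."""
    return {
        thr: df.loc[df[motif] < thr, "kstar_mean"].to_numpy() for thr in thresholds
    }


def pareto_front(df: pd.DataFrame, minimize: tuple[str, ...], maximize: tuple[str, ...]):
    """Boolean mask of rows not dominated on the given columns."""
    cols = [(c, 1.0) for c in minimize] + [(c, -1.0) for c in maximize]
    vals = np.column_stack([sign * df[c].to_numpy(dtype=float) for c, sign in cols])
    n = len(vals)
    efficient = np.ones(n, dtype=bool)
    for i in range(n):
        if not efficient[i]:
            continue
        # rows elementwise no better than row i, and strictly worse somewhere
        dominated = np.all(vals >= vals[i], axis=1) & np.any(vals > vals[i], axis=1)
        dominated[i] = False
        efficient &= ~dominated
    return efficient


def size_performance(
    library: SubReservoirLibrary,
    cfg: ExperimentConfig | None = None,
    filter_width: float = 1.25,
) -> pd.DataFrame:
    """Per sub-reservoir size vs mean k*, NARMA NRMSE, and delayed-AND NRMSE.

    Adds per-task outlier masks (within ``filter_width`` s.d. of the library
    mean) and a Pareto-efficiency flag over (size down, k* up, errors down).
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    cfg = cfg or ExperimentConfig()
    rows = []
    for mi, member in enumerate(library):
        g = member.graph
        scores = _mean_task_scores(g, cfg, 4, mi, tasks=("kstar", "narma", "dand"))
        rows.append(
            {
                "member": mi,
                "run": member.run,
                "step": member.step,
                "n_nodes": g.n_nodes,
                "n_edges": g.n_edges,
                "kstar_mean": scores["kstar"],
                "narma_nrmse_mean": scores["narma"],
                "dand_nrmse_mean": scores["dand"],
                "n": cfg.n_realizations,
                **_provenance(cfg),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        for col, mask_col in (
            ("kstar_mean", "kstar_kept"),
            ("narma_nrmse_mean", "narma_kept"),
            ("dand_nrmse_mean", "dand_kept"),
        ):
            df[mask_col] = performance_filter(df[col].to_numpy(), width=filter_width)
    else:
        df["kstar_kept"] = df["narma_kept"] = df["dand_kept"] = True
    df["pareto"] = pareto_front(
        df,
        minimize=("n_nodes", "narma_nrmse_mean", "dand_nrmse_mean"),
        maximize=("kstar_mean",),
    )
    return df
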