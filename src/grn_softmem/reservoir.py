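"""Echo-state reservoir construction and dynamics on signed digraphs.

The recurrent core of a regulatory network is turned into a discrete-time
reservoir

    x_t = tanh(W_in u_t + W x_{t-1}),

where ``W`` carries one nonzero entry per regulatory edge — magnitude drawn
i.i.d. U(0, 1), sign set by the edge (activation +, repression -) — and is
rescaled to a prescribed spectral radius ``rho``, the global gain that drives
the order-to-chaos transition.  Input weights ``W_in`` are +/-0.05
equiprobably.  By convention ``W[i, j]`` couples presynaptic node ``j`` into
node ``i``, i.e. edge j -> i occupies entry (i, j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SignedDigraph

__all__ = [
    "INPUT_WEIGHT",
    "ReservoirSystem",
    "StateMatrix",
    "build_reservoir",
    "run_reservoir",
    "echo_state_distance",
]

#: magnitude of every input weight
INPUT_WEIGHT = 0.05


@dataclass
class ReservoirSystem:
    """Weight matrices of one reservoir realization.

    ``node_order`` maps matrix indices to node ids of the source graph; the
    zero pattern and signs of ``W`` match its edges exactly, and the spectral
    radius of ``W`` equals ``rho`` (up to floating-point normalization).
    """

    W: np.ndarray
    W_in: np.ndarray
    rho: float
    node_order: tuple = ()
    seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.W))))

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            W=self.W,
            W_in=self.W_in,
            rho=np.float64(self.rho),
            node_order=np.array([str(u) for u in self.node_order]),
            seed=np.int64(-1 if self.seed is None else self.seed),
        )

    @classmethod
    def load_npz(cls, path) -> "ReservoirSystem":
        with np.load(path) as z:
            seed = int(z["seed"])
            return cls(
                W=z["W"],
                W_in=z["W_in"],
                rho=float(z["rho"]),
                node_order=tuple(z["node_order"].tolist()),
                seed=None if seed < 0 else seed,
            )


@dataclass
class StateMatrix:
    """N x T reservoir trajectory; ``washout`` leading columns are transient."""

    X: np.ndarray
    washout: int = 0

    @property
    def trimmed(self) -> np.ndarray:
        return self.X[:, self.washout :]


def build_reservoir(
    g: SignedDigraph,
    rho: float,
    n_inputs: int = 1,
    seed: int = 0,
    input_nodes: list | None = None,
) -> ReservoirSystem:
    """Draw reservoir weights for ``g`` and normalize to spectral radius ``rho``.

    Edge magnitudes are i.i.d. U(0, 1), signed per edge; the raw matrix is
    rescaled as ``W = rho * W_raw / spectral_radius(W_raw)``.  Acyclic graphs
    have a nilpotent (zero-spectral-radius) matrix and cannot be normalized.
    ``input_nodes`` optionally restricts which nodes receive input; by
    default every node does.
    """
    if g.n_nodes == 0:
        raise ValueError("cannot build a reservoir from an empty graph")
    if rho <= 0:
        raise ValueError("rho must be positive")
    rng = np.random.default_rng(seed)
    order = g.nodes
    index = {u: i for i, u in enumerate(order)}
    n = len(order)

    edges = list(g.edges())
    mags = rng.random(len(edges))
    W_raw = np.zeros((n, n))
    for (u, v, s), mag in zip(edges, mags):
        W_raw[index[v], index[u]] = s * mag

    sr = float(np.max(np.abs(np.linalg.eigvals(W_raw)))) if edges else 0.0
    if sr < 1e-12:
        raise ValueError("cannot normalize acyclic reservoir (spectral radius 0)")
    W = (rho / sr) * W_raw

    W_in = INPUT_WEIGHT * rng.choice([-1.0, 1.0], size=(n, n_inputs))
    if input_nodes is not None:
        mask = np.zeros(n, dtype=bool)
        for u in input_nodes:
            mask[index[u]] = True
        W_in = W_in * mask[:, None]

    return ReservoirSystem(W=W, W_in=W_in, rho=float(rho), node_order=order, seed=seed)


def run_reservoir(
    sys: ReservoirSystem,
    U: np.ndarray,
    x0: np.ndarray | None = None,
    washout: int = 0,
) -> StateMatrix:
    """Iterate ``x_t = tanh(W_in u_t + W x_{t-1})`` over the columns of ``U``.

    ``U`` is N_in x T; the initial state defaults to zero.  All T states are
    returned; ``washout`` is only recorded on the result for downstream
    trimming.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[0] != sys.n_inputs:
        raise ValueError(
            f"input has {U.shape[0]} rows but reservoir expects {sys.n_inputs}"
        )
    n, T = sys.n_nodes, U.shape[1]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"x0 must have shape ({n},), got {x.shape}")
    drive = sys.W_in @ U  # precomputed input contribution, N x T
    W = sys.W
    X = np.empty((n, T))
    for t in range(T):
        x = np.tanh(drive[:, t] + W @ x)
        X[:, t] = x
    return StateMatrix(X=X, washout=washout)


def echo_state_distance(
    sys: ReservoirSystem,
    U: np.ndarray,
    x0a: np.ndarray,
    x0b: np.ndarray,
) -> np.ndarray:
    """Per-step Euclidean distance between trajectories from two initial states.

    Both trajectories receive the identical input; a decaying distance is the
    echo-state (fading-memory) property.
    """
    Xa = run_reservoir(sys, U, x0=np.asarray(x0a, dtype=float)).X
    Xb = run_reservoir(sys, U, x0=np.asarray(x0b, dtype=float)).X
    return np.linalg.norm(Xa - Xb, axis=0)
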