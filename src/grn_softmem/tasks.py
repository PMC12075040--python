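"""Benchmark tasks probing the soft memory of a reservoir.

Three tasks, each following the same protocol — 10 input/output series
(9 for ridge training, the last held out for testing), a per-series washout
of 100 steps:

* **memory capacity**: a single input u_t ~ U(-1, 1) drives the reservoir
  and a readout is trained to reproduce the k-step-delayed input.  The score
  MC_k is the squared Pearson correlation between u_{t-k} and the test-set
  output; the *critical memory capacity* k* is the largest delay with
  MC_k > 0.5.
* **NARMA-10**: reproduce the output of the 10th-order nonlinear
  autoregressive moving-average system driven by s_t ~ U(0, 0.5), scored by
  NRMSE on the held-out series.
* **delayed AND**: two pulse-train inputs; the target is I1[t-k] AND I2[t]
  (k = 6 by default), the analogue of anticipatory associative responses in
  bacteria.  The readout output is binarized at 0.5 before NRMSE scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from .readout import DEFAULT_GAMMA, nrmse, solve_ridge
from .reservoir import ReservoirSystem, run_reservoir

__all__ = [
    "TaskProtocol",
    "TaskResult",
    "memory_coefficient",
    "memory_capacity_at_k",
    "memory_capacity_profile",
    "kstar_from_profile",
    "critical_memory_capacity",
    "narma10_response",
    "narma10_series",
    "narma10_task",
    "pulse_train",
    "delayed_and_target",
    "paired_pulse_inputs",
    "delayed_and_task",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskProtocol:
    """Train/test protocol shared by all tasks.

    ``n_series`` independent series of ``series_length`` steps are generated;
    the first ``n_train`` are concatenated (after discarding ``washout``
    leading steps from each) to fit the readout and the remainder are used
    for testing.
    """

    n_series: int = 10
    series_length: int = 1000
    n_train: int = 9
    washout: int = 100
    seed: int = 0
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not self.n_train < self.n_series:
            raise ValueError("n_train must be smaller than n_series")
        if not self.series_length > self.washout:
            raise ValueError("series_length must exceed washout")


@dataclass(frozen=True)
class TaskResult:
    """Score of one task realization plus its configuration provenance."""

    score: float
    task: str
    seed: int
    params: dict = field(default_factory=dict)


def _sub_seed(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def memory_coefficient(y, target) -> float:
    """Squared Pearson correlation between output and delayed input.

    This is the per-delay memory score MC_k = cov^2 / (var * var); zero
    output variance (a degenerate readout) scores 0 with a warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if np.var(y) == 0.0 or np.var(t) == 0.0:
        warnings.warn("degenerate (zero-variance) series; MC set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(y, t)[0, 1]
    return float(r * r)


def _memory_capacities(
    sys: ReservoirSystem, ks: np.ndarray, protocol: TaskProtocol
) -> np.ndarray:
    """MC_k for each delay in ``ks``, sharing one set of reservoir runs.

    The state trajectories do not depend on the delay, so the reservoir is
    run once per series and the ridge normal matrix is factored once; only
    the delayed targets change across k.
    """
    if sys.n_inputs != 1:
        raise ValueError("memory capacity requires a single input node")
    p = protocol
    kmax = int(ks.max())
    if p.washout < kmax:
        raise ValueError(
            f"washout ({p.washout}) must cover the largest delay ({kmax})"
        )
    rng = np.random.default_rng(p.seed)
    U = rng.uniform(-1.0, 1.0, size=(p.n_series, p.series_length))
    states = [run_reservoir(sys, u[None, :]).X for u in U]

    w, T = p.washout, p.series_length
    X_tr = np.hstack([S[:, w:] for S in states[: p.n_train]])
    X_te = states[p.n_train][:, w:]
    u_te = U[p.n_train]

    mcs = np.empty(len(ks))
    targets = np.stack(
        [
            np.concatenate([U[s][w - k : T - k] for s in range(p.n_train)])
            for k in ks
        ]
    )
    W_out = solve_ridge(X_tr, targets, p.gamma)
    Y_hat = W_out @ X_te
    for i, k in enumerate(ks):
        mcs[i] = memory_coefficient(Y_hat[i], u_te[w - k : T - k])
    return mcs


def memory_capacity_at_k(
    sys: ReservoirSystem, k: int, protocol: TaskProtocol | None = None
) -> TaskResult:
    """Memory score MC_k at a single delay ``k >= 1``."""
    if k < 1:
        raise ValueError("delay k must be >= 1")
    p = protocol or TaskProtocol()
    mc = _memory_capacities(sys, np.array([k]), p)[0]
    return TaskResult(
        score=float(mc), task="memory_capacity", seed=p.seed, params={"k": k}
    )


def memory_capacity_profile(
    sys: ReservoirSystem, k_max: int = 30, protocol: TaskProtocol | None = None
) -> np.ndarray:
    """MC_k for k = 1 .. k_max (index 0 holds k=1)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    p = protocol or TaskProtocol()
    return _memory_capacities(sys, np.arange(1, k_max + 1), p)


def kstar_from_profile(
    profile: np.ndarray, threshold: float = 0.5, first_crossing: bool = False
) -> int:
    """Critical memory capacity from an MC profile (profile[0] is k=1).

    By default the *largest* delay with MC_k > threshold, even across
    non-monotone profiles; ``first_crossing`` instead stops at the last delay
    before the profile first drops to or below the threshold.
    """
    above = np.asarray(profile) > threshold
    if not above.any():
        return 0
    if first_crossing:
        below = np.flatnonzero(~above)
        return int(below[0]) if below.size else len(above)
    return int(np.flatnonzero(above)[-1] + 1)


def critical_memory_capacity(
    sys: ReservoirSystem,
    k_max: int = 30,
    protocol: TaskProtocol | None = None,
    first_crossing: bool = False,
) -> TaskResult:
    """Largest delay k <= k_max with MC_k > 0.5 (0 if none)."""
    p = protocol or TaskProtocol()
    profile = memory_capacity_profile(sys, k_max=k_max, protocol=p)
    kstar = kstar_from_profile(profile, first_crossing=first_crossing)
    return TaskResult(
        score=float(kstar),
        task="critical_memory_capacity",
        seed=p.seed,
        params={"k_max": k_max, "first_crossing": first_crossing},
    )


# ---------------------------------------------------------------------------
# NARMA-10
# ---------------------------------------------------------------------------

#: divergence guard for the NARMA-10 recursion
NARMA_DIVERGENCE_BOUND = 10.0


def narma10_response(s: np.ndarray) -> np.ndarray:
    """Output of the 10th-order NARMA system for a given input series.

    y(t+1) = 0.3 y(t) + 0.05 y(t) sum_{i=0}^{9} y(t-i) + 1.5 s(t-9) s(t) + 0.1,
    with y and s taken as 0 for t <= 0.  Raises OverflowError when |y|
    exceeds the divergence bound (the recursion is unstable for rare input
    draws).
    """
    s = np.asarray(s, dtype=float).ravel()
    T = len(s)
    y = np.zeros(T)
    running = 0.0  # sum of the last 10 outputs y(t-i), i = 0..9
    for t in range(T - 1):
        running += y[t]
        if t >= 10:
            running -= y[t - 10]
        s_lag = s[t - 9] if t >= 9 else 0.0
        y[t + 1] = 0.3 * y[t] + 0.05 * y[t] * running + 1.5 * s_lag * s[t] + 0.1
        if abs(y[t + 1]) > NARMA_DIVERGENCE_BOUND:
            raise OverflowError(f"NARMA-10 diverged at step {t + 1}")
    return y


def narma10_series(
    length: int, seed: int, max_attempts: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """An input/output pair of the NARMA-10 system, s_t ~ U(0, 0.5).

    Diverging draws (a documented instability of the recursion) are logged
    and resampled with the next sub-seed.
    """
    if length <= 10:
        raise ValueError("length must exceed the system order (10)")
    for attempt in range(max_attempts):
        rng = _sub_seed(seed, attempt)
        s = rng.uniform(0.0, 0.5, size=length)
        try:
            return s, narma10_response(s)
        except OverflowError:
            log.warning(
                "NARMA-10 series diverged (seed=%d, attempt=%d); resampling",
                seed,
                attempt,
            )
    raise RuntimeError(f"NARMA-10 diverged {max_attempts} times for seed {seed}")


def narma10_task(
    sys: ReservoirSystem, protocol: TaskProtocol | None = None
) -> TaskResult:
    """Train a readout to emulate NARMA-10 from the reservoir state; NRMSE."""
    if sys.n_inputs != 1:
        raise ValueError("the NARMA task requires a single input node")
    p = protocol or TaskProtocol()
    seeds = np.random.SeedSequence(p.seed).generate_state(p.n_series)
    series = [narma10_series(p.series_length, int(sd)) for sd in seeds]
    states = [run_reservoir(sys, s[None, :]).X for s, _ in series]

    w = p.washout
    X_tr = np.hstack([S[:, w:] for S in states[: p.n_train]])
    y_tr = np.concatenate([y[w:] for _, y in series[: p.n_train]])
    w_out = solve_ridge(X_tr, y_tr[None, :], p.gamma)

    X_te = states[p.n_train][:, w:]
    y_te = series[p.n_train][1][w:]
    score = nrmse(w_out @ X_te, y_te)
    return TaskResult(
        score=score, task="narma10", seed=p.seed, params={"gamma": p.gamma}
    )


# ---------------------------------------------------------------------------
# Delayed AND
# ---------------------------------------------------------------------------


def pulse_train(
    length: int = 600,
    pulse_duration: int = 3,
    rate: float = 0.02,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary series of unit-height pulses of fixed duration.

    Onsets follow a Bernoulli(rate) process thinned by a refractory gap of
    ``pulse_duration + 6`` steps between onsets, so pulses never overlap and
    delayed pulse pairs remain resolvable.
    """
    if pulse_duration < 1:
        raise ValueError("pulse_duration must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.zeros(length)
    draws = rng.random(length)
    next_allowed = 0
    for t in range(length - pulse_duration + 1):
        if t >= next_allowed and draws[t] < rate:
            x[t : t + pulse_duration] = 1.0
            next_allowed = t + pulse_duration + 6
    return x


def delayed_and_target(I1, I2, k: int) -> np.ndarray:
    """target[t] = I1[t - k] AND I2[t]; negative indices of I1 read as 0."""
    I1 = np.asarray(I1, dtype=float).ravel()
    I2 = np.asarray(I2, dtype=float).ravel()
    if I1.shape != I2.shape:
        raise ValueError("inputs must have equal lengths")
    if k < 0:
        raise ValueError("delay k must be >= 0")
    shifted = np.zeros_like(I1)
    if k < len(I1):
        shifted[k:] = I1[: len(I1) - k]
    return ((shifted > 0.5) & (I2 > 0.5)).astype(float)


def paired_pulse_inputs(
    length: int,
    k: int,
    rng: np.random.Generator,
    pulse_duration: int = 3,
    rate: float = 0.02,
    coincidence_prob: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two pulse trains with planted lag-k coincidences.

    I1 is a plain pulse train; I2 combines its own random pulses with pulses
    planted at lag ``k`` after a fraction ``coincidence_prob`` of I1's
    onsets, so both AND classes (coincidence and non-coincidence) occur.
    """
    I1 = pulse_train(length, pulse_duration, rate, rng=rng)
    I2 = pulse_train(length, pulse_duration, rate, rng=rng)
    refractory = pulse_duration + 6
    onsets1 = np.flatnonzero(np.diff(np.concatenate([[0.0], I1])) > 0.5)
    onsets2 = list(np.flatnonzero(np.diff(np.concatenate([[0.0], I2])) > 0.5))
    for o in onsets1:
        if rng.random() >= coincidence_prob:
            continue
        t = o + k
        if t + pulse_duration > length:
            continue
        if any(abs(t - p) < refractory for p in onsets2):
            continue
        I2[t : t + pulse_duration] = 1.0
        onsets2.append(t)
    return I1, I2


def delayed_and_task(
    sys: ReservoirSystem,
    protocol: TaskProtocol | None = None,
    k: int = 6,
    max_attempts: int = 20,
) -> TaskResult:
    """Delayed-AND classification: binarize the readout at 0.5, then NRMSE.

    Requires two input nodes.  If a drawn test series has a constant target
    (no coincidence events), the series set is resampled with the next
    sub-seed.
    """
    if sys.n_inputs != 2:
        raise ValueError("the delayed AND task requires two input nodes")
    p = protocol or TaskProtocol(series_length=600)
    for attempt in range(max_attempts):
        rng = _sub_seed(p.seed, attempt)
        pairs = [
            paired_pulse_inputs(p.series_length, k, rng) for _ in range(p.n_series)
        ]
        targets = [delayed_and_target(I1, I2, k) for I1, I2 in pairs]
        w = p.washout
        if np.var(targets[p.n_train][w:]) == 0.0 or any(
            np.var(t[w:]) == 0.0 for t in targets[: p.n_train]
        ):
            log.warning("constant delayed-AND target (attempt %d); resampling", attempt)
            continue
        states = [run_reservoir(sys, np.vstack(pair)).X for pair in pairs]
        X_tr = np.hstack([S[:, w:] for S in states[: p.n_train]])
        y_tr = np.concatenate([t[w:] for t in targets[: p.n_train]])
        w_out = solve_ridge(X_tr, y_tr[None, :], p.gamma)
        y_hat = w_out @ states[p.n_train][:, w:]
        y_bin = (y_hat > 0.5).astype(float)
        score = nrmse(y_bin, targets[p.n_train][w:])
        return TaskResult(
            score=score,
            task="delayed_and",
            seed=p.seed,
            params={"k": k, "gamma": p.gamma, "attempt": attempt},
        )
    raise RuntimeError("could not draw a non-constant delayed-AND test target")
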