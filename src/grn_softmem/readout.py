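"""Linear readout: ridge regression training, prediction, and NRMSE.

The readout is the only trained part of a reservoir computer:

    Y = W_out X,      W_out = Y_target X' (X X' + gamma^2 I)^{-1},

solved with a Cholesky factorization rather than explicit inversion.
Performance is scored with the normalized root mean squared error

    NRMSE = sqrt( <(y - y_target)^2>_t / <(y_target - <y_target>_t)^2>_t ),

where angle brackets are time averages (population variance in the
denominator): 0 is a perfect fit and 1 matches a constant mean predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .reservoir import StateMatrix

__all__ = ["DEFAULT_GAMMA", "ReadoutModel", "ridge_fit", "predict", "nrmse"]

#: default ridge regularization coefficient gamma
DEFAULT_GAMMA = 1e-6


@dataclass
class ReadoutModel:
    """Trained linear readout: ``W_out`` (N_out x N) and its ridge gamma."""

    W_out: np.ndarray
    gamma: float

    def to_json(self) -> str:
        import json

        return json.dumps({"gamma": self.gamma, "W_out": self.W_out.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ReadoutModel":
        import json

        d = json.loads(text)
        return cls(W_out=np.asarray(d["W_out"], dtype=float), gamma=float(d["gamma"]))


def _as_array(X) -> np.ndarray:
    if isinstance(X, StateMatrix):
        return X.trimmed
    return np.atleast_2d(np.asarray(X, dtype=float))


def ridge_fit(X, Y_target, gamma: float = DEFAULT_GAMMA) -> ReadoutModel:
    """Fit ``W_out = Y_target X' (X X' + gamma^2 I)^{-1}``.

    ``X`` is N x T (a :class:`StateMatrix` is trimmed of its washout first),
    ``Y_target`` is N_out x T.  With ``gamma == 0`` a rank-deficient state
    covariance raises instead of silently pseudo-inverting.
    """
    X = _as_array(X)
    Y = np.atleast_2d(np.asarray(Y_target, dtype=float))
    n, T = X.shape
    if Y.shape[1] != T:
        raise ValueError(f"X has {T} columns but Y_target has {Y.shape[1]}")
    if T < n:
        warnings.warn(
            f"fewer samples (T={T}) than reservoir nodes (N={n}); "
            "the ridge solution is underdetermined",
            stacklevel=2,
        )
    if gamma == 0.0:
        A = X @ X.T
        try:
            c, low = scipy.linalg.cho_factor(A)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular state covariance with gamma=0; use gamma > 0"
            ) from exc
        W_out = scipy.linalg.cho_solve((c, low), X @ Y.T).T
        return ReadoutModel(W_out=W_out, gamma=0.0)
    return ReadoutModel(W_out=solve_ridge(X, Y, gamma), gamma=float(gamma))


def solve_ridge(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """Ridge normal equations via Cholesky, with a least-squares fallback.

    Strongly saturated reservoirs can make ``X X' + gamma^2 I`` numerically
    indefinite when gamma is tiny relative to the state scale; the fallback
    returns the minimum-norm least-squares solution of the same system.
    """
    n = X.shape[0]
    A = X @ X.T + (gamma**2) * np.eye(n)
    B = X @ Y.T
    try:
        W_out = scipy.linalg.cho_solve(scipy.linalg.cho_factor(A), B).T
    except np.linalg.LinAlgError:
        warnings.warn(
            "state covariance numerically singular; using least-squares "
            "ridge solution",
            stacklevel=2,
        )
        W_out = np.linalg.lstsq(A, B, rcond=None)[0].T
    return np.atleast_2d(W_out)


def predict(model: ReadoutModel, X) -> np.ndarray:
    """Linear readout ``Y = W_out X`` (no output nonlinearity)."""
    X = _as_array(X)
    if X.shape[0] != model.W_out.shape[1]:
        raise ValueError(
            f"X has {X.shape[0]} rows but W_out expects {model.W_out.shape[1]}"
        )
    return model.W_out @ X


def nrmse(y, y_target) -> float:
    """Root mean squared error normalized by the target's (population) s.d."""
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(y_target, dtype=float).ravel()
    if y.shape != t.shape:
        raise ValueError("y and y_target must have equal lengths")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    var = float(np.mean((t - t.mean()) ** 2))
    if var == 0.0:
        raise ValueError("y_target is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((y - t) ** 2) / var))
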