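"""Functional connectivity inference by lagged least squares.

Discretizing the linear network dynamics at the frame interval gives the
lag-1 autoregression

    V_i(t + dt) = sum_j T_ij V_j(t) + V_i_ext,

which is fitted per neuron by ordinary least squares with intercept: the
coefficients fill row i of the coupling matrix T (incoming weights) and
the intercept is the constant external drive.  The model is trained on the
first 75% of frames (contiguous temporal split) and evaluated on the rest
with the grand-mean squared prediction error.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .io import TraceSet

__all__ = [
    "FunctionalConnectivity",
    "build_lagged_design",
    "fit_connectivity",
    "min_data_requirement",
    "connection_sign_counts",
    "delta_connectivity",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FunctionalConnectivity:
    """Inferred coupling matrix plus external drive and fit diagnostics.

    ``T[i, j]`` is the weight of the signal neuron j sends to neuron i;
    positive entries are functional-excitatory, negative
    functional-inhibitory.
    """

    T: np.ndarray
    v_ext: np.ndarray
    train_error: float
    test_error: float
    threshold_used: float = float("nan")
    train_frac: float = 0.75
    dt: float = 0.1
    per_neuron_train_error: np.ndarray | None = None
    per_neuron_test_error: np.ndarray | None = None
    neuron_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.v_ext = np.asarray(self.v_ext, dtype=float).ravel()
        n = self.T.shape[0]
        if self.T.shape != (n, n):
            raise ValueError("T must be square")
        if self.v_ext.shape != (n,):
            raise ValueError("v_ext length must match T")
        if not np.all(np.isfinite(self.T)):
            raise ValueError("T must be finite")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(n))

    @property
    def n_neurons(self) -> int:
        return self.T.shape[0]

    def to_dict(self) -> dict:
        return {
            "T": self.T.tolist(),
            "v_ext": self.v_ext.tolist(),
            "train_error": self.train_error,
            "test_error": self.test_error,
            "threshold_used": self.threshold_used,
            "train_frac": self.train_frac,
            "dt": self.dt,
            "neuron_ids": list(self.neuron_ids),
        }


def build_lagged_design(traces: TraceSet) -> tuple[np.ndarray, np.ndarray]:
    """Predictor/response pair for the lag-1 regression.

    Row t of X is the population vector V(t); row t of Y is V(t + dt).
    Time order ascending.
    """
    if traces.n_frames < 2:
        raise ValueError("need at least 2 frames")
    V = traces.values
    return V[:, :-1].T.copy(), V[:, 1:].T.copy()


def _stack_designs(traces: TraceSet | Sequence[TraceSet]) -> tuple[np.ndarray, np.ndarray, float]:
    if isinstance(traces, TraceSet):
        traces = [traces]
    if len(traces) == 0:
        raise ValueError("no trace sets supplied")
    n = traces[0].n_neurons
    dt = traces[0].dt
    Xs, Ys = [], []
    for ts in traces:
        if ts.n_neurons != n:
            raise ValueError("all trace sets must share the neuron count")
        X, Y = build_lagged_design(ts)
        Xs.append(X)
        Ys.append(Y)
    return np.vstack(Xs), np.vstack(Ys), dt


def solve_lagged_ols(X: np.ndarray, Y: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares solve for (T, v_ext) given stacked design rows.

    Rank-deficient designs (including all-zero traces) fall through to the
    minimum-norm pseudo-inverse solution with a logged warning.
    """
    rows, n = X.shape
    A = np.hstack([X, np.ones((rows, 1))])
    if ridge > 0:
        reg = np.sqrt(ridge) * np.eye(n + 1)
        reg[-1, -1] = 0.0  # do not penalize the intercept
        A = np.vstack([A, reg])
        Y = np.vstack([Y, np.zeros((n + 1, Y.shape[1]))])
    coef, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < n + 1:
        logger.warning(
            "lagged design is rank-deficient (rank %d < %d); using minimum-norm solution",
            rank,
            n + 1,
        )
    return coef[:n].T, coef[n]


def fit_connectivity(
    traces: TraceSet | Sequence[TraceSet],
    train_frac: float = 0.75,
    *,
    ridge: float = 0.0,
    threshold_used: float = float("nan"),
) -> FunctionalConnectivity:
    """Per-neuron lagged OLS estimate of (T, v_ext) with train/test split.

    Accepts a single TraceSet or a sequence of sessions of the same
    network; sessions are lag-stacked independently (no spurious pair
    across a session boundary).  The temporal split takes the first
    ``train_frac`` of stacked rows for training.
    """
    if not 0 < train_frac <= 1:
        raise ValueError("train_frac must be in (0, 1]")
    X, Y, dt = _stack_designs(traces)
    rows = X.shape[0]
    n_train = max(1, int(round(train_frac * rows)))
    T, v_ext = solve_lagged_ols(X[:n_train], Y[:n_train], ridge=ridge)

    def _errors(Xp: np.ndarray, Yp: np.ndarray) -> tuple[float, np.ndarray]:
        if Xp.shape[0] == 0:
            return float("nan"), np.full(X.shape[1], np.nan)
        resid = Xp @ T.T + v_ext - Yp
        per_neuron = (resid**2).mean(axis=0)
        return float((resid**2).mean()), per_neuron

    train_error, per_train = _errors(X[:n_train], Y[:n_train])
    test_error, per_test = _errors(X[n_train:], Y[n_train:])
    return FunctionalConnectivity(
        T=T,
        v_ext=v_ext,
        train_error=train_error,
        test_error=test_error,
        threshold_used=threshold_used,
        train_frac=train_frac,
        dt=dt,
        per_neuron_train_error=per_train,
        per_neuron_test_error=per_test,
    )


def min_data_requirement(n_neurons: int, dt: float) -> tuple[int, float]:
    """Unknown count and minimum recording duration for identifiability.

    Counts the unique entries of a symmetric coupling matrix,
    n(n+1)/2, plus the n external drives; the minimum duration is one
    frame per unknown.  (The fitted matrix itself is unconstrained and
    asymmetric; this arithmetic is the conventional lower bound.)
    """
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_unknowns = n_neurons * (n_neurons + 1) // 2 + n_neurons
    return n_unknowns, n_unknowns * dt


def connection_sign_counts(fc: FunctionalConnectivity | np.ndarray) -> tuple[int, int, float]:
    """Counts of positive/negative off-diagonal couplings and their ratio."""
    T = fc.T if isinstance(fc, FunctionalConnectivity) else np.asarray(fc, dtype=float)
    off = T[~np.eye(T.shape[0], dtype=bool)]
    n_pos = int((off > 0).sum())
    n_neg = int((off < 0).sum())
    ratio = n_pos / n_neg if n_neg else float("inf")
    return n_pos, n_neg, ratio


def delta_connectivity(
    fc_before: FunctionalConnectivity,
    fc_after: FunctionalConnectivity,
    bins: int | np.ndarray = 50,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Coupling change T_after - T_before and its off-diagonal histogram."""
    if fc_before.T.shape != fc_after.T.shape:
        raise ValueError("connectivity matrices must have matching dimensions")
    delta = fc_after.T - fc_before.T
    off = delta[~np.eye(delta.shape[0], dtype=bool)]
    counts, edges = np.histogram(off, bins=bins)
    return delta, (counts, edges)
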