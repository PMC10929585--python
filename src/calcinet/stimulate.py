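"""Forecasting the network response to external current protocols.

With the coupling matrix estimated, the response to an arbitrary external
current is obtained by unrolling the lag-1 recursion

    V(n dt) = T^n V(0) + sum_{k=0}^{n-1} T^k V_ext((n-k-1) dt),

with the diagonal of T zeroed (a neuron's self-term is excluded when
forecasting).  The implementation steps the recursion (O(N^2) per step);
the explicit matrix-power form above is its closed-form equivalent.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import FunctionalConnectivity
from .io import TraceSet

__all__ = [
    "StimulusProtocol",
    "ramp_then_cutoff",
    "pulse",
    "forecast_response",
    "decay_profile",
]


@dataclasses.dataclass
class StimulusProtocol:
    """External current per neuron per step, in trace units."""

    ext_current: np.ndarray  # (n_neurons, n_steps)
    dt: float = 0.1

    def __post_init__(self) -> None:
        self.ext_current = np.atleast_2d(np.asarray(self.ext_current, dtype=float))
        if not np.all(np.isfinite(self.ext_current)):
            raise ValueError("stimulus must be finite")
        if self.ext_current.shape[1] < 1:
            raise ValueError("protocol needs at least one step")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return self.ext_current.shape[1]


def ramp_then_cutoff(
    n_neurons: int,
    n_steps: int,
    t_off: int,
    amplitude: float = 1.0,
    dt: float = 0.1,
) -> StimulusProtocol:
    """Linearly increasing common input that drops to zero at step t_off."""
    if not 0 < t_off <= n_steps:
        raise ValueError("t_off must lie within the protocol")
    current = np.zeros((n_neurons, n_steps))
    ramp = amplitude * np.arange(1, t_off + 1) / t_off
    current[:, :t_off] = ramp[None, :]
    return StimulusProtocol(ext_current=current, dt=dt)


def pulse(
    n_neurons: int,
    n_steps: int,
    onset: int,
    duration: int,
    amplitude: float = 1.0,
    targets: np.ndarray | None = None,
    dt: float = 0.1,
) -> StimulusProtocol:
    """Rectangular pulse delivered to ``targets`` (default: all neurons)."""
    if onset < 0 or onset + duration > n_steps:
        raise ValueError("pulse must fit inside the protocol")
    current = np.zeros((n_neurons, n_steps))
    sel = slice(None) if targets is None else np.asarray(targets, dtype=int)
    current[sel, onset : onset + duration] = amplitude
    return StimulusProtocol(ext_current=current, dt=dt)


def forecast_response(
    fc: FunctionalConnectivity | np.ndarray,
    v0: np.ndarray,
    protocol: StimulusProtocol,
    n_steps: int | None = None,
) -> np.ndarray:
    """Trajectory of shape (N, n_steps+1); column 0 is the initial state.

    Step k applies ``V <- T0 V + V_ext(k)`` with T0 the coupling matrix
    with its diagonal zeroed.
    """
    T = fc.T if isinstance(fc, FunctionalConnectivity) else np.asarray(fc, dtype=float)
    T0 = T.copy()
    np.fill_diagonal(T0, 0.0)
    n = T0.shape[0]
    v0 = np.asarray(v0, dtype=float).ravel()
    if v0.shape != (n,):
        raise ValueError(f"v0 must have shape ({n},)")
    if protocol.ext_current.shape[0] != n:
        raise ValueError("protocol neuron count must match the network")
    if n_steps is None:
        n_steps = protocol.n_steps
    if n_steps > protocol.n_steps:
        raise ValueError("n_steps exceeds the protocol length")
    traj = np.empty((n, n_steps + 1))
    traj[:, 0] = v0
    for k in range(n_steps):
        traj[:, k + 1] = T0 @ traj[:, k] + protocol.ext_current[:, k]
    return traj


def decay_profile(trajectory: np.ndarray, t_off: int) -> np.ndarray:
    """Per-neuron effective decay rate after the stimulus turns off.

    Least-squares slope of log V over the steps from ``t_off`` on; NaN for
    neurons whose post-cutoff trajectory is not strictly positive (decay
    undefined on the log scale).
    """
    trajectory = np.asarray(trajectory, dtype=float)
    n, cols = trajectory.shape
    if not 0 <= t_off < cols - 1:
        raise ValueError("t_off out of range")
    tail = trajectory[:, t_off:]
    steps = np.arange(tail.shape[1], dtype=float)
    rates = np.full(n, np.nan)
    for i in range(n):
        y = tail[i]
        if np.all(y > 0):
            slope = np.polyfit(steps, np.log(y), 1)[0]
            rates[i] = slope
    return rates
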