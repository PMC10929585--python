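"""Synthetic ground truth: networks, trace simulation, and landscape sampling.

Every downstream stage of the pipeline is validated against data generated
here, where the generating parameters are known exactly.

The generative model mirrors the linearized Hopfield picture: recorded
("feature") neurons are coupled through hidden neurons by a synaptic matrix
``xi`` of shape (n_feature, n_hidden); eliminating the fast hidden dynamics
leaves a symmetric effective coupling ``T = xi @ xi.T`` among the recorded
neurons, whose rank cannot exceed the number of hidden units.  Discretized
at the frame interval, the free dynamics are the lag-1 linear recursion

    V(t + dt) = T V(t) + V_ext + noise,

with an additive Gaussian noise floor and (optionally) clipping at zero to
mimic non-negative dF/F.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import trapezoid

from .io import TraceSet
from .landscape import ActivitySeries

__all__ = [
    "GroundTruthNetwork",
    "make_ground_truth_network",
    "simulate_linear_dynamics",
    "simulate_sessions",
    "simulate_rc_cycle",
    "sample_landscape_activity",
]


@dataclasses.dataclass
class GroundTruthNetwork:
    """A known coupling structure used to generate synthetic recordings.

    ``T_true = xi @ xi.T`` holds exactly (symmetric, rank <= n_hidden);
    ``v_ext_true`` is the constant external drive, chosen so that the
    noise-free fixed point of the dynamics is strictly positive.
    """

    xi: np.ndarray
    T_true: np.ndarray
    v_ext_true: np.ndarray
    noise_sd: float
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.T_true.shape[0]

    @property
    def fixed_point(self) -> np.ndarray:
        """Noise-free stationary state ``(I - T)^-1 v_ext``."""
        n = self.n_neurons
        return np.linalg.solve(np.eye(n) - self.T_true, self.v_ext_true)

    def to_dict(self) -> dict:
        return {
            "xi": self.xi.tolist(),
            "T_true": self.T_true.tolist(),
            "v_ext_true": self.v_ext_true.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthNetwork":
        return cls(
            xi=np.asarray(d["xi"], dtype=float),
            T_true=np.asarray(d["T_true"], dtype=float),
            v_ext_true=np.asarray(d["v_ext_true"], dtype=float),
            noise_sd=float(d["noise_sd"]),
            seed=int(d["seed"]),
        )


def _positive_fraction(base: np.ndarray, shift: float) -> float:
    xi = base + shift
    T = xi @ xi.T
    off = T[~np.eye(T.shape[0], dtype=bool)]
    return float((off > 0).mean())


def make_ground_truth_network(
    n_feature: int,
    n_hidden: int,
    ei_target: float = 2.0,
    scale: float = 1.0,
    seed: int = 0,
    *,
    stable: bool = True,
    spectral_radius: float = 0.9,
    noise_sd: float = 0.0,
    baseline_range: tuple[float, float] = (0.5, 1.5),
) -> GroundTruthNetwork:
    """Draw a low-rank symmetric coupling with a target sign ratio.

    ``xi`` entries are Gaussian with a common positive shift; the shift is
    tuned by bisection so that the fraction of positive off-diagonal
    couplings approximates ``ei_target : 1`` (positive : negative), the
    roughly 2:1 excess of functional-excitatory couplings seen in cortical
    recordings.  When ``stable``, ``T`` (and ``xi`` with it, preserving
    ``T = xi xi^T``) is rescaled so that both the full matrix and its
    off-diagonal-zeroed version have spectral radius ``spectral_radius`` at
    most, guaranteeing decaying free dynamics whether or not the diagonal
    is retained.
    """
    if n_feature < 2 or n_hidden < 1:
        raise ValueError("need n_feature >= 2 and n_hidden >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not 0 < ei_target < np.inf:
        raise ValueError("ei_target must be a positive finite ratio")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, scale, size=(n_feature, n_hidden))

    # bisection on the common shift: positive fraction is monotone in it
    target_frac = ei_target / (1.0 + ei_target)
    lo, hi = 0.0, 5.0 * scale
    while _positive_fraction(base, hi) < target_frac:
        hi *= 2.0
        if hi > 1e3 * scale:  # pragma: no cover - pathological draw
            break
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _positive_fraction(base, mid) < target_frac:
            lo = mid
        else:
            hi = mid
    xi = base + 0.5 * (lo + hi)
    T = xi @ xi.T

    if stable:
        off = T.copy()
        np.fill_diagonal(off, 0.0)
        radius = max(
            np.abs(np.linalg.eigvals(T)).max(),
            np.abs(np.linalg.eigvals(off)).max(),
        )
        if radius > 0:
            factor = spectral_radius / radius
            T = T * factor
            xi = xi * np.sqrt(factor)

    baseline = rng.uniform(*baseline_range, size=n_feature)
    v_ext = (np.eye(n_feature) - T) @ baseline
    return GroundTruthNetwork(xi=xi, T_true=T, v_ext_true=v_ext, noise_sd=noise_sd, seed=seed)


def simulate_linear_dynamics(
    net: GroundTruthNetwork,
    n_frames: int,
    v0: np.ndarray | None = None,
    dt: float = 0.1,
    seed: int = 0,
    *,
    clip: bool = True,
    condition: str = "synthetic",
) -> TraceSet:
    """Iterate ``V(t+dt) = T V(t) + V_ext + eps(t)`` for ``n_frames`` frames.

    ``eps`` is iid Gaussian with sd ``net.noise_sd``; values are clipped at
    zero by default to mimic the non-negative dF/F signal (disable with
    ``clip=False`` when an exactly linear trajectory is wanted).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    n = net.n_neurons
    if v0 is None:
        v0 = net.fixed_point
    v0 = np.asarray(v0, dtype=float)
    if v0.shape != (n,):
        raise ValueError(f"v0 must have shape ({n},)")
    rng = np.random.default_rng(seed)
    V = np.empty((n, n_frames))
    V[:, 0] = np.maximum(v0, 0.0) if clip else v0
    for t in range(1, n_frames):
        v = net.T_true @ V[:, t - 1] + net.v_ext_true
        if net.noise_sd > 0:
            v = v + rng.normal(0.0, net.noise_sd, size=n)
        if clip:
            v = np.maximum(v, 0.0)
        V[:, t] = v
    return TraceSet(values=V, dt=dt, condition=condition)


def simulate_sessions(
    net: GroundTruthNetwork,
    n_sessions: int,
    frames_per_session: int,
    dt: float = 0.1,
    seed: int = 0,
    *,
    v0_jitter: float = 0.4,
    clip: bool = True,
) -> list[TraceSet]:
    """Simulate several independent recording sessions of the same network.

    Each session restarts from the fixed point plus a uniform jitter.  A
    stable autonomous linear system excites, from a single start, only the
    Krylov subspace of its initial deviation and then settles; restarts are
    what make the coupling matrix identifiable from noise-free data.
    """
    rng = np.random.default_rng(seed)
    fp = net.fixed_point
    sessions = []
    for k in range(n_sessions):
        v0 = fp + rng.uniform(-v0_jitter, v0_jitter, size=net.n_neurons)
        sessions.append(
            simulate_linear_dynamics(
                net,
                frames_per_session,
                v0=v0,
                dt=dt,
                seed=int(rng.integers(2**31 - 1)),
                clip=clip,
            )
        )
    return sessions


def simulate_rc_cycle(
    v_b: float,
    tau: float,
    t_switch: float,
    dt: float,
    n_cycles: int = 1,
    t_discharge: float | None = None,
) -> TraceSet:
    """Single-neuron charge/discharge trace of the RC circuit analogy.

    During charging the membrane follows ``v_b * (1 - exp(-t/tau))``; at
    ``t = t_switch`` the battery disconnects and the stored level decays as
    a continuous offset exponential ``V(T) * exp(-(t-T)/tau)``.  The cycle
    repeats ``n_cycles`` times.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 < dt < t_switch:
        raise ValueError("need 0 < dt < t_switch")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    if t_discharge is None:
        t_discharge = t_switch
    t_charge = np.arange(0.0, t_switch, dt)
    charge = v_b * (1.0 - np.exp(-t_charge / tau))
    v_top = v_b * (1.0 - np.exp(-t_switch / tau))
    t_dis = np.arange(0.0, t_discharge, dt)
    discharge = v_top * np.exp(-t_dis / tau)
    cycle = np.concatenate([charge, discharge])
    values = np.tile(cycle, n_cycles)[None, :]
    return TraceSet(values=values, dt=dt, condition="synthetic", neuron_ids=[0])


def sample_landscape_activity(
    c: np.ndarray,
    mu: float,
    sigma: float,
    n_samples: int,
    support: tuple[float, float] = (-2.7, 2.7),
    seed: int = 0,
    *,
    dt: float = 0.1,
    grid_points: int = 100_000,
    condition: str = "synthetic",
) -> ActivitySeries:
    """Draw mean-activity samples from a quartic Boltzmann density.

    The scaled variable m' is distributed with density proportional to
    ``exp(-sum_j c_j m'^j)`` truncated to ``support``; sampling is by
    inverse CDF on a dense grid.  The returned series is the unscaled
    ``m = mu + sigma * m'``.
    """
    c = np.asarray(c, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo, hi = support
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("support must be a finite interval")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    grid = np.linspace(lo, hi, grid_points)
    with np.errstate(over="ignore", invalid="ignore"):
        energy = np.polynomial.polynomial.polyval(grid, c)
        energy = energy - energy.min()  # normalization-safe shift
        density = np.exp(-energy)
        total = trapezoid(density, grid)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("density is numerically zero everywhere on the support")
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n_samples)
    m_prime = np.interp(u, cdf, grid)
    return ActivitySeries(m=mu + sigma * m_prime, dt=dt, condition=condition)
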