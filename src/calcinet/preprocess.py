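"""Background-noise thresholding, threshold selection, and binarization.

Relative calcium intensities below a threshold are treated as background
and set to zero.  The threshold is chosen by a sensitivity sweep: for each
candidate threshold, fit the lagged regression on a random 70% subset of
time points and score how much the fitted coefficients and intercepts move
between consecutive thresholds; the chosen threshold is the smallest one
beyond which the model is stable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import build_lagged_design, solve_lagged_ols
from .io import TraceSet

__all__ = [
    "SensitivityReport",
    "apply_threshold",
    "threshold_sensitivity",
    "select_threshold",
    "binarize",
    "DEFAULT_THRESHOLDS",
]

# the conventional sweep range for dF/F percent-style intensities
DEFAULT_THRESHOLDS = np.arange(0.0, 21.0)


class NoStableThresholdError(RuntimeError):
    """No candidate threshold satisfies the stability tolerance."""


@dataclasses.dataclass
class SensitivityReport:
    """Per-threshold regression parameters and consecutive-pair instability.

    ``instability[k]`` compares thresholds k and k+1:
    ||theta_{k+1} - theta_k||_F / (||theta_k||_F + eps) with theta the
    stacked (coefficients, intercepts).
    """

    thresholds: np.ndarray
    coefficients: list[np.ndarray]
    intercepts: list[np.ndarray]
    instability: np.ndarray
    subset_frac: float = 0.7
    seed: int = 0
    chosen_threshold: float | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.instability = np.asarray(self.instability, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if len(self.coefficients) != self.thresholds.size:
            raise ValueError("one coefficient record per threshold required")
        if self.instability.size != max(self.thresholds.size - 1, 0):
            raise ValueError("instability scores are defined for consecutive pairs only")

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "instability": self.instability.tolist(),
            "subset_frac": self.subset_frac,
            "seed": self.seed,
            "chosen_threshold": self.chosen_threshold,
        }


def apply_threshold(traces: TraceSet, threshold: float) -> TraceSet:
    """Zero out values strictly below the threshold (>= survives)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = np.where(traces.values < threshold, 0.0, traces.values)
    return traces.copy(values=values)


def binarize(traces: TraceSet, threshold: float) -> np.ndarray:
    """1 where the trace is at or above threshold, else 0."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return (traces.values >= threshold).astype(np.int8)


def threshold_sensitivity(
    traces: TraceSet,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    subset_frac: float = 0.7,
    seed: int = 0,
) -> SensitivityReport:
    """Sweep thresholds and measure regression-parameter instability.

    For each threshold the traces are thresholded, a seeded random
    ``subset_frac`` of lagged time points is drawn, and the lag-1
    regression is fitted; consecutive fits are compared by relative
    Frobenius-norm change of the stacked parameters.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("need at least one threshold")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if not 0 < subset_frac <= 1:
        raise ValueError("subset_frac must be in (0, 1]")

    rng = np.random.default_rng(seed)
    X, Y = build_lagged_design(traces)  # thresholding commutes with lagging
    rows, n = X.shape
    n_sub = max(1, int(round(subset_frac * rows)))
    if n_sub < n + 1:
        raise ValueError(
            f"under-determined fit: {n_sub} subset rows for {n + 1} unknowns per neuron"
        )

    # one subset for the whole sweep: consecutive fits are then paired, and
    # thresholds that leave the data unchanged score exactly zero
    idx = np.sort(rng.choice(rows, size=n_sub, replace=False))
    coefficients: list[np.ndarray] = []
    intercepts: list[np.ndarray] = []
    for thr in thresholds:
        Xt = np.where(X < thr, 0.0, X)
        Yt = np.where(Y < thr, 0.0, Y)
        T, v = solve_lagged_ols(Xt[idx], Yt[idx])
        coefficients.append(T)
        intercepts.append(v)

    eps = 1e-12
    instability = np.empty(max(thresholds.size - 1, 0))
    for k in range(instability.size):
        theta_k = np.concatenate([coefficients[k].ravel(), intercepts[k]])
        theta_n = np.concatenate([coefficients[k + 1].ravel(), intercepts[k + 1]])
        instability[k] = np.linalg.norm(theta_n - theta_k) / (np.linalg.norm(theta_k) + eps)

    return SensitivityReport(
        thresholds=thresholds,
        coefficients=coefficients,
        intercepts=intercepts,
        instability=instability,
        subset_frac=subset_frac,
        seed=seed,
    )


def select_threshold(report: SensitivityReport, tol: float = 0.05) -> float:
    """Smallest threshold beyond which all instability scores stay below tol."""
    if report.thresholds.size < 2:
        raise ValueError("need at least 2 thresholds to select from")
    scores = report.instability
    for i in range(scores.size):
        if np.all(scores[i:] < tol):
            chosen = float(report.thresholds[i])
            report.chosen_threshold = chosen
            return chosen
    raise NoStableThresholdError(
        f"no threshold keeps all subsequent instability scores below {tol}"
    )
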