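"""Energy landscape of mean population activity.

The order parameter is m(t), the mean of the binarized per-neuron activity
at each frame.  Interpreting the stationary distribution p(m) as a
Boltzmann weight with unit effective temperature, the energy functional is
E[m] = -log p(m).  The estimation pipeline is:

1. standardize m (Eq.-style z-scoring with the population sd),
2. Gaussian kernel density estimate of the standardized variable on a
   dense grid spanning [-2.7, 2.7] (one million bins by default),
3. weighted least-squares fit of a quartic polynomial
   sum_j c_j m'^j to -log p-hat on the grid,
4. binomial back-transformation to the unscaled coefficients a_j,
5. stability classification: the state is stable iff E has an interior
   local minimum over the observed activity range.

The fit is weighted by the estimated density by default: the quartic is a
local expansion around the data, and unweighted regression over the full
grid would be dominated by the -log of underflowing tail densities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ActivitySeries",
    "EnergyLandscape",
    "StabilityVerdict",
    "mean_activity",
    "standardize",
    "estimate_neg_log_density",
    "fit_energy_polynomial",
    "unscale_coefficients",
    "rescale_coefficients",
    "classify_stability",
    "estimate_landscape",
]

DEFAULT_SUPPORT = (-2.7, 2.7)
DEFAULT_BINS = 1_000_000
_DENSITY_FLOOR = 1e-300


@dataclasses.dataclass
class ActivitySeries:
    """Time series of mean activity m(t).

    When produced by :func:`mean_activity` the values lie in [0, 1]
    (fraction of simultaneously active neurons); the synthetic landscape
    sampler reuses the container for scaled variables without that bound.
    """

    m: np.ndarray
    dt: float = 0.1
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        if not np.all(np.isfinite(self.m)):
            raise ValueError("activity values must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.m.size


@dataclasses.dataclass
class StabilityVerdict:
    """Outcome of the interior-minimum test on E[m]."""

    stable: bool
    minimum: float | None = None  # location of the interior minimum (scaled units)
    drift_direction: int | None = None  # -1 / +1: downhill direction when unstable

    @property
    def label(self) -> str:
        return "stable" if self.stable else "unstable"


@dataclasses.dataclass
class EnergyLandscape:
    """Quartic energy estimate in scaled (c) and unscaled (a) coordinates."""

    mu_m: float
    sigma_m: float
    c: np.ndarray  # c_0..c_4, scaled space
    a: np.ndarray  # a_0..a_4, unscaled m space
    grid_lo: float = DEFAULT_SUPPORT[0]
    grid_hi: float = DEFAULT_SUPPORT[1]
    n_bins: int = DEFAULT_BINS
    stability: StabilityVerdict | None = None
    condition: str = "synthetic"

    def energy(self, m: np.ndarray) -> np.ndarray:
        """Evaluate E at unscaled activity values."""
        return np.polynomial.polynomial.polyval(np.asarray(m, dtype=float), self.a)

    def to_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "mu_m": self.mu_m,
            "sigma_m": self.sigma_m,
            "c": list(map(float, self.c)),
            "a": list(map(float, self.a)),
            "grid": {"lo": self.grid_lo, "hi": self.grid_hi, "n_bins": self.n_bins},
        }
        if self.stability is not None:
            d["stability"] = {
                "verdict": self.stability.label,
                "minimum": self.stability.minimum,
                "drift_direction": self.stability.drift_direction,
            }
        return d


def mean_activity(binary: np.ndarray, dt: float = 0.1, condition: str = "synthetic") -> ActivitySeries:
    """Mean-field order parameter: fraction of active neurons per frame."""
    binary = np.asarray(binary)
    if binary.ndim != 2:
        raise ValueError("binary must be a 2-D (neurons x frames) matrix")
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("input must be binary (0/1)")
    return ActivitySeries(m=binary.mean(axis=0), dt=dt, condition=condition)


def standardize(series: ActivitySeries) -> tuple[np.ndarray, float, float]:
    """Z-score the activity with the population (1/n) standard deviation."""
    m = series.m
    if m.size < 2:
        raise ValueError("need at least 2 frames to standardize")
    mu = float(m.mean())
    sigma = float(m.std())
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("degenerate series: zero variance")
    return (m - mu) / sigma, mu, sigma


def _scott_bandwidth(x: np.ndarray) -> float:
    return float(x.std(ddof=1) * x.size ** (-0.2))


def estimate_neg_log_density(
    m_prime: np.ndarray,
    support: tuple[float, float] = DEFAULT_SUPPORT,
    n_bins: int = DEFAULT_BINS,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-KDE estimate of -log p on a dense regular grid.

    Returns ``(grid, neg_log_p, density)``.  The kernel sum is evaluated by
    binned convolution (linear histogram + FFT convolution with the
    Gaussian kernel), which makes the million-bin grid tractable; the
    density is floored at 1e-300 before the log.  Bandwidth defaults to
    Scott's rule.
    """
    m_prime = np.asarray(m_prime, dtype=float).ravel()
    if m_prime.size == 0:
        raise ValueError("empty sample")
    if m_prime.size < 30:
        raise ValueError("need at least 30 samples for a usable density estimate")
    lo, hi = support
    if not lo < hi:
        raise ValueError("support must be a nonempty interval")
    if bandwidth is None:
        bandwidth = _scott_bandwidth(m_prime)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    edges = np.linspace(lo, hi, n_bins + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    dx = edges[1] - edges[0]
    hist, _ = np.histogram(m_prime, bins=edges)
    half = int(np.ceil(6.0 * bandwidth / dx))
    kx = np.arange(-half, half + 1) * dx
    kernel = np.exp(-0.5 * (kx / bandwidth) ** 2) / (bandwidth * np.sqrt(2.0 * np.pi))
    density = fftconvolve(hist / m_prime.size, kernel, mode="same")
    density = np.maximum(density, 0.0)
    neg_log_p = -np.log(np.maximum(density, _DENSITY_FLOOR))
    return grid, neg_log_p, density


def fit_energy_polynomial(
    grid: np.ndarray,
    neg_log_p: np.ndarray,
    degree: int = 4,
    weight_mode: str = "density",
) -> np.ndarray:
    """Weighted LS fit of ``sum_j c_j m'^j`` to -log p-hat on the grid.

    ``weight_mode="density"`` weights each grid point by p-hat (recovered
    as exp(-neg_log_p)), confining the fit to where data exist;
    ``weight_mode="none"`` is the literal unweighted regression.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    neg_log_p = np.asarray(neg_log_p, dtype=float).ravel()
    if grid.shape != neg_log_p.shape:
        raise ValueError("grid and values must be aligned")
    if grid.size < degree + 1:
        raise ValueError("need at least degree+1 grid points")
    if weight_mode == "density":
        w = np.exp(-neg_log_p)
    elif weight_mode == "none":
        w = np.ones_like(grid)
    else:
        raise ValueError("weight_mode must be 'density' or 'none'")
    sw = np.sqrt(w)
    V = np.vander(grid, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V * sw[:, None], neg_log_p * sw, rcond=None)
    return coef


def unscale_coefficients(c: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Expand sum_j c_j ((m - mu)/sigma)^j into powers of m."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    c = np.asarray(c, dtype=float)
    # compose with the affine map m' = (m - mu)/sigma
    inner = np.polynomial.Polynomial([-mu / sigma, 1.0 / sigma])
    composed = np.polynomial.Polynomial(c)(inner)
    a = composed.coef
    if a.size < c.size:  # trailing zeros trimmed by composition
        a = np.pad(a, (0, c.size - a.size))
    return a


def rescale_coefficients(a: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Inverse of :func:`unscale_coefficients` (m = mu + sigma * m')."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.asarray(a, dtype=float)
    inner = np.polynomial.Polynomial([mu, sigma])
    composed = np.polynomial.Polynomial(a)(inner)
    c = composed.coef
    if c.size < a.size:
        c = np.pad(c, (0, a.size - c.size))
    return c


def classify_stability(
    coeffs: np.ndarray,
    domain: tuple[float, float],
) -> StabilityVerdict:
    """Stable iff E(m) = sum_j coeffs_j m^j has an interior local minimum.

    Minima are roots of E' with E'' > 0 strictly inside ``domain``.  When
    none exists the verdict is unstable, with the downhill drift direction
    given by the sign pointing toward the lower-energy domain edge.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("coefficients must be finite")
    lo, hi = domain
    if not lo < hi:
        raise ValueError("domain must be a nonempty interval")
    poly = np.polynomial.Polynomial(coeffs)
    deriv = poly.deriv()
    second = deriv.deriv()
    eps = 1e-9 * (hi - lo)
    minima = []
    if np.any(np.abs(deriv.coef[1:]) > 0) or deriv.coef.size > 1:
        roots = deriv.roots() if deriv.degree() >= 1 else np.array([])
        for r in roots:
            if abs(r.imag) > 1e-8:
                continue
            x = float(r.real)
            if lo + eps < x < hi - eps and second(x) > 0:
                minima.append(x)
    if minima:
        # report the deepest interior minimum
        best = min(minima, key=poly)
        return StabilityVerdict(stable=True, minimum=best)
    drift = 1 if poly(hi) < poly(lo) else -1
    return StabilityVerdict(stable=False, minimum=None, drift_direction=drift)


def estimate_landscape(
    series: ActivitySeries,
    support: tuple[float, float] = DEFAULT_SUPPORT,
    n_bins: int = DEFAULT_BINS,
    bandwidth: float | None = None,
    weight_mode: str = "density",
    degree: int = 4,
) -> EnergyLandscape:
    """Full landscape pipeline: standardize -> KDE -> quartic fit -> classify.

    The stability verdict is evaluated in the scaled coordinate over the
    observed data range (clipped to the grid support), the domain where
    the density estimate is informed by data.
    """
    m_prime, mu, sigma = standardize(series)
    grid, neg_log_p, _ = estimate_neg_log_density(m_prime, support=support, n_bins=n_bins, bandwidth=bandwidth)
    c = fit_energy_polynomial(grid, neg_log_p, degree=degree, weight_mode=weight_mode)
    a = unscale_coefficients(c, mu, sigma)
    lo = max(float(m_prime.min()), support[0])
    hi = min(float(m_prime.max()), support[1])
    verdict = classify_stability(c, (lo, hi))
    return EnergyLandscape(
        mu_m=mu,
        sigma_m=sigma,
        c=c,
        a=a,
        grid_lo=support[0],
        grid_hi=support[1],
        n_bins=n_bins,
        stability=verdict,
        condition=series.condition,
    )
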