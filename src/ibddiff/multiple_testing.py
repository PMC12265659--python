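"""Family-wise error rate control for OU-correlated genome scans.

The scan statistic along the genome is modelled as a stationary
Ornstein-Uhlenbeck process with decay parameter ``theta`` (per Morgan)
sampled every ``delta`` Morgans.  The probability that its maximum over a
genome of total length ``L`` Morgans split into ``C`` chromosomes exceeds
``z`` is approximated by the Siegmund-Yakir excursion formula

    P(max Z >= z) ~= 1 - exp( -C * (1 - Phi(z))
                              - theta * L * z * phi(z) * nu(z * sqrt(2*theta*delta)) )

where ``nu`` corrects for testing on a discrete grid rather than in
continuum.  Solving this for the family-wise level ``alpha`` yields the
genome-wide critical value ``z*`` and per-test significance level
``alpha* = 1 - Phi(z*)``.  A simulation-based alternative takes the
empirical ``(1 - alpha)`` quantile of maxima of simulated OU difference
tracks, and a Bonferroni fallback uses ``alpha / M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from . import ou_simulator


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeLayout:
    """Tested genome geometry: chromosome lengths (cM) and test spacing (cM)."""

    chrom_lengths_cm: tuple
    step_cm: float

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths_cm",
                           tuple(float(x) for x in self.chrom_lengths_cm))
        if self.C < 1:
            raise ThresholdError("layout needs at least one chromosome")
        if self.step_cm <= 0 or any(x <= 0 for x in self.chrom_lengths_cm):
            raise ThresholdError("lengths and step must be positive")

    @property
    def C(self) -> int:
        return len(self.chrom_lengths_cm)

    @property
    def L_m(self) -> float:
        """Total tested length in Morgans."""
        return sum(self.chrom_lengths_cm) / 100.0

    @property
    def delta_m(self) -> float:
        """Test spacing in Morgans."""
        return self.step_cm / 100.0

    @property
    def positions_per_chrom(self):
        return tuple(int(math.floor(x / self.step_cm + 1e-9)) + 1
                     for x in self.chrom_lengths_cm)

    @property
    def M(self) -> int:
        """Total number of tests."""
        return sum(self.positions_per_chrom)


def layout_from_grid(grid) -> GenomeLayout:
    """Genome layout of a built scan grid (spans of tested positions)."""
    lengths = [float(grid.cm[sl][-1] - grid.cm[sl][0])
               for sl in (grid.chrom_slice(c) for c in grid.chroms)]
    return GenomeLayout(tuple(lengths), grid.step_cm)


@dataclass
class ThresholdResult:
    """A FWER-controlling per-test significance level and critical value."""

    alpha: float
    alpha_star: float
    z_star: float
    method: str
    layout: Optional[GenomeLayout] = None
    theta: Optional[float] = None
    theta_case: Optional[float] = None
    theta_control: Optional[float] = None
    rho: Optional[float] = None
    n_sims: Optional[int] = None
    seed: Optional[int] = None
    two_sided: bool = False

    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha, "alpha_star": self.alpha_star,
            "z_star": self.z_star, "method": self.method,
            "two_sided": self.two_sided,
        }
        if self.layout is not None:
            out["layout"] = {
                "chrom_lengths_cm": list(self.layout.chrom_lengths_cm),
                "step_cm": self.layout.step_cm,
                "L_morgans": self.layout.L_m, "C": self.layout.C,
                "M": self.layout.M,
            }
        for key in ("theta", "theta_case", "theta_control", "rho", "n_sims", "seed"):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        return out


# ---------------------------------------------------------------------------
# The discretization correction nu
# ---------------------------------------------------------------------------

def nu(y):
    """Siegmund's discretization correction for grid-sampled OU maxima.

    Two-term rational approximation
    ``nu(y) ~= [(2/y) (Phi(y/2) - 1/2)] / [(y/2) Phi(y/2) + phi(y/2)]``
    with ``nu(0) = 1``; decreasing from 1 toward ``2/y**2`` as the grid
    coarsens.  Accepts scalars or arrays, ``y >= 0``.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ThresholdError("nu is defined for y >= 0")
    safe = np.where(arr == 0, 1.0, arr)
    num = (2.0 / safe) * (norm.cdf(safe / 2.0) - 0.5)
    den = (safe / 2.0) * norm.cdf(safe / 2.0) + norm.pdf(safe / 2.0)
    out = np.where(arr == 0, 1.0, num / den)
    return float(out) if np.isscalar(y) or arr.ndim == 0 else out


def nu_series(y, k_max: int = 10_000):
    """Exact series form of ``nu`` (truncated), used as an independent oracle.

    ``nu(y) = (2/y**2) * exp(-2 * sum_{k>=1} Phi(-y*sqrt(k)/2) / k)``.
    """
    arr = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(arr <= 0):
        raise ThresholdError("series form needs y > 0")
    k = np.arange(1, k_max + 1)
    out = np.empty_like(arr)
    for i, yi in enumerate(arr):
        s = np.sum(norm.cdf(-yi * np.sqrt(k) / 2.0) / k)
        out[i] = (2.0 / yi**2) * math.exp(-2.0 * s)
    return float(out[0]) if np.isscalar(y) or np.asarray(y).ndim == 0 else out


# ---------------------------------------------------------------------------
# Threshold calculations
# ---------------------------------------------------------------------------

def fwer_approx(z: float, theta: float, layout: GenomeLayout) -> float:
    """Excursion approximation to P(max of the scan track >= z)."""
    if theta < 0:
        raise ThresholdError("theta must be non-negative")
    if z <= 0:
        raise ThresholdError("z must be positive")
    exponent = layout.C * norm.sf(z)
    exponent += (theta * layout.L_m * z * norm.pdf(z)
                 * nu(z * math.sqrt(2.0 * theta * layout.delta_m)))
    return float(-np.expm1(-exponent))


def analytic_threshold(alpha: float, theta: float, layout: GenomeLayout,
                       two_sided: bool = False) -> ThresholdResult:
    """Solve the excursion approximation for the critical value at level alpha.

    Brent root-finding on z in [1, 10] (widened to [0.1, 20] if needed).
    With ``two_sided=True`` both tails contribute and the exceedance terms
    are doubled before solving.
    """
    if not 0 < alpha < 1:
        raise ThresholdError("alpha must be in (0, 1)")
    if theta <= 0:
        raise ThresholdError("theta must be positive")
    fold = 2.0 if two_sided else 1.0

    def f(z):
        exponent = fold * layout.C * norm.sf(z)
        exponent += (fold * theta * layout.L_m * z * norm.pdf(z)
                     * nu(z * math.sqrt(2.0 * theta * layout.delta_m)))
        return -np.expm1(-exponent) - alpha

    lo, hi = 1.0, 10.0
    if f(lo) * f(hi) > 0:
        lo, hi = 0.1, 20.0
        if f(lo) * f(hi) > 0:
            raise ThresholdError(
                "no critical value in z ∈ [0.1, 20]; check alpha, theta and layout"
            )
    z_star = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    if abs(f(z_star)) > 1e-10:
        raise ThresholdError("root solver did not converge")
    return ThresholdResult(alpha=alpha, alpha_star=float(norm.sf(z_star)),
                           z_star=float(z_star), method="analytic",
                           layout=layout, theta=theta, two_sided=two_sided)


def bonferroni(alpha: float, M: int) -> ThresholdResult:
    """Per-test level alpha / M for M tests."""
    if M < 1:
        raise ThresholdError("M must be >= 1")
    alpha_star = alpha / M
    return ThresholdResult(alpha=alpha, alpha_star=alpha_star,
                           z_star=float(norm.isf(alpha_star)), method="bonferroni")


def simulation_threshold(alpha: float, theta1: float, theta0: float, rho: float,
                         layout: GenomeLayout, n_sims: int = 1000,
                         seed: int = 0, two_sided: bool = False) -> ThresholdResult:
    """Empirical (1 - alpha) quantile of simulated genome-wide maxima.

    Simulates ``n_sims`` genomes as cross-correlated OU pairs, re-standardizes
    each difference track to unit variance (matching the data pipeline), and
    takes the conservative upper order statistic ``ceil((1 - alpha) * n_sims)``
    of the maxima (never interpolating downward).  Bitwise reproducible for a
    given seed.
    """
    if not 0 < alpha < 1:
        raise ThresholdError("alpha must be in (0, 1)")
    if n_sims < 100:
        raise ThresholdError("n_sims must be >= 100")
    maxima = ou_simulator.simulate_max_differences(
        theta1, theta0, rho, layout, n_sims,
        np.random.Generator(np.random.PCG64(seed)), two_sided=two_sided)
    k = int(math.ceil((1.0 - alpha) * n_sims))
    z_star = float(np.sort(maxima)[k - 1])
    return ThresholdResult(alpha=alpha, alpha_star=float(norm.sf(z_star)),
                           z_star=z_star, method="simulation", layout=layout,
                           theta_case=theta1, theta_control=theta0, rho=rho,
                           n_sims=n_sims, seed=seed, two_sided=two_sided)


def two_sided_threshold(alpha: float, theta: float, layout: GenomeLayout,
                        method: str = "simulation", theta0: Optional[float] = None,
                        rho: float = 0.0, n_sims: int = 1000,
                        seed: int = 0) -> ThresholdResult:
    """Two-sided critical value for scans sensitive to both tails.

    ``method="analytic"`` doubles the excursion terms in the approximation;
    ``method="simulation"`` (default) takes the (1 - alpha) quantile of
    maxima of the absolute standardized difference track.
    """
    if method == "analytic":
        return analytic_threshold(alpha, theta, layout, two_sided=True)
    if method == "simulation":
        return simulation_threshold(alpha, theta, theta if theta0 is None else theta0,
                                    rho, layout, n_sims=n_sims, seed=seed,
                                    two_sided=True)
    raise ThresholdError(f"unknown two-sided method {method!r}")
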