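"""Release kinetics: barrier -> rate conversion and power-law curve fitting.

Two layers connect the free-energy calculations to observable release:

* a solubility--diffusion rate model in which the translocation rate is
  k_t ~ D exp(beta dG_t*), with dG_t* <= 0 the free energy of the compound's
  preferred location relative to bulk water.  With equal diffusion
  coefficients the prefactor cancels, so only rate *ratios* between
  compounds are exposed; a deeper (more negative) barrier means slower
  release;
* the Ritger-Peppas power law  M_t / M_inf = K t^n  for the cumulative
  release fraction, fitted by nonlinear least squares on the early-release
  portion of the curve (fractions <= 0.6, the standard validity domain of
  the power law), with a log-log linear regression supplying the starting
  point.  n is the diffusional exponent (n ~ 0.43-0.5 indicates Fickian
  diffusion for common geometries); K absorbs geometry and drug-matrix
  interaction strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .constants import KB, beta

__all__ = [
    "ReleaseCurve",
    "PeppasFit",
    "RankResult",
    "relative_rate",
    "rank_compounds",
    "barrier_relative_difference",
    "fit_peppas",
    "predict_release",
]


@dataclass(frozen=True)
class ReleaseCurve:
    """Cumulative fraction released M_t/M_inf over time (hours)."""

    times: np.ndarray  # h
    fraction_released: np.ndarray  # in [0, 1]
    stderr: Optional[np.ndarray] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_released, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_released", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fractions must be matching 1D arrays")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValueError("times must be non-negative and non-decreasing")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.stderr is not None:
            s = np.asarray(self.stderr, dtype=float)
            object.__setattr__(self, "stderr", s)
            if s.shape != t.shape or np.any(s < 0):
                raise ValueError("stderr must be non-negative and match times")


@dataclass(frozen=True)
class PeppasFit:
    """Fitted power-law parameters with their 2x2 covariance."""

    K: float  # h^-n
    n: float
    covariance: np.ndarray
    fit_range_max_fraction: float
    n_points: int

    def __post_init__(self):
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be > 0")


@dataclass(frozen=True)
class RankResult:
    """Compound ordering fastest -> slowest release, with ties reported."""

    order: List[str]
    barriers: Dict[str, float]
    ties: List[Tuple[str, str]]


def relative_rate(dg_a: float, dg_b: float, temperature: float) -> float:
    """Rate ratio k_a / k_b = exp(beta (dG_a - dG_b)).

    Both barriers are <= 0 by the package convention; equal diffusion
    coefficients are assumed so the prefactor cancels.  A deeper (more
    negative) barrier for A than B yields a ratio < 1.
    """
    if dg_a > 0 or dg_b > 0:
        raise ValueError("barriers must be <= 0 under the sign convention")
    return math.exp(beta(temperature) * (dg_a - dg_b))


def rank_compounds(barriers: Dict[str, float]) -> RankResult:
    """Order compounds fastest to slowest: descending dG_t* (least negative
    first).  Exact ties are broken alphabetically and reported."""
    if not barriers:
        raise ValueError("no compounds to rank")
    order = sorted(barriers, key=lambda name: (-barriers[name], name))
    ties = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if barriers[a] == barriers[b]
    ]
    return RankResult(order=order, barriers=dict(barriers), ties=ties)


def barrier_relative_difference(dg_a: float, dg_b: float) -> float:
    """Relative barrier difference in percent: 100 |dG_a - dG_b| / |dG_b|.

    The denominator is the second argument by convention.
    """
    if dg_b == 0:
        raise ZeroDivisionError("reference barrier dg_b must be non-zero")
    return 100.0 * abs(dg_a - dg_b) / abs(dg_b)


def fit_peppas(curve: ReleaseCurve, max_fraction: float = 0.6) -> PeppasFit:
    """Fit M_t/M_inf = K t^n to the early-release portion of a curve.

    Only points with 0 < fraction <= ``max_fraction`` and t > 0 enter the
    fit (at least 3 required).  Initial (K, n) comes from ordinary linear
    regression of log(fraction) on log(t); the nonlinear refinement is
    unweighted unless the curve carries per-point standard errors, in which
    case inverse-variance weighting is applied.
    """
    t = curve.times
    f = curve.fraction_released
    mask = (t > 0) & (f > 0) & (f <= max_fraction) & np.isfinite(f) & np.isfinite(t)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"need >= 3 points with 0 < fraction <= {max_fraction} and t > 0 "
            f"(got {int(mask.sum())})"
        )
    tt, ff = t[mask], f[mask]
    slope, intercept = np.polyfit(np.log(tt), np.log(ff), 1)
    p0 = (float(np.exp(intercept)), float(max(slope, 1e-3)))

    sigma = None
    if curve.stderr is not None:
        sigma = np.maximum(curve.stderr[mask], 1e-6)

    def model(x, K, n):
        return K * np.power(x, n)

    popt, pcov = curve_fit(
        model, tt, ff, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
        maxfev=10_000,
    )
    return PeppasFit(
        K=float(popt[0]),
        n=float(popt[1]),
        covariance=np.asarray(pcov),
        fit_range_max_fraction=max_fraction,
        n_points=int(mask.sum()),
    )


def predict_release(fit: PeppasFit, times) -> ReleaseCurve:
    """Evaluate a fitted power law, clipped to the physical range [0, 1]."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    frac = np.clip(fit.K * np.power(t, fit.n), 0.0, 1.0)
    return ReleaseCurve(times=t, fraction_released=frac)
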