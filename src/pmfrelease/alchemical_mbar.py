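"""Alchemical free energies via the multistate Bennett acceptance ratio (MBAR).

Estimates solvation free-energy differences between the endpoints of a
coupling schedule (lambda = 0 fully decoupled, lambda = 1 fully interacting)
from samples of every intermediate state, and derives transfer free energies
and the octanol--water partition coefficient log P_ow from them.  The
soft-core Lennard-Jones form used near the decoupled endpoint is provided as
a standalone function.

MBAR solves the self-consistency

    f_i = -ln sum_n  exp(-u_in) / sum_k N_k exp(f_k - u_kn)

over all pooled samples n, with reduced (dimensionless) energies
u_kn = beta U_k(x_n), anchored at f_0 = 0.  The implementation iterates the
fixed point in log space to a tight tolerance; the asymptotic covariance of
the state free energies supplies the uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import logsumexp

from .constants import KB, beta

__all__ = [
    "LambdaSchedule",
    "SoftCoreParams",
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "MbarResult",
    "MbarConvergenceError",
    "StateOverlapError",
    "softcore_lj",
    "mbar_solve",
    "solvation_dg",
    "transfer_dg",
    "logp_from_transfer",
]


class MbarConvergenceError(RuntimeError):
    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = list(trace)


class StateOverlapError(RuntimeError):
    """A pair of states shares no configurational overlap."""


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered coupling schedule over [0, 1].

    ``coupling_mode`` is bookkeeping: ``lj_only`` (uncharged solutes, a single
    Lennard-Jones switching leg) or ``coulomb_then_lj`` (charged solutes,
    electrostatics switched off before dispersion; represented as two stacked
    sub-schedules over the same [0, 1] axis).
    """

    lambdas: Tuple[float, ...]
    coupling_mode: str = "lj_only"

    def __post_init__(self):
        lams = tuple(float(x) for x in self.lambdas)
        object.__setattr__(self, "lambdas", lams)
        if len(lams) < 2:
            raise ValueError("schedule needs at least two states")
        if not math.isclose(lams[0], 0.0) or not math.isclose(lams[-1], 1.0):
            raise ValueError("schedule endpoints must be 0 and 1")
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambdas must be strictly increasing")
        if self.coupling_mode not in ("lj_only", "coulomb_then_lj"):
            raise ValueError(f"unknown coupling mode {self.coupling_mode!r}")

    @property
    def n_states(self) -> int:
        return len(self.lambdas)


def uniform_schedule(n_windows: int = 10, coupling_mode: str = "lj_only") -> LambdaSchedule:
    """Evenly spaced schedule lambda = 0, 1/n, ..., 1 (n_windows intervals)."""
    return LambdaSchedule(
        lambdas=tuple(np.linspace(0.0, 1.0, n_windows + 1)), coupling_mode=coupling_mode
    )


@dataclass(frozen=True)
class SoftCoreParams:
    """Beutler-form soft-core constants (alpha=0.5, p=1 by default)."""

    sigma: float  # nm
    epsilon: float  # kJ/mol
    alpha: float = 0.5
    lambda_power: int = 1

    def __post_init__(self):
        if self.alpha < 0 or self.epsilon < 0:
            raise ValueError("alpha and epsilon must be >= 0")


def softcore_lj(r, lam: float, params: SoftCoreParams):
    """Soft-core Lennard-Jones energy in kJ/mol, finite at r = 0 for lam < 1.

    V = 4 eps lam^p [ sigma^12 / (alpha sigma^6 (1-lam) + r^6)^2
                      - sigma^6 / (alpha sigma^6 (1-lam) + r^6) ]

    At lam = 1 this is exactly the standard 12-6 potential; at lam = 0 the
    interaction vanishes for every r.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    s6 = params.sigma**6
    denom = params.alpha * s6 * (1.0 - lam) + r**6
    with np.errstate(divide="ignore"):
        v = 4.0 * params.epsilon * lam**params.lambda_power * (
            s6**2 / denom**2 - s6 / denom
        )
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class ReducedPotentialMatrix:
    """u[k, n] = beta U_k(x_n) over K states and N pooled samples."""

    u: np.ndarray  # (K, N)
    counts: np.ndarray  # (K,) samples originating from each state
    temperature: float

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "counts", counts)
        if u.ndim != 2:
            raise ValueError("u must be a K x N matrix")
        if counts.shape != (u.shape[0],) or np.any(counts < 0):
            raise ValueError("counts must be non-negative, one per state")
        if int(counts.sum()) != u.shape[1]:
            raise ValueError("sum of counts must equal the number of samples")
        if not np.all(np.isfinite(u)):
            raise ValueError("reduced potentials must be finite")
        if (counts > 0).sum() < 2:
            raise ValueError("need samples from at least two states")


@dataclass(frozen=True)
class FreeEnergyResult:
    delta_g: float  # kJ/mol
    stderr: float  # kJ/mol
    endpoints: Tuple[int, int]
    temperature: float

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class MbarResult:
    """Per-state reduced free energies (f_0 = 0) and asymptotic covariance."""

    f: np.ndarray  # (K,) in kT units
    covariance: np.ndarray  # (K, K) of the f estimates
    n_iter: int
    weights: np.ndarray  # (N, K) normalised mixture weights, sum_n W_nk = 1

    def delta_f(self, i: int, j: int) -> Tuple[float, float]:
        """(f_j - f_i, stderr) in kT units."""
        var = self.covariance[i, i] + self.covariance[j, j] - 2 * self.covariance[i, j]
        return float(self.f[j] - self.f[i]), float(np.sqrt(max(var, 0.0)))


def _mbar_covariance(w: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of the reduced free energies from the weight
    matrix W (N x K), via the SVD form Theta = V S (I - S V' N V S)^+ S V'."""
    u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
    v = vt.T
    inner = np.eye(len(s)) - np.diag(s) @ v.T @ np.diag(counts.astype(float)) @ v @ np.diag(s)
    theta = v @ np.diag(s) @ np.linalg.pinv(inner, rcond=1e-10) @ np.diag(s) @ v.T
    return theta


def _check_state_connectivity(w: np.ndarray, counts: np.ndarray, min_overlap: float = 1e-8):
    """Overlap matrix O_ij = sum_n N_i W_ni W_nj; flag disconnected pairs."""
    K = w.shape[1]
    o = (w * counts[None, :]).T @ w  # (K, K)
    adj = o > min_overlap
    seen = np.zeros(K, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    if not np.all(seen):
        i = 0
        j = int(np.flatnonzero(~seen)[0])
        raise StateOverlapError(
            f"states {i} and {j} share no configurational overlap "
            f"(max pairwise overlap {o[i, j]:.2e}); free energies between "
            "them are not identifiable"
        )


def mbar_solve(
    u: ReducedPotentialMatrix, tol: float = 1e-10, max_iter: int = 50_000
) -> MbarResult:
    """Solve the MBAR self-consistency for per-state reduced free energies.

    Log-sum-exp-stabilised self-consistent iteration until
    max |df| < ``tol`` (kT units).  States with no samples are handled
    naturally (their free
    energy is still estimated by reweighting).  Raises
    :class:`StateOverlapError` when a state pair is disconnected and
    :class:`MbarConvergenceError` (with iteration trace) on failure.
    """
    umat = u.u
    counts = u.counts
    K, N = umat.shape
    log_n = np.where(counts > 0, np.log(np.maximum(counts, 1)), -np.inf)

    f = np.zeros(K)
    trace = []
    converged = False
    for it in range(max_iter):
        log_denom = logsumexp(log_n[:, None] + f[:, None] - umat, axis=0)  # (N,)
        f_new = -logsumexp(-umat - log_denom[None, :], axis=1)
        f_new -= f_new[0]
        df = float(np.max(np.abs(f_new - f)))
        trace.append(df)
        f = f_new
        if df < tol:
            converged = True
            break
    if not converged:
        raise MbarConvergenceError(
            f"MBAR did not converge in {max_iter} iterations "
            f"(last |df| = {trace[-1]:.3g} kT)",
            trace,
        )
    log_denom = logsumexp(log_n[:, None] + f[:, None] - umat, axis=0)
    log_w = (f[:, None] - umat - log_denom[None, :]).T  # (N, K)
    w = np.exp(log_w)
    _check_state_connectivity(w, counts)
    theta = _mbar_covariance(w, counts)
    return MbarResult(f=f, covariance=theta, n_iter=it + 1, weights=w)


def solvation_dg(
    schedule: LambdaSchedule,
    u: ReducedPotentialMatrix,
    tol: float = 1e-10,
    max_iter: int = 50_000,
) -> FreeEnergyResult:
    """End-to-end solvation free energy over the schedule, in kJ/mol.

    dG_solv = (f_{lambda=1} - f_{lambda=0}) kT, with the MBAR asymptotic
    standard error.
    """
    if u.u.shape[0] != schedule.n_states:
        raise ValueError(
            f"matrix has {u.u.shape[0]} states but schedule has {schedule.n_states}"
        )
    res = mbar_solve(u, tol=tol, max_iter=max_iter)
    kT = KB * u.temperature
    df, se = res.delta_f(0, schedule.n_states - 1)
    return FreeEnergyResult(
        delta_g=df * kT,
        stderr=se * kT,
        endpoints=(0, schedule.n_states - 1),
        temperature=u.temperature,
    )


def transfer_dg(
    dg_solv_in_a: FreeEnergyResult, dg_solv_in_b: FreeEnergyResult
) -> FreeEnergyResult:
    """Transfer free energy A -> B: dG_solv(B) - dG_solv(A); errors in quadrature."""
    if not math.isclose(dg_solv_in_a.temperature, dg_solv_in_b.temperature):
        raise ValueError(
            "solvation free energies were computed at different temperatures"
        )
    return FreeEnergyResult(
        delta_g=dg_solv_in_b.delta_g - dg_solv_in_a.delta_g,
        stderr=math.hypot(dg_solv_in_a.stderr, dg_solv_in_b.stderr),
        endpoints=(dg_solv_in_a.endpoints[1], dg_solv_in_b.endpoints[1]),
        temperature=dg_solv_in_a.temperature,
    )


def logp_from_transfer(dg_o_to_w: float, temperature: float) -> float:
    """log P_ow from the octanol -> water transfer free energy (kJ/mol).

    log P_ow = dG_{O->W} / (ln 10 * R * T); positive when moving the solute
    into water is costly, i.e. for hydrophobic compounds.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return dg_o_to_w / (math.log(10.0) * KB * temperature)
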