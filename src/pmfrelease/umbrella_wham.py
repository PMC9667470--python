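"""Weighted-histogram (WHAM) reconstruction of translocation free-energy profiles.

Combines umbrella-sampling windows (harmonically biased trajectories of the
drug--matrix distance) into one unbiased potential of mean force G(z), with
bootstrap error bars, and extracts the translocation barrier dG_t* — the free
energy of the compound's preferred location (matrix interior or interface)
relative to bulk water.  By the sign convention used throughout the package,
dG_t* <= 0 and a larger magnitude means slower release.

The estimator is the standard self-consistent WHAM iteration over binned
histograms::

    p(z)  ~  sum_i n_i(z) / sum_j N_j exp(beta (F_j - w_j(z)))
    F_j   =  -kT ln sum_z p(z) exp(-beta w_j(z))

run in log space until the largest change in any window free energy F_j falls
below ``tol`` (kJ/mol).  G(z) = -kT ln p(z) is shifted so the aqueous
reference region averages zero.  Empty bins are flagged and excluded — never
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .constants import KB, beta

__all__ = [
    "UmbrellaWindow",
    "WindowSet",
    "PMFProfile",
    "TranslocationBarrier",
    "OverlapReport",
    "WhamConvergenceError",
    "DisconnectedWindowsError",
    "wham",
    "check_overlap",
    "bootstrap_pmf_error",
    "extract_barrier",
]


class WhamConvergenceError(RuntimeError):
    """WHAM failed to converge; carries the F-change history."""

    def __init__(self, message, df_history):
        super().__init__(message)
        self.df_history = list(df_history)


class DisconnectedWindowsError(RuntimeError):
    """The window histograms do not form a connected overlap graph."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """One umbrella window: bias center/spring and reaction-coordinate samples."""

    center: float  # nm
    spring_constant: float  # kJ mol^-1 nm^-2
    samples: np.ndarray  # nm

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")

    def bias_energy(self, z):
        return 0.5 * self.spring_constant * (np.asarray(z, float) - self.center) ** 2


@dataclass(frozen=True)
class WindowSet:
    windows: Sequence[UmbrellaWindow]
    temperature: float

    def __post_init__(self):
        if len(self.windows) == 0:
            raise ValueError("WindowSet needs at least one window")
        centers = [w.center for w in self.windows]
        if any(b < a for a, b in zip(centers, centers[1:])):
            raise ValueError("window centers must be non-decreasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def centers(self):
        return np.array([w.center for w in self.windows])


@dataclass
class PMFProfile:
    """Reconstructed G(z): bin centers, free energies (NaN in empty bins),
    optional per-bin standard errors, and the zero-reference interval."""

    z_grid: np.ndarray
    free_energy: np.ndarray
    stderr: Optional[np.ndarray]
    reference_region: Tuple[float, float]
    populated: np.ndarray
    temperature: float
    window_free_energies: Optional[np.ndarray] = None
    info: dict = field(default_factory=dict)
    replicates: Optional[np.ndarray] = None  # (n_boot, n_bins) bootstrap profiles


@dataclass(frozen=True)
class TranslocationBarrier:
    """dG_t* = G(minimum) - <G(reference region)>; <= 0 for a bound compound."""

    delta_g: float
    minimum_location: float
    reference_region: Tuple[float, float]
    stderr: Optional[float]


@dataclass(frozen=True)
class OverlapReport:
    """Histogram-intersection fractions for adjacent window pairs."""

    pairs: Sequence[Tuple[int, int]]
    fractions: np.ndarray
    threshold: float

    @property
    def flagged(self):
        """Adjacent pairs whose overlap falls below the threshold."""
        return [p for p, f in zip(self.pairs, self.fractions) if f < self.threshold]


# --------------------------------------------------------------------------- #


def _make_grid(windows, bin_width):
    zmin = min(float(np.min(w.samples)) for w in windows)
    zmax = max(float(np.max(w.samples)) for w in windows)
    span = max(zmax - zmin, bin_width)
    n_bins = int(np.ceil(span / bin_width)) + 1
    edges = zmin + bin_width * np.arange(n_bins + 1) - 0.5 * bin_width
    return edges


def _default_reference(edges, solvent_side):
    lo, hi = edges[0], edges[-1]
    frac = 0.10
    if solvent_side == "upper":
        return (hi - frac * (hi - lo), hi)
    return (lo, lo + frac * (hi - lo))


def _check_connected(counts):
    """counts: (K, Z) per-window histograms. Windows are linked when their
    supports share a bin; raise if the graph is disconnected."""
    K = counts.shape[0]
    support = counts > 0
    seen = np.zeros(K, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        touch = support[i]
        for j in range(K):
            if not seen[j] and np.any(support[j] & touch):
                seen[j] = True
                stack.append(j)
    if not np.all(seen):
        missing = np.flatnonzero(~seen).tolist()
        raise DisconnectedWindowsError(
            f"window histogram graph is disconnected; windows {missing} share "
            "no bins with the component containing window 0"
        )


def wham(
    windows: WindowSet,
    bin_width: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    reference_region: Optional[Tuple[float, float]] = None,
    solvent_side: str = "upper",
    stride: int = 1,
    f_init: Optional[np.ndarray] = None,
    bin_edges: Optional[np.ndarray] = None,
    overlap_threshold: float = 0.03,
    method: str = "hybrid",
) -> PMFProfile:
    """Self-consistent WHAM estimate of the unbiased free-energy profile.

    Parameters follow the standard protocol: ``bin_width`` in nm, ``tol`` the
    convergence threshold on max |dF_j| in kJ/mol, ``stride`` an optional
    decorrelation subsampling of each window's samples.  The returned profile
    is shifted so that its average over ``reference_region`` (default: the
    outermost 10% of the sampled range on the solvent side) is zero.

    ``method`` selects the solver.  ``"hybrid"`` (default) first minimises
    the convex WHAM log-likelihood in the window free energies by damped
    Newton iteration,
    then runs self-consistent sweeps until max |dF| < ``tol`` — the two share
    the same fixed point, and the direct minimisation avoids the very slow
    geometric tail of plain iteration on many-window problems.  ``"scf"``
    iterates the self-consistency from scratch.

    Raises :class:`WhamConvergenceError` after ``max_iter`` sweeps and
    :class:`DisconnectedWindowsError` when the windows cannot be stitched.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    wins = list(windows.windows)
    kT = KB * windows.temperature
    b = 1.0 / kT
    samples = [w.samples[::stride] for w in wins]
    if bin_edges is None:
        edges = _make_grid(
            [UmbrellaWindow(w.center, w.spring_constant, s) for w, s in zip(wins, samples)],
            bin_width,
        )
    else:
        edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    K, Z = len(wins), centers.size

    counts = np.zeros((K, Z))
    for i, s in enumerate(samples):
        counts[i], _ = np.histogram(s, bins=edges)
    if len(wins) > 1:
        rep = check_overlap(windows, bin_width=bin_width, threshold=overlap_threshold)
        if rep.flagged:
            warnings.warn(
                f"{len(rep.flagged)} adjacent window pair(s) overlap below "
                f"{overlap_threshold}: {rep.flagged[:5]}...",
                stacklevel=2,
            )
    _check_connected(counts)

    c_z = counts.sum(axis=0)
    n_j = counts.sum(axis=1)
    log_nj = np.log(n_j)
    bw = np.empty((K, Z))
    for i, w in enumerate(wins):
        bw[i] = b * w.bias_energy(centers)

    populated = c_z > 0
    log_c = np.full(Z, -np.inf)
    log_c[populated] = np.log(c_z[populated])

    g = np.zeros(K) if f_init is None else b * np.asarray(f_init, dtype=float).copy()
    g -= g[0]
    if method not in ("hybrid", "scf"):
        raise ValueError(f"unknown method {method!r}")
    if method == "hybrid" and K > 1:
        g = _wham_ml_solve(g, log_nj, log_c, bw)
    df_history = []
    converged = False
    for it in range(max_iter):
        # log p(z) up to a constant
        log_denom = logsumexp(log_nj[:, None] + g[:, None] - bw, axis=0)
        log_p = log_c - log_denom
        g_new = -logsumexp(log_p[None, :] - bw, axis=1)
        g_new -= g_new[0]
        df = float(np.max(np.abs(g_new - g))) * kT
        df_history.append(df)
        g = g_new
        if df < tol:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last |dF| = {df_history[-1]:.3g} kJ/mol)",
            df_history,
        )

    log_denom = logsumexp(log_nj[:, None] + g[:, None] - bw, axis=0)
    log_p = log_c - log_denom
    G = np.full(Z, np.nan)
    G[populated] = -kT * log_p[populated]

    if reference_region is None:
        reference_region = _default_reference(edges, solvent_side)
    ref_mask = populated & (centers >= reference_region[0]) & (centers <= reference_region[1])
    if not np.any(ref_mask):
        raise ValueError(f"reference region {reference_region} contains no populated bins")
    G -= np.mean(G[ref_mask])

    return PMFProfile(
        z_grid=centers,
        free_energy=G,
        stderr=None,
        reference_region=tuple(reference_region),
        populated=populated,
        temperature=windows.temperature,
        window_free_energies=g * kT,
        info={"iterations": it + 1, "df_history": df_history, "bin_edges": edges},
    )


def _wham_ml_solve(g0, log_nj, log_c, bw, max_newton: int = 200):
    """Minimise the convex WHAM negative log-likelihood over the window
    (reduced) free energies g_j, gauge-fixed at g_0 = 0, by damped Newton
    iteration (the Hessian is K x K and explicit)."""
    pop = np.isfinite(log_c)
    c_z = np.exp(log_c[pop])
    n_j = np.exp(log_nj)
    bwp = bw[:, pop]

    def value_grad_hess(g):
        logw = log_nj[:, None] + g[:, None] - bwp
        log_d = logsumexp(logw, axis=0)  # (Zp,)
        val = -np.dot(n_j, g) + np.dot(c_z, log_d)
        w = np.exp(logw - log_d[None, :])  # (K, Zp), columns sum to 1
        grad = -n_j + w @ c_z
        h = (w * c_z[None, :]) @ w.T
        hess = np.diag(w @ c_z) - h
        return val, grad, hess

    g = g0 - g0[0]
    val, grad, hess = value_grad_hess(g)
    for _ in range(max_newton):
        # reduced system with g_0 pinned at 0
        try:
            step = np.linalg.solve(
                hess[1:, 1:] + 1e-10 * np.eye(len(g) - 1), -grad[1:]
            )
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(40):
            g_try = g.copy()
            g_try[1:] += t * step
            val_try, grad_try, hess_try = value_grad_hess(g_try)
            if val_try <= val:
                break
            t *= 0.5
        else:
            break
        g, val, grad, hess = g_try, val_try, grad_try, hess_try
        if np.max(np.abs(grad[1:])) < 1e-9 * max(1.0, np.max(n_j)):
            break
    return g


def check_overlap(
    windows: WindowSet, bin_width: float = 0.05, threshold: float = 0.03
) -> OverlapReport:
    """Histogram-intersection fraction for each adjacent window pair.

    The fraction is sum_z min(p_i(z), p_j(z)) with each histogram normalised
    to unit mass on a shared grid; 1 for identical distributions, 0 for
    disjoint supports.  Pairs below ``threshold`` are flagged (not an error).
    """
    wins = list(windows.windows)
    if len(wins) < 2:
        raise ValueError("need at least two windows to assess overlap")
    edges = _make_grid(wins, bin_width)
    pairs, fracs = [], []
    for i in range(len(wins) - 1):
        h1, _ = np.histogram(wins[i].samples, bins=edges)
        h2, _ = np.histogram(wins[i + 1].samples, bins=edges)
        p1 = h1 / h1.sum()
        p2 = h2 / h2.sum()
        pairs.append((i, i + 1))
        fracs.append(float(np.minimum(p1, p2).sum()))
    return OverlapReport(pairs=pairs, fractions=np.array(fracs), threshold=threshold)


def bootstrap_pmf_error(
    windows: WindowSet,
    n_boot: int,
    seed: int,
    bin_width: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    reference_region: Optional[Tuple[float, float]] = None,
    solvent_side: str = "upper",
    stride: int = 1,
) -> PMFProfile:
    """WHAM profile with per-bin bootstrap standard errors.

    Each window's samples are resampled with replacement ``n_boot`` times; the
    per-bin standard deviation across re-solved profiles is the error
    estimate.  Replicate profiles are kept on the shared grid (``replicates``
    attribute) so derived quantities such as the barrier can propagate errors
    honestly.  WHAM non-convergence in a replicate is re-raised with the
    replicate index.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    base = wham(
        windows,
        bin_width=bin_width,
        tol=tol,
        max_iter=max_iter,
        reference_region=reference_region,
        solvent_side=solvent_side,
        stride=stride,
    )
    edges = base.info["bin_edges"]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reps = np.full((n_boot, base.z_grid.size), np.nan)
    for r in range(n_boot):
        resampled = []
        for w in windows.windows:
            s = w.samples[::stride]
            idx = rng.integers(0, s.size, size=s.size)
            resampled.append(UmbrellaWindow(w.center, w.spring_constant, s[idx]))
        wset = WindowSet(windows=resampled, temperature=windows.temperature)
        try:
            prof = wham(
                wset,
                bin_width=bin_width,
                tol=tol,
                max_iter=max_iter,
                reference_region=base.reference_region,
                solvent_side=solvent_side,
                bin_edges=edges,
                f_init=base.window_free_energies,
            )
        except WhamConvergenceError as err:
            raise WhamConvergenceError(
                f"bootstrap replicate {r}: {err}", err.df_history
            ) from err
        reps[r] = prof.free_energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        stderr = np.nanstd(reps, axis=0, ddof=1)
    return PMFProfile(
        z_grid=base.z_grid,
        free_energy=base.free_energy,
        stderr=stderr,
        reference_region=base.reference_region,
        populated=base.populated,
        temperature=base.temperature,
        window_free_energies=base.window_free_energies,
        info=base.info,
        replicates=reps,
    )


def extract_barrier(
    pmf: PMFProfile, reference_region: Optional[Tuple[float, float]] = None
) -> TranslocationBarrier:
    """Translocation barrier: deepest populated bin relative to the aqueous
    reference.  The minimum may sit in the matrix interior or at the
    interface; both occur for real compounds.

    When the profile carries bootstrap replicates, the barrier's standard
    error is the standard deviation of the barrier across replicates;
    otherwise per-bin errors are propagated in quadrature.
    """
    region = reference_region if reference_region is not None else pmf.reference_region
    z, G, pop = pmf.z_grid, pmf.free_energy, pmf.populated
    ref_mask = pop & (z >= region[0]) & (z <= region[1])
    if int(ref_mask.sum()) < 3:
        raise ValueError(f"reference region {region} has fewer than 3 populated bins")

    def _barrier(profile):
        vals = np.where(pop, profile, np.nan)
        ref = np.nanmean(profile[ref_mask])
        imin = np.nanargmin(vals)
        return vals[imin] - ref, z[imin]

    delta_g, zmin = _barrier(G)
    stderr = None
    if pmf.replicates is not None:
        deltas = []
        for rep in pmf.replicates:
            if np.all(np.isnan(rep[ref_mask])):
                continue
            d, _ = _barrier(rep)
            deltas.append(d)
        if len(deltas) >= 2:
            stderr = float(np.std(deltas, ddof=1))
    elif pmf.stderr is not None:
        imin = np.nanargmin(np.where(pop, G, np.nan))
        se_min = pmf.stderr[imin]
        se_ref = pmf.stderr[ref_mask]
        stderr = float(np.sqrt(se_min**2 + np.nanmean(se_ref) ** 2 / ref_mask.sum()))
    return TranslocationBarrier(
        delta_g=float(delta_g),
        minimum_location=float(zmin),
        reference_region=tuple(region),
        stderr=stderr,
    )
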