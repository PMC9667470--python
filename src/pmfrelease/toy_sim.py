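"""Synthetic-data engine: overdamped stochastic dynamics on analytic 1D potentials.

This module generates every kind of input the downstream estimators consume:

* biased (umbrella) and unbiased trajectories of a single coordinate under
  analytic potentials, via overdamped Euler--Maruyama dynamics;
* multi-state (lambda-scaled) samples for alchemical free-energy estimation,
  drawn exactly by rejection sampling with a known quadrature reference;
* Boltzmann ensembles of bonded coordinates (bonds, angles, dihedrals);
* power-law drug-release curves with additive noise;
* periodic particle configurations with planted cluster structure.

Every generator is deterministic under a fixed seed and returns (or is
parameterised by) its ground truth, so recovery tests need no bookkeeping.

The integrator is the position-only Euler--Maruyama scheme

    z <- z - beta * D * U'(z) * dt + sqrt(2 * D * dt) * xi,   xi ~ N(0, 1)

whose stationary distribution approaches exp(-beta U) as ``beta*D*k*dt -> 0``
for local stiffness ``k``.  Defaults keep that product ~1e-3 for the stiffest
traps used here, so discretisation bias is far below sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE, beta

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "PotentialSpec",
    "LangevinConfig",
    "BiasSpec",
    "Trajectory1D",
    "ParticleConfiguration",
    "PlantedConfiguration",
    "AlchemicalDataset",
    "harmonic_potential",
    "double_well_potential",
    "make_translocation_potential",
    "tabulated_potential",
    "simulate_langevin",
    "generate_umbrella_dataset",
    "generate_alchemical_dataset",
    "sample_bonded_ensemble",
    "generate_release_curve",
    "generate_particle_config",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Trajectory left its configured domain (or became non-finite)."""


# --------------------------------------------------------------------------- #
# Potentials
# --------------------------------------------------------------------------- #

_FORM_IDS = {"harmonic": 0, "double_well": 1, "translocation": 2, "tabulated": 3}


@dataclass(frozen=True)
class PotentialSpec:
    """Analytic 1D potential U(z) with energies in kJ/mol and lengths in nm.

    Use the factory functions (:func:`harmonic_potential`,
    :func:`double_well_potential`, :func:`make_translocation_potential`,
    :func:`tabulated_potential`) rather than constructing directly.
    """

    form: str
    params: dict
    table_z: Optional[np.ndarray] = None
    table_u: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.form not in _FORM_IDS:
            raise ValueError(f"unknown potential form {self.form!r}")

    # -- evaluation --------------------------------------------------------- #

    def energy(self, z):
        """U(z), vectorised over z."""
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "harmonic":
            return 0.5 * p["spring_constant"] * (z - p["center"]) ** 2
        if self.form == "double_well":
            u = (z - p["center"]) / p["half_separation"]
            return p["barrier_height"] * (u * u - 1.0) ** 2
        if self.form == "translocation":
            return p["plateau_value"] + p["well_depth"] * self._shape(z)
        # tabulated: linear interpolation (flat extrapolation)
        return np.interp(z, self.table_z, self.table_u)

    def derivative(self, z):
        """dU/dz, vectorised over z."""
        z = np.asarray(z, dtype=float)
        p = self.params
        if self.form == "harmonic":
            return p["spring_constant"] * (z - p["center"])
        if self.form == "double_well":
            a = p["half_separation"]
            u = (z - p["center"]) / a
            return 4.0 * p["barrier_height"] * u * (u * u - 1.0) / a
        if self.form == "translocation":
            return p["well_depth"] * self._shape_derivative(z)
        dz = np.gradient(self.table_u, self.table_z)
        return np.interp(z, self.table_z, dz)

    # -- translocation shape ------------------------------------------------ #
    # g(z) = smoothstep(matrix->solvent) * Gaussian well envelope, scaled so
    # that min g = -? ... the profile attains exactly well_depth at its
    # minimum and exactly plateau_value on the solvent side (the smoothstep
    # has compact support, so the plateau is flat to machine precision).

    def _shape(self, z):
        p = self.params
        ic, w = p["interface_center"], p["interface_width"]
        u = np.clip((z - (ic - w)) / (2.0 * w), 0.0, 1.0)
        s = 1.0 - u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
        env = np.exp(-0.5 * ((z - p["well_center"]) / p["well_sigma"]) ** 2)
        return s * env / p["_norm"]

    def _shape_derivative(self, z):
        p = self.params
        ic, w = p["interface_center"], p["interface_width"]
        u = np.clip((z - (ic - w)) / (2.0 * w), 0.0, 1.0)
        s = 1.0 - u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
        ds = -30.0 * u * u * (1.0 - u) ** 2 / (2.0 * w)
        x = (z - p["well_center"]) / p["well_sigma"]
        env = np.exp(-0.5 * x * x)
        denv = -x / p["well_sigma"] * env
        return (ds * env + s * denv) / p["_norm"]

    # -- kernel plumbing ---------------------------------------------------- #

    def _kernel_args(self):
        fid = _FORM_IDS[self.form]
        p = self.params
        if self.form == "harmonic":
            vec = np.array([p["spring_constant"], p["center"], 0.0, 0.0, 0.0, 0.0])
        elif self.form == "double_well":
            vec = np.array(
                [p["barrier_height"], p["half_separation"], p["center"], 0.0, 0.0, 0.0]
            )
        elif self.form == "translocation":
            vec = np.array(
                [
                    p["well_depth"] / p["_norm"],
                    p["well_center"],
                    p["well_sigma"],
                    p["interface_center"],
                    p["interface_width"],
                    0.0,
                ]
            )
        else:
            vec = np.zeros(6)
        tz = self.table_z if self.table_z is not None else np.zeros(2)
        tu = self.table_u if self.table_u is not None else np.zeros(2)
        if self.form == "tabulated":
            tu = np.gradient(self.table_u, self.table_z)  # kernel needs dU/dz
        return fid, vec, np.asarray(tz, float), np.asarray(tu, float)


def harmonic_potential(spring_constant: float, center: float = 0.0) -> PotentialSpec:
    """U(z) = 1/2 k (z - c)^2."""
    if spring_constant < 0:
        raise ValueError("spring_constant must be >= 0")
    return PotentialSpec("harmonic", {"spring_constant": spring_constant, "center": center})


def double_well_potential(
    barrier_height: float, half_separation: float, center: float = 0.0
) -> PotentialSpec:
    """Symmetric quartic double well with minima at center +- half_separation.

    U(z) = h * (((z-c)/a)^2 - 1)^2; the barrier between the two minima is
    exactly ``barrier_height``.
    """
    if barrier_height < 0:
        raise ValueError("barrier_height must be >= 0")
    if half_separation <= 0:
        raise ValueError("half_separation must be > 0")
    return PotentialSpec(
        "double_well",
        {
            "barrier_height": barrier_height,
            "half_separation": half_separation,
            "center": center,
        },
    )


def make_translocation_potential(
    well_depth: float,
    well_center: float,
    interface_center: float,
    interface_width: float,
    plateau_value: float = 0.0,
    well_sigma: float = 1.5,
) -> PotentialSpec:
    """Analytic matrix->water translocation profile.

    A localized free-energy well of depth ``well_depth`` (<= 0) at
    ``well_center`` inside the polymer matrix, rising across the matrix-water
    interface (``interface_center`` +- ``interface_width``) to a flat aqueous
    plateau at ``plateau_value``.  ``well_sigma`` sets the Gaussian breadth of
    the well region.  The profile equals ``plateau_value`` exactly on the
    solvent side and ``plateau_value + well_depth`` exactly at its minimum.
    """
    if well_depth > 0:
        raise ValueError(f"well_depth must be <= 0 (a well), got {well_depth}")
    if interface_width <= 0:
        raise ValueError("interface_width must be > 0")
    if well_sigma <= 0:
        raise ValueError("well_sigma must be > 0")
    params = {
        "well_depth": well_depth,
        "well_center": well_center,
        "well_sigma": well_sigma,
        "interface_center": interface_center,
        "interface_width": interface_width,
        "plateau_value": plateau_value,
        "_norm": 1.0,
    }
    spec = PotentialSpec("translocation", params)
    if well_depth < 0:
        # normalise so the global minimum is exactly plateau + well_depth
        from scipy.optimize import minimize_scalar

        zg = np.linspace(
            well_center - 8 * well_sigma, interface_center + interface_width, 20001
        )
        i = int(np.argmax(spec._shape(zg)))
        lo = zg[max(i - 1, 0)]
        hi = zg[min(i + 1, zg.size - 1)]
        res = minimize_scalar(
            lambda z: -float(spec._shape(np.array([z]))[0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        params = dict(params)
        params["_norm"] = -float(res.fun)
        spec = PotentialSpec("translocation", params)
    return spec


def tabulated_potential(z: Sequence[float], u: Sequence[float]) -> PotentialSpec:
    """Piecewise-linear potential from a table; abscissa must be strictly increasing."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.ndim != 1 or z.shape != u.shape or z.size < 2:
        raise ValueError("z and u must be matching 1D arrays with >= 2 points")
    if not np.all(np.diff(z) > 0):
        raise ValueError("tabulated abscissa must be strictly increasing")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(u))):
        raise ValueError("tabulated potential must be finite")
    return PotentialSpec("tabulated", {}, table_z=z, table_u=u)


# --------------------------------------------------------------------------- #
# Langevin dynamics
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class LangevinConfig:
    """Parameters of an overdamped Langevin run.

    diffusion_coeff is in nm^2/ps, timestep in ps.  ``domain`` bounds trigger
    a :class:`DivergenceError` naming the offending step when escaped.
    """

    n_steps: int
    seed: int
    temperature: float = DEFAULT_TEMPERATURE
    diffusion_coeff: float = 2.0e-3
    timestep: float = 2.0e-3
    initial_position: float = 0.0
    domain: tuple = (-math.inf, math.inf)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.diffusion_coeff <= 0:
            raise ValueError("diffusion_coeff must be > 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not self.domain[0] < self.domain[1]:
            raise ValueError("domain must be an increasing (lo, hi) pair")


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella bias w(z) = 1/2 k (z - center)^2."""

    center: float
    spring_constant: float

    def __post_init__(self):
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")

    def energy(self, z):
        return 0.5 * self.spring_constant * (np.asarray(z, float) - self.center) ** 2

    def derivative(self, z):
        return self.spring_constant * (np.asarray(z, float) - self.center)


@dataclass(frozen=True)
class Trajectory1D:
    times: np.ndarray  # ps
    positions: np.ndarray  # nm

    def __post_init__(self):
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@njit(cache=False)
def _potential_force(fid, pvec, tz, tdu, z):  # dU/dz at scalar z
    if fid == 0:
        return pvec[0] * (z - pvec[1])
    if fid == 1:
        u = (z - pvec[2]) / pvec[1]
        return 4.0 * pvec[0] * u * (u * u - 1.0) / pvec[1]
    if fid == 2:
        scaled_depth, zc, sig, ic, w = pvec[0], pvec[1], pvec[2], pvec[3], pvec[4]
        u = (z - (ic - w)) / (2.0 * w)
        if u < 0.0:
            u = 0.0
        elif u > 1.0:
            u = 1.0
        s = 1.0 - u * u * u * (10.0 + u * (-15.0 + 6.0 * u))
        ds = -30.0 * u * u * (1.0 - u) * (1.0 - u) / (2.0 * w)
        x = (z - zc) / sig
        env = math.exp(-0.5 * x * x)
        return scaled_depth * (ds * env - s * x / sig * env)
    # tabulated derivative table, flat extrapolation
    n = tz.shape[0]
    if z <= tz[0]:
        return tdu[0]
    if z >= tz[n - 1]:
        return tdu[n - 1]
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tz[mid] <= z:
            lo = mid
        else:
            hi = mid
    f = (z - tz[lo]) / (tz[lo + 1] - tz[lo])
    return tdu[lo] * (1.0 - f) + tdu[lo + 1] * f


@njit(cache=False)
def _em_chunk(
    fid, pvec, tz, tdu, z, centers, spring, betaD_dt, sigma_step, noise,
    lo, hi, out, step0, equil, stride,
):
    """Advance all walkers through one noise chunk; record strided samples.

    Returns (error_step, error_walker) or (-1, -1) on success.
    """
    n_chunk = noise.shape[0]
    n_w = z.shape[0]
    for i in range(n_chunk):
        step = step0 + i
        for j in range(n_w):
            zj = z[j]
            grad = _potential_force(fid, pvec, tz, tdu, zj)
            if spring[j] > 0.0:
                grad += spring[j] * (zj - centers[j])
            zj = zj - betaD_dt * grad + sigma_step * noise[i, j]
            if not (lo <= zj <= hi) or zj != zj:
                return step, j
            z[j] = zj
        k = step - equil
        if k >= 0 and k % stride == 0:
            idx = k // stride
            if idx < out.shape[0]:
                for j in range(n_w):
                    out[idx, j] = z[j]
    return -1, -1


def _run_windows(
    potential: PotentialSpec,
    centers: np.ndarray,
    springs: np.ndarray,
    config: LangevinConfig,
    initial: np.ndarray,
    n_record: int,
    equil: int,
    stride: int,
    chunk: int = 50_000,
) -> np.ndarray:
    """Shared driver: simulate len(centers) independent walkers, return
    recorded positions with shape (n_record, n_walkers)."""
    fid, pvec, tz, tdu = potential._kernel_args()
    b = beta(config.temperature)
    betaD_dt = b * config.diffusion_coeff * config.timestep
    sigma_step = math.sqrt(2.0 * config.diffusion_coeff * config.timestep)
    n_total = equil + n_record * stride
    z = np.array(initial, dtype=float).copy()
    out = np.empty((n_record, len(z)), dtype=float)
    gens = [
        np.random.default_rng(c)
        for c in np.random.SeedSequence(config.seed).spawn(len(z))
    ]
    lo, hi = config.domain
    step0 = 0
    while step0 < n_total:
        m = min(chunk, n_total - step0)
        noise = np.empty((m, len(z)))
        for j, g in enumerate(gens):
            noise[:, j] = g.standard_normal(m)
        err_step, err_walker = _em_chunk(
            fid, pvec, tz, tdu, z, centers, springs, betaD_dt, sigma_step,
            noise, lo, hi, out, step0, equil, stride,
        )
        if err_step >= 0:
            raise DivergenceError(
                f"walker {err_walker} left domain [{lo}, {hi}] "
                f"(or became non-finite) at step {err_step + 1}"
            )
        step0 += m
    return out


def simulate_langevin(
    potential: PotentialSpec,
    bias: Optional[BiasSpec],
    config: LangevinConfig,
) -> Trajectory1D:
    """Overdamped Euler--Maruyama trajectory under potential (+ optional bias).

    The returned trajectory includes the initial position at t = 0 followed by
    ``config.n_steps`` updates; identical config (seed included) yields a
    bit-identical trajectory.
    """
    center = bias.center if bias is not None else 0.0
    spring = bias.spring_constant if bias is not None else 0.0
    pos = _run_windows(
        potential,
        centers=np.array([center]),
        springs=np.array([spring]),
        config=config,
        initial=np.array([config.initial_position]),
        n_record=config.n_steps,
        equil=0,
        stride=1,
    )[:, 0]
    times = np.arange(config.n_steps + 1) * config.timestep
    positions = np.concatenate(([config.initial_position], pos))
    return Trajectory1D(times=times, positions=positions)


def generate_umbrella_dataset(
    potential: PotentialSpec,
    window_centers: Optional[Sequence[float]],
    spring: float,
    config: LangevinConfig,
    equilibration_steps: int = 2000,
    sample_stride: int = 1,
):
    """Umbrella-sampling dataset: one biased trajectory per window.

    Default geometry (``window_centers=None``) follows the standard pulling
    protocol: 60 windows at 0.2 nm spacing starting at
    ``config.initial_position``.  Each window starts at its bias center and is
    seeded independently and reproducibly from ``(config.seed, window index)``
    via :class:`numpy.random.SeedSequence` spawning.  ``config.n_steps``
    production steps are run per window after ``equilibration_steps`` discarded
    steps; every ``sample_stride``-th position is kept as a sample.
    """
    from .umbrella_wham import UmbrellaWindow, WindowSet

    if window_centers is None:
        window_centers = config.initial_position + 0.2 * np.arange(60)
    centers = np.asarray(window_centers, dtype=float)
    if centers.size == 0:
        raise ValueError("window_centers must be non-empty")
    if np.any(np.diff(centers) < 0):
        raise ValueError("window_centers must be sorted")
    if spring < 0:
        raise ValueError("spring must be >= 0")
    n_samples = config.n_steps // sample_stride
    if n_samples < 1:
        raise ValueError("n_steps // sample_stride must be >= 1")
    samples = _run_windows(
        potential,
        centers=centers,
        springs=np.full(centers.shape, float(spring)),
        config=config,
        initial=centers.copy(),
        n_record=n_samples,
        equil=equilibration_steps,
        stride=sample_stride,
    )
    windows = [
        UmbrellaWindow(
            center=float(c), spring_constant=float(spring), samples=samples[:, j].copy()
        )
        for j, c in enumerate(centers)
    ]
    return WindowSet(windows=windows, temperature=config.temperature)


# --------------------------------------------------------------------------- #
# Alchemical (lambda-scaled) sampling
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class AlchemicalDataset:
    """Planted-truth multi-state dataset for free-energy estimators.

    ``umatrix`` is the K x N reduced-potential matrix; ``true_delta_g`` is the
    quadrature end-to-end free-energy difference in kJ/mol (the planted truth).
    """

    umatrix: "object"  # alchemical_mbar.ReducedPotentialMatrix
    samples: np.ndarray
    lambdas: np.ndarray
    true_delta_g: float


def generate_alchemical_dataset(
    lambdas: Sequence[float],
    n_samples_per_state: int,
    seed: int,
    temperature: float = 300.0,
    restraint_k: float = 100.0,
    well_amplitude: float = 10.0,
    well_sigma: float = 0.3,
) -> AlchemicalDataset:
    """Exact samples of a particle in a lambda-scaled attractive well.

    State lambda has energy  U_l(x) = 1/2 k_r x^2 - l * A exp(-x^2 / 2 s^2):
    a harmonic restraint keeps every state normalisable while the attractive
    well is switched on with the coupling parameter.  Sampling is exact
    rejection sampling (envelope: the restraint Gaussian; acceptance
    exp(-beta*l*(V_w - V_w_min)) <= 1), so the only error downstream
    estimators see is statistical.  The planted truth is the quadrature
    free-energy difference between the first and last states.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.ndim != 1 or lambdas.size < 2:
        raise ValueError("need at least two lambda states")
    if n_samples_per_state < 1:
        raise ValueError("n_samples_per_state must be >= 1")
    from .alchemical_mbar import ReducedPotentialMatrix

    b = beta(temperature)
    sd = math.sqrt(1.0 / (b * restraint_k))

    def vwell(x):
        return -well_amplitude * np.exp(-0.5 * (x / well_sigma) ** 2)

    def energy(x, lam):
        return 0.5 * restraint_k * x * x + lam * vwell(x)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    all_samples = []
    for lam in lambdas:
        got: list = []
        while len(got) < n_samples_per_state:
            m = max(2 * (n_samples_per_state - len(got)), 64)
            x = rng.normal(0.0, sd, size=m)
            # V_w in [-A, 0]; accept with exp(-beta*lam*(V_w + A)) <= 1
            p_acc = np.exp(-b * lam * (vwell(x) + well_amplitude))
            keep = x[rng.random(m) < p_acc]
            got.extend(keep.tolist())
        all_samples.append(np.array(got[:n_samples_per_state]))
    x_all = np.concatenate(all_samples)
    u = np.empty((lambdas.size, x_all.size))
    for k, lam in enumerate(lambdas):
        u[k] = b * energy(x_all, lam)
    n_k = np.full(lambdas.size, n_samples_per_state, dtype=int)
    umat = ReducedPotentialMatrix(u=u, counts=n_k, temperature=temperature)
    # quadrature truth
    xg = np.linspace(-8 * sd, 8 * sd, 40001)
    z0 = np.trapezoid(np.exp(-b * energy(xg, lambdas[0])), xg)
    z1 = np.trapezoid(np.exp(-b * energy(xg, lambdas[-1])), xg)
    true_dg = -KB * temperature * math.log(z1 / z0)
    return AlchemicalDataset(
        umatrix=umat, samples=x_all, lambdas=lambdas, true_delta_g=true_dg
    )


# --------------------------------------------------------------------------- #
# Bonded-coordinate Boltzmann ensembles
# --------------------------------------------------------------------------- #


def sample_bonded_ensemble(params, n: int, temperature: float, seed: int) -> np.ndarray:
    """Draw n samples from the 1D Boltzmann density exp(-beta V) of a bonded term.

    ``params`` is a :class:`pmfrelease.cg_fit.BondedParams`.  Harmonic terms
    are sampled exactly (the Boltzmann density of 1/2 k (x - x0)^2 is a
    Gaussian; angles are restricted to [0, 180] deg and dihedrals wrapped to
    (-180, 180] deg by rejection/wrapping).  Harmonic-cosine terms
    V = 1/2 k (cos t - cos t0)^2 are sampled by rejection against a uniform
    envelope on [0, 180] deg, with acceptance exp(-beta V) <= 1.  Degrees are
    used for angular values; force constants are per nm^2 (bond) or per rad^2
    (angles/dihedrals).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.force_constant <= 0:
        raise ValueError("force_constant must be > 0")
    b = beta(temperature)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kind = params.kind
    form = params.functional_form
    if form == "harmonic":
        if kind == "bond":
            sd = math.sqrt(1.0 / (b * params.force_constant))
            return rng.normal(params.equilibrium_value, sd, size=n)
        # angular: k is per rad^2, values in degrees
        sd_deg = math.degrees(math.sqrt(1.0 / (b * params.force_constant)))
        out = np.empty(0)
        while out.size < n:
            x = rng.normal(params.equilibrium_value, sd_deg, size=2 * (n - out.size) + 8)
            if kind == "angle":
                x = x[(x >= 0.0) & (x <= 180.0)]
            else:  # dihedral: periodic wrap
                x = (x + 180.0) % 360.0 - 180.0
            out = np.concatenate([out, x])
        return out[:n]
    if form != "harmonic_cosine":
        raise ValueError(f"unknown functional form {form!r}")
    cos0 = math.cos(math.radians(params.equilibrium_value))
    out = np.empty(0)
    while out.size < n:
        m = 4 * (n - out.size) + 64
        theta = rng.uniform(0.0, 180.0, size=m)
        v = 0.5 * params.force_constant * (np.cos(np.radians(theta)) - cos0) ** 2
        keep = theta[rng.random(m) < np.exp(-b * v)]
        out = np.concatenate([out, keep])
    return out[:n]


# --------------------------------------------------------------------------- #
# Release curves
# --------------------------------------------------------------------------- #


def generate_release_curve(K: float, n: float, times, noise_sigma: float, seed: int):
    """Power-law release curve M_t/M_inf = clip(K t^n + eps, 0, 1), eps ~ N(0, sigma)."""
    from .release_kinetics import ReleaseCurve

    times = np.asarray(times, dtype=float)
    if K <= 0 or n <= 0:
        raise ValueError("K and n must be > 0")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    frac = K * np.power(times, n)
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        frac = frac + rng.normal(0.0, noise_sigma, size=times.shape)
    frac = np.clip(frac, 0.0, 1.0)
    frac[times == 0] = 0.0  # t = 0 releases nothing regardless of noise
    return ReleaseCurve(times=times, fraction_released=frac)


# --------------------------------------------------------------------------- #
# Particle configurations with planted clusters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ParticleConfiguration:
    """Point particles in an (optionally periodic) orthorhombic box."""

    positions: np.ndarray  # (n, 3) nm
    box: np.ndarray  # (3,) edge lengths nm
    periodic: bool = True

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if box.shape != (3,) or np.any(box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.periodic and (np.any(pos < 0) or np.any(pos >= box)):
            raise ValueError("wrapped positions must lie inside the box")


@dataclass(frozen=True)
class PlantedConfiguration:
    """A configuration plus its ground-truth cluster partition."""

    configuration: ParticleConfiguration
    true_sizes: tuple
    true_labels: np.ndarray


def generate_particle_config(
    cluster_sizes: Sequence[int],
    intra_spacing: float,
    inter_separation: float,
    box,
    seed: int,
    straddle_boundary: bool = False,
) -> PlantedConfiguration:
    """Plant clusters of the given sizes in a periodic box.

    Cluster members are chained at ``intra_spacing`` (so any cutoff >
    intra_spacing joins them by single linkage); cluster centroids sit on a
    3D grid whose spacing guarantees a minimum-image gap of at least
    ``inter_separation`` between particles of different clusters.  With
    ``straddle_boundary`` the first cluster is translated onto a box corner so
    it wraps across the periodic boundary.  The ground-truth partition under
    any cutoff in (intra_spacing, inter_separation) is exactly
    ``cluster_sizes``.
    """
    sizes = [int(s) for s in cluster_sizes]
    if len(sizes) == 0 or any(s < 1 for s in sizes):
        raise ValueError("cluster_sizes must be positive counts")
    if intra_spacing <= 0 or inter_separation <= intra_spacing:
        raise ValueError("need 0 < intra_spacing < inter_separation")
    box = np.asarray(box, dtype=float) * np.ones(3)
    # chains are centred on their centroid, so each cluster extends at most
    # half its contour length from its grid point
    extent = 0.5 * (max(sizes) - 1) * intra_spacing
    pitch = inter_separation + 2.0 * extent
    n_cells = np.floor(box / pitch).astype(int)
    if np.prod(n_cells) < len(sizes):
        raise ValueError(
            f"cannot place {len(sizes)} clusters with pitch {pitch:.3g} nm "
            f"in a {box} nm box"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cells = [
        (i, j, k)
        for i in range(n_cells[0])
        for j in range(n_cells[1])
        for k in range(n_cells[2])
    ]
    positions = []
    labels = []
    for ci, size in enumerate(sizes):
        cell = np.array(cells[ci], dtype=float)
        center = (cell + 0.5) * (box / n_cells)
        chain = [np.zeros(3)]
        for _ in range(size - 1):
            step = rng.normal(size=3)
            step *= intra_spacing / np.linalg.norm(step)
            chain.append(chain[-1] + step)
        chain = np.array(chain)
        chain = chain - chain.mean(axis=0) + center
        positions.extend(chain)
        labels.extend([ci] * size)
    positions = np.array(positions).reshape(len(labels), 3)
    if straddle_boundary:
        # center the first cluster's centroid on the box origin corner so its
        # members wrap across the periodic boundary
        positions = positions - positions[: sizes[0]].mean(axis=0)
    positions = np.mod(positions, box)
    config = ParticleConfiguration(positions=positions, box=box, periodic=True)
    return PlantedConfiguration(
        configuration=config,
        true_sizes=tuple(sorted(sizes, reverse=True)),
        true_labels=np.array(labels),
    )
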