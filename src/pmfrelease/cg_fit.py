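"""Coarse-grained bonded-parameter fitting by distribution matching.

Maps fine-grained (e.g. united-atom) trajectories onto bead centers of mass,
extracts bond/angle/dihedral distributions between bonded beads, fits
harmonic and harmonic-cosine parameters by Boltzmann inversion (equilibrium
value from the distribution mean, force constant from its width), and
iteratively refines the parameters so a coarse-grained resampling reproduces
the target distribution widths — the standard bottom-up parametrisation
workflow for bead force fields.

Conventions: lengths in nm, angles and dihedrals in degrees; force constants
in kJ mol^-1 nm^-2 for bonds and kJ mol^-1 rad^-2 for angular terms (the
harmonic-cosine constant, acting on cos(theta), is in kJ/mol).  Dihedral
statistics are circular-aware, so distributions peaked at +-180 deg fit
without wrap artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import jensenshannon

from .constants import KB, beta

__all__ = [
    "MappingScheme",
    "BondedDistribution",
    "BondedParams",
    "FitReport",
    "StiffLimitError",
    "map_trajectory",
    "extract_distributions",
    "fit_bonded",
    "refine_iteratively",
]


class StiffLimitError(ValueError):
    """Distribution has (near-)zero width; use a constraint, not a spring."""


@dataclass(frozen=True)
class MappingScheme:
    """Bead definitions: (name, member atom indices, member masses)."""

    beads: Sequence[Tuple[str, Sequence[int], Sequence[float]]]

    def __post_init__(self):
        seen: set = set()
        for name, idx, masses in self.beads:
            if len(idx) != len(masses) or len(idx) == 0:
                raise ValueError(f"bead {name!r}: indices and masses must match and be non-empty")
            if any(m <= 0 for m in masses):
                raise ValueError(f"bead {name!r}: masses must be > 0")
            overlap = seen.intersection(idx)
            if overlap:
                raise ValueError(f"bead {name!r}: atoms {sorted(overlap)} already assigned")
            seen.update(idx)

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class BondedDistribution:
    """Histogrammed geometric values of one bonded term.

    ``values`` are nm (bond) or degrees (angle/dihedral); ``density``
    integrates to 1 over ``bin_edges``.  ``mean`` and ``width`` are circular
    for dihedrals.  ``n_excluded`` counts degenerate frames dropped.
    """

    kind: str  # bond | angle | dihedral
    values: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    mean: float
    width: float
    beads: Tuple[int, ...] = ()
    n_excluded: int = 0

    @property
    def zero_width(self) -> bool:
        return self.width < 1e-12


@dataclass(frozen=True)
class BondedParams:
    kind: str  # bond | angle | dihedral
    equilibrium_value: float  # nm or degrees
    force_constant: float  # kJ/mol/nm^2, kJ/mol/rad^2, or kJ/mol (harmonic_cosine)
    functional_form: str = "harmonic"  # harmonic | harmonic_cosine

    def __post_init__(self):
        if self.kind not in ("bond", "angle", "dihedral"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.functional_form not in ("harmonic", "harmonic_cosine"):
            raise ValueError(f"unknown functional form {self.functional_form!r}")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")


@dataclass
class FitReport:
    mismatch_before: List[float]
    mismatch_after: List[float]
    iterations: int
    converged: bool
    damping_events: int = 0


# --------------------------------------------------------------------------- #
# Mapping
# --------------------------------------------------------------------------- #


def map_trajectory(fine_positions: np.ndarray, mapping: MappingScheme) -> np.ndarray:
    """Mass-weighted bead centers of mass, frame by frame.

    fine_positions: (frames, atoms, 3) nm -> (frames, beads, 3) nm.
    """
    pos = np.asarray(fine_positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("fine_positions must have shape (frames, atoms, 3)")
    n_atoms = pos.shape[1]
    out = np.empty((pos.shape[0], mapping.n_beads, 3))
    for b, (name, idx, masses) in enumerate(mapping.beads):
        idx = np.asarray(idx, dtype=int)
        if np.any(idx < 0) or np.any(idx >= n_atoms):
            raise IndexError(f"bead {name!r}: atom index out of range (0..{n_atoms - 1})")
        m = np.asarray(masses, dtype=float)
        total = m.sum()
        if total <= 0:
            raise ValueError(f"bead {name!r}: zero total mass")
        out[:, b, :] = np.einsum("fai,a->fi", pos[:, idx, :], m) / total
    return out


# --------------------------------------------------------------------------- #
# Geometry and distributions
# --------------------------------------------------------------------------- #

_KIND_BY_ARITY = {2: "bond", 3: "angle", 4: "dihedral"}


def _bond_values(p):
    return np.linalg.norm(p[:, 1] - p[:, 0], axis=1)


def _angle_values(p):
    v1 = p[:, 0] - p[:, 1]
    v2 = p[:, 2] - p[:, 1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    cosang = np.full(p.shape[0], np.nan)
    cosang[ok] = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral_values(p):
    """Signed dihedral (deg) via the atan2 convention, in (-180, 180]."""
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    ok = (np.linalg.norm(n1, axis=1) > 1e-12) & (np.linalg.norm(n2, axis=1) > 1e-12)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / np.maximum(b2n, 1e-300)[:, None])
    phi = np.degrees(np.arctan2(y, x))
    phi[~ok] = np.nan
    # map -180 -> +180 for the (-180, 180] convention
    phi[phi <= -180.0] += 360.0
    return phi


def _circular_mean_deg(values):
    rad = np.radians(values)
    return math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))


def _circular_std_deg(values):
    rad = np.radians(values)
    r = math.hypot(float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad))))
    r = min(max(r, 1e-300), 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r)))


def _histogram(values, bins="fd"):
    if np.ptp(values) < 1e-12:
        edges = np.array([values[0] - 0.5e-6, values[0] + 0.5e-6])
        return edges, np.array([1.0 / np.diff(edges)[0]])
    density, edges = np.histogram(values, bins=bins, density=True)
    return edges, density


def extract_distributions(
    coarse_trajectory: np.ndarray,
    bonded_topology: Sequence[Sequence[int]],
    bins="fd",
) -> List[BondedDistribution]:
    """Per-term geometric time series and histograms from a bead trajectory.

    ``bonded_topology`` lists bead-index tuples of length 2 (bond), 3 (angle)
    or 4 (dihedral).  Frames with degenerate geometry (zero-length vectors)
    are excluded per term, with the count reported on the distribution.
    Histogram binning defaults to Freedman-Diaconis.
    """
    pos = np.asarray(coarse_trajectory, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("coarse_trajectory must have shape (frames, beads, 3)")
    out = []
    for tup in bonded_topology:
        tup = tuple(int(i) for i in tup)
        if len(tup) not in _KIND_BY_ARITY:
            raise ValueError(f"topology tuple {tup} must have length 2, 3 or 4")
        if max(tup) >= pos.shape[1] or min(tup) < 0:
            raise IndexError(f"bead index out of range in {tup}")
        kind = _KIND_BY_ARITY[len(tup)]
        p = pos[:, tup, :]
        if kind == "bond":
            vals = _bond_values(p)
        elif kind == "angle":
            vals = _angle_values(p)
        else:
            vals = _dihedral_values(p)
        bad = ~np.isfinite(vals)
        vals = vals[~bad]
        if vals.size == 0:
            raise ValueError(f"term {tup}: no non-degenerate frames")
        if kind == "dihedral":
            mean = _circular_mean_deg(vals)
            width = _circular_std_deg(vals)
        else:
            mean = float(np.mean(vals))
            width = float(np.std(vals))
        edges, density = _histogram(vals, bins=bins)
        out.append(
            BondedDistribution(
                kind=kind,
                values=vals,
                bin_edges=edges,
                density=density,
                mean=mean,
                width=width,
                beads=tup,
                n_excluded=int(bad.sum()),
            )
        )
    return out


# --------------------------------------------------------------------------- #
# Boltzmann-inversion fitting
# --------------------------------------------------------------------------- #


def fit_bonded(
    dist: BondedDistribution, form: str, temperature: float
) -> BondedParams:
    """Fit one bonded term by Boltzmann inversion.

    Harmonic (V = 1/2 k (x - x0)^2): x0 is the distribution mean (circular
    mean for dihedrals) and k = k_B T / var(x), with angular variances taken
    in rad^2 so angular force constants come out per rad^2.  Harmonic-cosine
    (V = 1/2 k (cos t - cos t0)^2): cos t0 is the mean of cos(t) and
    k = k_B T / var(cos t).  A zero-width distribution has no finite spring
    and raises :class:`StiffLimitError`.
    """
    if dist.zero_width:
        raise StiffLimitError(
            f"{dist.kind} distribution has zero width; replace the spring "
            "with a rigid constraint"
        )
    kT = KB * temperature
    if form == "harmonic":
        if dist.kind == "bond":
            var = float(np.var(dist.values))
            eq = dist.mean
        elif dist.kind == "dihedral":
            eq = _circular_mean_deg(dist.values)
            var = math.radians(_circular_std_deg(dist.values)) ** 2
        else:
            eq = dist.mean
            var = math.radians(float(np.std(dist.values))) ** 2
        return BondedParams(dist.kind, eq, kT / var, "harmonic")
    if form != "harmonic_cosine":
        raise ValueError(f"unknown functional form {form!r}")
    cosv = np.cos(np.radians(dist.values))
    var = float(np.var(cosv))
    if var < 1e-300:
        raise StiffLimitError("cos(theta) distribution has zero width")
    cos0 = float(np.clip(np.mean(cosv), -1.0, 1.0))
    eq = math.degrees(math.acos(cos0))
    return BondedParams(dist.kind, eq, kT / var, "harmonic_cosine")


def _width_and_mean(params: BondedParams, samples: np.ndarray):
    if params.kind == "dihedral":
        return _circular_std_deg(samples), _circular_mean_deg(samples)
    if params.functional_form == "harmonic_cosine":
        cosv = np.cos(np.radians(samples))
        return float(np.std(cosv)), float(np.mean(samples))
    return float(np.std(samples)), float(np.mean(samples))


def _target_width(params: BondedParams, target: BondedDistribution):
    if params.kind == "dihedral":
        return _circular_std_deg(target.values)
    if params.functional_form == "harmonic_cosine":
        return float(np.std(np.cos(np.radians(target.values))))
    return float(np.std(target.values))


def _mismatch(params: BondedParams, target: BondedDistribution, samples) -> float:
    """Jensen-Shannon distance between model and target histograms on the
    target's bins (out-of-range model mass folded into the end bins)."""
    edges = target.bin_edges
    h, _ = np.histogram(np.clip(samples, edges[0], edges[-1]), bins=edges)
    p = h / max(h.sum(), 1)
    q = target.density * np.diff(edges)
    q = q / q.sum()
    return float(jensenshannon(p, q, base=2.0))


def refine_iteratively(
    initial: Sequence[BondedParams],
    targets: Sequence[BondedDistribution],
    sampler: Optional[Callable[[BondedParams, int, float, int], np.ndarray]] = None,
    max_iter: int = 10,
    tol: float = 0.05,
    temperature: float = 310.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> Tuple[List[BondedParams], FitReport]:
    """Trial-and-error width matching of a set of bonded terms.

    Per iteration each term is re-sampled from the current parameters, then
    the force constant is rescaled by (width_current / width_target)^2 and
    the equilibrium value shifted by the mean residual.  The per-term
    mismatch metric is the Jensen-Shannon distance between model and target
    histograms; iteration stops when the worst mismatch drops below ``tol``.
    If the total mismatch rises twice in a row, subsequent updates are damped
    by half (recorded in the report).
    """
    if len(initial) != len(targets):
        raise ValueError("need one target distribution per parameter set")
    if sampler is None:
        from .toy_sim import sample_bonded_ensemble as sampler  # noqa: F811
    params = list(initial)
    damp = 1.0
    damping_events = 0
    rises = 0
    prev_total = None
    mismatch_before = None
    mism = []
    it = 0
    for it in range(1, max_iter + 1):
        mism = []
        new_params = []
        for t, (p, target) in enumerate(zip(params, targets)):
            samples = sampler(p, n_samples, temperature, seed + 1000 * it + t)
            mism.append(_mismatch(p, target, samples))
            w_cur, m_cur = _width_and_mean(p, samples)
            w_tgt = _target_width(p, target)
            ratio = (w_cur / w_tgt) ** 2 if w_tgt > 0 else 1.0
            k_new = p.force_constant * ratio**damp
            shift = target.mean - m_cur
            if p.kind == "dihedral":
                shift = (shift + 180.0) % 360.0 - 180.0
            eq_new = p.equilibrium_value + damp * shift
            if p.kind == "dihedral":
                eq_new = (eq_new + 180.0) % 360.0 - 180.0
            new_params.append(
                BondedParams(p.kind, eq_new, k_new, p.functional_form)
            )
        if mismatch_before is None:
            mismatch_before = list(mism)
        total = float(np.sum(mism))
        if prev_total is not None and total > prev_total:
            rises += 1
            if rises >= 2:
                damp *= 0.5
                damping_events += 1
                rises = 0
        else:
            rises = 0
        prev_total = total
        if max(mism) < tol:
            return params, FitReport(
                mismatch_before, list(mism), it - 1, True, damping_events
            )
        params = new_params
    # final evaluation
    final = [
        _mismatch(p, target, sampler(p, n_samples, temperature, seed + 999_999 + t))
        for t, (p, target) in enumerate(zip(params, targets))
    ]
    return params, FitReport(
        mismatch_before or [], final, it, max(final) < tol, damping_events
    )
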