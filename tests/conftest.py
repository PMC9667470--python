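"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pmfrelease.constants import KB
from pmfrelease.umbrella_wham import UmbrellaWindow, WindowSet


# --------------------------------------------------------------------------- #
# Independent oracles (deliberately simple, O(n^2) where applicable)
# --------------------------------------------------------------------------- #


def brute_force_clusters(positions, box, cutoff, periodic=True):
    """O(n^2) minimum-image single-linkage clustering via union-find."""
    n = positions.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            if periodic:
                d = d - box * np.round(d / box)
            if np.sqrt(np.dot(d, d)) <= cutoff:
                union(i, j)
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    for r in np.unique(roots):
        members = np.flatnonzero(roots == r)
        labels[members] = members.min()
    sizes = tuple(sorted(np.bincount(labels)[np.unique(labels)], reverse=True))
    return labels, sizes


def boltzmann_quadrature(energy_fn, lo, hi, temperature, n=20001):
    """Normalised Boltzmann density and CDF of a 1D potential by quadrature."""
    x = np.linspace(lo, hi, n)
    w = np.exp(-energy_fn(x) / (KB * temperature))
    z = np.trapezoid(w, x)
    pdf = w / z
    cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(x))))
    cdf /= cdf[-1]
    return x, pdf, cdf


def sample_biased_boltzmann(potential, center, spring, temperature, n, rng):
    """Exact iid samples of exp(-beta (U + bias)) by rejection against the
    bias Gaussian — a sampling oracle independent of the Langevin engine."""
    b = 1.0 / (KB * temperature)
    sd = np.sqrt(1.0 / (b * spring))
    lo, hi = center - 8 * sd, center + 8 * sd
    xg = np.linspace(lo, hi, 4001)
    umin = float(np.min(potential.energy(xg)))
    out = np.empty(0)
    while out.size < n:
        m = 4 * (n - out.size) + 64
        x = rng.normal(center, sd, size=m)
        p = np.exp(-b * (potential.energy(x) - umin))
        out = np.concatenate([out, x[rng.random(m) < p]])
    return out[:n]


def make_iid_window_set(potential, centers, spring, temperature, n_per_window, seed):
    """WindowSet with exact iid biased Boltzmann samples per window."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    windows = [
        UmbrellaWindow(
            center=float(c),
            spring_constant=spring,
            samples=sample_biased_boltzmann(
                potential, float(c), spring, temperature, n_per_window, rng
            ),
        )
        for c in centers
    ]
    return WindowSet(windows=windows, temperature=temperature)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
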