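"""Tests of the WHAM free-energy reconstruction and barrier extraction."""

import numpy as np
import pytest
from scipy.stats import norm

from pmfrelease.constants import KB
from pmfrelease.toy_sim import (
    double_well_potential,
    make_translocation_potential,
    tabulated_potential,
)
from pmfrelease.umbrella_wham import (
    DisconnectedWindowsError,
    PMFProfile,
    UmbrellaWindow,
    WhamConvergenceError,
    WindowSet,
    bootstrap_pmf_error,
    check_overlap,
    extract_barrier,
    wham,
)

from conftest import make_iid_window_set

T = 310.0


def _align_rmse(prof, potential):
    """RMSE between the profile and the generating potential over populated
    bins, after removing the arbitrary common offset."""
    m = prof.populated
    d = prof.free_energy[m] - potential.energy(prof.z_grid[m])
    d = d - d.mean()
    return float(np.sqrt(np.mean(d**2)))


class TestWham:
    def test_flat_potential_single_window_is_constant(self, rng):
        samples = rng.uniform(0.0, 2.0, size=100_000)
        ws = WindowSet(
            windows=[UmbrellaWindow(1.0, 0.0, samples)], temperature=T
        )
        prof = wham(ws, bin_width=0.05, reference_region=(0.1, 1.9))
        # interior bins only: the outermost bins are partially covered by the
        # finite sample support and are censored, not flat
        g = prof.free_energy[prof.populated][1:-1]
        assert np.max(np.abs(g)) < 0.15  # a few per-bin standard errors

    def test_double_well_recovery_iid(self):
        """WHAM on exact iid window samples recovers the analytic double well."""
        pot = double_well_potential(10.0, 1.5)
        centers = np.arange(-2.4, 2.41, 0.2)
        ws = make_iid_window_set(pot, centers, 1000.0, T, 6000, seed=31)
        prof = wham(ws, bin_width=0.05)
        assert _align_rmse(prof, pot) < 0.5

    def test_shift_and_translation_invariance(self):
        """A constant energy offset and a rigid coordinate shift leave the
        referenced profile unchanged."""
        pot = double_well_potential(6.0, 1.0)
        centers = np.arange(-1.6, 1.61, 0.2)
        ws = make_iid_window_set(pot, centers, 1000.0, T, 2000, seed=32)
        prof = wham(ws, bin_width=0.05, reference_region=(-2.0, 2.0))
        shifted = WindowSet(
            windows=[
                UmbrellaWindow(w.center + 1.3, w.spring_constant, w.samples + 1.3)
                for w in ws.windows
            ],
            temperature=T,
        )
        prof2 = wham(shifted, bin_width=0.05, reference_region=(-0.7, 3.3))
        np.testing.assert_allclose(
            prof2.free_energy[prof2.populated],
            prof.free_energy[prof.populated],
            atol=1e-8,
        )

    def test_oracle_equivalence_on_random_potentials(self):
        """On several random smooth landscapes the reconstruction error stays
        below 3x the bootstrap standard error."""
        rng = np.random.default_rng(33)
        for trial in range(5):
            zt = np.linspace(-2.5, 2.5, 201)
            coeffs = rng.normal(0, 1.5, size=3)
            ut = sum(
                c * np.sin((k + 1) * np.pi * zt / 2.5) for k, c in enumerate(coeffs)
            )
            pot = tabulated_potential(zt, ut)
            centers = np.arange(-2.0, 2.01, 0.2)
            ws = make_iid_window_set(pot, centers, 1000.0, T, 1500, seed=100 + trial)
            prof = bootstrap_pmf_error(ws, n_boot=12, seed=200 + trial, bin_width=0.05)
            rmse = _align_rmse(prof, pot)
            med_se = float(np.nanmedian(prof.stderr[prof.populated]))
            assert rmse < 3.0 * max(med_se, 0.05)

    def test_sample_size_consistency(self):
        """Recovered well depth bias shrinks as samples per window grow."""
        pot = make_translocation_potential(-20.0, 0.5, 2.0, 0.5, well_sigma=0.8)
        centers = np.arange(-0.4, 3.61, 0.2)
        errs = []
        for n in (200, 1000, 5000):
            devs = []
            for seed in range(4):
                ws = make_iid_window_set(pot, centers, 1000.0, T, n, seed=40 + seed)
                prof = wham(ws, bin_width=0.05, reference_region=(2.9, 3.6))
                bar = extract_barrier(prof)
                devs.append(bar.delta_g - (-20.0))
            errs.append(np.mean(np.abs(devs)))
        assert errs[2] < errs[0]

    def test_scf_history_monotone_after_burn_in(self):
        pot = double_well_potential(4.0, 0.8)
        centers = np.arange(-1.2, 1.21, 0.2)
        ws = make_iid_window_set(pot, centers, 1000.0, T, 1000, seed=35)
        prof = wham(ws, bin_width=0.05, tol=1e-6, method="scf")
        hist = np.array(prof.info["df_history"][10:])
        assert np.all(np.diff(hist) <= 1e-12)

    def test_nonconvergence_returns_history(self):
        pot = double_well_potential(8.0, 1.0)
        centers = np.arange(-1.6, 1.61, 0.2)
        ws = make_iid_window_set(pot, centers, 1000.0, T, 500, seed=36)
        with pytest.raises(WhamConvergenceError) as err:
            wham(ws, tol=1e-14, max_iter=3, method="scf")
        assert len(err.value.df_history) == 3

    def test_disconnected_windows_raise(self):
        w1 = UmbrellaWindow(0.0, 1000.0, np.random.default_rng(1).normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(5.0, 1000.0, np.random.default_rng(2).normal(5.0, 0.05, 500))
        ws = WindowSet(windows=[w1, w2], temperature=T)
        with pytest.raises(DisconnectedWindowsError):
            with pytest.warns(UserWarning):
                wham(ws)


class TestOverlap:
    def test_identical_windows_overlap_fully(self, rng):
        s = rng.normal(0.0, 0.05, 5000)
        ws = WindowSet(
            windows=[UmbrellaWindow(0.0, 1000.0, s), UmbrellaWindow(0.0, 1000.0, s)],
            temperature=T,
        )
        rep = check_overlap(ws)
        assert rep.fractions[0] == pytest.approx(1.0)

    def test_disjoint_supports_flagged(self, rng):
        ws = WindowSet(
            windows=[
                UmbrellaWindow(0.0, 1000.0, rng.uniform(0.0, 0.5, 1000)),
                UmbrellaWindow(5.0, 1000.0, rng.uniform(5.0, 5.5, 1000)),
            ],
            temperature=T,
        )
        rep = check_overlap(ws, bin_width=0.05)
        assert rep.fractions[0] == 0.0
        assert rep.flagged == [(0, 1)]

    def test_gaussian_pair_matches_quadrature(self, rng):
        """sigma = 0.05 nm Gaussians 0.2 nm apart: intersection = 2 Phi(-2)."""
        ws = WindowSet(
            windows=[
                UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.05, 400_000)),
                UmbrellaWindow(0.2, 1000.0, rng.normal(0.2, 0.05, 400_000)),
            ],
            temperature=T,
        )
        rep = check_overlap(ws, bin_width=0.01)
        expected = 2 * norm.cdf(-2.0)
        assert rep.fractions[0] == pytest.approx(expected, abs=0.006)


class TestBootstrap:
    def test_zero_variance_samples_give_zero_stderr(self):
        wins = [UmbrellaWindow(1.0, 1000.0, np.full(50, 1.0)) for _ in range(3)]
        ws = WindowSet(windows=wins, temperature=T)
        prof = bootstrap_pmf_error(
            ws, n_boot=4, seed=1, reference_region=(0.9, 1.1)
        )
        assert np.all(prof.stderr[prof.populated] == 0.0)

    def test_stderr_nonnegative_and_scales_with_sample_size(self):
        pot = double_well_potential(5.0, 1.0)
        centers = np.arange(-1.6, 1.61, 0.2)
        med = []
        for n in (800, 1600):
            ses = []
            for seed in range(3):
                ws = make_iid_window_set(pot, centers, 1000.0, T, n, seed=50 + seed)
                prof = bootstrap_pmf_error(ws, n_boot=16, seed=60 + seed)
                assert np.all(prof.stderr[prof.populated] >= 0.0)
                ses.append(np.nanmedian(prof.stderr[prof.populated]))
            med.append(np.mean(ses))
        # doubling the samples should shrink stderr by about 1/sqrt(2)
        assert med[1] / med[0] == pytest.approx(1 / np.sqrt(2), abs=0.2)

    def test_bootstrap_is_seeded(self):
        pot = double_well_potential(5.0, 1.0)
        centers = np.arange(-1.2, 1.21, 0.2)
        ws = make_iid_window_set(pot, centers, 1000.0, T, 500, seed=70)
        p1 = bootstrap_pmf_error(ws, n_boot=6, seed=71)
        p2 = bootstrap_pmf_error(ws, n_boot=6, seed=71)
        np.testing.assert_array_equal(p1.stderr, p2.stderr)


class TestExtractBarrier:
    def _profile(self, z, g, ref):
        return PMFProfile(
            z_grid=z,
            free_energy=g,
            stderr=None,
            reference_region=ref,
            populated=np.ones(z.size, dtype=bool),
            temperature=T,
        )

    def test_constant_profile_has_zero_barrier(self):
        z = np.linspace(0, 10, 101)
        bar = extract_barrier(self._profile(z, np.zeros(101), (9.0, 10.0)))
        assert bar.delta_g == 0.0

    def test_planted_depth_recovered_from_analytic_profile(self):
        pot = make_translocation_potential(-90.7, 3.0, 7.0, 1.0)
        z = np.arange(0.0, 11.8, 0.01)
        bar = extract_barrier(self._profile(z, pot.energy(z), (10.0, 11.8)))
        assert bar.delta_g == pytest.approx(-90.7, abs=0.01)
        assert bar.minimum_location == pytest.approx(3.0, abs=0.05)

    def test_interfacial_minimum_wins_when_deeper(self):
        """A compound partitioning at the matrix-water interface has its
        barrier located there rather than in the matrix interior."""
        z = np.linspace(0.0, 10.0, 201)
        interior = -30.0 * np.exp(-((z - 2.0) ** 2) / 2.0)
        interface = -45.0 * np.exp(-((z - 6.0) ** 2) / 0.32)
        bar = extract_barrier(self._profile(z, interior + interface, (9.0, 10.0)))
        assert bar.minimum_location == pytest.approx(6.0, abs=0.1)
        assert bar.delta_g == pytest.approx(-45.0, rel=0.02)

    def test_unpopulated_reference_region_rejected(self):
        z = np.linspace(0, 10, 101)
        prof = self._profile(z, np.zeros(101), (9.0, 10.0))
        prof.populated[z > 8.5] = False
        with pytest.raises(ValueError, match="reference region"):
            extract_barrier(prof)
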