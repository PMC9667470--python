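"""Tests of the stochastic-dynamics engine and synthetic-data generators."""

import math

import numpy as np
import pytest
from scipy import stats

from pmfrelease.constants import KB
from pmfrelease.toy_sim import (
    BiasSpec,
    DivergenceError,
    LangevinConfig,
    double_well_potential,
    generate_alchemical_dataset,
    generate_particle_config,
    generate_release_curve,
    generate_umbrella_dataset,
    harmonic_potential,
    make_translocation_potential,
    sample_bonded_ensemble,
    simulate_langevin,
    tabulated_potential,
)
from pmfrelease.cg_fit import BondedParams

from conftest import boltzmann_quadrature, brute_force_clusters

T = 310.0
FLAT = tabulated_potential([-100.0, 100.0], [0.0, 0.0])


class TestLangevin:
    def test_equipartition_in_harmonic_trap(self):
        """Long-run variance in a stiff trap matches k_B T / k within 3 SE."""
        k = 1000.0
        cfg = LangevinConfig(n_steps=400_000, seed=5, diffusion_coeff=0.008)
        tr = simulate_langevin(harmonic_potential(k), None, cfg)
        sub = tr.positions[4000::500]  # decorrelated subsample
        var = sub.var(ddof=1)
        expect = KB * T / k
        se = expect * math.sqrt(2.0 / sub.size)
        assert abs(var - expect) < 3 * se

    def test_free_diffusion_msd(self):
        """Ensemble MSD on a flat potential grows as 2 D t."""
        D, dt, n_steps = 0.008, 0.002, 400
        disp2 = []
        for seed in range(400):
            cfg = LangevinConfig(
                n_steps=n_steps, seed=seed, diffusion_coeff=D, timestep=dt
            )
            tr = simulate_langevin(FLAT, None, cfg)
            disp2.append((tr.positions - tr.positions[0]) ** 2)
        msd = np.mean(disp2, axis=0)
        t = np.arange(n_steps + 1) * dt
        slope = np.polyfit(t, msd, 1)[0]
        assert slope == pytest.approx(2 * D, rel=0.2)  # ~3 ensemble SE

    def test_harmonic_trap_stationary_distribution(self):
        """Bias at 1.0 nm on a flat landscape: mean 1.0, variance k_B T / k."""
        cfg = LangevinConfig(
            n_steps=400_000, seed=7, diffusion_coeff=0.008, initial_position=1.0
        )
        tr = simulate_langevin(FLAT, BiasSpec(center=1.0, spring_constant=1000.0), cfg)
        sub = tr.positions[4000::500]
        assert np.mean(sub) == pytest.approx(1.0, abs=0.01)
        assert np.var(sub) == pytest.approx(KB * T / 1000.0, rel=0.25)

    def test_determinism(self):
        cfg = LangevinConfig(n_steps=5000, seed=42)
        t1 = simulate_langevin(harmonic_potential(100.0), None, cfg)
        t2 = simulate_langevin(harmonic_potential(100.0), None, cfg)
        assert np.array_equal(t1.positions, t2.positions)

    def test_divergence_guard_names_the_step(self):
        cfg = LangevinConfig(
            n_steps=100_000, seed=3, diffusion_coeff=0.05, domain=(-0.2, 0.2)
        )
        with pytest.raises(DivergenceError, match=r"step \d+"):
            simulate_langevin(FLAT, None, cfg)

    def test_boltzmann_consistency_double_well(self):
        """Unbiased sampling of a double well matches quadrature (KS test)."""
        pot = double_well_potential(5.0, 1.0)
        cfg = LangevinConfig(n_steps=2_400_000, seed=9, diffusion_coeff=0.008)
        tr = simulate_langevin(pot, None, cfg)
        sub = tr.positions[100_000::8000]
        x, _, cdf = boltzmann_quadrature(pot.energy, -3.0, 3.0, T)
        res = stats.ks_1samp(sub, lambda v: np.interp(v, x, cdf))
        assert res.pvalue > 0.005


class TestPotentials:
    def test_translocation_zero_depth_is_flat(self):
        pot = make_translocation_potential(0.0, 3.0, 7.0, 1.0)
        z = np.linspace(-2, 12, 500)
        assert np.allclose(pot.energy(z), 0.0)

    def test_translocation_depth_is_exact(self):
        """Planted well depth is the profile minimum relative to the plateau."""
        pot = make_translocation_potential(-69.8, 3.0, 7.0, 1.0)
        z = np.linspace(-5, 12, 20001)
        u = pot.energy(z)
        plateau = u[z > 9].mean()
        assert plateau == pytest.approx(0.0, abs=1e-12)
        # the test grid cannot hit the exact minimum; 1e-6 reflects its spacing
        assert float(u.min()) - plateau == pytest.approx(-69.8, abs=1e-5)

    def test_translocation_flat_at_plateau(self):
        pot = make_translocation_potential(-50.0, 3.0, 7.0, 1.0)
        assert pot.derivative(10.0) == pytest.approx(0.0, abs=1e-12)

    def test_positive_well_depth_rejected(self):
        with pytest.raises(ValueError, match="well_depth"):
            make_translocation_potential(5.0, 3.0, 7.0, 1.0)

    def test_tabulated_requires_increasing_abscissa(self):
        with pytest.raises(ValueError, match="increasing"):
            tabulated_potential([0.0, 0.0, 1.0], [0.0, 1.0, 2.0])


class TestUmbrellaDataset:
    def test_default_geometry_spans_11_8_nm(self):
        cfg = LangevinConfig(n_steps=10, seed=0)
        ws = generate_umbrella_dataset(FLAT, None, 1000.0, cfg)
        centers = ws.centers
        assert len(centers) == 60
        assert centers[-1] - centers[0] == pytest.approx(11.8)

    def test_window_means_track_bias_centers_on_flat_potential(self):
        centers = np.arange(0.0, 2.01, 0.5)
        cfg = LangevinConfig(n_steps=40_000, seed=12, diffusion_coeff=0.008)
        ws = generate_umbrella_dataset(
            FLAT, centers, 1000.0, cfg, equilibration_steps=2000, sample_stride=20
        )
        for w in ws.windows:
            assert np.mean(w.samples) == pytest.approx(w.center, abs=0.01)

    def test_zero_spring_windows_sample_identical_distribution(self):
        """No bias on a confining potential: all windows are exchangeable."""
        pot = harmonic_potential(50.0)
        cfg = LangevinConfig(n_steps=200_000, seed=13, diffusion_coeff=0.008)
        ws = generate_umbrella_dataset(
            pot, [0.0, 0.5, 1.0], 0.0, cfg, equilibration_steps=20_000, sample_stride=400
        )
        res = stats.ks_2samp(ws.windows[0].samples, ws.windows[2].samples)
        assert res.pvalue > 0.005

    def test_reproducible_per_window_seeding(self):
        cfg = LangevinConfig(n_steps=2000, seed=77)
        ws1 = generate_umbrella_dataset(FLAT, [0.0, 0.2], 1000.0, cfg)
        ws2 = generate_umbrella_dataset(FLAT, [0.0, 0.2], 1000.0, cfg)
        for a, b in zip(ws1.windows, ws2.windows):
            assert np.array_equal(a.samples, b.samples)

    def test_empty_centers_rejected(self):
        cfg = LangevinConfig(n_steps=10, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            generate_umbrella_dataset(FLAT, [], 1000.0, cfg)


class TestBondedEnsemble:
    def test_harmonic_bond_moments(self):
        """Gaussian Boltzmann ensemble: mean b0, variance k_B T / k."""
        params = BondedParams("bond", 0.47, 1250.0, "harmonic")
        s = sample_bonded_ensemble(params, 200_000, T, seed=1)
        assert np.mean(s) == pytest.approx(0.47, abs=5e-4)  # ~5 SE of the mean
        assert np.var(s) == pytest.approx(KB * T / 1250.0, rel=0.02)

    def test_stiff_limit_collapses_spread(self):
        params = BondedParams("bond", 0.47, 1.0e7, "harmonic")
        s = sample_bonded_ensemble(params, 10_000, T, seed=2)
        assert np.std(s) < 1e-3

    def test_harmonic_cosine_matches_quadrature(self):
        """Rejection-sampled histogram agrees with exp(-beta V)/Z from quadrature."""
        params = BondedParams("angle", 120.0, 25.0, "harmonic_cosine")
        s = sample_bonded_ensemble(params, 200_000, T, seed=3)
        cos0 = math.cos(math.radians(120.0))

        def v(theta_deg):
            return 0.5 * 25.0 * (np.cos(np.radians(theta_deg)) - cos0) ** 2

        x, pdf, _ = boltzmann_quadrature(v, 0.0, 180.0, T)
        hist, edges = np.histogram(s, bins=60, range=(0.0, 180.0), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert np.max(np.abs(hist - np.interp(centers, x, pdf))) < 0.05 * pdf.max()

    def test_nonpositive_n_rejected(self):
        params = BondedParams("bond", 0.47, 1250.0, "harmonic")
        with pytest.raises(ValueError, match="n must be"):
            sample_bonded_ensemble(params, 0, T, seed=1)


class TestReleaseCurveGenerator:
    def test_noiseless_values(self):
        c = generate_release_curve(1.0, 1.0, [0.5], 0.0, seed=0)
        assert c.fraction_released[0] == pytest.approx(0.5)
        c = generate_release_curve(0.3, 0.45, [4.0], 0.0, seed=0)
        assert c.fraction_released[0] == pytest.approx(0.3 * 4.0**0.45)

    def test_zero_time_releases_nothing_even_with_noise(self):
        c = generate_release_curve(0.5, 0.7, [0.0, 1.0], 0.2, seed=4)
        assert c.fraction_released[0] == 0.0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sigma"):
            generate_release_curve(0.3, 0.45, [1.0], -0.1, seed=0)

    def test_clipping_keeps_fractions_physical(self):
        c = generate_release_curve(1.0, 1.0, np.linspace(0, 5, 20), 0.3, seed=5)
        assert np.all((c.fraction_released >= 0) & (c.fraction_released <= 1))


class TestParticleConfigGenerator:
    def test_planted_partition_recovered_by_brute_force(self):
        planted = generate_particle_config(
            [5, 4], intra_spacing=0.45, inter_separation=3.0, box=[15.0] * 3, seed=8
        )
        cfg = planted.configuration
        _, sizes = brute_force_clusters(cfg.positions, cfg.box, 0.6)
        assert sizes == (5, 4)

    def test_27_dispersed_molecules_stay_singletons(self):
        planted = generate_particle_config(
            [1] * 27, intra_spacing=0.45, inter_separation=5.0, box=[15.0] * 3, seed=9
        )
        cfg = planted.configuration
        _, sizes = brute_force_clusters(cfg.positions, cfg.box, 0.6)
        assert sizes == tuple([1] * 27)

    def test_pair_straddling_periodic_boundary(self):
        planted = generate_particle_config(
            [2], intra_spacing=0.45, inter_separation=3.0, box=[15.0] * 3,
            seed=10, straddle_boundary=True,
        )
        cfg = planted.configuration
        # the pair really wraps: naive distance exceeds the cutoff
        naive = np.linalg.norm(cfg.positions[0] - cfg.positions[1])
        _, sizes = brute_force_clusters(cfg.positions, cfg.box, 0.6)
        assert sizes == (2,)
        assert naive > 0.6

    def test_geometric_infeasibility_raises(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_particle_config(
                [1] * 1000, intra_spacing=0.45, inter_separation=5.0,
                box=[15.0] * 3, seed=0,
            )


class TestAlchemicalGenerator:
    def test_deterministic_and_carries_truth(self):
        lams = np.linspace(0, 1, 6)
        d1 = generate_alchemical_dataset(lams, 200, seed=21)
        d2 = generate_alchemical_dataset(lams, 200, seed=21)
        assert np.array_equal(d1.samples, d2.samples)
        assert d1.true_delta_g == d2.true_delta_g
        assert d1.true_delta_g < 0  # switching on an attractive well lowers G

    def test_state_zero_is_pure_restraint(self):
        d = generate_alchemical_dataset(np.linspace(0, 1, 4), 50_000, seed=22,
                                        restraint_k=100.0, temperature=300.0)
        x0 = d.samples[:50_000]
        assert np.var(x0) == pytest.approx(KB * 300.0 / 100.0, rel=0.03)
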