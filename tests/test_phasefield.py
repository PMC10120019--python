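"""Chromatin phase-field model: conservation, energetics, phase behaviour."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import solve_ivp

from nucleostress.phasefield import (
    PhaseFieldParams,
    apply_compression,
    chemical_potential,
    compression_sweep,
    domain_stats,
    free_energy,
    initialize,
    kinetic_compression_step,
    run_to_steady,
    step,
)

P96 = PhaseFieldParams(grid_n=96)


class TestInitialize:
    def test_zero_noise_is_uniform(self):
        st = initialize(replace(P96, noise_amp=0.0))
        assert np.allclose(st.c[st.mask], P96.c_bar0)

    def test_seed_determinism(self):
        a = initialize(replace(P96, seed=4))
        b = initialize(replace(P96, seed=4))
        c = initialize(replace(P96, seed=5))
        assert np.array_equal(a.c[a.mask], b.c[b.mask])
        assert not np.array_equal(a.c[a.mask], c.c[c.mask])

    def test_mean_close_to_target(self):
        st = initialize(P96)
        n = st.mask.sum()
        tol = 3 * P96.noise_amp / np.sqrt(n)
        assert abs(st.c[st.mask].mean() - P96.c_bar0) < tol

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PhaseFieldParams(c_eu=0.7, c_het=0.3)
        with pytest.raises(ValueError):
            PhaseFieldParams(compression=0.9)


class TestChemicalPotential:
    def test_uniform_at_well_bottom_is_zero(self):
        p = replace(P96, noise_amp=0.0, c_bar0=P96.c_eu)
        st = initialize(p)
        mu = chemical_potential(st, p)
        assert np.allclose(mu[st.mask], 0.0, atol=1e-12)

    def test_uniform_midpoint_matches_hand_derivative(self):
        mid = 0.5 * (P96.c_eu + P96.c_het)
        p = replace(P96, noise_amp=0.0, c_bar0=mid)
        st = initialize(p)
        mu = chemical_potential(st, p)
        # f'(c) = 2w (c-a)(c-b)(2c-a-b) = 0 at the midpoint too; use a
        # composition off every stationary point instead
        p2 = replace(P96, noise_amp=0.0, c_bar0=0.4)
        st2 = initialize(p2)
        mu2 = chemical_potential(st2, p2)
        w, a, b = P96.well_height, P96.c_eu, P96.c_het
        want = 2 * w * (0.4 - a) * (0.4 - b) * (2 * 0.4 - a - b)
        assert np.allclose(mu[st.mask], 0.0, atol=1e-12)
        assert np.allclose(mu2[st2.mask], want, atol=1e-12)

    def test_sinusoid_matches_discrete_laplacian_analytics(self):
        p = replace(P96, noise_amp=0.0)
        st = initialize(p)
        lat_dx = p.dx
        n = p.grid_n
        x = np.arange(n) * lat_dx
        q = 2 * np.pi / (n * lat_dx) * 6
        eps = 1e-3
        c = p.c_bar0 + eps * np.sin(q * x)[None, :] * np.ones((n, 1))
        st.c = np.where(st.mask, c, np.nan)
        mu = chemical_potential(st, p)
        # five-point Laplacian of sin(qx) has the discrete symbol
        q2 = (2 - 2 * np.cos(q * lat_dx)) / lat_dx**2
        want = p.fprime(c) + p.gradient_coeff * q2 * (c - p.c_bar0)
        inner = ndimage.binary_erosion(st.mask, iterations=2)
        assert np.allclose(mu[inner], want[inner], rtol=1e-6, atol=1e-9)


class TestStepConservationAndEnergy:
    def test_mass_conserved_over_1e4_steps(self):
        p = replace(P96, n_steps=0)
        st = initialize(p)
        m0 = st.total_mass
        s = st
        for _ in range(10_000):
            s = step(s, p)
        assert abs(s.total_mass - m0) / abs(m0) < 1e-8

    def test_free_energy_never_increases(self):
        p = P96
        s = initialize(p)
        prev = s.free_energy
        for _ in range(1500):
            s = step(s, p)
            assert s.free_energy <= prev + 1e-10 * abs(prev)
            prev = s.free_energy

    def test_semi_implicit_matches_explicit_at_small_dt(self):
        # independent-route check: both integrators advance the same
        # dynamics.  Compared in the linearly stable regime (decaying
        # perturbations) where discretization differences do not get
        # exponentially amplified by spinodal growth.
        p_base = replace(P96, grid_n=48, noise_amp=0.02, c_bar0=0.36, seed=3)
        dt = 0.5 * p_base.explicit_dt_bound()
        pe = replace(p_base, scheme="explicit", dt=dt)
        ps = replace(p_base, scheme="semi-implicit", dt=dt)
        se = initialize(pe)
        ss = initialize(ps)
        for _ in range(200):
            se = step(se, pe)
            ss = step(ss, ps)
        diff = np.nanmax(np.abs(se.c - ss.c))
        assert diff < 0.05 * p_base.noise_amp

    def test_explicit_dt_bound_enforced(self):
        with pytest.raises(ValueError):
            replace(P96, scheme="explicit", dt=1.0)

    def test_pure_reaction_matches_scalar_ode(self):
        # M = 0, Gamma > 0, uniform field: dc/dt = -Gamma f'(c)
        p = replace(P96, grid_n=48, mobility=0.0, reaction_rate=0.05,
                    noise_amp=0.0, c_bar0=0.6, dt=1e-3)
        s = initialize(p)
        traj = [s.c[s.mask].mean()]
        for _ in range(2000):
            s = step(s, p)
            traj.append(s.c[s.mask].mean())
        sol = solve_ivp(lambda t, c: -p.reaction_rate * p.fprime(c),
                        (0, 2000 * p.dt), [0.6], rtol=1e-10, atol=1e-12)
        assert traj[-1] == pytest.approx(float(sol.y[0, -1]), abs=1e-3)
        # monotone relaxation toward the nearest well (c_het = 0.7)
        diffs = np.diff(traj)
        assert np.all(diffs >= -1e-12)


class TestCompression:
    def test_identity_at_lambda_one(self):
        p = replace(P96, compression=1.0)
        st = initialize(p)
        st2 = apply_compression(st, p)
        assert np.allclose(st2.c[st2.mask], st.c[st.mask])

    def test_instant_mode_scales_mean(self):
        p = replace(P96, compression=1.2, noise_amp=0.0)
        st = apply_compression(initialize(p), p)
        assert st.c[st.mask].mean() == pytest.approx(1.2 * p.c_bar0)

    def test_chromatin_amount_conserved(self):
        p = replace(P96, compression=1.2, noise_amp=0.01)
        st = initialize(p)
        st2 = apply_compression(st, p)
        assert st2.total_mass == pytest.approx(st.total_mass, rel=1e-12)

    def test_kinetic_mode_matches_scalar_ode(self):
        p = replace(P96, compression=1.2, noise_amp=0.0,
                    water_permeability=2.0, dt=0.01)
        st = initialize(p)
        target = 1.2 * p.c_bar0
        means = [st.c[st.mask].mean()]
        for _ in range(400):
            st = kinetic_compression_step(st, p)
            means.append(st.c[st.mask].mean())
        means = np.array(means)
        assert np.all(np.diff(means) > -1e-15)  # monotone approach
        assert means[-1] == pytest.approx(target, rel=0.01)
        # exponential relaxation: c_bar(t) = target - (target-c0) e^{-kt}
        t = 400 * p.dt
        want = target - (target - p.c_bar0) * np.exp(-p.water_permeability * t)
        assert means[-1] == pytest.approx(want, rel=1e-3)

    def test_lambda_below_one_rejected(self):
        with pytest.raises(ValueError):
            replace(P96, compression=0.8)


class TestSteadyStates:
    def test_well_bottom_start_converges_immediately(self):
        p = replace(P96, noise_amp=0.0, c_bar0=P96.c_eu, n_steps=2000)
        st = run_to_steady(p)
        assert st.converged_by == "free_energy"
        assert np.allclose(st.c[st.mask], P96.c_eu, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_spinodal_dichotomy(self, seed):
        # f'' < 0 at 0.5 -> decompose; f'' > 0 at 0.36 -> stay uniform
        p_in = replace(P96, c_bar0=0.5, seed=seed, n_steps=2500)
        p_out = replace(P96, c_bar0=0.36, seed=seed, n_steps=1500)
        assert p_in.spinodal_unstable(0.5)
        assert not p_out.spinodal_unstable(0.36)
        st_in = run_to_steady(p_in)
        st_out = run_to_steady(p_out)
        assert st_in.c[st_in.mask].std() > 0.1
        assert st_out.c[st_out.mask].std() < p_out.noise_amp

    def test_deep_quench_ends_bimodal(self):
        p = replace(P96, c_bar0=0.5, dt=0.01, n_steps=20_000, seed=4)
        st = run_to_steady(p)
        c = st.c[st.mask]
        near_well = (np.abs(c - p.c_eu) < 0.1) | (np.abs(c - p.c_het) < 0.1)
        assert near_well.mean() >= 0.95

    def test_lamina_wetting_enriches_rim(self):
        p = replace(P96, lamina_affinity=0.5, n_steps=3000)
        st = run_to_steady(p)
        rim = st.mask & ~ndimage.binary_erosion(st.mask, iterations=2)
        interior = ndimage.binary_erosion(st.mask, iterations=2)
        assert st.c[rim].mean() > st.c[interior].mean()


class TestDomainStats:
    def test_all_euchromatin_has_no_domains(self):
        p = replace(P96, noise_amp=0.0, c_bar0=P96.c_eu)
        st = initialize(p)
        ds = domain_stats(st, p)
        assert ds.n_domains == 0 and ds.het_area_fraction == 0.0

    def test_hand_placed_disks(self):
        p = replace(P96, noise_amp=0.0, c_bar0=P96.c_eu)
        st = initialize(p)
        c = st.c.copy()
        yy, xx = np.mgrid[0:p.grid_n, 0:p.grid_n]
        for cx, cy in ((30, 30), (60, 60)):
            blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= 8
            c[blob & st.mask] = p.c_het
        st.c = c
        ds = domain_stats(st, p)
        n_px = int(((c > 0.5) & st.mask).sum())
        assert ds.n_domains == 2
        assert ds.mean_domain_area == pytest.approx(n_px / 2 * p.dx**2)

    def test_matches_independent_flood_fill(self):
        p = replace(P96, c_bar0=0.5, n_steps=1500, seed=2)
        st = run_to_steady(p)
        ds = domain_stats(st, p)
        het = (st.c > 0.5) & st.mask
        labels, n = ndimage.label(het)  # reference flood fill
        sizes = np.bincount(labels.ravel())[1:]
        sizes = sizes[sizes >= 4]
        assert ds.n_domains == len(sizes)
        assert ds.mean_domain_area == pytest.approx(sizes.mean() * p.dx**2)


class TestCompressionSweep:
    def test_single_lambda_reproduces_run_to_steady(self):
        p = replace(P96, n_steps=800, seed=9)
        df = compression_sweep(p, (1.0,), n_seeds=1)
        st = run_to_steady(replace(p, compression=1.0))
        ds = domain_stats(st, p)
        assert df.loc[0, "mean_domain_area_um2"] == pytest.approx(ds.mean_domain_area)

    def test_determinism(self):
        p = replace(P96, n_steps=600, seed=3)
        df1 = compression_sweep(p, (1.0, 1.1), n_seeds=1)
        df2 = compression_sweep(p, (1.0, 1.1), n_seeds=1)
        assert df1.equals(df2)

    def test_unsorted_lambdas_rejected(self):
        with pytest.raises(ValueError):
            compression_sweep(P96, (1.2, 1.0), n_seeds=1)
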