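"""Spatial building blocks: energetics, frictions, velocities, chemistry."""

import numpy as np
import pytest

from tmemix.grid import Grid2D
from tmemix import spatial as sp
from tmemix import _kernels
from tmemix import fixtures as fx


class TestGrid:
    def test_laplacian_of_linear_field_vanishes_in_interior(self, grid32):
        x, y = grid32.coords()
        lap = grid32.laplacian(2.0 * x + 3.0 * y)
        inner = lap[1:-1, 1:-1]
        assert np.abs(inner).max() < 1e-10

    def test_masks(self, grid32):
        m = grid32.boundary_mask()
        assert m.sum() == 4 * 32 - 4
        assert grid32.boundary_mask("left").sum() == 32
        disk = grid32.disk_mask((75.0, 75.0), 30.0)
        exact = np.pi * 30.0**2 / grid32.cell_area
        assert abs(disk.sum() - exact) / exact < 0.1
        with pytest.raises(ValueError):
            grid32.disk_mask((5.0, 5.0), 30.0)  # pokes out of the domain
        with pytest.raises(ValueError):
            Grid2D(4, 4, 1.0)


class TestFreeEnergy:
    def test_pure_passive_phase_has_zero_energy(self, grid32, params):
        f = sp.free_energy_density(sp.FieldState.zeros(grid32), params)
        assert np.abs(f).max() == 0.0

    def test_uniform_half_cancer_hand_value(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        st.phi[0][:] = 0.5
        f = sp.free_energy_density(st, params)
        expected = (1e5 + 1e6) * 0.5 * np.log(0.5) - 2.5e5 * 0.25
        assert np.allclose(f, expected)

    def test_fibroblast_attraction_is_inactive_by_default(self, grid32, params):
        # lambda_cf = 0: adding fibroblasts changes f only via their entropy
        st = sp.FieldState.zeros(grid32)
        st.phi[0][:] = 0.3
        f0 = sp.free_energy_density(st, params)
        st.phi[2][:] = 0.2
        f1 = sp.free_energy_density(st, params)
        entropy = params.d_naf * 0.2 * np.log(0.2) + params.d0 * (
            0.5 * np.log(0.5) - 0.7 * np.log(0.7)
        )
        assert np.allclose(f1 - f0, entropy)

    def test_rejects_out_of_range_fractions(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        st.phi[0][:] = 1.2
        with pytest.raises(ValueError):
            sp.free_energy_density(st, params)


class TestChemicalPotentials:
    def test_uniform_state_has_no_gradient_contribution(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        st.phi[:] = 0.1
        mu = sp.chemical_potentials(st, params)
        for i in range(4):
            assert np.ptp(mu[i]) < 1e-9  # spatially constant

    @pytest.mark.parametrize("osmotic", [False, True])
    def test_matches_finite_difference_of_f(self, grid32, osmotic):
        # kappa = 0 so mu is the pointwise partial derivative of f
        params = sp.SpatialParams(kappa=0.0, d0_osmotic=osmotic)
        st = sp.FieldState.zeros(grid32)
        st.phi[:] = np.array([0.3, 0.1, 0.08, 0.12])[:, None, None]
        mu = sp.chemical_potentials(st, params)
        h = 1e-7
        for i in range(4):
            up, dn = st.copy(), st.copy()
            up.phi[i] += h
            dn.phi[i] -= h
            fd = (
                sp.free_energy_density(up, params, include_passive=osmotic)
                - sp.free_energy_density(dn, params, include_passive=osmotic)
            ) / (2 * h)
            assert np.allclose(mu[i], fd, rtol=1e-5, atol=1e-3)

    def test_kappa_zero_checkerboard_is_pointwise(self, grid32):
        params = sp.SpatialParams(kappa=0.0)
        st = sp.FieldState.zeros(grid32)
        st.phi[0] = 0.2 + 0.1 * ((np.indices(grid32.shape).sum(axis=0)) % 2)
        mu = sp.chemical_potentials(st, params)
        expected = params.d_c * (1.0 + np.log(st.phi[0])) - 2 * params.lambda_cc * st.phi[0]
        assert np.allclose(mu[0], expected)

    def test_floor_counter_reports_empty_cells(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        counter = {}
        sp.chemical_potentials(st, params, floor_counter=counter)
        assert counter["phi"] == 4 * grid32.n_cells


def brute_force_friction(phi, xi0, xi1, phi0_floor):
    """Direct index-by-index evaluation of the friction matrix formulas."""
    phi0 = max(1.0 - phi.sum(), phi0_floor)
    phit = phi / phi0

    def xi(i, j):
        return xi0 + xi1 * phi[3] if (i == 3 or j == 3) else xi0

    def xi_0(i):
        return xi0 + xi1 * phi[3] if i == 3 else xi0

    a = np.zeros((4, 4))
    for i in range(4):
        a[i, i] = sum(
            (xi(i, j) + xi_0(j) * phit[i]) * phi[j] for j in range(4) if j != i
        ) + xi_0(i) * (1.0 + phit[i]) ** 2
        for j in range(4):
            if j == i:
                continue
            a[i, j] = phi[j] * (
                -xi(i, j)
                + xi_0(i) * (1 + phit[i])
                + xi_0(j) * (1 + phit[j])
                + sum(xi_0(k) * phit[k] for k in range(4) if k not in (i, j))
            )
    return a


class TestFrictionMatrix:
    def test_no_cafs_collapses_to_uniform_friction(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        st.phi[:3] = 0.15
        a = sp.friction_matrix(st, params)
        b = sp.friction_matrix(st, sp.SpatialParams(xi1=0.0))
        assert np.allclose(a, b)

    def test_single_cell_against_brute_force(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        vals = np.array([0.2, 0.1, 0.1, 0.2])
        st.phi[:] = vals[:, None, None]
        a = sp.friction_matrix(st, params)[0, 0]
        b = brute_force_friction(vals, params.xi0, params.xi1, sp.PHI0_FLOOR)
        assert np.allclose(a, b, rtol=1e-12)

    def test_equal_fractions_symmetric_structure(self, grid32):
        params = sp.SpatialParams(xi1=0.0)
        st = sp.FieldState.zeros(grid32)
        st.phi[:] = 0.2
        a = sp.friction_matrix(st, params)[0, 0]
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), a[0, 0])

    def test_weighted_form_is_dissipative(self, grid32, params):
        # D = sum_i phi_i v_i . (A v)_i > 0 for random nonzero velocities:
        # the quantity whose positivity makes F a Lyapunov functional
        rng = np.random.default_rng(3)
        st = fx.make_mixture_fixture(grid32, seed=5, scale=0.18)
        a = sp.friction_matrix(st, params)
        v = rng.normal(size=(*grid32.shape, 4))
        av = (a @ v[..., None])[..., 0]
        phi = np.moveaxis(st.phi, 0, -1)
        d = (phi * v * av).sum(axis=-1)
        assert d.min() > 0


class TestSolveVelocities:
    def test_uniform_mu_gives_zero_velocity(self, grid32, params, mixture_state):
        a = sp.friction_matrix(mixture_state, params)
        mu = np.ones((4, *grid32.shape)) * 7.0
        vx, vy = sp.solve_velocities(a, mu, grid32)
        assert np.abs(vx).max() == 0 and np.abs(vy).max() == 0

    def test_diagonal_friction_analytic_inverse(self, grid32):
        xi = 250.0
        a = np.zeros((*grid32.shape, 4, 4)) + xi * np.eye(4)
        x, _ = grid32.coords()
        mu = np.stack([(i + 1) * 10.0 * x for i in range(4)])
        vx, vy = sp.solve_velocities(a, mu, grid32)
        for i in range(4):
            assert np.allclose(vx[i], -(i + 1) * 10.0 / xi)
            assert np.abs(vy[i]).max() < 1e-12

    def test_residual_on_random_dominant_systems(self, grid32):
        rng = np.random.default_rng(11)
        a = rng.random((*grid32.shape, 4, 4)) + 6.0 * np.eye(4)
        mu = rng.random((4, *grid32.shape)) * 1e3
        vx, vy = sp.solve_velocities(a, mu, grid32)
        gx = np.stack([grid32.gradient(mu[i])[0] for i in range(4)])
        gy = np.stack([grid32.gradient(mu[i])[1] for i in range(4)])
        for comp, g in ((vx, gx), (vy, gy)):
            v = np.moveaxis(comp, 0, -1)[..., None]
            resid = (a @ v)[..., 0] + np.moveaxis(g, 0, -1)
            rel = np.abs(resid).max() / np.abs(g).max()
            assert rel < 1e-10

    def test_kernel_and_reference_paths_agree(self, grid32, params, nest_state):
        if not _kernels.HAVE_NUMBA:
            pytest.skip("numba unavailable")
        st = nest_state
        for rhs_mode in ("grad_mu", "phi_grad_mu", "mixed"):
            simA = sp.Simulation(st.copy(), params=params, use_kernel=True,
                                 velocity_rhs=rhs_mode)
            simB = sp.Simulation(st.copy(), params=params, use_kernel=False,
                                 velocity_rhs=rhs_mode)
            a = simA.step(dt=1e-5)
            b = simB.step(dt=1e-5)
            assert np.abs(a.phi - b.phi).max() < 1e-13


class TestChemicalField:
    def test_uniform_production(self, grid32, params):
        c = sp.chemical_field(np.full(grid32.shape, 0.4), params, grid32)
        assert np.allclose(c, params.alpha_cc * 0.4)

    def test_default_production_ratio(self, params):
        assert params.alpha_cc == 3.0

    def test_decay_length_recovery_1d(self):
        # long thin domain, source column at the left edge: the far field
        # decays as exp(-x / lambda_c)
        grid = Grid2D(nx=512, ny=8, dx=1.0)
        params = sp.SpatialParams()
        phi_c = np.zeros(grid.shape)
        phi_c[:, :4] = 0.8
        c = sp.chemical_field(phi_c, params, grid)
        x = (np.arange(grid.nx) + 0.5) * grid.dx
        window = (x > 60) & (x < 200)
        prof = c[4]
        slope = np.polyfit(x[window], np.log(prof[window]), 1)[0]
        assert -1.0 / slope == pytest.approx(params.lambda_c, rel=0.05)

    def test_rejects_bad_fractions(self, grid32, params):
        with pytest.raises(ValueError):
            sp.chemical_field(np.full(grid32.shape, 1.5), params, grid32)


class TestSourceTerms:
    def test_no_chemical_no_influx(self, grid32, params, mixture_state):
        c = np.zeros(grid32.shape)
        gam = sp.source_terms(mixture_state, c, sp.SourceGeometry(), params)
        s = mixture_state.active_sum
        # pure decay/growth terms remain
        expected_t = -params.delta * mixture_state.phi[1] * s
        assert np.allclose(gam[1], expected_t)

    def test_activation_off_keeps_nafs(self, grid32, params, mixture_state):
        c = np.full(grid32.shape, 0.5)
        toggles = sp.SourceToggles(activation=False)
        gam = sp.source_terms(mixture_state, c, sp.SourceGeometry(), params, toggles)
        s = mixture_state.active_sum
        assert np.allclose(gam[3], -params.delta * mixture_state.phi[3] * s)

    def test_single_cell_hand_oracle(self, params):
        grid = Grid2D(8, 8, 2.0)
        st = sp.FieldState.zeros(grid)
        st.phi[:] = np.array([0.5, 0.1, 0.1, 0.1])[:, None, None]
        c = np.full(grid.shape, 0.3)
        gam = sp.source_terms(st, c, sp.SourceGeometry(), params)
        s = 0.8
        interior = (slice(2, 6), slice(2, 6))  # away from the source layer
        assert np.allclose(
            gam[0][interior],
            1.0 * 0.5 - params.delta_ct * 0.5 * 0.1 - params.delta * 0.5 * s,
        )
        assert np.allclose(
            gam[2][interior],
            -params.k_plast * 0.1 * 0.3 - params.delta * 0.1 * s,
        )
        assert np.allclose(
            gam[3][interior],
            params.k_plast * 0.1 * 0.3 - params.delta * 0.1 * s,
        )
        # boundary cells additionally receive the influx flux / dx
        influx = 0.3 * (1 - s) * params.tau_t / grid.dx
        assert gam[1][0, 0] == pytest.approx(
            -params.delta * 0.1 * s + influx
        )

    def test_growth_threshold_gates_proliferation(self, grid32, params):
        st = sp.FieldState.zeros(grid32)
        st.phi[0][:] = params.growth_threshold / 2.0
        gam = sp.source_terms(st, np.zeros(grid32.shape), sp.SourceGeometry(), params)
        assert np.all(gam[0] <= 0)  # no growth below the nucleation cut


class TestInitialConditions:
    def test_empty(self, grid32, params):
        st = sp.make_initial_condition("empty", grid32, params)
        assert st.phi.max() == 0 and st.c.max() == 0

    def test_single_nest_profile(self, params):
        grid = Grid2D.square(96, 150.0)
        st = sp.make_initial_condition("single-nest", grid, params, nest_radius=25.0)
        assert st.phi[0].max() == pytest.approx(0.8, abs=0.01)
        mid = grid.ny // 2
        prof = st.phi[0][mid]
        x = (np.arange(grid.nx) + 0.5) * grid.dx
        hi = x[prof > 0.9 * 0.8].max()
        lo = x[(prof < 0.1 * 0.8) & (x > 75.0)].min()
        assert lo - hi == pytest.approx(2.2 * 10.0, rel=0.35)

    def test_two_nests_mirror_symmetric(self, params):
        grid = Grid2D.square(64, 150.0)
        st = sp.make_initial_condition(
            "two-nests", grid, params, nest_radius=15.0, nest_offset=30.0
        )
        assert np.allclose(st.phi[0], st.phi[0][:, ::-1], atol=1e-12)
        from tmemix.observables import label_nests

        assert label_nests(st.phi[0]) == 2

    def test_unknown_kind(self, grid32, params):
        with pytest.raises(ValueError):
            sp.make_initial_condition("blob", grid32, params)
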