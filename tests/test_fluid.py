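"""Projection solver: Poisson contract, divergence, vorticity, channel flow."""

import numpy as np
import pytest

from ciliasim.fluid import (BoundaryValues, EulerianGrid, FlowState,
                            FluidProps, NavierStokesSolver,
                            apply_laplacian_neumann, divergence,
                            kinetic_energy, poisson_solve, vorticity_field)
from ciliasim.scenario import DriveSignal, rl_motion, side_bc

GRID = EulerianGrid(nx=64, ny=16, h=312.5e-9)
PROPS = FluidProps()


class TestPoisson:
    def test_zero_rhs_gives_zero(self):
        p = poisson_solve(np.zeros(GRID.p_shape()), GRID.h)
        np.testing.assert_array_equal(p, 0.0)

    def test_manufactured_solution_recovered(self):
        nx, ny, h = GRID.nx, GRID.ny, GRID.h
        x = (np.arange(nx) + 0.5) * h
        y = (np.arange(ny) + 0.5) * h
        p_star = np.cos(2 * np.pi * x[:, None] / GRID.length) * \
            np.cos(np.pi * y[None, :] / GRID.height)
        rhs = apply_laplacian_neumann(p_star, h)
        p = poisson_solve(rhs, h)
        np.testing.assert_allclose(p, p_star - p_star.mean(), atol=1e-13)

    def test_residual_at_rounding_level(self):
        rng = np.random.default_rng(0)
        rhs = rng.normal(size=GRID.p_shape())
        rhs -= rhs.mean()
        p = poisson_solve(rhs, GRID.h)
        res = apply_laplacian_neumann(p, GRID.h) - rhs
        assert np.abs(res).max() <= 1e-10 * np.abs(rhs).max()

    def test_incompatible_rhs_raises(self):
        from ciliasim.fluid import SolverError
        with pytest.raises(SolverError):
            poisson_solve(np.ones(GRID.p_shape()), GRID.h, tol=1e-8)


class TestVorticity:
    def test_uniform_flow_has_zero_vorticity(self):
        u = np.full(GRID.u_shape(), 2e-5)
        v = np.full(GRID.v_shape(), -3e-5)
        np.testing.assert_allclose(vorticity_field(u, v, GRID.h), 0.0)

    def test_solid_body_rotation_gives_two_omega(self):
        om = 5.0
        xc, yc = GRID.length / 2, GRID.height / 2
        xu, yu = GRID.u_face_coords()
        u = -om * (yu[None, :] - yc) * np.ones((GRID.nx + 1, 1))
        xv, yv = GRID.v_face_coords()
        v = om * (xv[:, None] - xc) * np.ones((1, GRID.ny + 1))
        w = vorticity_field(u, v, GRID.h)
        np.testing.assert_allclose(w[1:-1, 1:-1], 2 * om, rtol=1e-10)

    def test_linear_shear_gives_minus_gamma(self):
        gamma = 7.0
        _, yu = GRID.u_face_coords()
        u = np.broadcast_to(gamma * yu[None, :], GRID.u_shape()).copy()
        v = np.zeros(GRID.v_shape())
        w = vorticity_field(u, v, GRID.h)
        np.testing.assert_allclose(w[1:-1, 1:-1], -gamma, rtol=1e-10)


class TestProjectionStep:
    def test_zero_state_zero_forcing_stays_zero(self):
        solver = NavierStokesSolver(GRID, PROPS, 5e-6)
        st = FlowState.zeros(GRID)
        st = solver.step(st, np.zeros(GRID.u_shape()), np.zeros(GRID.v_shape()),
                         BoundaryValues())
        assert not st.u.any() and not st.v.any()

    def test_post_projection_divergence_is_rounding_level(self):
        solver = NavierStokesSolver(GRID, PROPS, 5e-6)
        rng = np.random.default_rng(1)
        st = FlowState.zeros(GRID)
        drive = DriveSignal()
        _, yu = GRID.u_face_coords()
        for n in range(3):
            t = (n + 1) * 5e-6
            f_u = rng.normal(size=GRID.u_shape()) * 1e2
            f_v = rng.normal(size=GRID.v_shape()) * 1e2
            _, (vx, vy) = rl_motion(t, drive)
            prof = side_bc(yu, t, drive, PROPS, GRID.height)
            bc = BoundaryValues(u_bottom=vx, v_wall=vy, u_left=prof, u_right=prof)
            st = solver.step(st, f_u, f_v, bc)
            div = divergence(st.u, st.v, GRID.h)
            assert np.abs(div).max() <= 1e-10 * (np.abs(st.u).max() / GRID.h)

    def test_viscous_decay_of_kinetic_energy(self):
        """No forcing, stationary walls: energy must be non-increasing."""
        solver = NavierStokesSolver(GRID, PROPS, 5e-6, advection=False)
        rng = np.random.default_rng(2)
        st = FlowState.zeros(GRID)
        # make a nontrivial divergence-free-ish field by one forced step
        f_u = rng.normal(size=GRID.u_shape()) * 1e3
        f_v = rng.normal(size=GRID.v_shape()) * 1e3
        st = solver.step(st, f_u, f_v, BoundaryValues())
        z_u, z_v = np.zeros(GRID.u_shape()), np.zeros(GRID.v_shape())
        energies = [kinetic_energy(st, GRID, PROPS.density)]
        for _ in range(5):
            st = solver.step(st, z_u, z_v, BoundaryValues())
            energies.append(kinetic_energy(st, GRID, PROPS.density))
        assert all(b <= a * (1 + 1e-12) for a, b in zip(energies, energies[1:]))
        assert energies[-1] < 0.9 * energies[0]

    def test_cfl_violation_raises(self):
        from ciliasim.fluid import SolverError
        solver = NavierStokesSolver(GRID, PROPS, 5e-6)
        st = FlowState.zeros(GRID)
        st.u[:] = 100.0           # absurd velocity: CFL blown
        with pytest.raises(SolverError):
            solver.step(st, np.zeros(GRID.u_shape()), np.zeros(GRID.v_shape()),
                        BoundaryValues())


def test_dst_and_lu_helmholtz_backends_agree():
    """The sine-transform solver is a drop-in for the sparse-LU solver."""
    grid = EulerianGrid(32, 16, 312.5e-9)
    rng = np.random.default_rng(3)
    bc = BoundaryValues(u_bottom=2e-5, v_wall=-1e-5,
                        u_left=rng.normal(size=16) * 1e-5,
                        u_right=rng.normal(size=16) * 1e-5)
    st0 = FlowState(rng.normal(size=grid.u_shape()) * 1e-5,
                    rng.normal(size=grid.v_shape()) * 1e-5,
                    np.zeros(grid.p_shape()))
    f_u = rng.normal(size=grid.u_shape()) * 1e2
    f_v = rng.normal(size=grid.v_shape()) * 1e2
    a = NavierStokesSolver(grid, PROPS, 5e-7, method="lu").step(
        st0.copy(), f_u, f_v, bc)
    b = NavierStokesSolver(grid, PROPS, 5e-7, method="dst").step(
        st0.copy(), f_u, f_v, bc)
    np.testing.assert_allclose(a.u, b.u, rtol=0, atol=1e-13 * np.abs(a.u).max())
    np.testing.assert_allclose(a.v, b.v, rtol=0, atol=1e-13 * np.abs(a.v).max())


def run_channel(ny, n_per_cycle=1000, n_cycles=3, H=5e-6):
    """No-bundle oscillating-wall channel at resolution ny; return the max
    deviation of the mid-domain u-profile from the analytic solution."""
    drive = DriveSignal(amp_v=0.0)
    h = H / ny
    grid = EulerianGrid(8, ny, h)
    dt = drive.period / n_per_cycle
    solver = NavierStokesSolver(grid, PROPS, dt, advection=False)
    st = FlowState.zeros(grid)
    zu, zv = np.zeros(grid.u_shape()), np.zeros(grid.v_shape())
    _, yu = grid.u_face_coords()
    for n in range(n_cycles * n_per_cycle):
        t0, t1 = n * dt, (n + 1) * dt
        bcs = []
        for t in (t0, t1):
            prof = side_bc(yu, t, drive, PROPS, H)
            _, (vx, vy) = rl_motion(t, drive)
            bcs.append(BoundaryValues(u_bottom=vx, v_wall=vy,
                                      u_left=prof, u_right=prof))
        st = solver.step(st, zu, zv, bcs[1], bcs[0])
    exact = side_bc(yu, st.t, drive, PROPS, H)
    return np.abs(st.u[4, :] - exact).max() / np.abs(exact).max()


def test_oscillatory_channel_matches_analytic_with_second_order_convergence():
    """After the start-up transient the solver reproduces the analytic
    oscillatory Stokes-layer profile; halving h cuts the error ~4x."""
    err_coarse = run_channel(16)
    err_fine = run_channel(32)
    assert err_coarse < 5e-3
    assert err_fine < err_coarse / 3.0
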