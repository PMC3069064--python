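"""Incompressible Navier-Stokes on a uniform MAC grid via Chorin projection.

Layout (staggered / marker-and-cell):

* ``u`` (horizontal velocity): shape (nx+1, ny), at vertical cell faces
  (x = i*h, y = (j+1/2)*h);
* ``v`` (vertical velocity): shape (nx, ny+1), at horizontal faces
  (x = (i+1/2)*h, y = j*h);
* ``p`` (pressure): shape (nx, ny), at cell centers.

All four domain edges carry Dirichlet velocity conditions: the moving bottom
wall (reticular lamina), the horizontally fixed / vertically co-moving top
wall (tectorial membrane), and analytic oscillatory-channel profiles on the
sides.  Normal components are imposed directly on boundary faces; tangential
components through ghost cells folded into the operators.

Time stepping: explicit centered advection (the Reynolds number of the
subtectorial flow is ~1e-3, so the advective term is a formality and can be
switched off for Stokes-mode verification), Crank-Nicolson diffusion (the
diffusion number nu*dt/h^2 is O(10^2-10^3) here, far beyond any explicit
limit), then a pressure projection with a fast DCT Poisson solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProps:
    density: float = 1000.0              # rho, kg/m^3
    kinematic_viscosity: float = 0.7e-6  # nu = 0.7e-2 cm^2/s, endolymph

    def __post_init__(self):
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def dynamic_viscosity(self) -> float:
        return self.density * self.kinematic_viscosity


@dataclass(frozen=True)
class EulerianGrid:
    nx: int
    ny: int
    h: float

    @property
    def length(self) -> float:
        return self.nx * self.h

    @property
    def height(self) -> float:
        return self.ny * self.h

    def u_shape(self):
        return (self.nx + 1, self.ny)

    def v_shape(self):
        return (self.nx, self.ny + 1)

    def p_shape(self):
        return (self.nx, self.ny)

    def u_face_coords(self):
        x = np.arange(self.nx + 1) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return x, y

    def v_face_coords(self):
        x = (np.arange(self.nx) + 0.5) * self.h
        y = np.arange(self.ny + 1) * self.h
        return x, y

    def corner_coords(self):
        return np.arange(self.nx + 1) * self.h, np.arange(self.ny + 1) * self.h


@dataclass
class BoundaryValues:
    """Dirichlet velocity data on the four edges at one time level."""

    u_bottom: float = 0.0            # tangential, reticular lamina horizontal
    u_top: float = 0.0               # tangential, tectorial membrane (0)
    v_wall: float = 0.0              # normal on bottom AND top (co-moving walls)
    u_left: np.ndarray | float = 0.0   # normal side profiles, shape (ny,)
    u_right: np.ndarray | float = 0.0
    v_side: float = 0.0              # tangential on both sides

    def u_left_arr(self, ny):
        return np.broadcast_to(np.asarray(self.u_left, dtype=float), (ny,))

    def u_right_arr(self, ny):
        return np.broadcast_to(np.asarray(self.u_right, dtype=float), (ny,))


@dataclass
class FlowState:
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, grid: EulerianGrid, t: float = 0.0) -> "FlowState":
        return cls(np.zeros(grid.u_shape()), np.zeros(grid.v_shape()),
                   np.zeros(grid.p_shape()), t)

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy(), self.t)


# ---------------------------------------------------------------------------
# fast Poisson solve (homogeneous Neumann on all sides, cell-centered)
# ---------------------------------------------------------------------------

def poisson_solve(rhs: np.ndarray, h: float, tol: float = 1e-8) -> np.ndarray:
    """Solve the 5-point Laplacian with homogeneous Neumann BCs via DCT-II.

    The rhs must have (numerically) zero mean; the mean is removed and the
    solution gauge-fixed to zero mean.  Raises on grossly incompatible rhs.
    """
    nx, ny = rhs.shape
    mean = rhs.mean()
    scale = np.abs(rhs).max()
    if scale > 0 and abs(mean) > tol * scale:
        raise SolverError(
            f"Poisson rhs incompatible with Neumann BCs: mean/max = {mean / scale:.2e}"
        )
    rhs = rhs - mean
    rhat = scipy.fft.dctn(rhs, type=2, norm="ortho")
    i = np.arange(nx)[:, None]
    j = np.arange(ny)[None, :]
    lam = (-4.0 * np.sin(np.pi * i / (2 * nx)) ** 2
           - 4.0 * np.sin(np.pi * j / (2 * ny)) ** 2) / h**2
    lam[0, 0] = 1.0
    phat = rhat / lam
    phat[0, 0] = 0.0
    phi = scipy.fft.idctn(phat, type=2, norm="ortho")
    return phi - phi.mean()


def apply_laplacian_neumann(phi: np.ndarray, h: float) -> np.ndarray:
    """The 5-point cell-centered Laplacian with mirror (Neumann) ghosts."""
    padded = np.pad(phi, 1, mode="edge")
    return (padded[2:, 1:-1] + padded[:-2, 1:-1] + padded[1:-1, 2:]
            + padded[1:-1, :-2] - 4.0 * phi) / h**2


def divergence(u: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h


def vorticity_field(u: np.ndarray, v: np.ndarray, h: float) -> np.ndarray:
    """omega = dv/dx - du/dy at interior cell corners, shape (nx+1, ny+1).

    Edge corners are copied from their nearest interior neighbor (they sit on
    Dirichlet walls where the discrete curl is one-sided anyway).
    """
    nx1, ny = u.shape
    nx = nx1 - 1
    omega = np.zeros((nx + 1, ny + 1))
    dvdx = (v[1:, 1:-1] - v[:-1, 1:-1]) / h          # (nx-1, ny-1)
    dudy = (u[1:-1, 1:] - u[1:-1, :-1]) / h
    omega[1:-1, 1:-1] = dvdx - dudy
    omega[0, :] = omega[1, :]
    omega[-1, :] = omega[-2, :]
    omega[:, 0] = omega[:, 1]
    omega[:, -1] = omega[:, -2]
    return omega


def streamfunction(u: np.ndarray, h: float) -> np.ndarray:
    """psi at cell corners from u = d(psi)/dy, psi = 0 on the bottom edge."""
    nx1, ny = u.shape
    psi = np.zeros((nx1, ny + 1))
    psi[:, 1:] = np.cumsum(u * h, axis=1)
    return psi


# ---------------------------------------------------------------------------
# Navier-Stokes stepper
# ---------------------------------------------------------------------------

class NavierStokesSolver:
    """Projection stepper with pre-factorized Crank-Nicolson operators.

    The implicit Helmholtz matrices depend only on (grid, nu, dt), so they are
    assembled and LU-factorized once per time-step size; boundary data enters
    through per-step right-hand-side contributions.
    """

    def __init__(self, grid: EulerianGrid, props: FluidProps, dt: float,
                 advection: bool = True, method: str = "dst"):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.grid = grid
        self.props = props
        self.dt = dt
        self.advection = advection
        self.method = method
        self.alpha = 0.5 * props.kinematic_viscosity * dt
        if method == "lu":
            self._lu_u = splu(self._helmholtz_u().tocsc())
            self._lu_v = splu(self._helmholtz_v().tocsc())
        elif method == "dst":
            self._prepare_dst()
        else:
            raise ValueError(f"unknown Helmholtz method {method!r}")

    def _prepare_dst(self):
        """Eigenvalue grids for the separable Helmholtz operators.

        Both implicit operators are constant-coefficient and separable:
        DST-I diagonalizes the interior-Dirichlet direction and DST-II the
        ghost-folded (Dirichlet at a half-cell offset) direction, so the
        solves reduce to fast sine transforms plus a pointwise division.
        """
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        # u: DST-I in x over i=1..nx-1, DST-II in y over j=0..ny-1
        lam_x_u = -4.0 * np.sin(np.pi * np.arange(1, nx) / (2 * nx)) ** 2 / h**2
        lam_y_u = -4.0 * np.sin(np.pi * np.arange(1, ny + 1) / (2 * ny)) ** 2 / h**2
        self._den_u = 1.0 - self.alpha * (lam_x_u[:, None] + lam_y_u[None, :])
        # v: DST-II in x over i=0..nx-1, DST-I in y over j=1..ny-1
        lam_x_v = -4.0 * np.sin(np.pi * np.arange(1, nx + 1) / (2 * nx)) ** 2 / h**2
        lam_y_v = -4.0 * np.sin(np.pi * np.arange(1, ny) / (2 * ny)) ** 2 / h**2
        self._den_v = 1.0 - self.alpha * (lam_x_v[:, None] + lam_y_v[None, :])

    def _solve_helmholtz_u(self, rhs: np.ndarray) -> np.ndarray:
        if self.method == "lu":
            nx, ny = self.grid.nx, self.grid.ny
            return self._lu_u.solve(rhs.ravel()).reshape(nx - 1, ny)
        rhat = scipy.fft.dst(scipy.fft.dst(rhs, type=1, axis=0, norm="ortho"),
                             type=2, axis=1, norm="ortho")
        rhat /= self._den_u
        return scipy.fft.idst(scipy.fft.idst(rhat, type=2, axis=1, norm="ortho"),
                              type=1, axis=0, norm="ortho")

    def _solve_helmholtz_v(self, rhs: np.ndarray) -> np.ndarray:
        if self.method == "lu":
            nx, ny = self.grid.nx, self.grid.ny
            return self._lu_v.solve(rhs.ravel()).reshape(nx, ny - 1)
        rhat = scipy.fft.dst(scipy.fft.dst(rhs, type=2, axis=0, norm="ortho"),
                             type=1, axis=1, norm="ortho")
        rhat /= self._den_v
        return scipy.fft.idst(scipy.fft.idst(rhat, type=1, axis=1, norm="ortho"),
                              type=2, axis=0, norm="ortho")

    # -- operator assembly --------------------------------------------------
    # u unknowns: i = 1..nx-1 (sides Dirichlet), all j; walls via ghosts.
    def _helmholtz_u(self):
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        n_i, n_j = nx - 1, ny
        diag = np.full((n_i, n_j), 4.0)
        diag[:, 0] += 1.0      # bottom ghost: u_ghost = 2*u_wall - u -> extra +1
        diag[:, -1] += 1.0
        main = 1.0 + self.alpha / h**2 * diag.ravel()
        A = sp.diags(main).tolil()
        idx = lambda i, j: i * n_j + j
        c = -self.alpha / h**2
        for i in range(n_i):
            for j in range(n_j):
                k = idx(i, j)
                if i > 0:
                    A[k, idx(i - 1, j)] = c
                if i < n_i - 1:
                    A[k, idx(i + 1, j)] = c
                if j > 0:
                    A[k, idx(i, j - 1)] = c
                if j < n_j - 1:
                    A[k, idx(i, j + 1)] = c
        return A

    # v unknowns: j = 1..ny-1 (walls Dirichlet), all i; sides via ghosts.
    def _helmholtz_v(self):
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        n_i, n_j = nx, ny - 1
        diag = np.full((n_i, n_j), 4.0)
        diag[0, :] += 1.0      # side ghost: v_ghost = 2*v_side - v
        diag[-1, :] += 1.0
        main = 1.0 + self.alpha / h**2 * diag.ravel()
        A = sp.diags(main).tolil()
        idx = lambda i, j: i * n_j + j
        c = -self.alpha / h**2
        for i in range(n_i):
            for j in range(n_j):
                k = idx(i, j)
                if i > 0:
                    A[k, idx(i - 1, j)] = c
                if i < n_i - 1:
                    A[k, idx(i + 1, j)] = c
                if j > 0:
                    A[k, idx(i, j - 1)] = c
                if j < n_j - 1:
                    A[k, idx(i, j + 1)] = c
        return A

    # -- Laplacians with boundary data --------------------------------------
    def _lap_u(self, u: np.ndarray, bc: BoundaryValues) -> np.ndarray:
        """Laplacian of u at interior-in-x faces, ghost walls folded in."""
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        ext = np.empty((nx + 1, ny + 2))
        ext[:, 1:-1] = u
        ext[:, 0] = 2.0 * bc.u_bottom - u[:, 0]
        ext[:, -1] = 2.0 * bc.u_top - u[:, -1]
        lap = (ext[2:, 1:-1] + ext[:-2, 1:-1] + ext[1:-1, 2:] + ext[1:-1, :-2]
               - 4.0 * ext[1:-1, 1:-1]) / h**2
        return lap          # shape (nx-1, ny)

    def _lap_v(self, v: np.ndarray, bc: BoundaryValues) -> np.ndarray:
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        ext = np.empty((nx + 2, ny + 1))
        ext[1:-1, :] = v
        ext[0, :] = 2.0 * bc.v_side - v[0, :]
        ext[-1, :] = 2.0 * bc.v_side - v[-1, :]
        lap = (ext[2:, 1:-1] + ext[:-2, 1:-1] + ext[1:-1, 2:] + ext[1:-1, :-2]
               - 4.0 * ext[1:-1, 1:-1]) / h**2
        return lap          # shape (nx, ny-1)

    # -- advection (centered, MAC) ------------------------------------------
    def _advect(self, u: np.ndarray, v: np.ndarray):
        nx, ny, h = self.grid.nx, self.grid.ny, self.grid.h
        # d(u)/dx, d(u)/dy at u faces (interior in x)
        ui = u[1:-1, :]
        dudx = (u[2:, :] - u[:-2, :]) / (2 * h)
        dudy = np.zeros_like(ui)
        dudy[:, 1:-1] = (ui[:, 2:] - ui[:, :-2]) / (2 * h)
        dudy[:, 0] = (ui[:, 1] - ui[:, 0]) / h
        dudy[:, -1] = (ui[:, -1] - ui[:, -2]) / h
        # v averaged to interior u faces
        v_at_u = 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])  # (nx-1, ny)
        Nu = ui * dudx + v_at_u * dudy

        vi = v[:, 1:-1]
        dvdy = (v[:, 2:] - v[:, :-2]) / (2 * h)
        dvdx = np.zeros_like(vi)
        dvdx[1:-1, :] = (vi[2:, :] - vi[:-2, :]) / (2 * h)
        dvdx[0, :] = (vi[1, :] - vi[0, :]) / h
        dvdx[-1, :] = (vi[-1, :] - vi[-2, :]) / h
        # u averaged to interior v faces
        u_at_v = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])  # (nx, ny-1)
        Nv = u_at_v * dvdx + vi * dvdy
        return Nu, Nv

    # -- one projection step -------------------------------------------------
    def step(self, state: FlowState, f_u: np.ndarray, f_v: np.ndarray,
             bc_new: BoundaryValues, bc_old: BoundaryValues | None = None,
             cfl_limit: float = 1.0) -> FlowState:
        """Advance one time step with external force density (f_u, f_v).

        ``f_u``/``f_v`` are force per unit volume on the full face arrays.
        ``bc_old`` defaults to ``bc_new`` (boundary data treated at the new
        time level only — the difference is O(dt) and immaterial here).
        """
        grid, dt, h = self.grid, self.dt, self.grid.h
        nx, ny = grid.nx, grid.ny
        rho = self.props.density
        if bc_old is None:
            bc_old = bc_new
        u, v = state.u, state.v

        umax = max(np.abs(u).max(), np.abs(v).max())
        if self.advection and umax * dt / h > cfl_limit:
            raise SolverError(
                f"advective CFL violated: |u|max*dt/h = {umax * dt / h:.3g}"
            )

        rhs_u = u[1:-1, :] + self.alpha * self._lap_u(u, bc_old) \
            + dt * f_u[1:-1, :] / rho
        rhs_v = v[:, 1:-1] + self.alpha * self._lap_v(v, bc_old) \
            + dt * f_v[:, 1:-1] / rho
        if self.advection:
            Nu, Nv = self._advect(u, v)
            rhs_u -= dt * Nu
            rhs_v -= dt * Nv

        # implicit boundary contributions at the new time level
        a = self.alpha / h**2
        rhs_u[0, :] += a * bc_new.u_left_arr(ny)
        rhs_u[-1, :] += a * bc_new.u_right_arr(ny)
        rhs_u[:, 0] += 2.0 * a * bc_new.u_bottom
        rhs_u[:, -1] += 2.0 * a * bc_new.u_top
        rhs_v[:, 0] += a * bc_new.v_wall
        rhs_v[:, -1] += a * bc_new.v_wall
        rhs_v[0, :] += 2.0 * a * bc_new.v_side
        rhs_v[-1, :] += 2.0 * a * bc_new.v_side

        u_star = np.empty_like(u)
        v_star = np.empty_like(v)
        u_star[1:-1, :] = self._solve_helmholtz_u(rhs_u)
        u_star[0, :] = bc_new.u_left_arr(ny)
        u_star[-1, :] = bc_new.u_right_arr(ny)
        v_star[:, 1:-1] = self._solve_helmholtz_v(rhs_v)
        v_star[:, 0] = bc_new.v_wall
        v_star[:, -1] = bc_new.v_wall

        # projection
        div = divergence(u_star, v_star, h)
        rhs_p = div / dt
        rhs_p = rhs_p - rhs_p.mean()
        phi = poisson_solve(rhs_p, h, tol=np.inf)
        u_new = u_star.copy()
        v_new = v_star.copy()
        u_new[1:-1, :] -= dt * (phi[1:, :] - phi[:-1, :]) / h
        v_new[:, 1:-1] -= dt * (phi[:, 1:] - phi[:, :-1]) / h

        return FlowState(u_new, v_new, rho * phi, state.t + dt)


def kinetic_energy(state: FlowState, grid: EulerianGrid, rho: float) -> float:
    h2 = grid.h**2
    return 0.5 * rho * h2 * (np.sum(state.u**2) + np.sum(state.v**2))
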