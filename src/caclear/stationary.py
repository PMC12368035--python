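"""Stationary pipette-infusion diffusion problem on the spherical cell.

Laplace's equation ∇²c = 0 holds in the accessible cytosol under constant
infusion; the pipette-cell contact patch imposes a Dirichlet value c_pip
on a polar spherical cap (whose area equals the disc of the pipette
contact radius), while the remaining membrane carries the nonlinear flux
balance

    D_c ∂c/∂n = (j_leak − j_PMCA(c)) / (ions_per_uM_um3 · θ)

with the Hill-type pump efflux and the constant leak that pins the rest
state at c₀ (the pumps occupy only the non-pipette surface here).

The axisymmetric problem is discretized by a conservative finite-volume
scheme on (r, x = cosθ): the spherical Laplacian splits into radial
(r²∂r) and angular ((1−x²)∂x) flux terms, the polar axis and cell centre
are natural no-flux boundaries, and the angular mesh is graded toward
the cap edge where the mixed boundary condition makes the solution
gradient singular.  The nonlinear membrane condition is handled by
Newton iteration on the assembled sparse system (the pump term is
linearized in the boundary-cell concentration), initialized at
c = c_pip.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

from .constants import IONS_PER_UM_UM3
from .field import (
    ConcentrationField,
    SolverError,
    leak_influx_density,
    pump_outflux_density,
)
from .params import CellGeometry, PumpParams


def _hill_derivative(c, pump: PumpParams):
    n, ch = pump.hill_n, pump.c_half
    c = np.asarray(c, dtype=float)
    cn = c**n
    chn = ch**n
    with np.errstate(divide="ignore", invalid="ignore"):
        d = n * c ** (n - 1.0) * chn / (cn + chn) ** 2
    return np.where(c > 0, d, 0.0)


def _graded_faces(a: float, b: float, n: int, cluster_at_b: bool,
                  ratio: float = 20.0) -> np.ndarray:
    """n+1 faces on [a, b] with spacing shrinking ~ratio-fold toward one
    end (geometric grading toward the cap edge)."""
    u = np.linspace(0.0, 1.0, n + 1)
    g = (ratio**u - 1.0) / (ratio - 1.0)
    if cluster_at_b:
        return a + (b - a) * (1.0 - g[::-1])
    return a + (b - a) * g


class StationarySolution(ConcentrationField):
    """Finite-volume field on the (r, x) grid with surface helpers."""

    r_centres: np.ndarray
    x_centres: np.ndarray
    cap_mask: np.ndarray  # over angular cells

    @property
    def surface_profile(self):
        """(x_centres, c) along the membrane (outer shell, all angles)."""
        nx = self.x_centres.size
        return self.x_centres, self.free_ca[-nx:]


def solve_stationary(
    geometry: CellGeometry,
    pump: PumpParams,
    c_pip: float,
    d_ca: float = 220.0,
    n_r: int = 80,
    n_x: int = 192,
    leak_density: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> StationarySolution:
    """Solve the stationary infusion/extrusion balance.

    Parameters
    ----------
    n_r, n_x : int
        Radial and angular cell counts (the angular mesh is split at the
        cap edge and graded toward it from both sides).
    leak_density : float, optional
        Override for the constant leak influx density (ions·µm⁻²·s⁻¹);
        default is the rest-pinning value j_PMCA(c₀).

    Returns a :class:`StationarySolution` whose membrane nodes are the
    outer-shell cells outside the pipette cap, with area weights summing
    to the non-pipette membrane area.
    """
    if geometry.pipette_contact_radius <= 0:
        raise ValueError("stationary problem requires a pipette contact patch")
    if c_pip <= 0:
        raise ValueError("c_pip must be positive")

    R = geometry.radius
    x0 = geometry.pipette_cap_cos
    theta = geometry.accessible_fraction
    leak = leak_influx_density(pump) if leak_density is None else leak_density
    conv = IONS_PER_UM_UM3 * theta

    # mesh: radial and angular cells graded toward the cap edge (r = R,
    # x = x0) where the mixed boundary condition is gradient-singular
    r_faces = _graded_faces(0.0, R, n_r, cluster_at_b=True, ratio=8.0)
    n_cap = max(4, int(round(n_x * (1.0 - x0) * 4)))  # refine the small cap
    n_mem = n_x
    x_faces = np.concatenate([
        _graded_faces(-1.0, x0, n_mem, cluster_at_b=True),
        _graded_faces(x0, 1.0, n_cap, cluster_at_b=False)[1:],
    ])
    nx = x_faces.size - 1
    r_c = 0.5 * (r_faces[:-1] + r_faces[1:])
    x_c = 0.5 * (x_faces[:-1] + x_faces[1:])
    dx = np.diff(x_faces)
    cap_cell = x_c > x0

    def idx(i, j):  # radial i, angular j
        return i * nx + j

    n_unk = n_r * nx
    # assemble the constant (Laplacian + Dirichlet cap) part once
    A0 = lil_matrix((n_unk, n_unk))
    b0 = np.zeros(n_unk)
    for i in range(n_r):
        for j in range(nx):
            k = idx(i, j)
            # radial faces
            if i > 0:
                g = r_faces[i] ** 2 * dx[j] / (r_c[i] - r_c[i - 1])
                A0[k, k] -= g
                A0[k, idx(i - 1, j)] += g
            if i < n_r - 1:
                g = r_faces[i + 1] ** 2 * dx[j] / (r_c[i + 1] - r_c[i])
                A0[k, k] -= g
                A0[k, idx(i + 1, j)] += g
            else:
                if cap_cell[j]:
                    # Dirichlet half-cell closure at the membrane
                    g = R**2 * dx[j] / (R - r_c[i])
                    A0[k, k] -= g
                    b0[k] -= g * c_pip
                # membrane flux handled in the Newton loop
            # angular faces
            if j > 0:
                f = x_faces[j]
                g = (1.0 - f * f) * (r_faces[i + 1] - r_faces[i]) / (
                    x_c[j] - x_c[j - 1]
                )
                A0[k, k] -= g
                A0[k, idx(i, j - 1)] += g
            if j < nx - 1:
                f = x_faces[j + 1]
                g = (1.0 - f * f) * (r_faces[i + 1] - r_faces[i]) / (
                    x_c[j + 1] - x_c[j]
                )
                A0[k, k] -= g
                A0[k, idx(i, j + 1)] += g
    A0 = A0.tocsr()

    mem_cells = np.array([idx(n_r - 1, j) for j in range(nx) if not cap_cell[j]])
    mem_dx = dx[~cap_cell]

    def membrane_q(c):
        """inward flux density / D, in µM/µm."""
        return (leak - pump_outflux_density(np.clip(c, 0.0, None), pump)) / (
            conv * d_ca
        )

    def membrane_dq(c):
        return -pump.cycle_rate * pump.density * _hill_derivative(
            np.clip(c, 0.0, None), pump
        ) / (conv * d_ca)

    mem_scale = R**2 * mem_dx

    def residual(cv):
        F = A0 @ cv - b0
        F[mem_cells] += mem_scale * membrane_q(cv[mem_cells])
        return F

    # Newton with backtracking line search on the residual norm; the
    # residual is scaled by the Dirichlet row magnitude so tol is relative
    c = np.full(n_unk, float(c_pip))
    scale = float(np.abs(b0).max()) or 1.0
    F = residual(c)
    last = float(np.abs(F).max()) / scale
    converged = last < tol
    for _ in range(max_iter):
        if converged:
            break
        J = A0.tolil(copy=True)
        dq = membrane_dq(c[mem_cells])
        for m, k in enumerate(mem_cells):
            J[k, k] += mem_scale[m] * dq[m]
        step = spsolve(J.tocsr(), -F)
        alpha = 1.0
        for _ in range(40):
            c_try = np.clip(c + alpha * step, 0.0, None)
            F_try = residual(c_try)
            if np.abs(F_try).max() < np.abs(F).max():
                break
            alpha *= 0.5
        else:
            raise SolverError("stationary Newton stalled", residual=last)
        c, F = c_try, F_try
        last = float(np.abs(F).max()) / scale
        converged = last < tol
    if not converged:
        raise SolverError("stationary solve did not converge", residual=last)
    if c.min() < -1e-8 * c_pip:
        raise SolverError("negative concentration in stationary solve",
                          residual=float(c.min()))
    c = np.clip(c, 0.0, None)

    pos = np.empty((n_unk, 2))
    for i in range(n_r):
        pos[i * nx:(i + 1) * nx, 0] = r_c[i]
        pos[i * nx:(i + 1) * nx, 1] = x_c
    sol = StationarySolution(
        node_positions=pos,
        free_ca=c,
        membrane_nodes=mem_cells,
        membrane_weights=2.0 * np.pi * R * R * mem_dx,
        residual=last,
    )
    sol.r_centres = r_c
    sol.x_centres = x_c
    sol.cap_mask = cap_cell
    return sol
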