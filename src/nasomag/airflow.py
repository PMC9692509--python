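"""Steady incompressible laminar airflow on a labeled 2-D Domain.

The inhalation flow is modeled as steady, incompressible, isothermal and
laminar, with the three boundary conditions of the delivery problem: a
uniform normal inflow speed at the INLET, a fixed gauge pressure at the
OUTLET, and no-slip on every WALL/OLFACTORY boundary.  Air properties
default to body-temperature values (rho = 1.14 kg/m^3, eta = 1.9e-5 Pa s).

Discretization: a marker-and-cell (MAC) staggered grid on the domain's
uniform cell lattice with mask-based stair-step walls (first order at
irregular boundaries; ghost-reflection no-slip on straight wall lines, so a
grid-aligned channel recovers plane Poiseuille flow to second order).
Advection is first-order upwind, diffusion is integrated implicitly
(backward Euler) and incompressibility is enforced each pseudo-time step by
a pressure projection with a direct sparse factorization, marching to the
stationary state.  The momentum residual is normalized by u_in^2/h so the
stated solver tolerance is a relative steady-state criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import SamplingError, SolverError
from .geometry import Domain, RegionLabel

__all__ = ["FlowParams", "FlowField", "solve_flow", "sample_velocity"]

# face type codes
_UNKNOWN, _FIXED, _OPEN, _DEAD = 0, 1, 2, 3


@dataclass(frozen=True)
class FlowParams:
    """Air properties and solver settings.

    density [kg/m^3] and viscosity [Pa s] default to 36.6 C air; u_in is the
    uniform inward normal speed on the INLET boundary [m/s];
    outlet_pressure is the gauge pressure on the OUTLET [Pa].  ``tolerance``
    is the normalized steady-state residual at which the march stops.
    """

    density: float = 1.14
    viscosity: float = 1.9e-5
    u_in: float = 0.5
    outlet_pressure: float = 0.0
    tolerance: float = 1.0e-6
    max_iterations: int = 200_000
    cfl: float = 0.4

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")
        if self.u_in < 0:
            raise ValueError("u_in must be non-negative")


@dataclass
class FlowField:
    """Steady solution on the MAC grid.

    ``u`` (ny+1, nz) is the y-velocity on vertical faces, ``w`` (ny, nz+1)
    the z-velocity on horizontal faces, ``p`` (ny, nz) the cell pressure.
    Boundary faces carry their boundary values, so bilinear sampling near
    walls interpolates toward zero.
    """

    domain: Domain
    params: FlowParams
    u: np.ndarray
    w: np.ndarray
    p: np.ndarray
    residual_history: np.ndarray
    converged: bool = True

    def sample(self, points) -> np.ndarray:
        """Bilinear velocity interpolation at (..., 2) points [m/s]."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        oy, oz = self.domain.origin
        h = self.domain.grid_spacing
        vy = _bilinear(self.u, (pts2[:, 0] - oy) / h,
                       (pts2[:, 1] - oz) / h - 0.5)
        vz = _bilinear(self.w, (pts2[:, 0] - oy) / h - 0.5,
                       (pts2[:, 1] - oz) / h)
        out = np.stack([vy, vz], axis=1)
        return out[0] if single else out.reshape(pts.shape)

    def max_speed(self) -> float:
        return float(
            max(np.abs(self.u).max(initial=0.0), np.abs(self.w).max(initial=0.0))
        )

    def divergence(self) -> np.ndarray:
        """Discrete cell divergence (zero on solid cells) [1/s]."""
        h = self.domain.grid_spacing
        div = (self.u[1:, :] - self.u[:-1, :] + self.w[:, 1:] - self.w[:, :-1]) / h
        return np.where(self.domain.mask, div, 0.0)

    def checksum(self) -> int:
        """Content hash used to assert the field is never mutated."""
        return hash((self.u.tobytes(), self.w.tobytes(), self.p.tobytes()))

    def boundary_fluxes(self):
        """(inflow, outflow) volumetric flux per unit depth [m^2/s]."""
        grids = _classify_faces(self.domain, self.params)
        h = self.domain.grid_spacing
        inflow = 0.0
        outflow = 0.0
        for vel, g in ((self.u, grids["u"]), (self.w, grids["w"])):
            fixed_in = (g["type"] == _FIXED) & (g["value"] != 0.0)
            inflow += float(np.abs(vel[fixed_in]).sum()) * h
            op = g["type"] == _OPEN
            outflow += float(np.abs(vel[op]).sum()) * h
        return inflow, outflow


def sample_velocity(flow: FlowField, point) -> np.ndarray:
    """Velocity at a point strictly inside the fluid region [m/s]."""
    p = np.asarray(point, dtype=float)
    if p.ndim == 1 and not flow.domain.contains(p[None, :])[0]:
        raise SamplingError(f"point {p} lies outside the fluid region")
    return flow.sample(p)


def _bilinear(arr, gi, gj):
    """Bilinear interpolation on a 2-D array at fractional indices (clamped)."""
    ni, nj = arr.shape
    gi = np.clip(gi, 0.0, ni - 1.0)
    gj = np.clip(gj, 0.0, nj - 1.0)
    i0 = np.clip(np.floor(gi).astype(int), 0, ni - 2) if ni > 1 else np.zeros_like(gi, int)
    j0 = np.clip(np.floor(gj).astype(int), 0, nj - 2) if nj > 1 else np.zeros_like(gj, int)
    fi = gi - i0
    fj = gj - j0
    i1 = np.minimum(i0 + 1, ni - 1)
    j1 = np.minimum(j0 + 1, nj - 1)
    return ((1 - fi) * (1 - fj) * arr[i0, j0] + fi * (1 - fj) * arr[i1, j0]
            + (1 - fi) * fj * arr[i0, j1] + fi * fj * arr[i1, j1])


# -- face classification -----------------------------------------------------


def _classify_faces(domain: Domain, params: FlowParams):
    """Type/value grids for u- and w-faces.

    Boundary faces (one fluid neighbor) take the label of the nearest
    boundary segment: INLET -> fixed inward normal speed, OUTLET -> open
    (zero-gradient + pressure Dirichlet), WALL/OLFACTORY -> fixed zero.
    """
    mask = domain.mask
    ny, nz = mask.shape
    h = domain.grid_spacing
    oy, oz = domain.origin
    out = {}
    for comp in ("u", "w"):
        if comp == "u":
            lo = np.zeros((ny + 1, nz), bool)
            hi = np.zeros((ny + 1, nz), bool)
            lo[1:, :] = mask   # fluid on the -y side of the face
            hi[:-1, :] = mask  # fluid on the +y side
            fy = oy + h * np.arange(ny + 1)[:, None] + 0.0 * np.arange(nz)
            fz = oz + h * (np.arange(nz) + 0.5)[None, :] + 0.0 * fy
        else:
            lo = np.zeros((ny, nz + 1), bool)
            hi = np.zeros((ny, nz + 1), bool)
            lo[:, 1:] = mask
            hi[:, :-1] = mask
            fy = oy + h * (np.arange(ny) + 0.5)[:, None] + 0.0 * np.arange(nz + 1)
            fz = oz + h * np.arange(nz + 1)[None, :] + 0.0 * fy
        ftype = np.full(lo.shape, _DEAD, dtype=np.int8)
        value = np.zeros(lo.shape)
        ftype[lo & hi] = _UNKNOWN
        bmask = lo ^ hi
        if np.any(bmask):
            centers = np.column_stack([fy[bmask], fz[bmask]])
            _, labels = domain.distance_to_boundary(centers)
            # inward normal sign: +1 if fluid sits on the + side of the face
            normal = np.where(hi[bmask], 1.0, -1.0)
            t = np.full(labels.shape, _FIXED, dtype=np.int8)
            v = np.zeros(labels.shape)
            t[labels == RegionLabel.OUTLET] = _OPEN
            inlet = labels == RegionLabel.INLET
            v[inlet] = params.u_in * normal[inlet]
            ftype[bmask] = t
            value[bmask] = v
        out[comp] = {"type": ftype, "value": value, "lo": lo, "hi": hi}
    return out


def _open_source_indices(ftype, axis):
    """For each OPEN face, the index of the interior face it copies from."""
    idx = np.argwhere(ftype == _OPEN)
    src = idx.copy()
    n = ftype.shape[axis]
    for row in src:
        for step in (-1, 1):
            j = row[axis] + step
            if 0 <= j < n:
                probe = row.copy()
                probe[axis] = j
                if ftype[tuple(probe)] == _UNKNOWN:
                    row[axis] = j
                    break
    return idx, src


# -- assembly ----------------------------------------------------------------


def _momentum_matrix(ftype, alpha, axis):
    """A = I - nu*dt*L over unknown faces; returns (LU, rhs_const, ids)."""
    shape = ftype.shape
    ids = -np.ones(shape, dtype=np.int64)
    unk = ftype == _UNKNOWN
    n = int(unk.sum())
    ids[unk] = np.arange(n)
    pos = np.argwhere(unk)

    rows, cols, vals = [], [], []
    diag = np.ones(n)
    # rhs_const collects alpha * fixed-neighbor values (inlet speed)
    rhs_rows, rhs_vals = [], []

    for d, tangential in (((1, 0), axis != 0), ((-1, 0), axis != 0),
                          ((0, 1), axis != 1), ((0, -1), axis != 1)):
        np_pos = pos + d
        inb = ((np_pos[:, 0] >= 0) & (np_pos[:, 0] < shape[0])
               & (np_pos[:, 1] >= 0) & (np_pos[:, 1] < shape[1]))
        ntype = np.full(len(pos), _DEAD, dtype=np.int8)
        ntype[inb] = ftype[np_pos[inb, 0], np_pos[inb, 1]]

        is_unk = ntype == _UNKNOWN
        diag[is_unk] += alpha
        rows.extend(np.arange(n)[is_unk])
        cols.extend(ids[np_pos[is_unk, 0], np_pos[is_unk, 1]])
        vals.extend(np.full(int(is_unk.sum()), -alpha))

        is_fix = ntype == _FIXED
        diag[is_fix] += alpha
        rhs_rows.append((np.arange(n)[is_fix], np_pos[is_fix]))

        # open neighbor: zero-gradient, no Laplacian contribution
        is_dead = ntype == _DEAD
        if tangential:
            # ghost reflection: no-slip wall on the face line
            diag[is_dead] += 2.0 * alpha
        else:
            diag[is_dead] += alpha  # wall value 0 at the neighbor position

    rows.extend(np.arange(n))
    cols.extend(np.arange(n))
    vals.extend(diag)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return splu(A), ids, pos, rhs_rows


def _pressure_matrix(domain, grids, h, p_out):
    mask = domain.mask
    ny, nz = mask.shape
    cid = -np.ones((ny, nz), dtype=np.int64)
    n = int(mask.sum())
    cid[mask] = np.arange(n)
    pos = np.argwhere(mask)
    beta = 1.0 / h**2

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs_const = np.zeros(n)
    ut, wt = grids["u"]["type"], grids["w"]["type"]

    # faces of cell (i,j): u at (i,j) [-y], u at (i+1,j) [+y],
    #                      w at (i,j) [-z], w at (i,j+1) [+z]
    face_specs = (
        (ut, pos, (-1, 0)), (ut, pos + (1, 0), (1, 0)),
        (wt, pos, (0, -1)), (wt, pos + (0, 1), (0, 1)),
    )
    for ftype, fidx, d in face_specs:
        t = ftype[fidx[:, 0], fidx[:, 1]]
        is_int = t == _UNKNOWN
        nb = pos[is_int] + d
        diag[is_int] -= beta
        rows.extend(np.arange(n)[is_int])
        cols.extend(cid[nb[:, 0], nb[:, 1]])
        vals.extend(np.full(int(is_int.sum()), beta))
        is_open = t == _OPEN
        diag[is_open] -= 2.0 * beta
        rhs_const[is_open] += -2.0 * beta * p_out

    rows.extend(np.arange(n))
    cols.extend(np.arange(n))
    vals.extend(diag)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return splu(A), cid, rhs_const


# -- solver ------------------------------------------------------------------


def _fill_boundary(vel, g, open_idx, open_src):
    vel[g["type"] == _FIXED] = g["value"][g["type"] == _FIXED]
    vel[g["type"] == _DEAD] = 0.0
    if len(open_idx):
        vel[open_idx[:, 0], open_idx[:, 1]] = vel[open_src[:, 0], open_src[:, 1]]
    return vel


def _upwind_advection(u, w, h):
    """First-order upwind advection terms for both velocity components."""
    up = np.pad(u, 1, mode="edge")
    wp = np.pad(w, 1, mode="edge")

    # transverse velocity averaged onto the other component's faces
    ny1, nz = u.shape
    w_at_u = 0.25 * (wp[0:ny1, 1:nz + 1] + wp[1:ny1 + 1, 1:nz + 1]
                     + wp[0:ny1, 2:nz + 2] + wp[1:ny1 + 1, 2:nz + 2])
    ny, nz1 = w.shape
    u_at_w = 0.25 * (up[1:ny + 1, 0:nz1] + up[2:ny + 2, 0:nz1]
                     + up[1:ny + 1, 1:nz1 + 1] + up[2:ny + 2, 1:nz1 + 1])

    def upwind(f, fp, a_norm, a_tan):
        dn_m = (f - fp[0:-2, 1:-1]) / h
        dn_p = (fp[2:, 1:-1] - f) / h
        dt_m = (f - fp[1:-1, 0:-2]) / h
        dt_p = (fp[1:-1, 2:] - f) / h
        dn = np.where(a_norm > 0, dn_m, dn_p)
        dtan = np.where(a_tan > 0, dt_m, dt_p)
        return a_norm * dn + a_tan * dtan

    adv_u = upwind(u, up, u, w_at_u)
    dw_y_m = (w - wp[0:-2, 1:-1]) / h
    dw_y_p = (wp[2:, 1:-1] - w) / h
    dw_z_m = (w - wp[1:-1, 0:-2]) / h
    dw_z_p = (wp[1:-1, 2:] - w) / h
    adv_w = (u_at_w * np.where(u_at_w > 0, dw_y_m, dw_y_p)
             + w * np.where(w > 0, dw_z_m, dw_z_p))
    return adv_u, adv_w


def solve_flow(domain: Domain, params: FlowParams) -> FlowField:
    """March the incompressible Navier-Stokes equations to steady state.

    Raises SolverError (with the residual history attached) if the
    normalized momentum residual does not reach ``params.tolerance`` within
    ``params.max_iterations`` pseudo-time steps.
    """
    h = domain.grid_spacing
    rho, eta = params.density, params.viscosity
    nu = eta / rho

    inlet_width = float(
        domain.segment_lengths[domain.seg_label == RegionLabel.INLET].sum()
    )
    reynolds = rho * params.u_in * inlet_width / eta
    if reynolds >= 2000.0:
        raise SolverError(
            f"inlet Reynolds number {reynolds:.0f} is outside the laminar "
            "regime (>= 2000); the steady laminar model does not apply"
        )

    grids = _classify_faces(domain, params)

    if params.u_in == 0.0:
        # null forcing: the exact solution is quiescent at uniform pressure
        ny, nz = domain.mask.shape
        return FlowField(domain, params, np.zeros((ny + 1, nz)),
                         np.zeros((ny, nz + 1)),
                         np.full((ny, nz), params.outlet_pressure),
                         np.zeros(1))

    u = np.zeros(grids["u"]["type"].shape)
    w = np.zeros(grids["w"]["type"].shape)
    uo_idx, uo_src = _open_source_indices(grids["u"]["type"], axis=0)
    wo_idx, wo_src = _open_source_indices(grids["w"]["type"], axis=1)
    u = _fill_boundary(u, grids["u"], uo_idx, uo_src)
    w = _fill_boundary(w, grids["w"], wo_idx, wo_src)

    u_ref = params.u_in
    dt = params.cfl * h / u_ref
    history = []
    iteration = 0

    while True:
        alpha = nu * dt / h**2
        lu_u, uid, upos, urhs = _momentum_matrix(grids["u"]["type"], alpha, axis=0)
        lu_w, wid, wpos, wrhs = _momentum_matrix(grids["w"]["type"], alpha, axis=1)
        lu_p, cid, prhs_const = _pressure_matrix(
            domain, grids, h, params.outlet_pressure
        )
        uval, wval = grids["u"]["value"], grids["w"]["value"]
        u_const = np.zeros(int((grids["u"]["type"] == _UNKNOWN).sum()))
        for rws, npos in urhs:
            u_const[rws] += alpha * uval[npos[:, 0], npos[:, 1]]
        w_const = np.zeros(int((grids["w"]["type"] == _UNKNOWN).sum()))
        for rws, npos in wrhs:
            w_const[rws] += alpha * wval[npos[:, 0], npos[:, 1]]

        unk_u = grids["u"]["type"] == _UNKNOWN
        unk_w = grids["w"]["type"] == _UNKNOWN
        mask = domain.mask
        rescale = False

        while iteration < params.max_iterations:
            iteration += 1
            adv_u, adv_w = _upwind_advection(u, w, h)

            u_star = u.copy()
            w_star = w.copy()
            u_star[unk_u] = lu_u.solve(
                u[unk_u] - dt * adv_u[unk_u] + u_const
            )
            w_star[unk_w] = lu_w.solve(
                w[unk_w] - dt * adv_w[unk_w] + w_const
            )
            u_star = _fill_boundary(u_star, grids["u"], uo_idx, uo_src)
            w_star = _fill_boundary(w_star, grids["w"], wo_idx, wo_src)

            div = (u_star[1:, :] - u_star[:-1, :]
                   + w_star[:, 1:] - w_star[:, :-1]) / h
            rhs_p = rho / dt * div[mask] + prhs_const
            pvec = lu_p.solve(rhs_p)
            p = np.zeros(mask.shape)
            p[mask] = pvec

            # interior u faces: face (i,j) sits between cells (i-1,j), (i,j)
            iy, iz = np.nonzero(unk_u)
            u_star[iy, iz] -= dt / (rho * h) * (p[iy, iz] - p[iy - 1, iz])
            iy, iz = np.nonzero(unk_w)
            w_star[iy, iz] -= dt / (rho * h) * (p[iy, iz] - p[iy, iz - 1])
            # open faces: one-sided half-cell gradient to the outlet pressure
            if len(uo_idx):
                fi = uo_idx
                on_hi = grids["u"]["hi"][fi[:, 0], fi[:, 1]]
                pc = np.where(on_hi, p[np.minimum(fi[:, 0], mask.shape[0] - 1),
                                       fi[:, 1]],
                              p[fi[:, 0] - 1, fi[:, 1]])
                grad = np.where(on_hi,
                                (pc - params.outlet_pressure),
                                (params.outlet_pressure - pc))
                u_star[fi[:, 0], fi[:, 1]] -= 2 * dt / (rho * h) * grad
            if len(wo_idx):
                fi = wo_idx
                on_hi = grids["w"]["hi"][fi[:, 0], fi[:, 1]]
                pc = np.where(on_hi, p[fi[:, 0],
                                       np.minimum(fi[:, 1], mask.shape[1] - 1)],
                              p[fi[:, 0], fi[:, 1] - 1])
                grad = np.where(on_hi,
                                (pc - params.outlet_pressure),
                                (params.outlet_pressure - pc))
                w_star[fi[:, 0], fi[:, 1]] -= 2 * dt / (rho * h) * grad

            change = max(np.abs(u_star - u).max(), np.abs(w_star - w).max())
            residual = change * h / (dt * u_ref**2)
            history.append(residual)
            u, w = u_star, w_star

            vmax = max(np.abs(u).max(), np.abs(w).max())
            if vmax * dt / h > 0.95:
                # flow accelerated beyond the CFL budget: rebuild with
                # a smaller pseudo-time step
                dt *= 0.5
                rescale = True
                break

            if residual < params.tolerance:
                return FlowField(domain, params, u, w, p, np.asarray(history))

        if not rescale:
            raise SolverError(
                f"flow solver did not reach tolerance {params.tolerance} in "
                f"{params.max_iterations} iterations "
                f"(last residual {history[-1]:.3e})",
                residual_history=np.asarray(history),
            )
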