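"""Desk-scale pulsatile incompressible flow solver.

Chorin-type fractional-step (projection) scheme on the 2-D masked Cartesian
grid of a :class:`~laaoflow.domain.FlowDomain`:

* staggered (MAC) velocity arrangement: ``u`` on x-faces, ``v`` on y-faces;
* explicit first-order time stepping with first-order upwind advection and
  second-order centred diffusion; tangential no-slip at walls enters through
  reflected ghost values;
* inlets and the outlet carry prescribed plug velocities from the
  :class:`~laaoflow.domain.FluxProgram` (signed - pulmonary-vein backflow at
  the atrial kick simply reverses the plug);
* the pressure Poisson equation (pure Neumann, compatible by exact mass
  closure of the flux program) is solved with a sparse LU factorisation
  computed once, leaving the discrete divergence at round-off level after
  every projection.

The advective CFL condition is enforced by automatic sub-stepping of the
nominal time step.  Velocity snapshots are retained at a fixed cadence per
cycle for the downstream metrics and ink-transport modules; the full-rate
fields exist only transiently inside the loop.

Units: mm, s, mm/s; fluid properties are given in SI and converted
internally (kinematic viscosity in mm^2/s).  The solver is intentionally
2-D - the 3-D voxel domain mode serves geometry fidelity, not flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from laaoflow.domain import FlowDomain, FluxProgram
from laaoflow.errors import ParameterError, SolverError


@dataclass
class FluidProps:
    """Newtonian fluid constants (blood defaults)."""

    density: float = 1060.0          # kg/m^3
    dynamic_viscosity: float = 0.0035  # Pa*s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ParameterError("density and dynamic_viscosity must be > 0")

    @property
    def kinematic_viscosity_mm2_s(self) -> float:
        return self.dynamic_viscosity / self.density * 1e6


@dataclass
class ResidualHistory:
    """Per-step normalised residuals of the discrete equations."""

    time: np.ndarray
    continuity: np.ndarray
    momentum_x: np.ndarray
    momentum_y: np.ndarray


@dataclass
class ConvergenceReport:
    threshold: float
    history: ResidualHistory
    accepted: np.ndarray          # per-step bool
    all_accepted: bool
    worst: Dict[str, float]


@dataclass
class FlowField:
    """Time-resolved MAC velocity snapshots on a domain.

    ``u`` has shape (n_stored, nx+1, ny) and ``v`` (n_stored, nx, ny+1), in
    mm/s.  ``times`` are the snapshot times; snapshots are uniformly spaced
    with ``store_per_cycle`` per cardiac cycle, covering all ``n_cycles`` of
    which the first ``n_init_cycles`` are the initialisation phase.
    """

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    domain: FlowDomain
    fluid: FluidProps
    dt: float
    cycle_length: float
    n_cycles: int
    n_init_cycles: int
    store_per_cycle: int
    residuals: ResidualHistory

    def snapshot_indices(self, cycles: Optional[tuple] = None) -> np.ndarray:
        """Snapshot indices for the half-open cycle window [c0, c1).

        Default: the post-initialisation window."""
        if cycles is None:
            cycles = (self.n_init_cycles, self.n_cycles)
        c0, c1 = cycles
        if not (0 <= c0 < c1 <= self.n_cycles):
            raise ValueError(f"cycle window {cycles} outside the stored run")
        k = np.arange(len(self.times))
        cyc = k // self.store_per_cycle
        return k[(cyc >= c0) & (cyc < c1)]

    def cell_velocity(self, k: int) -> np.ndarray:
        """Cell-centred velocity (nx, ny, 2) of snapshot k."""
        uc = 0.5 * (self.u[k, :-1, :] + self.u[k, 1:, :])
        vc = 0.5 * (self.v[k, :, :-1] + self.v[k, :, 1:])
        return np.stack([uc, vc], axis=-1)

    def cell_speed(self, k: int) -> np.ndarray:
        vel = self.cell_velocity(k)
        return np.hypot(vel[..., 0], vel[..., 1])

    def divergence(self, k: int) -> np.ndarray:
        """Discrete divergence (1/s) of snapshot k on fluid cells, else 0."""
        h = self.domain.spacing
        div = (self.u[k, 1:, :] - self.u[k, :-1, :]
               + self.v[k, :, 1:] - self.v[k, :, :-1]) / h
        div[~self.domain.mask("fluid")] = 0.0
        return div

    def kinetic_energy(self, k: int) -> float:
        """Volume-integrated 0.5*rho*|u|^2 of snapshot k (J, using SI)."""
        speed2 = (self.cell_speed(k) ** 2)[self.domain.mask("fluid")]
        vol_m3 = self.domain.cell_volume * 1e-9
        return float(0.5 * self.fluid.density * np.sum(speed2) * 1e-6 * vol_m3)

    def export_vtk_series(self, directory, prefix="field", cycles=None):
        import os
        from laaoflow.vtkio import write_vtk_structured_points
        os.makedirs(directory, exist_ok=True)
        paths = []
        for k in self.snapshot_indices(cycles):
            vel = self.cell_velocity(k)
            path = os.path.join(directory, f"{prefix}_{k:05d}.vtk")
            write_vtk_structured_points(
                path, tuple(self.domain.origin), self.domain.spacing,
                self.domain.labels.shape,
                cell_scalars={"region": self.domain.labels.astype(float)},
                cell_vectors={"velocity": vel},
                comment=f"laaoflow velocity t={self.times[k]:.6f}")
            paths.append(path)
        return paths


class _Stencil:
    """Precomputed masks, face index sets and the pressure factorisation."""

    def __init__(self, domain: FlowDomain, dt: float):
        if domain.ndim != 2:
            raise ParameterError("the flow solver operates on 2-D domains; "
                                 "use mode='2d' (3-D voxel mode serves geometry)")
        F = domain.mask("fluid")
        nx, ny = F.shape
        self.h = domain.spacing
        self.F = F

        u_int = np.zeros((nx + 1, ny), dtype=bool)
        u_int[1:nx, :] = F[:-1, :] & F[1:, :]
        v_int = np.zeros((nx, ny + 1), dtype=bool)
        v_int[:, 1:ny] = F[:, :-1] & F[:, 1:]
        self.u_int, self.v_int = u_int, v_int

        u_live = np.zeros((nx + 1, ny), dtype=bool)
        u_live[1:nx, :] = F[:-1, :] | F[1:, :]
        u_live[0, :] = F[0, :]
        u_live[nx, :] = F[-1, :]
        v_live = np.zeros((nx, ny + 1), dtype=bool)
        v_live[:, 1:ny] = F[:, :-1] | F[:, 1:]
        v_live[:, 0] = F[:, 0]
        v_live[:, ny] = F[:, -1]
        self.u_live, self.v_live = u_live, v_live

        # prescribed boundary faces per kind -> (array, index tuple)
        self.face_sets = {}
        for kind, rows in domain.boundary_faces.items():
            if len(rows) == 0:
                self.face_sets[kind] = None
                continue
            ax = rows[:, 2]
            off = (rows[:, 3] + 1) // 2
            ui = rows[ax == 0]
            vi = rows[ax == 1]
            self.face_sets[kind] = {
                "u": (ui[:, 0] + (ui[:, 3] + 1) // 2, ui[:, 1], ui[:, 3]),
                "v": (vi[:, 0], vi[:, 1] + (vi[:, 3] + 1) // 2, vi[:, 3]),
                "n_faces": len(rows),
            }

        # pressure Poisson operator over fluid cells (Neumann walls), pinned
        idx = -np.ones(F.shape, dtype=np.int64)
        ids = np.arange(np.count_nonzero(F))
        idx[F] = ids
        self.cell_index = idx
        n = len(ids)
        rows_, cols_, vals_ = [], [], []
        diag = np.zeros(n)
        for daxis, (di, dj) in enumerate(((1, 0), (0, 1))):
            for sgn in (1, -1):
                here = np.argwhere(F)
                there = here + sgn * np.array([di, dj])
                ok = (there[:, 0] >= 0) & (there[:, 0] < nx) \
                    & (there[:, 1] >= 0) & (there[:, 1] < ny)
                here, there = here[ok], there[ok]
                nbr_fluid = F[there[:, 0], there[:, 1]]
                here, there = here[nbr_fluid], there[nbr_fluid]
                a = idx[here[:, 0], here[:, 1]]
                b = idx[there[:, 0], there[:, 1]]
                rows_.append(a)
                cols_.append(b)
                vals_.append(np.ones(len(a)))
                np.add.at(diag, a, -1.0)
        rows_ = np.concatenate(rows_ + [ids])
        cols_ = np.concatenate(cols_ + [ids])
        vals_ = np.concatenate(vals_ + [diag]) / self.h ** 2
        A = sp.csc_matrix((vals_, (rows_, cols_)), shape=(n, n))
        # pin the first cell to fix the Neumann nullspace
        A = A.tolil()
        A.rows[0] = [0]
        A.data[0] = [1.0]
        self.lu = splu(A.tocsc())
        self.n_cells = n

    def apply_bc(self, u, v, face_values: Dict[str, float]):
        """Set prescribed plug velocities; positive value = inflow."""
        for kind, fs in self.face_sets.items():
            if fs is None:
                continue
            if kind == "wall":
                un = 0.0
                sgn_u = sgn_v = 0.0
            else:
                un = face_values.get(kind, 0.0)
            ui, uj, uside = fs["u"]
            vi, vj, vside = fs["v"]
            if kind == "wall":
                u[ui, uj] = 0.0
                v[vi, vj] = 0.0
            elif kind == "outlet":
                u[ui, uj] = uside * un
                v[vi, vj] = vside * un
            else:  # inlet: velocity opposes the outward normal
                u[ui, uj] = -uside * un
                v[vi, vj] = -vside * un

    def project(self, u, v, dt):
        h = self.h
        div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
        rhs = div[self.F] / dt
        rhs -= rhs.mean()
        p = self.lu.solve(rhs)
        pg = np.zeros(self.F.shape)
        pg[self.F] = p
        gx = (pg[1:, :] - pg[:-1, :]) / h
        gy = (pg[:, 1:] - pg[:, :-1]) / h
        u[1:-1, :][self.u_int[1:-1, :]] -= dt * gx[self.u_int[1:-1, :]]
        v[:, 1:-1][self.v_int[:, 1:-1]] -= dt * gy[self.v_int[:, 1:-1]]


def _upwind_terms(u, v, stencil, nu):
    """Advection and diffusion updates for both velocity components."""
    h = stencil.h
    # --- u component ---
    uc = u
    ue = np.roll(u, -1, axis=0)
    uw = np.roll(u, 1, axis=0)
    un_raw = np.roll(u, -1, axis=1)
    us_raw = np.roll(u, 1, axis=1)
    live_n = np.roll(stencil.u_live, -1, axis=1)
    live_s = np.roll(stencil.u_live, 1, axis=1)
    un = np.where(live_n, un_raw, -uc)   # reflected ghost: no-slip wall
    us = np.where(live_s, us_raw, -uc)
    v_at_u = np.zeros_like(u)
    v_pad = v
    v_at_u[1:-1, :] = 0.25 * (v_pad[:-1, :-1] + v_pad[:-1, 1:]
                              + v_pad[1:, :-1] + v_pad[1:, 1:])
    dudx = np.where(uc > 0, (uc - uw) / h, (ue - uc) / h)
    dudy = np.where(v_at_u > 0, (uc - us) / h, (un - uc) / h)
    adv_u = uc * dudx + v_at_u * dudy
    lap_u = (ue - 2 * uc + uw + un + us - 2 * uc) / h ** 2

    # --- v component ---
    vc = v
    vn = np.roll(v, -1, axis=1)
    vs = np.roll(v, 1, axis=1)
    ve_raw = np.roll(v, -1, axis=0)
    vw_raw = np.roll(v, 1, axis=0)
    live_e = np.roll(stencil.v_live, -1, axis=0)
    live_w = np.roll(stencil.v_live, 1, axis=0)
    ve = np.where(live_e, ve_raw, -vc)
    vw = np.where(live_w, vw_raw, -vc)
    u_at_v = np.zeros_like(v)
    u_at_v[:, 1:-1] = 0.25 * (u[:-1, :-1] + u[1:, :-1] + u[:-1, 1:] + u[1:, 1:])
    dvdy = np.where(vc > 0, (vc - vs) / h, (vn - vc) / h)
    dvdx = np.where(u_at_v > 0, (vc - vw) / h, (ve - vc) / h)
    adv_v = u_at_v * dvdx + vc * dvdy
    lap_v = (ve - 2 * vc + vw + vn + vs - 2 * vc) / h ** 2

    return adv_u, nu * lap_u, adv_v, nu * lap_v


def solve_flow(domain: FlowDomain, flux: FluxProgram, fluid: FluidProps = None,
               n_cycles: int = 12, dt: float = 0.001, n_init_cycles: int = 4,
               store_per_cycle: int = 50, initial_uv=None, cfl: float = 0.5,
               max_substeps: int = 64, residual_threshold: float = 1e-3) -> FlowField:
    """March the pulsatile flow for ``n_cycles`` cardiac cycles.

    The first ``n_init_cycles`` cycles initialise the flow and are flagged so
    downstream metrics exclude them by default.  Snapshots are stored
    ``store_per_cycle`` times per cycle.  Raises :class:`SolverError` if the
    advective CFL condition cannot be met within ``max_substeps`` sub-steps.
    """
    if fluid is None:
        fluid = FluidProps()
    if n_init_cycles >= n_cycles:
        raise ParameterError("n_cycles must exceed n_init_cycles")
    T = flux.cycle_length
    steps = int(round(T / dt))
    dt = T / steps
    if steps < store_per_cycle:
        raise ParameterError("dt too coarse for the snapshot cadence")
    stride = max(1, steps // store_per_cycle)
    store_per_cycle = steps // stride
    if steps % stride:
        raise ParameterError("store_per_cycle must divide the steps per cycle")

    stencil = _Stencil(domain, dt)
    h = domain.spacing
    nu = fluid.kinematic_viscosity_mm2_s
    nx, ny = domain.labels.shape
    if initial_uv is None:
        u = np.zeros((nx + 1, ny))
        v = np.zeros((nx, ny + 1))
    else:
        u, v = (np.array(initial_uv[0], dtype=float),
                np.array(initial_uv[1], dtype=float))

    # plug velocities (mm/s) per mL/s of programmed flow, per boundary kind
    area = domain.face_area
    per_kind_scale = {}
    for kind, fs in stencil.face_sets.items():
        if fs is not None and kind != "wall":
            per_kind_scale[kind] = 1000.0 / (fs["n_faces"] * area)

    # explicit diffusion stability
    dt_visc = 0.2 * h * h / nu
    u_scale = 1.0

    n_steps = n_cycles * steps
    times_res = np.empty(n_steps)
    res_c = np.empty(n_steps)
    res_u = np.empty(n_steps)
    res_v = np.empty(n_steps)
    snaps_t, snaps_u, snaps_v = [], [], []

    def bc_values(t):
        q = flux.interpolate(t)
        vals = {}
        for kind, scale in per_kind_scale.items():
            if kind == "outlet":
                vals[kind] = float(q["outlet"]) * scale
            else:
                vals[kind] = float(q.get(kind, 0.0)) * scale
        return vals

    stencil.apply_bc(u, v, bc_values(0.0))
    snaps_t.append(0.0)
    snaps_u.append(u.copy())
    snaps_v.append(v.copy())

    for step_i in range(n_steps):
        t0 = step_i * dt
        t1 = t0 + dt
        speed = max(np.abs(u).max(), np.abs(v).max(), 1e-9)
        nsub = int(np.ceil(dt * speed / (cfl * h)))
        nsub = max(nsub, int(np.ceil(dt / dt_visc)))
        if nsub > max_substeps:
            raise SolverError(
                f"CFL sub-step cap exceeded at t={t0:.4f}s "
                f"(max speed {speed:.1f} mm/s needs {nsub} sub-steps)")
        dts = dt / nsub
        u_prev = u.copy()
        v_prev = v.copy()
        for k in range(nsub):
            ts = t0 + (k + 1) * dts
            adv_u, dif_u, adv_v, dif_v = _upwind_terms(u, v, stencil, nu)
            du = dts * (-adv_u + dif_u)
            dv = dts * (-adv_v + dif_v)
            u = np.where(stencil.u_int, u + du, u)
            v = np.where(stencil.v_int, v + dv, v)
            stencil.apply_bc(u, v, bc_values(ts))
            stencil.project(u, v, dts)

        u_scale = max(u_scale, speed)
        div = (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / h
        times_res[step_i] = t1
        res_c[step_i] = np.abs(div[stencil.F]).max() * h / u_scale
        res_u[step_i] = np.abs(u - u_prev).max() / u_scale
        res_v[step_i] = np.abs(v - v_prev).max() / u_scale

        if (step_i + 1) % stride == 0:
            snaps_t.append(t1)
            snaps_u.append(u.copy())
            snaps_v.append(v.copy())

    # drop the initial rest snapshot so each cycle holds store_per_cycle frames
    history = ResidualHistory(time=times_res, continuity=res_c,
                              momentum_x=res_u, momentum_y=res_v)
    return FlowField(times=np.array(snaps_t[1:]), u=np.array(snaps_u[1:]),
                     v=np.array(snaps_v[1:]), domain=domain, fluid=fluid,
                     dt=dt, cycle_length=T, n_cycles=n_cycles,
                     n_init_cycles=n_init_cycles, store_per_cycle=store_per_cycle,
                     residuals=history)


def check_convergence(history: ResidualHistory,
                      threshold: float = 1e-3) -> ConvergenceReport:
    """Classify per-step residuals against the acceptance threshold.

    A step is accepted when the normalised continuity and both momentum
    residuals all fall below ``threshold`` (default 1e-3).
    """
    acc = (history.continuity < threshold) & (history.momentum_x < threshold) \
        & (history.momentum_y < threshold)
    worst = {
        "continuity": float(np.max(history.continuity)),
        "momentum_x": float(np.max(history.momentum_x)),
        "momentum_y": float(np.max(history.momentum_y)),
    }
    return ConvergenceReport(threshold=threshold, history=history,
                             accepted=acc, all_accepted=bool(acc.all()),
                             worst=worst)
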