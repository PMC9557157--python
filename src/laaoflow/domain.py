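"""Synthetic left-atrium + appendage flow domain and boundary-flux programs.

No patient geometry is consumed anywhere in the package; instead an idealized
left heart is built on a uniform Cartesian grid with labelled regions:

* ``LA``  - left atrial chamber fed by two pulmonary-vein (PV) inlets,
* ``LAA`` - a blind appendage pouch hanging off the atrial wall behind a neck,
* ``LV``  - ventricular chamber (including the mitral channel) draining into
  an apical assist-device cannula outlet.

Two modes exist.  The 2-D mode is the default working scale for the flow
solver: areas are converted to volumes with a fixed out-of-plane depth chosen
so the atrial (LA+LAA) volume matches its end-systolic target.  The 3-D voxel
mode assembles the chambers from analytic solids (capped sphere atrium, capped
prolate ellipsoid ventricle, spherical pouch plus neck cylinder) whose free
dimensions are fixed by deterministic bisection against the voxel-summed
region volumes, so both reference end-systolic chamber volumes (atrium
169 cm^3, ventricle 295 cm^3) are reproduced.

Occlusion (``occluded=True``) removes every appendage cell, sealing the pouch
at its neck plane; the rest of the domain is cell-for-cell identical to the
unoccluded variant.

The moving chamber walls of the original problem are replaced by a rigid
domain driven by a flux-equivalent boundary program (:func:`make_flux_program`):
the PV inflow carries the pump through-flow plus the flux equivalent of the
instantaneous LA+LV volume change, split 55/45 between right and left veins,
and the cannula outlet carries the same total so mass closes exactly at every
instant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from laaoflow.errors import ParameterError
from laaoflow.lpm import WaveformSet

OUTSIDE, LA, LAA, LV = 0, 1, 2, 3
REGION_IDS: Dict[str, int] = {"LA": LA, "LAA": LAA, "LV": LV}


@dataclass
class DomainConfig:
    """Geometry configuration; lengths in mm, volumes in cm^3.

    Fields prefixed ``la2d_``/``lv2d_`` only apply to the 2-D mode; the
    analytic-solid fields (``mitral_radius``, ``laa_pouch_radius``, ...) only
    to the 3-D voxel mode.
    """

    mode: str = "2d"                        # "2d" | "3d"
    spacing: float = 1.0                    # grid spacing, mm
    occluded: bool = False
    target_atrial_volume: float = 169.0     # cm^3, LA + LAA
    target_ventricular_volume: float = 295.0  # cm^3

    # -- 2-D layout -----------------------------------------------------
    la2d_width: float = 60.0
    la2d_height: float = 50.0
    lv2d_width: float = 50.0
    lv2d_height: float = 70.0
    mitral2d_half_width: float = 12.0
    mitral2d_channel_height: float = 10.0
    laa2d_pouch_width: float = 15.0
    laa2d_pouch_height: float = 15.0
    laa2d_neck_width: float = 10.0
    laa2d_neck_length: float = 2.0
    pv2d_inlet_width: float = 12.0
    # inlet centres: the left vein enters beside the appendage side of the
    # atrium (its anatomical neighbour), the right vein toward the middle
    pv2d_right_center: float = 12.0
    pv2d_left_center: float = -22.0
    outlet2d_width: float = 12.0
    depth: Optional[float] = None           # out-of-plane depth; None -> derived

    # -- 3-D solids -----------------------------------------------------
    mitral_radius: float = 14.0
    laa_pouch_radius: float = 12.9          # ~9 mL pouch
    laa_neck_width: float = 12.0            # neck cylinder diameter
    lv_aspect: float = 1.9                  # long/short semi-axis ratio
    pv_inlet_radius: float = 8.0
    outlet_radius: float = 6.0

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ParameterError("mode must be '2d' or '3d'")
        for name in ("spacing", "target_atrial_volume", "target_ventricular_volume",
                     "la2d_width", "la2d_height", "lv2d_width", "lv2d_height",
                     "mitral2d_half_width", "laa2d_pouch_width", "laa2d_pouch_height",
                     "laa2d_neck_width", "mitral_radius", "laa_pouch_radius",
                     "laa_neck_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.mode == "2d":
            if self.laa2d_neck_width >= self.laa2d_pouch_height:
                raise ParameterError("neck width must be smaller than the pouch")
            if self.laa2d_neck_width / self.spacing < 4:
                raise ParameterError(
                    "grid spacing too coarse: the appendage neck must span >= 4 cells")
        else:
            if self.laa_neck_width >= 2 * self.laa_pouch_radius:
                raise ParameterError("neck width must be smaller than the pouch")
            if self.laa_neck_width / self.spacing < 4:
                raise ParameterError(
                    "grid spacing too coarse: the appendage neck must span >= 4 cells")


@dataclass
class FlowDomain:
    """Labelled voxel/pixel domain with boundary-face metadata.

    ``labels`` is indexed ``[ix, iy]`` (2-D) or ``[ix, iy, iz]`` (3-D); cell
    centres sit at ``origin + (index + 0.5) * spacing``.  ``boundary_faces``
    maps face kind (``pv_right``, ``pv_left``, ``outlet``, ``laa_wall``,
    ``wall``) to an integer array with rows ``(cell index..., axis, side)``,
    ``side`` being +1/-1 for the face on the high/low side of the cell;
    ``laa_wall`` marks the pouch end-wall faces that stand in for the moving
    appendage wall.
    """

    labels: np.ndarray
    origin: np.ndarray
    spacing: float
    config: DomainConfig
    boundary_faces: Dict[str, np.ndarray]
    depth: Optional[float] = None           # 2-D only, mm

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def cell_volume(self) -> float:
        """Volume of one cell, mm^3 (2-D cells use the out-of-plane depth)."""
        if self.ndim == 2:
            return self.spacing ** 2 * self.depth
        return self.spacing ** 3

    @property
    def face_area(self) -> float:
        """Area of one cell face, mm^2."""
        if self.ndim == 2:
            return self.spacing * self.depth
        return self.spacing ** 2

    def mask(self, region: str) -> np.ndarray:
        if region == "fluid":
            return self.labels > 0
        if region == "atrium":
            return (self.labels == LA) | (self.labels == LAA)
        if region not in REGION_IDS:
            raise ParameterError(f"unknown region {region!r}")
        return self.labels == REGION_IDS[region]

    def region_volume(self, region: str) -> float:
        """Summed cell volume of a region, mm^3."""
        return float(np.count_nonzero(self.mask(region))) * self.cell_volume

    def cell_centers(self) -> np.ndarray:
        idx = np.indices(self.labels.shape).astype(float)
        return np.moveaxis(self.origin.reshape((-1,) + (1,) * self.ndim)
                           + (idx + 0.5) * self.spacing, 0, -1)

    def wall_faces_by_region(self) -> Dict[str, np.ndarray]:
        """Wall faces grouped by the region of their fluid cell."""
        walls = self.boundary_faces["wall"]
        cells = tuple(walls[:, d] for d in range(self.ndim))
        labels = self.labels[cells]
        out = {}
        for name, rid in REGION_IDS.items():
            out[name] = walls[labels == rid]
        return out

    def export_vtk(self, path):
        from laaoflow.vtkio import write_vtk_structured_points
        write_vtk_structured_points(
            path, tuple(self.origin), self.spacing, self.labels.shape,
            cell_scalars={"region": self.labels.astype(float)},
            comment="laaoflow synthetic left-heart domain")


# ---------------------------------------------------------------------------
# analytic solids (3-D oracle formulas)
# ---------------------------------------------------------------------------

def capped_sphere_volume(radius: float, center_height: float) -> float:
    """Volume of a sphere of ``radius`` centred ``center_height`` above a
    cutting plane, keeping the part above the plane (mm^3)."""
    h = radius - center_height           # height of the removed cap
    v = 4.0 / 3.0 * np.pi * radius ** 3
    if h > 0:
        v -= np.pi * h * h * (3 * radius - h) / 3.0
    return float(v)


def capped_ellipsoid_volume(b: float, c: float, center_depth: float) -> float:
    """Volume of an ellipsoid with semi-axes (b, b, c), centred
    ``center_depth`` below a cutting plane, keeping the part below (mm^3)."""
    u0 = center_depth / c                # plane height in unit-sphere frame
    v = 4.0 / 3.0 * np.pi * b * b * c
    if u0 < 1.0:
        v -= np.pi * b * b * c * (2.0 / 3.0 - u0 + u0 ** 3 / 3.0)
    return float(v)


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------

def build_domain(config: DomainConfig) -> FlowDomain:
    """Build the labelled domain for the configured mode.

    Raises ``ParameterError`` for a grid too coarse to resolve the appendage
    neck (checked in the config) and asserts single-connectedness of the
    fluid region.
    """
    if config.mode == "2d":
        dom = _build_domain_2d(config)
    else:
        dom = _build_domain_3d(config)
    _check_connected(dom)
    return dom


def _build_domain_2d(config: DomainConfig) -> FlowDomain:
    h = config.spacing
    c = config
    la_x0, la_x1 = -c.la2d_width / 2, c.la2d_width / 2
    la_y0 = c.mitral2d_channel_height
    la_y1 = la_y0 + c.la2d_height
    lv_x0, lv_x1 = -c.lv2d_width / 2, c.lv2d_width / 2
    lv_y1 = 0.0
    lv_y0 = -c.lv2d_height
    neck_x1 = la_x0
    neck_x0 = la_x0 - c.laa2d_neck_length
    pouch_x1 = neck_x0
    pouch_x0 = pouch_x1 - c.laa2d_pouch_width
    pouch_yc = la_y0 + 0.6 * c.la2d_height
    pouch_y0 = pouch_yc - c.laa2d_pouch_height / 2
    pouch_y1 = pouch_yc + c.laa2d_pouch_height / 2
    neck_y0 = pouch_yc - c.laa2d_neck_width / 2
    neck_y1 = pouch_yc + c.laa2d_neck_width / 2

    x_min, x_max = pouch_x0 - h, max(la_x1, lv_x1) + h
    y_min, y_max = lv_y0 - h, la_y1 + h
    origin = np.array([np.floor(x_min / h) * h, np.floor(y_min / h) * h])
    nx = int(np.ceil((x_max - origin[0]) / h))
    ny = int(np.ceil((y_max - origin[1]) / h))
    xc = origin[0] + (np.arange(nx) + 0.5) * h
    yc = origin[1] + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    def rect(x0, x1, y0, y1):
        return (X > x0) & (X < x1) & (Y > y0) & (Y < y1)

    labels = np.zeros((nx, ny), dtype=np.int8)
    labels[rect(la_x0, la_x1, la_y0, la_y1)] = LA
    # ventricle: half-ellipse tapering to the apex (no stagnant box corners)
    b_lv, c_lv = c.lv2d_width / 2, c.lv2d_height
    lv_ellipse = (X / b_lv) ** 2 + (Y / c_lv) ** 2 < 1.0
    labels[lv_ellipse & (Y < 0)] = LV
    labels[rect(-c.mitral2d_half_width, c.mitral2d_half_width, 0.0, la_y0)] = LV
    labels[rect(pouch_x0, pouch_x1, pouch_y0, pouch_y1)] = LAA
    labels[rect(neck_x0, neck_x1, neck_y0, neck_y1)] = LAA

    depth = c.depth
    if depth is None:
        atrial_area = np.count_nonzero((labels == LA) | (labels == LAA)) * h * h
        depth = c.target_atrial_volume * 1000.0 / atrial_area

    if c.occluded:
        labels[labels == LAA] = OUTSIDE

    faces = _boundary_faces(labels)
    centers_x = origin[0] + (faces[:, 0] + 0.5) * h
    centers_y = origin[1] + (faces[:, 1] + 0.5) * h
    kinds = np.full(len(faces), "wall", dtype=object)
    top = (faces[:, 2] == 1) & (faces[:, 3] == 1) & (centers_y > la_y1 - h)
    half_w = c.pv2d_inlet_width / 2
    kinds[top & (np.abs(centers_x - c.pv2d_right_center) < half_w)] = "pv_right"
    kinds[top & (np.abs(centers_x - c.pv2d_left_center) < half_w)] = "pv_left"
    bottom = (faces[:, 2] == 1) & (faces[:, 3] == -1) & (centers_y < 0.9 * lv_y0)
    kinds[bottom & (np.abs(centers_x) < c.outlet2d_width / 2)] = "outlet"
    # far end-wall of the pouch: stand-in for the moving appendage wall
    cell_lab = labels[faces[:, 0], faces[:, 1]]
    kinds[(cell_lab == LAA) & (faces[:, 2] == 0) & (faces[:, 3] == -1)
          & (centers_x < pouch_x0 + h)] = "laa_wall"

    boundary = {k: faces[kinds == k]
                for k in ("pv_right", "pv_left", "outlet", "laa_wall", "wall")}
    for k in ("pv_right", "pv_left", "outlet"):
        if len(boundary[k]) == 0:
            raise ParameterError(f"no faces found for boundary {k!r}; "
                                 "check inlet/outlet widths against the grid")
    return FlowDomain(labels=labels, origin=origin, spacing=h, config=replace(c),
                      boundary_faces=boundary, depth=depth)


def _build_domain_3d(config: DomainConfig) -> FlowDomain:
    c = config
    h = c.spacing
    a = c.mitral_radius

    # --- atrial sphere radius from the atrial volume target (bisection) ---
    r_p = c.laa_pouch_radius
    r_n = c.laa_neck_width / 2.0

    def atrial_voxel_volume(R_la):
        zc = np.sqrt(R_la ** 2 - a ** 2)
        la, laa = _atrial_masks_3d(R_la, zc, r_p, r_n, h)
        return (np.count_nonzero(la) + np.count_nonzero(laa)) * h ** 3

    target_a = c.target_atrial_volume * 1000.0
    R_la = _bisect(atrial_voxel_volume, target_a, max(a + 2.0, 20.0), 60.0)
    zc_la = np.sqrt(R_la ** 2 - a ** 2)

    # --- ventricular ellipsoid from the ventricular volume target ---
    def ventric_voxel_volume(b):
        cc = c.lv_aspect * b
        zc_lv = cc * np.sqrt(max(1.0 - a ** 2 / b ** 2, 0.0))
        return np.count_nonzero(_lv_mask_3d(b, cc, zc_lv, h)) * h ** 3

    target_v = c.target_ventricular_volume * 1000.0
    b_lv = _bisect(ventric_voxel_volume, target_v, max(a + 2.0, 20.0), 60.0)
    c_lv = c.lv_aspect * b_lv
    zc_lv = c_lv * np.sqrt(1.0 - a ** 2 / b_lv ** 2)

    # --- assemble full grid ---
    x_min = -(b_lv + 2 * h)
    x_max = R_la + 6.0 + 2 * r_p + 2 * h
    y_min, y_max = -(max(R_la, b_lv) + 2 * h), max(R_la, b_lv) + 2 * h
    z_min = -(zc_lv + c_lv + 2 * h)
    z_max = zc_la + R_la + 2 * h
    origin = np.floor(np.array([x_min, y_min, z_min]) / h) * h
    n = np.ceil((np.array([x_max, y_max, z_max]) - origin) / h).astype(int)
    coords = [origin[d] + (np.arange(n[d]) + 0.5) * h for d in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")

    la_sphere = X ** 2 + Y ** 2 + (Z - zc_la) ** 2 < R_la ** 2
    la_mask = la_sphere & (Z > 0)
    xp = R_la + 2.0 + r_p              # pouch centre, 2 mm gap bridged by the neck
    pouch = (X - xp) ** 2 + Y ** 2 + (Z - zc_la) ** 2 < r_p ** 2
    neck = (Y ** 2 + (Z - zc_la) ** 2 < r_n ** 2) & (X > R_la - 3.0) & (X < xp)
    laa_mask = (pouch | neck) & ~la_mask & (Z > 0)
    lv_mask = (X ** 2 + Y ** 2) / b_lv ** 2 + (Z + zc_lv) ** 2 / c_lv ** 2 < 1.0
    lv_mask &= Z < 0

    labels = np.zeros(tuple(n), dtype=np.int8)
    labels[la_mask] = LA
    labels[laa_mask] = LAA
    labels[lv_mask] = LV
    if c.occluded:
        labels[labels == LAA] = OUTSIDE

    faces = _boundary_faces(labels)
    centers = origin[None, :] + (faces[:, :3] + 0.5) * h
    kinds = np.full(len(faces), "wall", dtype=object)
    z_top = zc_la + R_la
    up = (faces[:, 3] == 2) & (faces[:, 4] == 1)
    for side, xa in (("pv_right", +14.0), ("pv_left", -14.0)):
        near = (centers[:, 0] - 0.0) ** 2 + (centers[:, 1] - xa) ** 2 \
            < c.pv_inlet_radius ** 2
        kinds[up & near & (centers[:, 2] > z_top - 0.35 * R_la)] = side
    down = (faces[:, 3] == 2) & (faces[:, 4] == -1)
    apex = centers[:, 0] ** 2 + centers[:, 1] ** 2 < c.outlet_radius ** 2
    kinds[down & apex & (centers[:, 2] < -(zc_lv + 0.8 * c_lv))] = "outlet"
    cell_lab = labels[faces[:, 0], faces[:, 1], faces[:, 2]]
    kinds[(cell_lab == LAA) & (faces[:, 3] == 0) & (faces[:, 4] == 1)
          & (centers[:, 0] > xp)] = "laa_wall"

    boundary = {k: faces[kinds == k]
                for k in ("pv_right", "pv_left", "outlet", "laa_wall", "wall")}
    dom = FlowDomain(labels=labels, origin=origin, spacing=h, config=replace(c),
                     boundary_faces=boundary, depth=None)
    # stash the fitted solids for the analytic-volume oracle
    dom.solids = {"R_la": float(R_la), "zc_la": float(zc_la), "b_lv": float(b_lv),
                  "c_lv": float(c_lv), "zc_lv": float(zc_lv),
                  "pouch_center_x": float(xp)}
    return dom


def _atrial_masks_3d(R_la, zc, r_p, r_n, h):
    margin = 2 * h
    x = np.arange(-R_la - margin, R_la + 6.0 + 2 * r_p + margin, h)
    y = np.arange(-R_la - margin, R_la + margin, h)
    z = np.arange(-margin, zc + R_la + margin, h)
    X, Y, Z = np.meshgrid(x + h / 2, y + h / 2, z + h / 2, indexing="ij")
    la_sphere = X ** 2 + Y ** 2 + (Z - zc) ** 2 < R_la ** 2
    la = la_sphere & (Z > 0)
    xp = R_la + 2.0 + r_p
    pouch = (X - xp) ** 2 + Y ** 2 + (Z - zc) ** 2 < r_p ** 2
    neck = (Y ** 2 + (Z - zc) ** 2 < r_n ** 2) & (X > R_la - 3.0) & (X < xp)
    return la, (pouch | neck) & ~la & (Z > 0)


def _lv_mask_3d(b, cc, zc_lv, h):
    margin = 2 * h
    x = np.arange(-b - margin, b + margin, h)
    z = np.arange(-(zc_lv + cc + margin), margin, h)
    X, Y, Z = np.meshgrid(x + h / 2, x + h / 2, z + h / 2, indexing="ij")
    return ((X ** 2 + Y ** 2) / b ** 2 + (Z + zc_lv) ** 2 / cc ** 2 < 1.0) & (Z < 0)


def _bisect(fn, target, lo, hi, iters=40):
    flo, fhi = fn(lo), fn(hi)
    if not (flo <= target <= fhi):
        raise ParameterError("volume target outside the bracketed solid sizes")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _boundary_faces(labels: np.ndarray) -> np.ndarray:
    """All faces between a fluid cell and a non-fluid (or grid-edge) neighbour.

    Rows: (cell index..., axis, side)."""
    fluid = labels > 0
    nd = labels.ndim
    rows = []
    for axis in range(nd):
        for side in (-1, 1):
            shifted = np.roll(fluid, -side, axis=axis)
            # roll wraps; edge cells are boundary faces by construction
            edge = np.zeros_like(fluid)
            idx = [slice(None)] * nd
            idx[axis] = -1 if side == 1 else 0
            edge[tuple(idx)] = True
            is_b = fluid & (~shifted | edge)
            cells = np.argwhere(is_b)
            if len(cells):
                extra = np.tile([axis, side], (len(cells), 1))
                rows.append(np.hstack([cells, extra]))
    return np.vstack(rows) if rows else np.empty((0, nd + 2), dtype=int)


def _check_connected(dom: FlowDomain):
    from scipy import ndimage
    lab, num = ndimage.label(dom.labels > 0)
    if num != 1:
        raise ParameterError(f"fluid domain is not connected ({num} components)")


def channel_domain(length: float = 60.0, height: float = 10.0,
                   spacing: float = 1.0, depth: float = 10.0) -> FlowDomain:
    """Straight rectangular channel (2-D), inlet left, outlet right.

    A verification geometry: steady flow through it develops the
    plane-Poiseuille profile with wall shear stress 6*mu*U_mean/height.  The
    whole channel is labelled ``LA`` and its single inlet reuses the
    ``pv_right`` face kind so the solver drives it like any other domain.
    """
    h = spacing
    origin = np.array([-h, -h])
    nx = int(round(length / h)) + 2
    ny = int(round(height / h)) + 2
    labels = np.zeros((nx, ny), dtype=np.int8)
    labels[1:-1, 1:-1] = LA
    faces = _boundary_faces(labels)
    kinds = np.full(len(faces), "wall", dtype=object)
    kinds[(faces[:, 2] == 0) & (faces[:, 3] == -1)] = "pv_right"
    kinds[(faces[:, 2] == 0) & (faces[:, 3] == 1)] = "outlet"
    boundary = {k: faces[kinds == k] for k in ("pv_right", "outlet", "wall")}
    boundary["pv_left"] = faces[:0]
    boundary["laa_wall"] = faces[:0]
    cfg = DomainConfig(mode="2d", spacing=h, depth=depth,
                       target_atrial_volume=length * height * depth / 1000.0)
    return FlowDomain(labels=labels, origin=origin, spacing=h, config=cfg,
                      boundary_faces=boundary, depth=depth)


def steady_flux_program(q_ml_per_s: float, duration: float = 1.0,
                        inlets=("pv_right",), n: int = 51) -> FluxProgram:
    """Constant-flow program (for verification runs on test geometries)."""
    t = np.linspace(0.0, duration, n)
    per = q_ml_per_s / len(inlets)
    inflow = {"pv_right": np.zeros(n), "pv_left": np.zeros(n)}
    for k in inlets:
        inflow[k] = np.full(n, per)
    total = sum(inflow.values())
    return FluxProgram(time=t, inflow=inflow, outflow=total,
                       mitral_plane=np.zeros(n), heart_rate=60.0 / duration)


# ---------------------------------------------------------------------------
# flux program
# ---------------------------------------------------------------------------

@dataclass
class FluxProgram:
    """Boundary flow-rate program over one cardiac cycle (mL/s).

    ``inflow`` maps inlet name to its series; the 55/45 right/left split
    holds exactly at every instant, and ``outflow`` equals the summed inflow
    (rigid domain: no storage).  ``mitral_plane`` is the circulation model's
    mitral flow, carried as a diagnostic of diastolic timing.
    """

    time: np.ndarray
    inflow: Dict[str, np.ndarray]
    outflow: np.ndarray
    mitral_plane: np.ndarray
    heart_rate: float

    @property
    def cycle_length(self) -> float:
        return float(self.time[-1] - self.time[0])

    def total_inflow(self) -> np.ndarray:
        return sum(self.inflow.values())

    def interpolate(self, t):
        """Periodic interpolation of (inflows..., outflow) at time(s) t."""
        tau = np.mod(t, self.cycle_length)
        out = {k: np.interp(tau, self.time, v) for k, v in self.inflow.items()}
        out["outlet"] = np.interp(tau, self.time, self.outflow)
        return out

    def to_dataframe(self):
        import pandas as pd
        data = {"time_s": self.time}
        for k, v in self.inflow.items():
            data[f"inflow_{k}_ml_per_s"] = v
        data["outflow_ml_per_s"] = self.outflow
        data["mitral_plane_ml_per_s"] = self.mitral_plane
        return pd.DataFrame(data)


def _periodic_derivative(series: np.ndarray, dt: float) -> np.ndarray:
    vp = series[:-1]  # drop duplicated endpoint; series is periodic
    d = (np.roll(vp, -1) - np.roll(vp, 1)) / (2.0 * dt)
    return np.append(d, d[0])


def make_flux_program(w: WaveformSet, domain: FlowDomain,
                      split=(0.55, 0.45)) -> FluxProgram:
    """Translate converged circulation waveforms into boundary fluxes.

    The rigid domain sees PV inflow equal to the pump through-flow plus the
    flux equivalent of the LA+LV volume change (the physical pulmonary-vein
    return of the moving-wall system), split 55/45 right/left.

    The appendage's share of the atrial wall motion is carried by the pouch
    end-wall (``laa_wall`` boundary): the pouch walls move with the atrium,
    so their flux equivalent is the appendage volume fraction of the LA
    volume-change rate - a strong pulse at the atrial kick in sinus rhythm,
    a weaker passive swing in AF, zero in the occluded domain.  The outlet
    carries the instantaneous sum of all inflows, so net boundary flux is
    zero at every instant while the cycle-mean outlet flow equals the
    cycle-mean pump flow.
    """
    if not getattr(w, "converged", False):
        raise ValueError("flux program requires a converged waveform set")
    t = w.time
    dvdt = _periodic_derivative(w.volumes["la"] + w.volumes["lv"], w.dt)
    pv_total = w.flows["pump"] + dvdt
    inflow = {"pv_right": split[0] * pv_total, "pv_left": split[1] * pv_total}

    v_laa = domain.region_volume("LAA")
    if v_laa > 0:
        frac = v_laa / domain.region_volume("atrium")
        # atrial wall moves in: fluid displaced into the domain
        inflow["laa_wall"] = -frac * _periodic_derivative(w.volumes["la"], w.dt)
    else:
        inflow["laa_wall"] = np.zeros_like(pv_total)
    return FluxProgram(time=t.copy(), inflow=inflow,
                       outflow=sum(inflow.values()),
                       mitral_plane=w.flows["mitral"].copy(),
                       heart_rate=w.heart_rate)
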