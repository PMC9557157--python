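"""Parametric mitral-valve surface.

The open mitral valve is modelled as a one-parameter family of closed curves
swept from the circular annulus (s = 0) to the free leaflet edge (s = 1):

    x(theta, s) = R cos(theta) (1 - s cos(phi)) - eps R s cos(phi)
    y(theta, s) = R sin(theta) (1 - s k cos(phi))
    z(theta, s) = -(s/2) [ (1 + k^2) + eps cos(theta) + (1 - k^2) cos(2 theta) ] R sin(phi)

with annulus radius R, anterior/posterior symmetry ratio eps, leaflet-edge
ellipticity k, and opening angle phi.  At s = 0 every term collapses to the
circle of radius R in the annulus plane z = 0.  The z equation admits a second
typographic reading with coefficients (1+k)/2 and (1-k)/2; it is available via
``z_convention="half-k"`` but the squared-k reading above is the default.

The valve is static and rigid (open configuration); there are no leaflet
kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from laaoflow.errors import ParameterError


@dataclass
class ValveShapeParams:
    """Shape parameters of the parametric valve surface.

    Defaults follow the standard parametrisation: eps = 0.35, k = 0.6,
    phi = 60 degrees, sampled on a 100 x 40 (theta x s) grid.  R defaults to
    14 mm, the mitral orifice radius of the synthetic flow domain.
    """

    R: float = 14.0          # annulus radius, mm
    epsilon: float = 0.35    # anterior/posterior symmetry ratio
    k: float = 0.6           # ellipticity of the leaflet edge
    phi: float = 60.0        # opening angle, degrees
    n_theta: int = 100
    n_s: int = 40
    z_convention: str = "squared-k"   # or "half-k"

    def __post_init__(self):
        if self.R <= 0:
            raise ParameterError("R must be > 0")
        if not (0.0 <= self.epsilon < 1.0):
            raise ParameterError("epsilon must be in [0, 1)")
        if not (0.0 < self.k <= 1.0):
            raise ParameterError("k must be in (0, 1]")
        if not (0.0 < self.phi < 90.0):
            raise ParameterError("phi must be in (0, 90) degrees")
        if self.n_theta < 3 or self.n_s < 2:
            raise ParameterError("need n_theta >= 3 and n_s >= 2")
        if self.z_convention not in ("squared-k", "half-k"):
            raise ParameterError("z_convention must be 'squared-k' or 'half-k'")


def valve_point(theta, s, p: ValveShapeParams):
    """Point(s) on the valve surface, mm.  ``theta`` in radians, ``s`` in [0, 1]."""
    theta = np.asarray(theta, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ParameterError("s must be in [0, 1]")
    cphi = np.cos(np.deg2rad(p.phi))
    sphi = np.sin(np.deg2rad(p.phi))
    x = p.R * np.cos(theta) * (1.0 - s * cphi) - p.epsilon * p.R * s * cphi
    y = p.R * np.sin(theta) * (1.0 - s * p.k * cphi)
    if p.z_convention == "squared-k":
        bracket = (1.0 + p.k ** 2) + p.epsilon * np.cos(theta) \
            + (1.0 - p.k ** 2) * np.cos(2.0 * theta)
    else:
        bracket = (1.0 + p.k) / 2.0 + p.epsilon * np.cos(theta) \
            + ((1.0 - p.k) / 2.0) * np.cos(2.0 * theta)
    z = -(s / 2.0) * bracket * p.R * sphi
    return x, y, z


@dataclass
class ValveSurface:
    """Triangulated valve surface on an ``n_theta x n_s`` vertex grid.

    ``vertices`` has shape (n_theta * n_s, 3) in mm with vertex (i, j) at row
    ``i * n_s + j`` (i indexes theta, j indexes s); the first and last theta
    rings coincide, closing the surface.  ``faces`` is an (m, 3) int array.
    ``placement`` records the rigid transform applied so far as a (4, 4)
    homogeneous matrix.
    """

    vertices: np.ndarray
    faces: np.ndarray
    n_theta: int
    n_s: int
    params: ValveShapeParams
    placement: np.ndarray

    def grid(self) -> np.ndarray:
        return self.vertices.reshape(self.n_theta, self.n_s, 3)

    def surface_area(self) -> float:
        """Total area (mm^2) as the sum of triangle areas."""
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def export_stl(self, path, ascii_format: bool = False):
        mesh = self.to_trimesh()
        if ascii_format:
            with open(path, "wb") as fh:
                mesh.export(fh, file_type="stl_ascii")
        else:
            mesh.export(path, file_type="stl")

    def export_vtk(self, path):
        from laaoflow.vtkio import write_vtk_polydata
        write_vtk_polydata(path, self.vertices, self.faces,
                           comment="laaoflow parametric mitral valve")


def build_valve_mesh(p: ValveShapeParams) -> ValveSurface:
    """Sample the parametric surface on the (theta, s) grid and triangulate.

    theta runs over ``n_theta`` points from 0 to 2*pi inclusive (the first and
    last rings coincide), s over ``n_s`` points from 0 to 1, giving exactly
    ``n_theta * n_s`` vertices (4000 at the 100 x 40 default).  Faces wind
    consistently so normals share an orientation.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, p.n_theta)
    s = np.linspace(0.0, 1.0, p.n_s)
    tt, ss = np.meshgrid(theta, s, indexing="ij")
    x, y, z = valve_point(tt, ss, p)
    vertices = np.stack([x, y, z], axis=-1).reshape(-1, 3)

    ii, jj = np.meshgrid(np.arange(p.n_theta - 1), np.arange(p.n_s - 1), indexing="ij")
    v00 = (ii * p.n_s + jj).ravel()
    v10 = v00 + p.n_s
    tri1 = np.column_stack([v00, v10, v00 + 1])
    tri2 = np.column_stack([v10, v10 + 1, v00 + 1])
    faces = np.empty((2 * len(v00), 3), dtype=np.int64)
    faces[0::2] = tri1
    faces[1::2] = tri2
    surf = ValveSurface(vertices=vertices, faces=faces, n_theta=p.n_theta,
                        n_s=p.n_s, params=replace(p), placement=np.eye(4))
    areas = 0.5 * np.linalg.norm(
        np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                 vertices[faces[:, 2]] - vertices[faces[:, 0]]), axis=1)
    if np.any(areas < 1e-12 * p.R ** 2):
        import warnings
        warnings.warn("valve mesh contains (near-)degenerate faces; "
                      "check the shape parameters", stacklevel=2)
    return surf


def place_valve(mesh: ValveSurface, origin, normal, reference_direction) -> ValveSurface:
    """Rigidly place the valve: annulus centre at ``origin``, annulus plane
    perpendicular to ``normal``, with the local +x axis aligned to the
    projection of ``reference_direction`` onto the annulus plane."""
    origin = np.asarray(origin, dtype=float)
    n = np.asarray(normal, dtype=float)
    r = np.asarray(reference_direction, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ParameterError("normal must be non-zero")
    n = n / nn
    r_proj = r - np.dot(r, n) * n
    if np.linalg.norm(r_proj) < 1e-9 * max(np.linalg.norm(r), 1.0):
        raise ParameterError("reference_direction must not be parallel to normal")
    ex = r_proj / np.linalg.norm(r_proj)
    ey = np.cross(n, ex)
    rot = np.column_stack([ex, ey, n])

    tf = np.eye(4)
    tf[:3, :3] = rot
    tf[:3, 3] = origin
    return replace(
        mesh,
        vertices=mesh.vertices @ rot.T + origin,
        placement=tf @ mesh.placement,
    )
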