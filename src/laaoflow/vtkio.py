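"""Minimal legacy ASCII VTK writers/readers.

Covers exactly the subset this package exchanges: POLYDATA triangle surfaces
(valve export) and STRUCTURED_POINTS grids with cell data (domain labels,
velocity snapshots, ink concentration).  Files are plain text and readable by
ParaView and by :func:`read_vtk_structured_points` for round-tripping
externally produced velocity series in the same layout.
"""

from __future__ import annotations

import numpy as np


def write_vtk_polydata(path, vertices, faces, comment="laaoflow surface"):
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:255] + "\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for v in vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_vtk_structured_points(path, origin, spacing, cell_dims,
                                cell_scalars=None, cell_vectors=None,
                                comment="laaoflow grid"):
    """Write a uniform grid with per-cell data.

    ``cell_dims`` is the number of cells per axis (2-D data is written with a
    single cell in z).  ``cell_scalars``/``cell_vectors`` map names to arrays
    of shape ``cell_dims`` (Fortran-style iteration: x fastest) or
    ``cell_dims + (3,)`` for vectors.
    """
    dims = tuple(int(d) for d in cell_dims)
    if len(dims) == 2:
        dims = dims + (1,)
        origin = tuple(origin) + (0.0,)
    ncells = int(np.prod(dims))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0] + 1} {dims[1] + 1} {dims[2] + 1}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"CELL_DATA {ncells}\n")
        for name, arr in (cell_scalars or {}).items():
            arr = np.asarray(arr).reshape(dims, order="A")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = arr.flatten(order="F")
            np.savetxt(fh, flat[:, None], fmt="%.9g")
        for name, arr in (cell_vectors or {}).items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[-1] == 2:  # pad 2-D vectors with zero z
                arr = np.concatenate([arr, np.zeros(arr.shape[:-1] + (1,))], axis=-1)
            comps = [arr[..., i].reshape(dims, order="A").flatten(order="F")
                     for i in range(3)]
            fh.write(f"VECTORS {name} float\n")
            np.savetxt(fh, np.column_stack(comps), fmt="%.9g")


def read_vtk_structured_points(path):
    """Read a STRUCTURED_POINTS file written by this module.

    Returns ``(origin, spacing, cell_dims, scalars, vectors)`` where the data
    dictionaries hold arrays shaped ``cell_dims`` (+ ``(3,)`` for vectors).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(lines)
    dims = origin = None
    spacing = None
    scalars, vectors = {}, {}
    ncells = 0
    line = next(it, None)
    while line is not None:
        tok = line.split()
        if not tok:
            line = next(it, None)
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(x) - 1 for x in tok[1:4])
        elif key == "ORIGIN":
            origin = tuple(float(x) for x in tok[1:4])
        elif key == "SPACING":
            spacing = float(tok[1])
        elif key == "CELL_DATA":
            ncells = int(tok[1])
        elif key == "SCALARS":
            name = tok[1]
            next(it)  # LOOKUP_TABLE line
            vals = _read_floats(it, ncells)
            scalars[name] = vals.reshape(dims, order="F")
        elif key == "VECTORS":
            name = tok[1]
            vals = _read_floats(it, 3 * ncells).reshape(-1, 3)
            vectors[name] = np.stack(
                [vals[:, i].reshape(dims, order="F") for i in range(3)], axis=-1)
        line = next(it, None)
    return origin, spacing, dims, scalars, vectors


class ExternalVelocityField:
    """Cell-centred velocity series read from VTK, for the metrics modules.

    Implements the read-side protocol of :class:`laaoflow.solver.FlowField`
    (``snapshot_indices``, ``cell_velocity``, ``cell_speed``, timing
    attributes) on externally produced data.  Face velocities are not
    reconstructed, so the ink-transport module, which needs conservative
    face fluxes, only accepts internally solved fields.
    """

    def __init__(self, cells, domain, cycle_length, n_cycles=1,
                 n_init_cycles=0, fluid=None):
        from laaoflow.solver import FluidProps

        self.cells = np.asarray(cells, dtype=float)
        self.domain = domain
        self.cycle_length = float(cycle_length)
        self.n_cycles = int(n_cycles)
        self.n_init_cycles = int(n_init_cycles)
        self.fluid = fluid or FluidProps()
        n = len(self.cells)
        self.store_per_cycle = n // self.n_cycles
        self.times = (np.arange(n) + 1) * (cycle_length / (n / self.n_cycles))

    def snapshot_indices(self, cycles=None):
        if cycles is None:
            cycles = (self.n_init_cycles, self.n_cycles)
        c0, c1 = cycles
        k = np.arange(len(self.times))
        cyc = k // self.store_per_cycle
        return k[(cyc >= c0) & (cyc < c1)]

    def cell_velocity(self, k):
        return self.cells[k]

    def cell_speed(self, k):
        vel = self.cells[k]
        return np.hypot(vel[..., 0], vel[..., 1])


def load_velocity_series(paths, domain, cycle_length, n_cycles=1,
                         n_init_cycles=0, fluid=None) -> ExternalVelocityField:
    """Read a VTK snapshot series into an :class:`ExternalVelocityField`.

    ``paths`` are STRUCTURED_POINTS files (one per stored instant, in time
    order) carrying a cell-data vector named ``velocity``, as written by
    :meth:`laaoflow.solver.FlowField.export_vtk_series`.
    """
    cells = []
    for p in paths:
        _, _, dims, _, vectors = read_vtk_structured_points(p)
        vel = vectors["velocity"]
        if dims[2] == 1:  # 2-D series stored with one z cell
            vel = vel[:, :, 0, :2]
        cells.append(vel)
    return ExternalVelocityField(cells, domain, cycle_length, n_cycles,
                                 n_init_cycles, fluid)


def _read_floats(it, n):
    out = np.empty(n)
    k = 0
    while k < n:
        for x in next(it).split():
            out[k] = float(x)
            k += 1
    return out
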