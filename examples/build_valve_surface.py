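"""Generate and place the parametric mitral-valve surface.

The open valve is a swept surface between the circular annulus and an
elliptic free edge, controlled by four shape parameters: annulus radius R,
leaflet symmetry ratio eps, edge ellipticity k and opening angle phi.
"""

import numpy as np

from laaoflow import ValveShapeParams, build_valve_mesh, place_valve

params = ValveShapeParams(R=14.0, epsilon=0.35, k=0.6, phi=60.0)
mesh = build_valve_mesh(params)
print(f"valve mesh: {len(mesh.vertices)} vertices "
      f"({params.n_theta} x {params.n_s} grid), "
      f"{len(mesh.faces)} triangles, area {mesh.surface_area():.0f} mm^2")

# place it at an oblique mitral plane
placed = place_valve(mesh, origin=(0.0, 0.0, 42.0),
                     normal=(0.2, 0.0, -1.0), reference_direction=(1.0, 0.0, 0.0))
center = placed.grid()[:, 0, :].mean(axis=0)
print("annulus centre after placement:", np.round(center, 3), "(mm)")

mesh.export_stl("valve.stl")
print("wrote valve.stl - triangulated surface for any mesh viewer")
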