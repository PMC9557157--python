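"""Build the synthetic left-heart flow domains.

The 3-D voxel mode reproduces the study patient's end-systolic chamber
volumes (atrium 169 cm^3, ventricle 295 cm^3); the 2-D mode is the working
scale for the flow solver, with an out-of-plane depth chosen so the atrial
volume matches.  Occlusion removes the appendage pouch at its neck.
"""

from laaoflow import DomainConfig, build_domain

dom3 = build_domain(DomainConfig(mode="3d"))
print("3-D voxel domain:")
print(f"  atrium (LA+LAA) {dom3.region_volume('atrium') / 1000:.2f} cm^3 "
      f"(target 169), ventricle {dom3.region_volume('LV') / 1000:.2f} cm^3 "
      f"(target 295), pouch {dom3.region_volume('LAA') / 1000:.2f} cm^3")

dom2 = build_domain(DomainConfig(mode="2d"))
print("2-D working domain:")
print(f"  grid {dom2.labels.shape}, spacing {dom2.spacing} mm, "
      f"depth {dom2.depth:.1f} mm -> atrium "
      f"{dom2.region_volume('atrium') / 1000:.1f} cm^3")

occ = build_domain(DomainConfig(mode="2d", occluded=True))
print(f"  occluded variant: {int(occ.mask('LAA').sum())} appendage cells "
      f"(pouch sealed at the neck plane)")

dom2.export_vtk("domain_2d.vtk")
print("wrote domain_2d.vtk (region labels as cell data)")
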