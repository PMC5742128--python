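"""Compute a nerve-fiber orientation field on a test tube.

Pipeline: distance-surrogate Laplace solve (phi = 0 on the start surface,
uniform outflow elsewhere) -> most distant boundary point -> geodesic target
patch -> Robin-coupled Laplace solve -> normed gradient F.
"""

import numpy as np

import vestim as vs

mesh = vs.make_test_cylinder(length=0.02, radius=0.002, resolution=8)
start = vs.region_interface(mesh, "nerve", "start_marker")

phi_d = vs.solve_distance_surrogate(mesh, "nerve", start)
print(f"distance surrogate: min {phi_d.values.min():.4f} (most distant), "
      f"0 on the start surface by construction")

target = vs.find_target_surface(mesh, "nerve", start, patch_radius=0.004)
print(f"target surface: {len(target)} triangles around the far end")

phi = vs.solve_orientation_potential(mesh, "nerve", start, target,
                                     vs.CauchyParams(alpha_s=100, alpha_t=100))
field = vs.orientation_from_potential(mesh, "nerve", phi)
angles = np.degrees(np.arccos(np.clip(np.abs(field.vectors[:, 0]), 0, 1)))
print(f"orientation field: mean deviation from the tube axis "
      f"{angles.mean():.2f} deg over {len(field.vectors)} tets")
print("-> the normed potential gradient recovers the fiber direction; "
      "it also sets the axis of the anisotropic conductivity tensor.")
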