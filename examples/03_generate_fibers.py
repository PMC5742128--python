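"""Synthesize nerve fibers by streamline tracing and place nodes of Ranvier.

Seeds are scattered area-uniformly over the start surface; each trace
follows the orientation field (RK4) and is accepted only if it leaves the
nerve through the target surface.  Fiber types are drawn from zone-based
distributions on the epithelium and set the internodal spacing.
"""

import collections

import vestim as vs
from vestim.fibers import DEFAULT_INTERNODAL_DISTANCE, assign_fiber_types

mesh = vs.make_test_cylinder(0.02, 0.002, resolution=8)
start = vs.region_interface(mesh, "nerve", "start_marker")
target = vs.find_target_surface(mesh, "nerve", start, 0.004)
phi = vs.solve_orientation_potential(mesh, "nerve", start, target)
field = vs.orientation_from_potential(mesh, "nerve", phi)

fibers = vs.generate_fibers(mesh, "nerve", field, start, target,
                            n=100, rng_seed=42)
print(f"accepted {len(fibers)} fibers in {fibers.attempts} attempts "
      f"({fibers.rejections} rejected traces resampled)")

assign_fiber_types(fibers, start, rng_seed=1)
counts = collections.Counter(f.fiber_type for f in fibers.fibers)
print("fiber types:", dict(counts))

for f in fibers.fibers:
    vs.place_nodes_of_ranvier(f, DEFAULT_INTERNODAL_DISTANCE[f.fiber_type])
f0 = fibers.fibers[0]
print(f"first fiber: length {f0.length * 1e3:.2f} mm, "
      f"{len(f0.node_arc_lengths)} nodes of Ranvier "
      f"({f0.fiber_type}, {DEFAULT_INTERNODAL_DISTANCE[f0.fiber_type] * 1e6:.0f} um spacing)")
print("-> the node positions are where the extracellular potential couples "
      "into the axon cable model.")
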