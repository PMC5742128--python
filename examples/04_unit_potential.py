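"""Solve a unit-current potential and check it against the analytic
grounded-sphere solution phi(r) = (I / 4 pi sigma)(1/r - 1/R).

A small, highly conductive electrode region at the center of a homogeneous
sphere injects 1 A; the outer surface is the 0 V reference (the monopolar
arrangement).  The same solver handles anisotropic nerve tensors and
bipolar references in the full model.
"""

import numpy as np

import vestim as vs
from vestim.potential import ConductivityTable, SourceSpec, per_tet_conductivity

R, nvox = 1.0, 16
h = R / nvox
n = 2 * nvox + 2
c = (np.arange(n) + 0.5) * h - (n * h) / 2
X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
r = np.sqrt(X**2 + Y**2 + Z**2)
labels = np.zeros((n, n, n), dtype=np.int32)
labels[r < R] = 1
labels[r < 2.5 * h] = 2
mesh = vs.voxel_to_tetmesh(labels, h, {1: "saline", 2: "electrode"},
                           origin=(np.array([0.5, 0.5, 0.5]) - n / 2) * h)
print(f"sphere mesh: {mesh.n_tets} tets, {mesh.n_vertices} vertices")

tensors = per_tet_conductivity(mesh, ConductivityTable({"saline": 1.0, "electrode": 1e6}))
unit = vs.solve_unit_current(mesh, tensors, SourceSpec(active_regions=["electrode"]))
print(f"solver: {unit.diagnostics['method']}, "
      f"current balance {unit.diagnostics['current_balance']:.6f}")

dirs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0]], dtype=float)
phi = vs.interpolate_at_points(unit, 0.5 * dirs).mean()
analytic = (1 / (4 * np.pi)) * (1 / 0.5 - 1 / R)
print(f"phi(R/2): FEM {phi:.4f} V/A vs analytic {analytic:.4f} V/A "
      f"({abs(phi - analytic) / analytic * 100:.1f}% off)")
print("-> quasistatic scaling means any stimulus instant is just this field "
      "times the instantaneous waveform amplitude.")
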