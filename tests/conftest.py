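"""Shared fixtures: small voxel-derived meshes and solved fields.

Everything is generated programmatically; the expensive fixtures are
session-scoped so solve-heavy tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import vestim as vs


@pytest.fixture(scope="session")
def two_voxel_mesh():
    """Two unit voxels side by side, labels A | B."""
    labels = np.zeros((2, 1, 1), dtype=np.int32)
    labels[0] = 1
    labels[1] = 2
    return vs.voxel_to_tetmesh(labels, 1.0, {1: "A", 2: "B"})


@pytest.fixture(scope="session")
def cylinder():
    """Straight nerve tube, 20 mm x 2 mm radius, with end markers."""
    return vs.make_test_cylinder(0.02, 0.002, resolution=8)


@pytest.fixture(scope="session")
def cylinder_start(cylinder):
    patch = vs.region_interface(cylinder, "nerve", "start_marker")
    patch.role = "start"
    return patch


@pytest.fixture(scope="session")
def cylinder_boundary(cylinder):
    return vs.region_boundary(cylinder, "nerve", "all")


@pytest.fixture(scope="session")
def cylinder_orientation(cylinder, cylinder_start):
    """Start/target surfaces, orientation potential and field on the tube."""
    target = vs.find_target_surface(cylinder, "nerve", cylinder_start, 0.004)
    phi = vs.solve_orientation_potential(cylinder, "nerve", cylinder_start, target)
    field = vs.orientation_from_potential(cylinder, "nerve", phi)
    return {"start": cylinder_start, "target": target, "phi": phi, "field": field}


@pytest.fixture(scope="session")
def torus_segment():
    """Quarter-torus nerve tube fixture (curved geometry)."""
    return vs.make_test_torus_segment(0.01, 0.002, angle=np.pi / 2, resolution=7)


@pytest.fixture(scope="session")
def grounded_sphere():
    """Voxelized homogeneous sphere (R = 1 m, sigma = 1 S/m) with a small
    highly conductive central electrode region; the analytic monopolar
    solution is phi(r) = (I / 4 pi sigma)(1/r - 1/R)."""
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
    mesh = vs.voxel_to_tetmesh(
        labels, h, {1: "saline", 2: "electrode"},
        origin=(np.array([0.5, 0.5, 0.5]) - n / 2) * h,
    )
    tensors = per_tet_conductivity(
        mesh, ConductivityTable({"saline": 1.0, "electrode": 1.0e6})
    )
    unit = vs.solve_unit_current(
        mesh, tensors, SourceSpec(active_regions=["electrode"])
    )
    return {"mesh": mesh, "unit": unit, "R": R, "a": 2.5 * h, "sigma": 1.0}


@pytest.fixture(scope="session")
def toy_fiber_potentials():
    """Unit-current extracellular potentials of a point source 1 mm from a
    straight 21-node fiber (the standard toy fiber)."""
    xs = (np.arange(21) - 10) * 300e-6
    return 1.0 / (4 * np.pi * 0.3) / np.sqrt(xs**2 + 1e-3**2)
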