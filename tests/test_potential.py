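"""Conductivity tensors, unit-current solves, scaling and interpolation."""

import numpy as np
import pytest

import vestim as vs
from vestim.electrodes import Electrode
from vestim.fiberfield import OrientationField
from vestim.potential import (
    ConductivityError,
    ConductivityTable,
    SourceSpec,
    default_conductivities,
)


# ------------------------------------------------------------- tensors

def test_tensor_aligned_with_z():
    labels = np.ones((2, 2, 2), dtype=np.int32)
    mesh = vs.voxel_to_tetmesh(labels, 1e-3, {1: "nerve_x"})
    idx = mesh.tets_of_region("nerve_x")
    F = np.tile([0.0, 0.0, 1.0], (len(idx), 1))
    field = OrientationField(mesh, "nerve_x", idx, F)
    table = ConductivityTable({"nerve": (0.3333, 0.0143)})
    tens = vs.per_tet_conductivity(mesh, table, {"nerve_x": field})
    np.testing.assert_allclose(tens[0], np.diag([0.0143, 0.0143, 0.3333]), atol=1e-12)


def test_tensor_isotropic_when_sigmas_equal():
    labels = np.ones((1, 1, 1), dtype=np.int32)
    mesh = vs.voxel_to_tetmesh(labels, 1e-3, {1: "nerve_x"})
    idx = mesh.tets_of_region("nerve_x")
    rng = np.random.default_rng(0)
    F = rng.standard_normal((len(idx), 3))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    field = OrientationField(mesh, "nerve_x", idx, F)
    tens = vs.per_tet_conductivity(
        mesh, ConductivityTable({"nerve": (0.5, 0.5)}), {"nerve_x": field}
    )
    for t in tens:
        np.testing.assert_allclose(t, 0.5 * np.eye(3), atol=1e-12)


def test_tensor_eigenstructure_random_orientations():
    """Eigenvalues are {sigma_l, sigma_t, sigma_t} with the principal axis
    along F (eigendecomposition oracle)."""
    labels = np.ones((2, 2, 1), dtype=np.int32)
    mesh = vs.voxel_to_tetmesh(labels, 1e-3, {1: "nerve_x"})
    idx = mesh.tets_of_region("nerve_x")
    rng = np.random.default_rng(3)
    F = rng.standard_normal((len(idx), 3))
    F /= np.linalg.norm(F, axis=1, keepdims=True)
    field = OrientationField(mesh, "nerve_x", idx, F)
    sl, st = 0.3333, 0.0143
    tens = vs.per_tet_conductivity(
        mesh, ConductivityTable({"nerve": (sl, st)}), {"nerve_x": field}
    )
    for t, f in zip(tens, F):
        w, v = np.linalg.eigh(t)
        np.testing.assert_allclose(sorted(w), [st, st, sl], atol=1e-12)
        principal = v[:, np.argmax(w)]
        assert abs(principal @ f) == pytest.approx(1.0, abs=1e-9)


def test_missing_conductivity_entry_raises(two_voxel_mesh):
    with pytest.raises(ConductivityError, match="no conductivity"):
        vs.per_tet_conductivity(two_voxel_mesh, ConductivityTable({"A": 1.0}))


def test_nonpositive_conductivity_rejected():
    with pytest.raises(ConductivityError):
        ConductivityTable({"bone": 0.0})


def test_default_table_values():
    t = default_conductivities()
    assert t.lookup("bone") == 0.0139
    assert t.lookup("nerve_target") == (0.3333, 0.0143)
    assert t.lookup("cochlear_nerve") == 0.1738
    assert t.lookup("endolymph") == 2.0
    assert t.lookup("perilymph") == 2.0
    assert t.lookup("saline") == 2.0
    assert t.lookup("scala_tympani") == 2.0
    assert t.lookup("electrode_x_a") == 1.0e6


# ---------------------------------------------------- analytic oracle

def test_monopolar_matches_grounded_sphere_analytic(grounded_sphere):
    """phi(R/2) agrees with (I/4 pi sigma)(1/r - 1/R) within 5%."""
    unit = grounded_sphere["unit"]
    R = grounded_sphere["R"]
    r = R / 2
    dirs = np.array(
        [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0, -1, 0], [0, 0, -1],
         [1, 1, 1], [-1, 1, -1]], dtype=float
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vals = vs.interpolate_at_points(unit, r * dirs)
    analytic = (1 / (4 * np.pi)) * (1 / r - 1 / R)
    assert vals.mean() == pytest.approx(analytic, rel=0.05)


def test_current_conservation(grounded_sphere):
    assert grounded_sphere["unit"].diagnostics["current_balance"] == pytest.approx(
        1.0, abs=0.02
    )


def test_linearity_in_current(grounded_sphere):
    """Doubling the injected current doubles the potential everywhere."""
    from vestim.potential import per_tet_conductivity, solve_unit_current

    mesh = grounded_sphere["mesh"]
    tensors = per_tet_conductivity(
        mesh, ConductivityTable({"saline": 1.0, "electrode": 1.0e6})
    )
    double = solve_unit_current(
        mesh, tensors, SourceSpec(active_regions=["electrode"], current=2.0)
    )
    np.testing.assert_allclose(
        double.values, 2.0 * grounded_sphere["unit"].values, rtol=1e-6, atol=1e-9
    )


@pytest.fixture(scope="module")
def bipolar_block():
    """Homogeneous conductive block with a symmetric electrode pair."""
    n = 20
    h = 1e-3
    labels = np.ones((n, n, n), dtype=np.int32)
    mesh = vs.voxel_to_tetmesh(labels, h, {1: "saline"})
    cA = np.array([7e-3, 10e-3, 10e-3])
    cR = np.array([13e-3, 10e-3, 10e-3])
    vs.place_electrode(mesh, Electrode("a", cA, 4e-3, "active"))
    vs.place_electrode(mesh, Electrode("r", cR, 4e-3, "reference"))
    tensors = vs.per_tet_conductivity(
        mesh, ConductivityTable({"saline": 2.0, "electrode": 1.0e6})
    )
    return {"mesh": mesh, "tensors": tensors}


def test_bipolar_antisymmetry(bipolar_block):
    """A symmetric dipole's potential is antisymmetric under the symmetry
    that swaps the electrodes (point inversion through the pair midpoint,
    which the Kuhn subdivision respects), up to the reference offset."""
    mesh = bipolar_block["mesh"]
    unit = vs.solve_unit_current(
        mesh, bipolar_block["tensors"],
        SourceSpec(active_regions=["electrode_a"], reference_regions=["electrode_r"]),
    )
    rng = np.random.default_rng(0)
    pts = rng.uniform(2e-3, 18e-3, size=(60, 3))
    cA, cR = np.array([7e-3, 10e-3, 10e-3]), np.array([13e-3, 10e-3, 10e-3])
    keep = (np.linalg.norm(pts - cA, axis=1) > 4.5e-3) & (
        np.linalg.norm(pts - cR, axis=1) > 4.5e-3
    )
    pts = pts[keep]
    mirror = 20e-3 - pts
    v = vs.interpolate_at_points(unit, pts)
    vm = vs.interpolate_at_points(unit, mirror)
    v0 = float(np.mean(v + vm) / 2)   # common-mode offset (reference at one pole)
    scale = np.abs(v - v0).max()
    np.testing.assert_allclose(v - v0, -(vm - v0), atol=0.02 * scale)


def test_bipolar_swap_negates_field(bipolar_block):
    """Reciprocity sanity: swapping active and reference negates the
    potential up to the common-mode shift."""
    mesh = bipolar_block["mesh"]
    a = vs.solve_unit_current(
        mesh, bipolar_block["tensors"],
        SourceSpec(active_regions=["electrode_a"], reference_regions=["electrode_r"]),
    )
    b = vs.solve_unit_current(
        mesh, bipolar_block["tensors"],
        SourceSpec(active_regions=["electrode_r"], reference_regions=["electrode_a"]),
    )
    rng = np.random.default_rng(1)
    pts = rng.uniform(3e-3, 17e-3, size=(40, 3))
    va = vs.interpolate_at_points(a, pts)
    vb = vs.interpolate_at_points(b, pts)
    # both solves pin their own reference to 0; the sum is the (constant)
    # total access voltage
    total = va + vb
    assert np.ptp(total) < 0.05 * np.abs(va).max()


def test_anisotropy_elongates_equipotentials():
    """With sigma_l >> sigma_t and axial F, the potential at distance d along
    the fiber axis exceeds the potential at distance d transverse to it."""
    n = 24
    h = 1e-3
    labels = np.ones((n, n, n), dtype=np.int32)
    mesh = vs.voxel_to_tetmesh(labels, h, {1: "nerve_x"})
    idx = mesh.tets_of_region("nerve_x")
    F = np.tile([1.0, 0.0, 0.0], (len(idx), 1))
    field = OrientationField(mesh, "nerve_x", idx, F)
    # carve a small electrode region at the center
    center = np.array([12e-3, 12e-3, 12e-3])
    vs.place_electrode(mesh, Electrode("c", center, 3e-3, "active"))
    tensors = vs.per_tet_conductivity(
        mesh, ConductivityTable({"nerve": (0.3333, 0.0143), "electrode": 1.0e6}),
        {"nerve_x": field},
    )
    unit = vs.solve_unit_current(
        mesh, tensors, SourceSpec(active_regions=["electrode_c"], saline_region="nerve_x")
    )
    d = 6e-3
    v_axial = vs.interpolate_at_points(unit, [center + [d, 0, 0], center - [d, 0, 0]]).mean()
    v_trans = vs.interpolate_at_points(
        unit, [center + [0, d, 0], center - [0, d, 0], center + [0, 0, d], center - [0, 0, d]]
    ).mean()
    assert v_axial > v_trans


def test_no_reference_raises(two_voxel_mesh):
    tensors = vs.per_tet_conductivity(
        two_voxel_mesh, ConductivityTable({"A": 1.0, "B": 1.0})
    )
    import vestim.fem as fem

    with pytest.raises(fem.SolverError, match="empty"):
        vs.solve_unit_current(
            two_voxel_mesh, tensors,
            SourceSpec(active_regions=["A"], reference_regions=[]),
        )


# ------------------------------------------------------------- scaling

def test_scale_potential_values(grounded_sphere):
    unit = grounded_sphere["unit"]
    w = vs.biphasic_waveform(200e-6, 30e-6)
    f = vs.scale_potential(unit, w, 1e-3, 100e-6)     # cathodic phase
    np.testing.assert_allclose(f.values, -1e-3 * unit.values)
    f0 = vs.scale_potential(unit, w, 1e-3, 1.0)       # after support
    assert not f0.values.any()
    f2 = vs.scale_potential(unit, w, 2e-3, 330e-6)
    np.testing.assert_allclose(f2.values, 2 * vs.scale_potential(unit, w, 1e-3, 330e-6).values)


# -------------------------------------------------------- interpolation

def test_interpolation_reproduces_linear_field(two_voxel_mesh):
    from vestim.mesh import ScalarField
    from vestim.potential import interpolate_at_points

    field = ScalarField(two_voxel_mesh, two_voxel_mesh.vertices[:, 0].copy())
    rng = np.random.default_rng(2)
    pts = rng.uniform(0.05, 1.95, size=(20, 3))
    pts[:, 1:] = rng.uniform(0.05, 0.95, size=(20, 2))
    vals = interpolate_at_points(field, pts)
    np.testing.assert_allclose(vals, pts[:, 0], atol=1e-12)


def test_interpolation_at_vertices(grounded_sphere):
    unit = grounded_sphere["unit"]
    mesh = grounded_sphere["mesh"]
    ids = np.linspace(0, mesh.n_vertices - 1, 7).astype(int)
    vals = vs.interpolate_at_points(unit, mesh.vertices[ids])
    np.testing.assert_allclose(vals, unit.values[ids], atol=1e-9)


def test_interpolation_matches_brute_force(two_voxel_mesh):
    """Random interior points against an exhaustive all-tet barycentric
    search oracle."""
    from vestim.mesh import ScalarField
    from vestim.potential import interpolate_at_points

    rng = np.random.default_rng(5)
    field = ScalarField(two_voxel_mesh, rng.standard_normal(two_voxel_mesh.n_vertices))
    pts = np.column_stack([
        rng.uniform(0.05, 1.95, 15), rng.uniform(0.05, 0.95, 15), rng.uniform(0.05, 0.95, 15)
    ])
    vals = interpolate_at_points(field, pts)
    v = two_voxel_mesh.vertices
    for p, got in zip(pts, vals):
        found = None
        for tet in two_voxel_mesh.tets:
            T = np.column_stack([v[tet[1]] - v[tet[0]], v[tet[2]] - v[tet[0]], v[tet[3]] - v[tet[0]]])
            lam123 = np.linalg.solve(T, p - v[tet[0]])
            lam = np.concatenate([[1 - lam123.sum()], lam123])
            if lam.min() >= -1e-12:
                found = lam @ field.values[tet]
                break
        assert found is not None
        assert got == pytest.approx(found, abs=1e-12)


def test_interpolation_outside_mesh_raises(two_voxel_mesh):
    from vestim.mesh import ScalarField
    from vestim.potential import interpolate_at_points

    field = ScalarField(two_voxel_mesh, np.zeros(two_voxel_mesh.n_vertices))
    with pytest.raises(ValueError, match="outside"):
        interpolate_at_points(field, np.array([[5.0, 5.0, 5.0]]))
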