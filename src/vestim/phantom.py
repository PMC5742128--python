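"""Synthetic labeled inner-ear-like anatomy.

The phantom reproduces the *topology* the workflow assumes — single-connected
nerve volumes contacting an epithelium/endolymph interface, a fluid labyrinth,
an IAC-like shared canal, an embedding bone sphere and an outer saline shell —
at a geometrically scaled-up, voxel-resolvable size.  Anatomical realism
beyond topology and scale is out of scope.

The phantom is voxel-rasterized and converted through the same Kuhn
subdivision path that real labeled volumes take.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .mesh import LabeledTetMesh, voxel_to_tetmesh


class PhantomGeometryError(ValueError):
    pass


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class BranchSpec:
    """A straight nerve tube ending in an epithelium disc and an ampulla-like
    fluid capsule, all sharing one axis."""

    p0: np.ndarray                   # proximal end (joins the IAC), meters
    p1: np.ndarray                   # distal end (at the epithelium), meters
    nerve_radius: float = 2.5e-3
    epithelium_thickness: float = 2.5e-3
    ampulla_radius: float = 4.0e-3
    ampulla_length: float = 9.0e-3

    @property
    def axis(self) -> np.ndarray:
        return _unit(np.asarray(self.p1) - np.asarray(self.p0))


def _default_branches() -> dict[str, BranchSpec]:
    mm = 1e-3
    # Branch axes are tilted out of the x-z plane: real nerve bundles have no
    # exact mirror symmetry, and a perfectly symmetric phantom would place
    # the fibers on the null plane of the canal-tangent dipole.  The two
    # ampullae are adjacent (a few mm apart, their fluid spaces merging),
    # as the ampullae of neighboring semicircular canals are — non-target
    # afferents within the monopolar recruitment range of the target are the
    # anatomical situation selective stimulation has to cope with.
    return {
        "target": BranchSpec(
            p0=np.array([-4.0, -1.5, 1.5]) * mm, p1=np.array([6.0, 1.5, 4.5]) * mm,
            ampulla_length=11.0e-3,
        ),
        "neighbor": BranchSpec(
            p0=np.array([-3.0, 1.5, -2.5]) * mm, p1=np.array([10.8, 3.07, -0.38]) * mm,
            ampulla_length=5.0e-3,
        ),
    }


@dataclass
class PhantomSpec:
    """Parameters of the synthetic anatomy.

    Defaults: bone sphere diameter 5 cm surrounded by a 1 cm saline layer;
    two ampullary nerve branches (one stimulation target, one non-target
    neighbor) joining an IAC tube; 1.5 mm voxels.  The geometry is fully
    deterministic; ``seed`` is recorded for provenance and reserved for
    optional randomized phantom variants.
    """

    bone_diameter: float = 0.05
    saline_thickness: float = 0.01
    voxel_size: float = 1.5e-3
    branches: dict[str, BranchSpec] = dc_field(default_factory=_default_branches)
    iac_p0: np.ndarray = dc_field(default_factory=lambda: np.array([-16e-3, 0.0, 0.0]))
    iac_p1: np.ndarray = dc_field(default_factory=lambda: np.array([-2e-3, 0.0, 0.0]))
    iac_radius: float = 3.5e-3
    seed: int = 0

    @property
    def bone_radius(self) -> float:
        return self.bone_diameter / 2

    @property
    def outer_radius(self) -> float:
        return self.bone_radius + self.saline_thickness

    def validate(self) -> None:
        if self.saline_thickness <= 0:
            raise PhantomGeometryError("saline shell must strictly enclose the bone sphere")
        rb = self.bone_radius
        for name, br in self.branches.items():
            u = br.axis
            e0 = np.asarray(br.p1) + br.epithelium_thickness * u
            amp_end = e0 + br.ampulla_length * u
            for pt, r in [
                (br.p0, br.nerve_radius),
                (br.p1, br.nerve_radius),
                (e0, br.ampulla_radius),
                (amp_end, br.ampulla_radius),
            ]:
                if np.linalg.norm(pt) + r >= rb:
                    raise PhantomGeometryError(
                        f"branch {name!r} exits the bone sphere "
                        f"(|{np.asarray(pt) * 1e3}| mm + {r * 1e3} mm >= {rb * 1e3} mm)"
                    )
        for pt in (self.iac_p0, self.iac_p1):
            if np.linalg.norm(pt) + self.iac_radius >= rb:
                raise PhantomGeometryError("IAC tube exits the bone sphere")

    # analytic stimulation frame for a branch, used for electrode placement
    def branch_frame(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(epithelium/endolymph interface center, transverse axis pointing
        into the fluid, canal-tangent axial axis)."""
        br = self.branches[name]
        u = br.axis
        center = np.asarray(br.p1) + br.epithelium_thickness * u
        # canal tangent: perpendicular to the branch axis, in the y direction
        t = np.cross(np.array([0.0, 1.0, 0.0]), u)
        t = np.array([0.0, 1.0, 0.0]) if np.linalg.norm(t) < 1e-12 else _unit(
            np.array([0.0, 1.0, 0.0]) - np.dot(np.array([0.0, 1.0, 0.0]), u) * u
        )
        return center, u, t


def _cylinder_mask(pts: np.ndarray, p0, p1, radius: float) -> np.ndarray:
    """Points inside the finite (flat-capped) cylinder from p0 to p1."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L = np.linalg.norm(d)
    u = d / L
    rel = pts - p0
    t = rel @ u
    radial2 = np.einsum("ij,ij->i", rel, rel) - t**2
    return (t >= 0) & (t <= L) & (radial2 <= radius**2)


def make_phantom(spec: PhantomSpec | None = None) -> LabeledTetMesh:
    """Rasterize and tet-mesh the phantom.

    Region vocabulary: ``bone``, ``saline``, ``endolymph``, ``IAC``,
    ``nerve_<branch>``, ``epithelium_<branch>``.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    h = spec.voxel_size
    R = spec.outer_radius
    n = int(np.ceil(2 * R / h)) + 1
    # voxel centers
    coords = (np.arange(n) + 0.5) * h - (n * h) / 2
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    rad = np.linalg.norm(pts, axis=1)

    BG, BONE, SALINE, ENDO, IAC = 0, 1, 2, 3, 4
    labels = np.zeros(len(pts), dtype=np.int32)
    labels[rad < R] = SALINE
    labels[rad < spec.bone_radius] = BONE

    names = {BONE: "bone", SALINE: "saline", ENDO: "endolymph", IAC: "IAC"}
    next_code = 5
    for bname, br in spec.branches.items():
        u = br.axis
        e0 = np.asarray(br.p1) + br.epithelium_thickness * u
        # ampulla + canal stub: fluid capsule continuing along the branch axis
        labels[_cylinder_mask(pts, e0, e0 + br.ampulla_length * u, br.ampulla_radius)] = ENDO
        epi_code, nerve_code = next_code, next_code + 1
        names[epi_code] = f"epithelium_{bname}"
        names[nerve_code] = f"nerve_{bname}"
        next_code += 2
        labels[_cylinder_mask(pts, br.p1, e0, br.nerve_radius)] = epi_code
        labels[_cylinder_mask(pts, br.p0, br.p1, br.nerve_radius)] = nerve_code
    # the IAC is painted last: nerve tubes overlap its end, so the shared
    # voxels become IAC and the nerves terminate on a nerve/IAC interface
    labels[_cylinder_mask(pts, spec.iac_p0, spec.iac_p1, spec.iac_radius)] = IAC

    grid = labels.reshape(n, n, n)
    mesh = voxel_to_tetmesh(
        grid, h, region_names=names, background=BG,
        origin=(np.array([0.5, 0.5, 0.5]) - n / 2) * h,
    )
    for bname in spec.branches:
        if not mesh.region_connected(f"nerve_{bname}"):
            raise PhantomGeometryError(
                f"nerve_{bname} is not single-connected at voxel size {h}; refine"
            )
    return mesh


def make_test_cylinder(
    length: float, radius: float, resolution: int = 8, axis_label: str = "nerve"
) -> LabeledTetMesh:
    """Straight tube fixture for the fiber-field solves.

    A cylinder along +x labeled ``nerve`` with one-voxel end slabs labeled
    ``start_marker`` / ``target_marker``.  ``resolution`` is the number of
    voxels across the diameter.
    """
    if resolution < 3:
        raise PhantomGeometryError("resolution too coarse: need >= 3 voxels across the diameter")
    h = 2 * radius / resolution
    nx = int(np.ceil(length / h))
    if nx < 3:
        raise PhantomGeometryError("cylinder too short for end markers at this resolution")
    ny = resolution + 1
    cy = ny * h / 2
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(ny), indexing="ij")
    yc = (jj + 0.5) * h - cy
    zc = (kk + 0.5) * h - cy
    inside = yc**2 + zc**2 <= radius**2
    labels = np.zeros((nx, ny, ny), dtype=np.int32)
    labels[inside] = 1
    labels[0][inside[0]] = 2
    labels[-1][inside[-1]] = 3
    mesh = voxel_to_tetmesh(
        labels, h,
        region_names={1: axis_label, 2: "start_marker", 3: "target_marker"},
    )
    if not mesh.region_connected(axis_label):
        raise PhantomGeometryError(
            f"tube disconnects at resolution {resolution}; increase resolution"
        )
    return mesh


def make_test_torus_segment(
    major_radius: float,
    tube_radius: float,
    angle: float = np.pi / 2,
    resolution: int = 8,
) -> LabeledTetMesh:
    """Curved-tube fixture: a torus segment around the z axis spanning
    ``angle`` radians, with marker slabs at both angular ends."""
    if resolution < 3:
        raise PhantomGeometryError("resolution too coarse for the tube radius")
    h = 2 * tube_radius / resolution
    extent = major_radius + tube_radius + h
    nxy = int(np.ceil(2 * extent / h))
    nz = resolution + 2
    c = np.arange(nxy) * h - extent + 0.5 * h
    cz = (np.arange(nz) + 0.5) * h - nz * h / 2
    X, Y = np.meshgrid(c, c, indexing="ij")
    theta = np.arctan2(Y, X)
    rho = np.sqrt(X**2 + Y**2)
    labels = np.zeros((nxy, nxy, nz), dtype=np.int32)
    dtheta = 1.5 * h / major_radius    # angular width of the end marker slabs
    for iz, z in enumerate(cz):
        inside = ((rho - major_radius) ** 2 + z**2 <= tube_radius**2)
        sect = np.zeros_like(inside, dtype=np.int32)
        span = (theta >= 0) & (theta <= angle)
        sect[inside & span] = 1
        sect[inside & span & (theta <= dtheta)] = 2
        sect[inside & span & (theta >= angle - dtheta)] = 3
        labels[:, :, iz] = sect
    mesh = voxel_to_tetmesh(
        labels, h, region_names={1: "nerve", 2: "start_marker", 3: "target_marker"}
    )
    if not mesh.region_connected("nerve"):
        raise PhantomGeometryError("torus tube disconnects; increase resolution")
    return mesh
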