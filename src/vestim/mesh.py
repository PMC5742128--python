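"""Labeled tetrahedral mesh data model and topology queries.

The mesh is the domain Ω for every solve in the workflow.  Each tetrahedron
carries a tissue region label (bone, saline, endolymph, nerve branches,
epithelium patches, electrode regions, ...).  Region labels are an open
string vocabulary; internally they are stored as small integer codes.

Coordinates are meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


class UnknownRegionError(KeyError):
    """Raised when an operation references a region label not in the mesh."""


# local faces of a tet (v0,v1,v2,v3), oriented outward for a positively
# oriented tet: face i is opposite vertex i
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


@dataclass
class LabeledTetMesh:
    """Conforming tetrahedral mesh with a tissue region per tetrahedron."""

    vertices: np.ndarray          # (n, 3) float64, meters
    tets: np.ndarray              # (m, 4) int64, positively oriented
    region_ids: np.ndarray        # (m,) int32 codes into region_names
    region_names: list[str]       # code -> label
    original_region_ids: np.ndarray | None = None  # provenance for electrodes
    electrode_tets: dict[str, np.ndarray] = field(default_factory=dict)
    _face_cache: tuple | None = field(default=None, repr=False, compare=False)

    # ---- label access -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def regions(self) -> set[str]:
        present = np.unique(self.region_ids)
        return {self.region_names[i] for i in present}

    def region_code(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise UnknownRegionError(f"region {name!r} not declared in mesh") from None

    def ensure_region_code(self, name: str) -> int:
        """Return the code for ``name``, declaring it if new."""
        if name in self.region_names:
            return self.region_names.index(name)
        self.region_names.append(name)
        return len(self.region_names) - 1

    def region_of_tet(self) -> np.ndarray:
        """Region label per tetrahedron as a string array."""
        return np.asarray(self.region_names, dtype=object)[self.region_ids]

    def tets_of_region(self, name: str) -> np.ndarray:
        """Indices of tetrahedra in region ``name`` (may reference a declared
        but currently empty region)."""
        code = self.region_code(name)
        return np.flatnonzero(self.region_ids == code)

    # ---- geometry -----------------------------------------------------
    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tets
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        c = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    def mean_edge_length(self, tet_idx: np.ndarray | None = None) -> float:
        t = self.tets if tet_idx is None else self.tets[tet_idx]
        v = self.vertices
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        acc = 0.0
        for i, j in pairs:
            acc += np.linalg.norm(v[t[:, i]] - v[t[:, j]], axis=1).sum()
        return acc / (6 * len(t))

    def orient_positive(self) -> None:
        """Flip tets with negative signed volume in place."""
        vol = self.tet_volumes()
        neg = vol < 0
        if neg.any():
            self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]

    # ---- topology -----------------------------------------------------
    def face_census(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique faces, their incidence count (1 or 2) and the incident tets.

        Returns (faces, counts, face_tets) where ``faces`` is (f, 3) with
        sorted vertex triples, ``counts`` (f,), and ``face_tets`` (f, 2) with
        the incident tet indices (-1 padding for boundary faces).

        The census depends only on connectivity (not labels) and is cached.
        """
        if self._face_cache is not None:
            return self._face_cache
        m = self.n_tets
        all_faces = self.tets[:, _TET_FACES]           # (m, 4, 3)
        flat = np.sort(all_faces.reshape(-1, 3), axis=1)
        owner = np.repeat(np.arange(m), 4)
        order = np.lexsort(flat.T[::-1])
        flat_s = flat[order]
        owner_s = owner[order]
        new = np.ones(len(flat_s), dtype=bool)
        new[1:] = (flat_s[1:] != flat_s[:-1]).any(axis=1)
        group = np.cumsum(new) - 1
        nfaces = group[-1] + 1 if len(group) else 0
        counts = np.bincount(group, minlength=nfaces)
        if counts.max(initial=0) > 2:
            bad = flat_s[new][counts > 2]
            raise MeshValidationError(
                f"nonconforming mesh: faces shared by >2 tets, e.g. {bad[:5].tolist()}"
            )
        faces = flat_s[new]
        face_tets = np.full((nfaces, 2), -1, dtype=np.int64)
        first = np.flatnonzero(new)
        face_tets[:, 0] = owner_s[first]
        second_mask = counts == 2
        face_tets[second_mask, 1] = owner_s[first[second_mask] + 1]
        self._face_cache = (faces, counts, face_tets)
        return self._face_cache

    def validate(self) -> None:
        """Check structural invariants; raise MeshValidationError on failure."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_vertices:
            raise MeshValidationError("tet vertex index out of range")
        vol = self.tet_volumes()
        if (vol <= 0).any():
            raise MeshValidationError(
                f"{int((vol <= 0).sum())} tets with non-positive volume; "
                "call orient_positive() or fix the input"
            )
        faces, counts, _ = self.face_census()
        # geometric duplicates among combinatorial boundary faces indicate a
        # non-conforming mesh (e.g. duplicated vertices along a seam)
        bfaces = faces[counts == 1]
        if len(bfaces):
            coords = self.vertices[bfaces]          # (f, 3, 3)
            centers = coords.mean(axis=1)
            scale = float(np.ptp(centers)) or 1.0
            key = np.round(centers / scale * 1e9).astype(np.int64)
            _, inv, cnt = np.unique(key, axis=0, return_inverse=True, return_counts=True)
            if (cnt > 1).any():
                dup = bfaces[np.isin(inv, np.flatnonzero(cnt > 1))]
                raise MeshValidationError(
                    "nonconforming mesh: geometrically coincident boundary faces "
                    f"with distinct vertex indices, e.g. {dup[:4].tolist()}"
                )

    def region_connected(self, region: str) -> bool:
        """True if the region is single-connected under face adjacency."""
        idx = self.tets_of_region(region)
        if len(idx) == 0:
            return False
        _, counts, face_tets = self.face_census()
        inregion = np.zeros(self.n_tets, dtype=bool)
        inregion[idx] = True
        interior = counts == 2
        a, b = face_tets[interior, 0], face_tets[interior, 1]
        keep = inregion[a] & inregion[b]
        local = -np.ones(self.n_tets, dtype=np.int64)
        local[idx] = np.arange(len(idx))
        g = sp.coo_matrix(
            (np.ones(keep.sum()), (local[a[keep]], local[b[keep]])),
            shape=(len(idx), len(idx)),
        )
        ncomp, _ = sp.csgraph.connected_components(g, directed=False)
        return ncomp == 1

    def copy(self) -> "LabeledTetMesh":
        return LabeledTetMesh(
            vertices=self.vertices.copy(),
            tets=self.tets.copy(),
            region_ids=self.region_ids.copy(),
            region_names=list(self.region_names),
            original_region_ids=None if self.original_region_ids is None
            else self.original_region_ids.copy(),
            electrode_tets={k: v.copy() for k, v in self.electrode_tets.items()},
        )


@dataclass
class SurfacePatch:
    """Oriented triangle subset of a region boundary (Γ, Γ_s, Γ_t, Γ_sal, ...).

    Triangles are vertex index triples ordered so the right-hand normal
    points outward from the owning region.
    """

    mesh: LabeledTetMesh
    triangles: np.ndarray         # (t, 3) int64, outward-oriented
    owner_region: str
    role: str = "generic"

    def __len__(self) -> int:
        return len(self.triangles)

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.unique(self.triangles)

    def face_keys(self) -> set[tuple[int, int, int]]:
        return {tuple(f) for f in np.sort(self.triangles, axis=1).tolist()}

    def areas(self) -> np.ndarray:
        v = self.mesh.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )

    def normals(self) -> np.ndarray:
        v = self.mesh.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.where(norm > 0, norm, 1.0)

    def area(self) -> float:
        return float(self.areas().sum())

    def centroid(self) -> np.ndarray:
        """Area-weighted centroid of the patch."""
        v = self.mesh.vertices
        tri_c = v[self.triangles].mean(axis=1)
        a = self.areas()
        return (tri_c * a[:, None]).sum(axis=0) / a.sum()

    def edge_connected(self) -> bool:
        if len(self) == 0:
            return False
        edges = {}
        for i, tri in enumerate(np.sort(self.triangles, axis=1)):
            for e in [(tri[0], tri[1]), (tri[0], tri[2]), (tri[1], tri[2])]:
                edges.setdefault(e, []).append(i)
        g = sp.dok_matrix((len(self), len(self)), dtype=np.int8)
        for tris in edges.values():
            for a in tris[1:]:
                g[tris[0], a] = 1
        ncomp, _ = sp.csgraph.connected_components(g.tocsr(), directed=False)
        return ncomp == 1


@dataclass
class ScalarField:
    """One value per mesh vertex.

    For solves restricted to a region, values outside the region's vertex
    set are zero and ``vertex_mask`` marks where the field is defined.
    """

    mesh: LabeledTetMesh
    values: np.ndarray                       # (n,) float64
    vertex_mask: np.ndarray | None = None    # (n,) bool, None = everywhere
    region: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("field length must equal vertex count")
        check = self.values if self.vertex_mask is None else self.values[self.vertex_mask]
        if not np.all(np.isfinite(check)):
            raise ValueError("field contains non-finite values")


# ----------------------------------------------------------------------
# region / boundary queries
# ----------------------------------------------------------------------

def _outward_faces(mesh: LabeledTetMesh, tet_idx: np.ndarray, face_mask_fn) -> np.ndarray:
    """Collect outward-oriented faces of ``tet_idx`` selected by a predicate
    on the face's neighboring tet (-1 for exterior)."""
    faces, counts, face_tets = mesh.face_census()
    sel = np.zeros(mesh.n_tets + 1, dtype=bool)   # +1 slot for -1 padding
    sel[tet_idx] = True
    a, b = face_tets[:, 0], face_tets[:, 1]
    in_a, in_b = sel[a], sel[b]
    # faces with exactly one incident tet inside the set
    one_side = in_a ^ in_b
    inner = np.where(in_a, a, b)
    outer = np.where(in_a, b, a)
    keep = one_side & face_mask_fn(outer)
    f = faces[keep]
    t = inner[keep]
    if len(f) == 0:
        return np.empty((0, 3), dtype=np.int64)
    verts = mesh.vertices
    # orient each face so its right-hand normal points away from the inner tet;
    # the opposite vertex is the tet vertex not on the face
    opp = mesh.tets[t].sum(axis=1) - f.sum(axis=1)
    n = np.cross(verts[f[:, 1]] - verts[f[:, 0]], verts[f[:, 2]] - verts[f[:, 0]])
    inward = np.einsum("ij,ij->i", n, verts[opp] - verts[f[:, 0]]) > 0
    f = f.copy()
    f[inward] = f[inward][:, [0, 2, 1]]
    return f


def region_interface(mesh: LabeledTetMesh, region_a: str, region_b: str) -> SurfacePatch:
    """Faces with one incident tet in ``region_a`` and one in ``region_b``,
    normals outward from ``region_a``.  Empty patch if not in contact."""
    code_b = mesh.region_code(region_b)
    idx_a = mesh.tets_of_region(region_a)
    reg = np.append(mesh.region_ids, -999)   # -1 padding maps to sentinel

    tris = _outward_faces(mesh, idx_a, lambda outer: reg[outer] == code_b)
    return SurfacePatch(mesh, tris, owner_region=region_a, role="generic")


def region_boundary(
    mesh: LabeledTetMesh, region: str, against: Iterable[str] | str = "all"
) -> SurfacePatch:
    """Boundary faces of ``region``.

    ``against="all"`` keeps every face whose neighbor is outside the region
    (including exterior faces); ``against="exterior"`` keeps only faces with
    no neighboring tet; an iterable of region names restricts to neighbors
    in those regions.
    """
    idx = mesh.tets_of_region(region)
    if len(idx) == 0:
        raise UnknownRegionError(f"region {region!r} has no tets")
    reg = np.append(mesh.region_ids, -999)
    if against == "all":
        pred = lambda outer: np.ones(len(outer), dtype=bool)
    elif against == "exterior":
        pred = lambda outer: outer == -1
    else:
        codes = {mesh.region_code(r) for r in against}
        pred = lambda outer: np.isin(reg[outer], list(codes))
    # _outward_faces pads selection array by one slot so index -1 is the slot
    # mesh.n_tets; exterior neighbors (-1) land there.
    tris = _outward_faces(mesh, idx, pred)
    return SurfacePatch(mesh, tris, owner_region=region, role="generic")


# ----------------------------------------------------------------------
# surface geodesics
# ----------------------------------------------------------------------

def surface_vertex_distances(surface: SurfacePatch, seeds: Sequence[int]) -> dict[int, float]:
    """Dijkstra geodesic distance over the surface edge graph from ``seeds``.

    Edge weight is Euclidean edge length.  Returns distances for all surface
    vertices reachable from the seeds.
    """
    vids = surface.vertex_ids
    local = {int(v): i for i, v in enumerate(vids)}
    tri = surface.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [0, 2]], tri[:, [1, 2]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)   # an edge may be shared
    w = np.linalg.norm(
        surface.mesh.vertices[edges[:, 0]] - surface.mesh.vertices[edges[:, 1]], axis=1
    )
    rows = np.array([local[int(v)] for v in edges[:, 0]])
    cols = np.array([local[int(v)] for v in edges[:, 1]])
    g = sp.coo_matrix((w, (rows, cols)), shape=(len(vids), len(vids))).tocsr()
    seed_local = [local[int(s)] for s in seeds]
    d = _csgraph_dijkstra(g, directed=False, indices=seed_local, min_only=True)
    return {int(v): float(d[i]) for i, v in enumerate(vids)}


def surface_geodesic_patch(
    surface: SurfacePatch, seed_vertex: int, radius: float
) -> SurfacePatch:
    """Triangles all of whose vertices lie within geodesic ``radius`` of
    ``seed_vertex``; triangles incident to the seed are always included."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if seed_vertex not in surface.vertex_ids:
        raise ValueError(f"seed vertex {seed_vertex} is not on the surface")
    dist = surface_vertex_distances(surface, [seed_vertex])
    tri = surface.triangles
    d = np.array([[dist.get(int(v), np.inf) for v in t] for t in tri])
    keep = (d <= radius).all(axis=1) | (tri == seed_vertex).any(axis=1)
    return SurfacePatch(
        surface.mesh, tri[keep], owner_region=surface.owner_region, role=surface.role
    )


# ----------------------------------------------------------------------
# voxel -> tet conversion (Freudenthal/Kuhn 6-tet split)
# ----------------------------------------------------------------------

# corner offsets of a cell, index c = (i<<2) | (j<<1) | k
_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)


def _kuhn_templates() -> np.ndarray:
    """Six tets along the main diagonal, identical in every cell (the uniform
    Freudenthal split is face-conforming across cells)."""
    def cid(i, j, k):
        return (i << 2) | (j << 1) | k

    e = [np.array(v) for v in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
    tets = []
    import itertools

    for p in itertools.permutations(range(3)):
        c0 = np.zeros(3, dtype=int)
        c1 = c0 + e[p[0]]
        c2 = c1 + e[p[1]]
        c3 = np.ones(3, dtype=int)
        tets.append([cid(*c) for c in (c0, c1, c2, c3)])
    return np.array(tets, dtype=np.int64)


_KUHN = _kuhn_templates()


def voxel_to_tetmesh(
    labels: np.ndarray,
    voxel_size: float | Sequence[float],
    region_names: dict[int, str] | None = None,
    background: int = 0,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> LabeledTetMesh:
    """Convert a 3-D integer label grid to a conforming labeled tet mesh.

    Each labeled voxel is split into 6 tetrahedra (Kuhn subdivision along the
    main diagonal); the split is identical in every voxel, which makes shared
    faces match between neighbors.  Background voxels are dropped.  Per-label
    volume is conserved exactly.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3 or labels.size == 0:
        raise ValueError("labels must be a nonempty 3-D array")
    if np.isscalar(voxel_size):
        h = np.array([voxel_size] * 3, dtype=np.float64)
    else:
        h = np.asarray(voxel_size, dtype=np.float64)
        if h.shape != (3,):
            raise ValueError("anisotropic voxel size requires explicit per-axis spacing (3 values)")
    if (h <= 0).any():
        raise ValueError("voxel size must be positive")

    occ = np.argwhere(labels != background)
    if len(occ) == 0:
        raise ValueError("label grid contains no foreground voxels")
    lab = labels[occ[:, 0], occ[:, 1], occ[:, 2]]

    ny1, nz1 = labels.shape[1] + 1, labels.shape[2] + 1

    def vid(ijk):  # (k,3) -> grid vertex id
        return (ijk[:, 0] * ny1 + ijk[:, 1]) * nz1 + ijk[:, 2]

    # 8 corner grid-ids per occupied voxel
    corners = occ[:, None, :] + _CORNERS[None, :, :]          # (v, 8, 3)
    corner_ids = vid(corners.reshape(-1, 3)).reshape(-1, 8)   # (v, 8)

    tets = corner_ids[:, _KUHN].reshape(-1, 4)                # (v*6, 4)
    tet_labels = np.repeat(lab, 6)

    used, inv = np.unique(tets, return_inverse=True)
    tets = inv.reshape(-1, 4).astype(np.int64)
    gi = used // (ny1 * nz1)
    gj = (used // nz1) % ny1
    gk = used % nz1
    verts = np.stack([gi, gj, gk], axis=1).astype(np.float64) * h + np.asarray(origin)

    values = np.unique(tet_labels)
    if region_names is None:
        region_names = {}
    names = [region_names.get(int(v), f"region_{int(v)}") for v in values]
    code_of = {int(v): i for i, v in enumerate(values)}
    region_ids = np.array([code_of[int(v)] for v in tet_labels], dtype=np.int32)

    mesh = LabeledTetMesh(verts, tets, region_ids, names)
    mesh.orient_positive()
    return mesh
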