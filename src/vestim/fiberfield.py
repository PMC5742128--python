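"""Nerve-fiber orientation fields from Laplace solves on the nerve volume.

Three-step procedure per nerve branch:

1. *Distance surrogate*: solve Δϕ = 0 on the nerve region with ϕ = 0 on the
   start surface Γ_s and a uniform outflow −∇ϕ·n = 1 on the remaining
   boundary.  The boundary vertex with the lowest ϕ approximates the most
   distant surface point from Γ_s.
2. *Target surface*: geodesic (Dijkstra) patch of the boundary around that
   extremal point.
3. *Orientation solve*: Δϕ = 0 with the Cauchy (Robin) condition
   −∇ϕ·n = α(x)[ϕ − ϕ_e(x)], where (α, ϕ_e) = (α_s, 0) on Γ_s, (α_t, 1) on
   Γ_t and α = 0 (insulating) elsewhere.  The fiber orientation is the
   normed gradient F = ∇ϕ/|∇ϕ|, constant per tetrahedron.

Larger α_s, α_t force a steeper (more normal) entrance/exit angle of F at
the respective surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .mesh import (
    LabeledTetMesh,
    ScalarField,
    SurfacePatch,
    region_boundary,
    surface_geodesic_patch,
)


@dataclass
class CauchyParams:
    """Robin coupling coefficients for the orientation solve (units m⁻²,
    following the convention of the underlying formulation; default 100)."""

    alpha_s: float = 100.0
    alpha_t: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha_s <= 0 or self.alpha_t <= 0:
            raise ValueError("alpha_s and alpha_t must be > 0")


@dataclass
class OrientationField:
    """Unit fiber-direction vector per tetrahedron of one nerve region."""

    mesh: LabeledTetMesh
    region: str
    tet_ids: np.ndarray       # (k,) indices into mesh.tets
    vectors: np.ndarray       # (k, 3) unit vectors

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientation vectors must have unit norm")

    def full(self) -> np.ndarray:
        """(m, 3) array over all tets, zero outside the region."""
        out = np.zeros((self.mesh.n_tets, 3))
        out[self.tet_ids] = self.vectors
        return out


@dataclass
class _RegionProblem:
    """Extracted single-region submesh with local vertex numbering."""

    mesh: LabeledTetMesh
    region: str
    tet_ids: np.ndarray
    local_tets: np.ndarray      # (k, 4) local indices
    verts: np.ndarray           # (p, 3)
    global_verts: np.ndarray    # (p,) local -> global
    to_local: dict[int, int]

    @classmethod
    def extract(cls, mesh: LabeledTetMesh, region: str) -> "_RegionProblem":
        tet_ids = mesh.tets_of_region(region)
        if len(tet_ids) == 0:
            raise ValueError(f"region {region!r} is empty")
        tets = mesh.tets[tet_ids]
        gverts, inv = np.unique(tets, return_inverse=True)
        return cls(
            mesh=mesh,
            region=region,
            tet_ids=tet_ids,
            local_tets=inv.reshape(-1, 4),
            verts=mesh.vertices[gverts],
            global_verts=gverts,
            to_local={int(g): i for i, g in enumerate(gverts)},
        )

    def localize_tris(self, tris: np.ndarray) -> np.ndarray:
        return np.array(
            [[self.to_local[int(v)] for v in t] for t in tris], dtype=np.int64
        ).reshape(-1, 3)

    def to_field(self, local_values: np.ndarray) -> ScalarField:
        vals = np.zeros(self.mesh.n_vertices)
        vals[self.global_verts] = local_values
        mask = np.zeros(self.mesh.n_vertices, dtype=bool)
        mask[self.global_verts] = True
        return ScalarField(self.mesh, vals, vertex_mask=mask, region=self.region)


def _check_patch_on_region(prob: _RegionProblem, patch: SurfacePatch, what: str) -> None:
    if len(patch) == 0:
        raise ValueError(f"{what} surface patch is empty")
    missing = [v for v in patch.vertex_ids if int(v) not in prob.to_local]
    if missing:
        raise ValueError(f"{what} surface is not on the boundary of region {prob.region!r}")


def solve_distance_surrogate(
    mesh: LabeledTetMesh, region: str, start: SurfacePatch
) -> ScalarField:
    """Distance-surrogate potential: ϕ = 0 on Γ_s, uniform outflow elsewhere.

    By the maximum principle the solution is ≤ 0 with its minimum away from
    Γ_s; lower values are (approximately) farther from the start surface.
    """
    prob = _RegionProblem.extract(mesh, region)
    _check_patch_on_region(prob, start, "start")
    boundary = region_boundary(mesh, region, "all")
    start_keys = start.face_keys()
    btris = boundary.triangles
    bkeys = [tuple(f) for f in np.sort(btris, axis=1).tolist()]
    neumann = btris[[k not in start_keys for k in bkeys]]

    K = fem.assemble_stiffness(prob.verts, prob.local_tets, 1.0)
    # weak form: ∫∇ϕ·∇v = ∮(∇ϕ·n) v dΓ with ∇ϕ·n = -1 on Γ\Γ_s
    b = fem.surface_load(len(prob.verts), prob.verts, prob.localize_tris(neumann), -1.0)
    dir_idx = np.unique([prob.to_local[int(v)] for v in start.vertex_ids])
    x, _ = fem.solve_constrained(K, b, dir_idx, 0.0)
    return prob.to_field(x)


def find_extremal_point(field: ScalarField, surface: SurfacePatch) -> int:
    """Boundary vertex with the minimal field value (ties: lowest index)."""
    vids = surface.vertex_ids
    if len(vids) == 0:
        raise ValueError("surface patch is empty")
    vals = field.values[vids]
    best = vals.min()
    return int(vids[np.flatnonzero(vals == best)[0]])


def find_target_surface(
    mesh: LabeledTetMesh,
    region: str,
    start: SurfacePatch,
    patch_radius: float,
) -> SurfacePatch:
    """Distance solve → extremal boundary point → geodesic patch = Γ_t."""
    if patch_radius <= 0:
        raise ValueError("patch_radius must be > 0")
    phi = solve_distance_surrogate(mesh, region, start)
    boundary = region_boundary(mesh, region, "all")
    far = find_extremal_point(phi, boundary)
    patch = surface_geodesic_patch(boundary, far, patch_radius)
    if patch.face_keys() & start.face_keys():
        raise ValueError(
            "target patch overlaps the start surface; use a smaller patch_radius"
        )
    patch.role = "target"
    return patch


def auto_start_surface_tube(
    mesh: LabeledTetMesh,
    region: str,
    patch_radius: float,
    rng_seed: int = 0,
) -> SurfacePatch:
    """Start surface for a tube-like nerve with no epithelium reference.

    A seeded random boundary triangle serves as a temporary Γ_s; the distance
    surrogate then finds the most distant boundary point, around which the
    definitive start surface is grown geodesically.
    """
    boundary = region_boundary(mesh, region, "all")
    rng = np.random.default_rng(rng_seed)
    pick = int(rng.integers(len(boundary.triangles)))
    temp = SurfacePatch(mesh, boundary.triangles[pick : pick + 1], region, role="start")
    phi = solve_distance_surrogate(mesh, region, temp)
    far = find_extremal_point(phi, boundary)
    patch = surface_geodesic_patch(boundary, far, patch_radius)
    patch.role = "start"
    return patch


def solve_orientation_potential(
    mesh: LabeledTetMesh,
    region: str,
    start: SurfacePatch,
    target: SurfacePatch,
    params: CauchyParams | None = None,
) -> ScalarField:
    """Laplace solve with Robin coupling: soft ϕ≈0 on Γ_s, ϕ≈1 on Γ_t,
    insulating elsewhere.  Values lie in [0, 1] up to discretization."""
    params = params or CauchyParams()
    prob = _RegionProblem.extract(mesh, region)
    _check_patch_on_region(prob, start, "start")
    _check_patch_on_region(prob, target, "target")
    if start.face_keys() & target.face_keys():
        raise ValueError("start and target surfaces must be disjoint")

    n = len(prob.verts)
    s_tris = prob.localize_tris(start.triangles)
    t_tris = prob.localize_tris(target.triangles)
    K = fem.assemble_stiffness(prob.verts, prob.local_tets, 1.0)
    K = K + fem.assemble_boundary_mass(n, prob.verts, s_tris, params.alpha_s)
    K = K + fem.assemble_boundary_mass(n, prob.verts, t_tris, params.alpha_t)
    # RHS: α_t · ϕ_e with ϕ_e = 1 on Γ_t (ϕ_e = 0 on Γ_s contributes nothing)
    b = fem.surface_load(n, prob.verts, t_tris, params.alpha_t * 1.0)
    x, _ = fem.solve_constrained(K, b)
    return prob.to_field(x)


def orientation_from_potential(
    mesh: LabeledTetMesh, region: str, field: ScalarField
) -> OrientationField:
    """Per-tet normed gradient F = ∇ϕ/|∇ϕ| of a P1 field on the region.

    Tets with a (near-)vanishing gradient inherit the averaged direction of
    their face neighbors.
    """
    prob = _RegionProblem.extract(mesh, region)
    grads, _ = fem.shape_gradients(prob.verts, prob.local_tets)
    phi = field.values[prob.global_verts]
    g = np.einsum("eiv,ei->ev", grads, phi[prob.local_tets])
    norms = np.linalg.norm(g, axis=1)
    ok = norms > 1e-12
    if not ok.any():
        raise ValueError(f"all gradients degenerate on region {region!r}")
    vec = np.zeros_like(g)
    vec[ok] = g[ok] / norms[ok, None]

    if (~ok).any():
        # face-neighbor adjacency restricted to the region
        _, counts, face_tets = mesh.face_census()
        sel = np.zeros(mesh.n_tets, dtype=np.int64) - 1
        sel[prob.tet_ids] = np.arange(len(prob.tet_ids))
        interior = counts == 2
        a = sel[face_tets[interior, 0]]
        bb = sel[face_tets[interior, 1]]
        keep = (a >= 0) & (bb >= 0)
        pairs = np.stack([a[keep], bb[keep]], axis=1)
        todo = np.flatnonzero(~ok)
        for _ in range(100):
            if len(todo) == 0:
                break
            progressed = False
            for t in todo:
                nbrs = np.concatenate([pairs[pairs[:, 0] == t, 1], pairs[pairs[:, 1] == t, 0]])
                good = nbrs[ok[nbrs]]
                if len(good):
                    avg = vec[good].sum(axis=0)
                    nn = np.linalg.norm(avg)
                    if nn > 1e-12:
                        vec[t] = avg / nn
                        ok[t] = True
                        progressed = True
            todo = np.flatnonzero(~ok)
            if not progressed:
                break
        if (~ok).any():
            raise ValueError(
                f"{int((~ok).sum())} tets with unrecoverable degenerate gradients"
            )
    return OrientationField(mesh, region, prob.tet_ids, vec)
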