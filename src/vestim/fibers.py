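"""Streamline synthesis of nerve-fiber trajectories.

Fibers grow from seed points scattered uniformly over the start surface Γ_s
along the orientation field F (piecewise constant per tet, RK4 fixed-step
integration with point location by tet walking).  A trace is accepted only
if it leaves the nerve volume through the target surface Γ_t; rejected seeds
are resampled until the requested count is reached.

Fiber types (regular / irregular / dimorphic) are assigned from the seed's
position on the epithelium: irregular afferents concentrate in the central
zone, regular ones peripherally, dimorphic everywhere.  Nodes of Ranvier are
placed along each accepted trajectory at type-dependent internodal spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .fiberfield import OrientationField
from .mesh import LabeledTetMesh, SurfacePatch, surface_vertex_distances


class TracingError(RuntimeError):
    pass


class FiberGenerationError(RuntimeError):
    pass


@dataclass
class Fiber:
    points: np.ndarray                 # (k, 3) polyline, meters
    branch: str
    fiber_type: str = "dimorphic"      # regular | irregular | dimorphic
    node_arc_lengths: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    seed_point: np.ndarray | None = None
    exit_face: tuple[int, int, int] | None = None

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_lengths()[-1])

    def node_points(self) -> np.ndarray:
        """Node-of-Ranvier coordinates by arc-length interpolation."""
        s = self.arc_lengths()
        out = np.empty((len(self.node_arc_lengths), 3))
        for d in range(3):
            out[:, d] = np.interp(self.node_arc_lengths, s, self.points[:, d])
        return out


@dataclass
class FiberSet:
    fibers: list[Fiber]
    branch: str
    seed: int
    attempts: int = 0
    rejections: int = 0

    def __len__(self) -> int:
        return len(self.fibers)


# ----------------------------------------------------------------------
# seeding
# ----------------------------------------------------------------------

def seed_start_points(start: SurfacePatch, n: int, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random points on the patch: triangles chosen area-weighted,
    positions by uniform barycentric sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(start) == 0:
        raise ValueError("cannot seed on an empty surface patch")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    areas = start.areas()
    tri_idx = rng.choice(len(start), size=n, p=areas / areas.sum())
    r1 = rng.random(n)
    r2 = rng.random(n)
    s1 = np.sqrt(r1)
    b0 = 1 - s1
    b1 = s1 * (1 - r2)
    b2 = s1 * r2
    v = start.mesh.vertices
    t = start.triangles[tri_idx]
    return b0[:, None] * v[t[:, 0]] + b1[:, None] * v[t[:, 1]] + b2[:, None] * v[t[:, 2]]


# ----------------------------------------------------------------------
# tet walking / point location
# ----------------------------------------------------------------------

class RegionWalker:
    """Point location and boundary bookkeeping for one region's tet subset."""

    def __init__(self, mesh: LabeledTetMesh, region: str):
        self.mesh = mesh
        self.region = region
        self.tet_ids = mesh.tets_of_region(region)
        if len(self.tet_ids) == 0:
            raise ValueError(f"region {region!r} is empty")
        self.local_of = -np.ones(mesh.n_tets, dtype=np.int64)
        self.local_of[self.tet_ids] = np.arange(len(self.tet_ids))
        self.tets = mesh.tets[self.tet_ids]
        self.verts = mesh.vertices

        # neighbor[l, f] = local neighbor across local face f (opposite vertex
        # f), or -1 when the face is a region boundary
        faces, counts, face_tets = mesh.face_census()
        self.neighbor = -np.ones((len(self.tet_ids), 4), dtype=np.int64)
        sorted_local_faces = {}
        for l, tet in enumerate(self.tets):
            for f in range(4):
                tri = tuple(sorted(np.delete(tet, f)))
                sorted_local_faces.setdefault(tri, []).append((l, f))
        for tri, inc in sorted_local_faces.items():
            if len(inc) == 2:
                (l1, f1), (l2, f2) = inc
                self.neighbor[l1, f1] = l2
                self.neighbor[l2, f2] = l1
        self._centroid_tree = cKDTree(self.verts[self.tets].mean(axis=1))
        # cache barycentric transform: x -> lambda via T^-1 (x - v0)
        v0 = self.verts[self.tets[:, 0]]
        T = np.stack([self.verts[self.tets[:, i]] - v0 for i in (1, 2, 3)], axis=2)
        self._Tinv = np.linalg.inv(T)
        self._v0 = v0

    def barycentric(self, ltet: int, point: np.ndarray) -> np.ndarray:
        lam123 = self._Tinv[ltet] @ (point - self._v0[ltet])
        return np.concatenate([[1.0 - lam123.sum()], lam123])

    def locate(self, point: np.ndarray, hint: int | None = None, tol: float = 1e-9) -> int | None:
        """Local tet containing ``point`` (barycentric tolerance), walking
        from ``hint`` with a KD-tree fallback.  None if outside the region."""
        candidates = []
        if hint is not None and hint >= 0:
            candidates.append(hint)
        _, nearest = self._centroid_tree.query(point, k=min(8, len(self.tets)))
        candidates.extend(np.atleast_1d(nearest).tolist())
        visited = set()
        for start in candidates:
            cur = int(start)
            for _ in range(2000):
                if cur in visited:
                    break
                visited.add(cur)
                lam = self.barycentric(cur, point)
                worst = int(np.argmin(lam))
                if lam[worst] >= -tol:
                    return cur
                nxt = self.neighbor[cur, worst]
                if nxt < 0:
                    break
                cur = int(nxt)
        # exhaustive fallback for robustness near corners
        lam0 = 1.0 - np.einsum("eij,ej->ei", self._Tinv, point - self._v0).sum(axis=1)
        lam123 = np.einsum("eij,ej->ei", self._Tinv, point - self._v0)
        lam_min = np.minimum(lam0, lam123.min(axis=1))
        best = int(np.argmax(lam_min))
        if lam_min[best] >= -tol:
            return best
        return None

    def face_triangle(self, ltet: int, lface: int) -> tuple[int, int, int]:
        tri = np.delete(self.tets[ltet], lface)
        return tuple(sorted(int(v) for v in tri))

    def clip_segment(self, x0: np.ndarray, x1: np.ndarray, ltet: int):
        """Walk the segment x0→x1 starting in tet ``ltet``.

        Returns (end_tet, None, None) if x1 stays inside the region, else
        (last_tet, exit_point, exit_face_triangle).
        """
        cur = ltet
        for _ in range(5000):
            lam = self.barycentric(cur, x1)
            worst = int(np.argmin(lam))
            if lam[worst] >= -1e-12:
                return cur, None, None
            nxt = self.neighbor[cur, worst]
            if nxt >= 0:
                cur = int(nxt)
                continue
            # exits through boundary face `worst` of `cur`: intersect the
            # segment with the plane lambda_worst = 0
            l0 = self.barycentric(cur, x0)[worst]
            l1 = lam[worst]
            t = l0 / (l0 - l1) if l0 != l1 else 0.0
            t = min(max(t, 0.0), 1.0)
            exit_pt = x0 + t * (x1 - x0)
            return cur, exit_pt, self.face_triangle(cur, worst)
        raise TracingError("tet walk did not terminate while clipping a segment")


# ----------------------------------------------------------------------
# streamline tracing
# ----------------------------------------------------------------------

def trace_streamline(
    field: OrientationField,
    seed: np.ndarray,
    step: float,
    max_steps: int = 10_000,
    walker: RegionWalker | None = None,
):
    """Fixed-step RK4 integration of dx/ds = F(x) through the region.

    Returns (polyline, exit_face, terminated) where ``exit_face`` is the
    sorted vertex triple of the boundary face the trace left through (None
    if ``max_steps`` was reached) and ``terminated`` flags regular exit.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    walker = walker or RegionWalker(field.mesh, field.region)
    fvec = field.vectors

    cur = walker.locate(np.asarray(seed, dtype=float))
    if cur is None:
        raise TracingError(f"seed point {seed} is not inside region {field.region!r}")

    def F(x, hint):
        t = walker.locate(x, hint, tol=1e-6)
        return fvec[t if t is not None else hint]

    pts = [np.asarray(seed, dtype=float)]
    x = pts[0]
    for _ in range(max_steps):
        k1 = F(x, cur)
        k2 = F(x + 0.5 * step * k1, cur)
        k3 = F(x + 0.5 * step * k2, cur)
        k4 = F(x + step * k3, cur)
        x1 = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        end_tet, exit_pt, exit_face = walker.clip_segment(x, x1, cur)
        if exit_face is not None:
            pts.append(exit_pt)
            return np.array(pts), exit_face, True
        cur = end_tet
        pts.append(x1)
        x = x1
    return np.array(pts), None, False


# ----------------------------------------------------------------------
# fiber set generation
# ----------------------------------------------------------------------

def generate_fibers(
    mesh: LabeledTetMesh,
    region: str,
    field: OrientationField,
    start: SurfacePatch,
    target: SurfacePatch,
    n: int,
    rng_seed: int = 0,
    max_attempts: int | None = None,
    step: float | None = None,
    branch: str | None = None,
) -> FiberSet:
    """Seed-and-trace until ``n`` fibers terminate on the target surface.

    Traces that exit elsewhere (or fail to terminate) are rejected and their
    seeds resampled.  Deterministic for a fixed ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    max_attempts = max_attempts if max_attempts is not None else 50 * n
    # RK4 step: quarter of the region's mean tet edge, balancing accuracy
    # against tet-walk robustness
    tet_ids = mesh.tets_of_region(region)
    step = step if step is not None else mesh.mean_edge_length(tet_ids) / 4.0
    walker = RegionWalker(mesh, region)
    target_keys = target.face_keys()
    rng = np.random.default_rng(rng_seed)

    fibers: list[Fiber] = []
    attempts = rejections = 0
    # push seeds slightly inside along the inward patch normal so that point
    # location is unambiguous on the boundary
    eps = step * 1e-3
    normals = start.normals()
    tri_tree = cKDTree(mesh.vertices[start.triangles].mean(axis=1))
    while len(fibers) < n and attempts < max_attempts:
        batch = min(max(n - len(fibers), 8), max_attempts - attempts)
        seeds = seed_start_points(start, batch, rng)
        _, tri_of = tri_tree.query(seeds)  # inward normal of nearest triangle
        for s, ti in zip(seeds, np.atleast_1d(tri_of)):
            if len(fibers) >= n:
                break
            attempts += 1
            s_in = s - eps * normals[ti]
            try:
                pts, exit_face, terminated = trace_streamline(
                    field, s_in, step, walker=walker
                )
            except TracingError:
                rejections += 1
                continue
            if terminated and exit_face in target_keys:
                pts[0] = s   # restore the exact on-surface seed
                fibers.append(
                    Fiber(points=pts, branch=branch or region, seed_point=s,
                          exit_face=exit_face)
                )
            else:
                rejections += 1
    if len(fibers) < n:
        rate = len(fibers) / attempts if attempts else 0.0
        raise FiberGenerationError(
            f"only {len(fibers)}/{n} fibers accepted after {attempts} attempts "
            f"(acceptance rate {rate:.3f}); check start/target surfaces"
        )
    return FiberSet(fibers=fibers, branch=branch or region, seed=int(rng_seed),
                    attempts=attempts, rejections=rejections)


# ----------------------------------------------------------------------
# fiber types and nodes of Ranvier
# ----------------------------------------------------------------------

DEFAULT_TYPE_PROBABILITIES = {
    "central": {"irregular": 0.5, "dimorphic": 0.5},
    "peripheral": {"regular": 0.5, "dimorphic": 0.5},
}

# type-dependent internodal distances (configurable; representative values
# for mammalian vestibular afferents)
DEFAULT_INTERNODAL_DISTANCE = {
    "regular": 350e-6,
    "irregular": 250e-6,
    "dimorphic": 300e-6,
}


def epithelium_zone_distances(start: SurfacePatch) -> dict[int, float]:
    """Geodesic distance of every patch vertex from the vertex nearest the
    patch's area centroid (the 'center' of the sensory epithelium)."""
    c = start.centroid()
    vids = start.vertex_ids
    center_vertex = int(vids[np.argmin(np.linalg.norm(start.mesh.vertices[vids] - c, axis=1))])
    return surface_vertex_distances(start, [center_vertex])


def assign_fiber_type(
    fiber: Fiber,
    start: SurfacePatch,
    central_fraction: float = 0.5,
    type_probabilities: dict[str, dict[str, float]] | None = None,
    rng: np.random.Generator | int = 0,
    _zone_distances: dict[int, float] | None = None,
) -> str:
    """Zone-based stochastic type assignment.

    The seed is 'central' if its geodesic distance from the epithelium center
    falls below the ``central_fraction`` quantile of all patch vertex
    distances, else 'peripheral'; the type is drawn from the zone's
    distribution.
    """
    if not 0 < central_fraction < 1:
        raise ValueError("central_fraction must be in (0, 1)")
    probs = type_probabilities or DEFAULT_TYPE_PROBABILITIES
    for zone, dist in probs.items():
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(f"type probabilities for zone {zone!r} do not sum to 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    dmap = _zone_distances if _zone_distances is not None else epithelium_zone_distances(start)
    vids = np.array(sorted(dmap.keys()))
    dists = np.array([dmap[int(v)] for v in vids])
    cutoff = np.quantile(dists, central_fraction)

    seed = fiber.seed_point if fiber.seed_point is not None else fiber.points[0]
    nearest = int(vids[np.argmin(np.linalg.norm(start.mesh.vertices[vids] - seed, axis=1))])
    zone = "central" if dmap[nearest] < cutoff else "peripheral"
    dist = probs[zone]
    types = sorted(dist.keys())
    p = np.array([dist[t] for t in types])
    fiber.fiber_type = str(rng.choice(types, p=p))
    return fiber.fiber_type


def assign_fiber_types(
    fiberset: FiberSet,
    start: SurfacePatch,
    central_fraction: float = 0.5,
    type_probabilities: dict[str, dict[str, float]] | None = None,
    rng_seed: int = 0,
) -> None:
    """Assign types to every fiber of a set (shared zone precomputation)."""
    rng = np.random.default_rng(rng_seed)
    dmap = epithelium_zone_distances(start)
    for f in fiberset.fibers:
        assign_fiber_type(f, start, central_fraction, type_probabilities, rng,
                          _zone_distances=dmap)


def place_nodes_of_ranvier(
    fiber: Fiber, internodal_distance: float, first_node_offset: float = 0.0
) -> np.ndarray:
    """Node arc lengths offset, offset+Δ, ... ≤ fiber length (≥ 2 nodes)."""
    if internodal_distance <= 0:
        raise ValueError("internodal_distance must be > 0")
    if first_node_offset < 0:
        raise ValueError("first_node_offset must be >= 0")
    L = fiber.length
    if L < first_node_offset + internodal_distance:
        raise ValueError(
            f"fiber of length {L:.6g} m too short for offset "
            f"{first_node_offset:.6g} + internodal distance {internodal_distance:.6g}"
        )
    k = int(np.floor((L - first_node_offset) / internodal_distance)) + 1
    nodes = first_node_offset + internodal_distance * np.arange(k)
    fiber.node_arc_lengths = nodes
    return nodes
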