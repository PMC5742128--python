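"""Quasistatic anisotropic volume-conductor solve.

The potential of a unit injected current obeys the Poisson equation
−∇·(σ∇ϕ) = I_s with the unit current distributed uniformly over the active
electrode region (I_s = I/V_a), a 0 V reference on the reference-electrode
region (bipolar) or on the outer saline surface (monopolar), and insulating
outer boundary otherwise.  Tissues are purely resistive (quasistatic
assumption), so the potential at any stimulus instant is the unit-current
solution scaled by the instantaneous amplitude.

Nerve tissue is anisotropic: σ = σ_t I + (σ_l − σ_t) F Fᵀ with the fiber
orientation F, longitudinal conductivity σ_l and transversal σ_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from . import fem
from .electrodes import StimulusWaveform
from .fiberfield import OrientationField
from .mesh import LabeledTetMesh, ScalarField, region_boundary


class ConductivityError(ValueError):
    pass


# Default conductivities (S/m).  Vestibular tissues from chinchilla
# measurements adopted for human modeling; cochlear nerve = mean of the
# longitudinal and transversal nerve values (no fibers generated there);
# epithelium treated the same way (thin unoriented neural tissue).
DEFAULT_SIGMA = {
    "bone": 0.0139,
    "nerve": (0.3333, 0.0143),        # (longitudinal, transversal)
    "cochlear_nerve": 0.1738,
    "scala": 2.0,
    "endolymph": 2.0,
    "perilymph": 2.0,
    "saline": 2.0,
    "electrode": 1.0e6,
    "epithelium": 0.1738,
    "IAC": (0.3333, 0.0143),
}


@dataclass
class ConductivityTable:
    """Per-region conductivity: isotropic σ or an anisotropic
    (σ_longitudinal, σ_transversal) pair bound to an orientation field."""

    entries: dict[str, float | tuple[float, float]] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, v in self.entries.items():
            vals = v if isinstance(v, tuple) else (v,)
            if any(s <= 0 for s in vals):
                raise ConductivityError(f"conductivity for {region!r} must be > 0")

    def lookup(self, region: str) -> float | tuple[float, float]:
        """Entry for a region, falling back to prefix matching against the
        default vocabulary (nerve_target -> 'nerve', electrode_x ->
        'electrode', ...)."""
        if region in self.entries:
            return self.entries[region]
        for prefix, v in self.entries.items():
            if region.startswith(prefix + "_") or region.startswith(prefix):
                return v
        raise ConductivityError(f"no conductivity entry for region {region!r}")


def default_conductivities() -> ConductivityTable:
    return ConductivityTable(dict(DEFAULT_SIGMA))


def per_tet_conductivity(
    mesh: LabeledTetMesh,
    table: ConductivityTable,
    fields: dict[str, OrientationField] | None = None,
) -> np.ndarray:
    """(m, 3, 3) symmetric positive definite conductivity tensors.

    Isotropic regions get σI.  Anisotropic regions need an orientation field
    covering every tet: σ = σ_t I + (σ_l − σ_t) F Fᵀ, so the eigenvalues are
    {σ_l, σ_t, σ_t} with principal axis F.  Anisotropic regions *without* a
    field entry fall back to the isotropic mean (σ_l + σ_t)/2.
    """
    fields = fields or {}
    m = mesh.n_tets
    tensors = np.zeros((m, 3, 3))
    eye = np.eye(3)
    for region in mesh.regions:
        idx = mesh.tets_of_region(region)
        entry = table.lookup(region)
        if isinstance(entry, tuple):
            sig_l, sig_t = entry
            if region in fields:
                f = fields[region]
                covered = np.isin(idx, f.tet_ids)
                if not covered.all():
                    raise ConductivityError(
                        f"orientation field for {region!r} does not cover all tets"
                    )
                full = f.full()[idx]
                tensors[idx] = sig_t * eye + (sig_l - sig_t) * np.einsum(
                    "ei,ej->eij", full, full
                )
            else:
                tensors[idx] = ((sig_l + sig_t) / 2.0) * eye
        else:
            tensors[idx] = float(entry) * eye
    return tensors


@dataclass
class SourceSpec:
    """Unit-current source: active electrode region(s) with total current I
    distributed uniformly, and exactly one reference mechanism."""

    active_regions: list[str]
    current: float = 1.0
    reference_regions: list[str] | None = None   # bipolar
    saline_region: str = "saline"                # monopolar ground surface

    @property
    def is_monopolar(self) -> bool:
        # an explicitly given (possibly empty) reference list means bipolar;
        # an empty list is caught as a solver error, not silently regrounded
        return self.reference_regions is None


@dataclass
class UnitPotential:
    """Potential field of a unit injected current (V per A)."""

    field: ScalarField
    source: SourceSpec
    diagnostics: dict
    active_vertices: np.ndarray | None = None      # vertex ids of Ω_a at solve time
    reference_vertices: np.ndarray | None = None   # vertex ids of Ω_r / Γ_sal

    @property
    def mesh(self) -> LabeledTetMesh:
        return self.field.mesh

    @property
    def values(self) -> np.ndarray:
        return self.field.values


def solve_unit_current(
    mesh: LabeledTetMesh,
    tensors: np.ndarray,
    source: SourceSpec,
) -> UnitPotential:
    """P1 FEM solve of the unit-current Poisson problem.

    Monopolar: Dirichlet ϕ=0 on all outer saline surface vertices.  Bipolar:
    Dirichlet ϕ=0 on all vertices of the reference region, natural zero-flux
    on the outer surface.  Diagnostics report the solver residual and the
    current balance (reaction current at the reference / injected current).
    """
    n = mesh.n_vertices
    active_idx = np.concatenate([mesh.tets_of_region(r) for r in source.active_regions])
    if len(active_idx) == 0:
        raise ConductivityError("active electrode region is empty")
    vols = mesh.tet_volumes()
    V_a = vols[active_idx].sum()
    I_s = source.current / V_a

    K = fem.assemble_stiffness(mesh.vertices, mesh.tets, tensors)
    b = np.zeros(n)
    contrib = (I_s * vols[active_idx] / 4.0)[:, None].repeat(4, axis=1)
    np.add.at(b, mesh.tets[active_idx].reshape(-1), contrib.reshape(-1))

    if source.is_monopolar:
        sal = region_boundary(mesh, source.saline_region, "exterior")
        dir_idx = sal.vertex_ids
        if len(dir_idx) == 0:
            raise fem.SolverError("no exterior saline surface found for monopolar reference")
    else:
        if not source.reference_regions:
            raise fem.SolverError("reference electrode region is empty")
        ref_tets = np.concatenate(
            [mesh.tets_of_region(r) for r in source.reference_regions]
        )
        if len(ref_tets) == 0:
            raise fem.SolverError("reference electrode region is empty")
        dir_idx = np.unique(mesh.tets[ref_tets])

    x, info = fem.solve_constrained(K, b, dir_idx, 0.0)
    # current balance: total reaction current at the reference equals -I
    reaction = (K @ x - b)[dir_idx].sum()
    diag = {
        "method": info.method,
        "residual": info.residual,
        "injected_current_A": source.current,
        "reference_current_A": float(reaction),
        "current_balance": float(-reaction / source.current),
        "active_volume_m3": float(V_a),
    }
    return UnitPotential(
        ScalarField(mesh, x), source, diag,
        active_vertices=np.unique(mesh.tets[active_idx]),
        reference_vertices=np.asarray(dir_idx),
    )


def scale_potential(
    unit: UnitPotential, waveform: StimulusWaveform, amplitude: float, t: float
) -> ScalarField:
    """Instantaneous potential: amplitude · w(t) · unit field (no re-solve)."""
    w = float(waveform(t))
    return ScalarField(unit.mesh, amplitude * w * unit.values)


class _PointLocator:
    """Containing-tet lookup by KD-tree candidate search over centroids."""

    def __init__(self, mesh: LabeledTetMesh):
        self.mesh = mesh
        v0 = mesh.vertices[mesh.tets[:, 0]]
        T = np.stack([mesh.vertices[mesh.tets[:, i]] - v0 for i in (1, 2, 3)], axis=2)
        self.Tinv = np.linalg.inv(T)
        self.v0 = v0
        self.tree = cKDTree(mesh.vertices[mesh.tets].mean(axis=1))

    def locate(self, point: np.ndarray, tol: float = 1e-9) -> tuple[int, np.ndarray] | None:
        for k in (16, 128, 1024):
            k = min(k, self.mesh.n_tets)
            _, cand = self.tree.query(point, k=k)
            for t in np.atleast_1d(cand):
                lam123 = self.Tinv[t] @ (point - self.v0[t])
                lam = np.concatenate([[1.0 - lam123.sum()], lam123])
                if lam.min() >= -tol:
                    return int(t), lam
            if k == self.mesh.n_tets:
                break
        return None


def interpolate_at_points(
    unit: UnitPotential | ScalarField,
    points: np.ndarray,
    locator: _PointLocator | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Barycentric P1 interpolation of the field at arbitrary mesh points
    (e.g. the nodes of Ranvier).  Points must lie inside the mesh within a
    small snap tolerance."""
    field = unit.field if isinstance(unit, UnitPotential) else unit
    mesh = field.mesh
    locator = locator or _PointLocator(mesh)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    # snap tolerance in barycentric units relative to local tet size
    out = np.empty(len(points))
    for i, p in enumerate(points):
        hit = locator.locate(p, tol=max(tol, 1e-9))
        if hit is None:
            raise ValueError(f"point {p.tolist()} lies outside the mesh")
        t, lam = hit
        out[i] = lam @ field.values[mesh.tets[t]]
    return out
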