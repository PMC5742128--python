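"""Virtual electrodes, placement into the mesh, and stimulus waveforms.

Electrodes are spheres (or ordered sphere arrays) inserted by relabeling the
tetrahedra whose centroid falls inside the electrode shape; the original
labels are retained so electrodes can be deactivated (restored) exactly.
Electrically the relabeled region acts as the highly conductive source
volume over which the stimulus current is distributed.

The reference stimulus is a charge-balanced cathodic-first symmetric
biphasic pulse (default 200 μs phases, 30 μs interphase gap).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .mesh import LabeledTetMesh


class ElectrodePlacementError(ValueError):
    pass


@dataclass
class Electrode:
    """Spherical electrode or ordered sphere array (shared diameter)."""

    id: str
    centers: np.ndarray              # (k, 3) sphere centers, meters
    diameter: float
    role: str = "active"             # active | reference | inactive

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.diameter <= 0:
            raise ValueError("electrode diameter must be > 0")
        if self.role not in ("active", "reference", "inactive"):
            raise ValueError(f"unknown electrode role {self.role!r}")

    @property
    def region_label(self) -> str:
        return f"electrode_{self.id}"

    def analytic_volume(self) -> float:
        return len(self.centers) * (np.pi / 6.0) * self.diameter**3

    def contains(self, points: np.ndarray) -> np.ndarray:
        r = self.diameter / 2.0
        inside = np.zeros(len(points), dtype=bool)
        for c in self.centers:
            inside |= np.linalg.norm(points - c, axis=1) <= r
        return inside


def place_electrode(mesh: LabeledTetMesh, electrode: Electrode) -> LabeledTetMesh:
    """Relabel tets whose centroid lies inside the electrode shape.

    Mutates and returns ``mesh``.  The previous labels are stored so
    :func:`deactivate_electrode` restores them exactly.  Requires the local
    tet size (cube-root of 6×volume, i.e. the generating voxel edge for
    voxel-derived meshes) to be at most ⅓ of the electrode diameter.
    """
    if electrode.region_label in mesh.electrode_tets:
        raise ElectrodePlacementError(f"electrode {electrode.id!r} already placed")
    centroids = mesh.tet_centroids()
    captured = np.flatnonzero(electrode.contains(centroids))
    if len(captured) == 0:
        raise ElectrodePlacementError(
            f"electrode {electrode.id!r} captures no tetrahedra (outside the mesh?)"
        )
    vols = mesh.tet_volumes()[captured]
    local_size = float(np.max((6.0 * vols) ** (1.0 / 3.0)))
    if local_size > electrode.diameter / 3.0 * (1.0 + 1e-9):
        raise ElectrodePlacementError(
            f"local tet size {local_size:.3g} m exceeds a third of the electrode "
            f"diameter {electrode.diameter:.3g} m; refine the mesh near the electrode"
        )
    # overlap with an already placed electrode region: sharing even a single
    # vertex would short-circuit the two highly conductive regions in the
    # P1 discretization, so the check is vertex-based
    new_verts = np.unique(mesh.tets[captured])
    for lbl, idx in mesh.electrode_tets.items():
        if np.isin(new_verts, np.unique(mesh.tets[idx])).any():
            raise ElectrodePlacementError(
                f"electrode {electrode.id!r} touches existing region {lbl!r}; "
                "increase the electrode separation or refine the mesh"
            )
    if mesh.original_region_ids is None:
        mesh.original_region_ids = mesh.region_ids.copy()
    code = mesh.ensure_region_code(electrode.region_label)
    mesh.region_ids[captured] = code
    mesh.electrode_tets[electrode.region_label] = captured
    return mesh


def deactivate_electrode(mesh: LabeledTetMesh, electrode_id: str) -> LabeledTetMesh:
    """Restore the original per-tet labels of a placed electrode (exact
    involution; idempotent once restored)."""
    label = f"electrode_{electrode_id}" if not electrode_id.startswith("electrode_") else electrode_id
    if label not in mesh.electrode_tets:
        raise ElectrodePlacementError(f"electrode {electrode_id!r} was not placed")
    idx = mesh.electrode_tets.pop(label)
    assert mesh.original_region_ids is not None
    mesh.region_ids[idx] = mesh.original_region_ids[idx]
    return mesh


def placed_volume_ratio(mesh: LabeledTetMesh, electrode: Electrode) -> float:
    """Relabeled volume / analytic shape volume (≈1 on a well-refined mesh)."""
    idx = mesh.electrode_tets[electrode.region_label]
    return float(mesh.tet_volumes()[idx].sum() / electrode.analytic_volume())


# ----------------------------------------------------------------------
# standard configurations
# ----------------------------------------------------------------------

@dataclass
class StimulationFrame:
    """Local axis frame at a sensory epithelium.

    ``center``: epithelium/endolymph interface centroid; ``transverse``:
    axis of the distalmost nerve portion, pointing into the fluid;
    ``axial``: tangent of the semicircular canal.  The third direction is
    their cross product.
    """

    center: np.ndarray
    transverse: np.ndarray
    axial: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        t = np.asarray(self.transverse, dtype=float)
        a = np.asarray(self.axial, dtype=float)
        nt, na = np.linalg.norm(t), np.linalg.norm(a)
        if nt < 1e-12 or na < 1e-12:
            raise ValueError("degenerate (zero-length) frame axis")
        self.transverse = t / nt
        a = a / na
        a = a - np.dot(a, self.transverse) * self.transverse
        na = np.linalg.norm(a)
        if na < 1e-12:
            raise ValueError("axial axis parallel to transverse axis")
        self.axial = a / na

    @property
    def binormal(self) -> np.ndarray:
        return np.cross(self.transverse, self.axial)


@dataclass
class ElectrodeConfiguration:
    """One stimulation scenario: active electrode plus reference mechanism
    (a reference electrode for bipolar, the grounded outer saline surface
    for monopolar)."""

    name: str
    active: Electrode
    reference: Electrode | None = None     # None = outer saline surface

    def __post_init__(self) -> None:
        if self.reference is not None:
            gap = min(
                np.linalg.norm(a - r)
                for a in self.active.centers
                for r in self.reference.centers
            )
            if gap < (self.active.diameter + self.reference.diameter) / 2.0:
                raise ValueError(
                    f"active and reference electrodes of {self.name!r} overlap"
                )

    @property
    def electrodes(self) -> list[Electrode]:
        return [self.active] + ([self.reference] if self.reference else [])

    @property
    def is_monopolar(self) -> bool:
        return self.reference is None


def standard_configurations(
    frame: StimulationFrame,
    diameter: float = 200e-6,
    offset: float = 750e-6,
    separation: float = 1e-3,
) -> dict[str, ElectrodeConfiguration]:
    """The four canonical configurations at an ampullary nerve.

    All electrodes are spheres of ``diameter``; the monopolar electrode sits
    ``offset`` from the epithelium along the transverse axis (distant return
    at the grounded saline surface); the three dipoles (separation
    ``separation``, centered on the monopolar position) are oriented along
    the transverse, axial, and perpendicular directions:

    * ``monopolar``
    * ``transverse_parallel`` — active sphere closer to the epithelium
    * ``axial`` — along the canal tangent
    * ``transverse_perpendicular`` — along the remaining orthogonal axis
    """
    c = frame.center + offset * frame.transverse
    half = separation / 2.0

    def pair(name, direction, active_sign):
        a = Electrode(f"{name}_a", c + active_sign * half * direction, diameter, "active")
        r = Electrode(f"{name}_r", c - active_sign * half * direction, diameter, "reference")
        return ElectrodeConfiguration(name, a, r)

    return {
        "monopolar": ElectrodeConfiguration(
            "monopolar", Electrode("monopolar_a", c, diameter, "active"), None
        ),
        # active closer to the epithelium
        "transverse_parallel": pair("transverse_parallel", frame.transverse, -1),
        # active more distant from the vestibule along the canal tangent
        "axial": pair("axial", frame.axial, +1),
        "transverse_perpendicular": pair("transverse_perpendicular", frame.binormal, +1),
    }


# ----------------------------------------------------------------------
# stimulus waveforms
# ----------------------------------------------------------------------

@dataclass
class StimulusWaveform:
    """Piecewise-constant dimensionless waveform w(t); 0 outside support."""

    phases: list[tuple[float, float]]      # (duration s, relative amplitude)
    name: str = "waveform"

    def __post_init__(self) -> None:
        for dur, _ in self.phases:
            if dur <= 0:
                raise ValueError("phase durations must be > 0")

    @property
    def support(self) -> float:
        return float(sum(d for d, _ in self.phases))

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        t0 = 0.0
        for dur, amp in self.phases:
            out = np.where((t >= t0) & (t < t0 + dur), amp, out)
            t0 += dur
        return out if out.ndim else float(out)

    def integral(self) -> float:
        """∫ w dt — zero for charge-balanced waveforms."""
        return float(sum(d * a for d, a in self.phases))

    def abs_integral_by_sign(self) -> tuple[float, float]:
        """(∫|w⁻|dt, ∫|w⁺|dt): per-polarity absolute time integrals."""
        neg = sum(d * -a for d, a in self.phases if a < 0)
        pos = sum(d * a for d, a in self.phases if a > 0)
        return float(neg), float(pos)

    def squared_integral(self) -> float:
        return float(sum(d * a * a for d, a in self.phases))

    def to_csv(self, path) -> None:
        ts, ws = [0.0], [self.phases[0][1]]
        t0 = 0.0
        for dur, amp in self.phases:
            ts += [t0, t0 + dur]
            ws += [amp, amp]
            t0 += dur
        with open(path, "w") as fh:
            fh.write("t_s,w\n")
            for t, w in zip(ts[1:], ws[1:]):
                fh.write(f"{t:.9g},{w:.9g}\n")


def biphasic_waveform(
    phase_duration: float = 200e-6,
    interphase_gap: float = 30e-6,
    cathodic_first: bool = True,
) -> StimulusWaveform:
    """Charge-balanced symmetric biphasic pulse.

    Cathodic-first: phases [(T, −1), (gap, 0), (T, +1)].  The zero-amplitude
    gap phase is omitted when the gap is 0.
    """
    if phase_duration <= 0:
        raise ValueError("phase_duration must be > 0")
    if interphase_gap < 0:
        raise ValueError("interphase_gap must be >= 0")
    s = -1.0 if cathodic_first else 1.0
    phases = [(phase_duration, s)]
    if interphase_gap > 0:
        phases.append((interphase_gap, 0.0))
    phases.append((phase_duration, -s))
    return StimulusWaveform(phases, name="biphasic")
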