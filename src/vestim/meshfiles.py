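"""Mesh and field file I/O.

Labeled tet meshes are exchanged as ASCII VTK XML unstructured grids (.vtu)
with a cell-data integer array ``region`` and a JSON sidecar
``<file>.regions.json`` mapping region codes to names.  Labeled voxel
volumes are read from NIfTI files (integer label per voxel) via nibabel.

Only the subset of VTU needed for this workflow is implemented: ASCII
format, tetrahedral cells, Int/Float data arrays.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import LabeledTetMesh, MeshValidationError
from .units import parse_quantity

VTK_TET = 10


class MeshFormatError(ValueError):
    pass


def write_mesh(
    mesh: LabeledTetMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write an ASCII .vtu file plus a region-name sidecar.

    Optional extra point/cell data arrays (e.g. solved potentials ϕ or the
    orientation field F) are written alongside for visual inspection.
    """
    path = Path(path)
    n, m = mesh.n_vertices, mesh.n_tets

    def arr(a, fmt):
        return " ".join(fmt % x for x in np.asarray(a).reshape(-1))

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(mesh.vertices, "%.17g"),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(mesh.tets, "%d"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(np.arange(1, m + 1) * 4, "%d"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full(m, VTK_TET), "%d"),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
        '<DataArray type="Int32" Name="region" format="ascii">',
        arr(mesh.region_ids, "%d"),
        "</DataArray>",
    ]
    for name, data in (cell_data or {}).items():
        data = np.asarray(data)
        comps = 1 if data.ndim == 1 else data.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{comps}" format="ascii">',
            arr(data, "%.17g"),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    if point_data:
        lines.append("<PointData>")
        for name, data in point_data.items():
            data = np.asarray(data)
            comps = 1 if data.ndim == 1 else data.shape[1]
            lines += [
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{comps}" format="ascii">',
                arr(data, "%.17g"),
                "</DataArray>",
            ]
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))

    sidecar = path.with_suffix(path.suffix + ".regions.json")
    sidecar.write_text(json.dumps({str(i): name for i, name in enumerate(mesh.region_names)}))


def _read_vtu(path: Path, unit: str | float) -> LabeledTetMesh:
    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise MeshFormatError(f"{path}: no <Piece> element")

    def get_array(parent_tag, name=None, required=True):
        parent = piece.find(parent_tag)
        if parent is None:
            if required:
                raise MeshFormatError(f"{path}: missing <{parent_tag}>")
            return None
        for da in parent.findall("DataArray"):
            if name is None or da.get("Name") == name:
                if da.get("format", "ascii") != "ascii":
                    raise MeshFormatError(f"{path}: only ascii DataArrays supported")
                return np.fromstring(da.text or "", sep=" ")
        if required:
            raise MeshFormatError(f"{path}: missing DataArray {name!r} in <{parent_tag}>")
        return None

    pts = get_array("Points").reshape(-1, 3)
    conn = get_array("Cells", "connectivity").astype(np.int64)
    offsets = get_array("Cells", "offsets").astype(np.int64)
    types = get_array("Cells", "types").astype(np.int64)
    if not np.all(types == VTK_TET):
        raise MeshFormatError(
            f"{path}: unsupported cell types {sorted(set(types) - {VTK_TET})}; "
            "only tetrahedra (type 10) are supported"
        )
    if not np.all(np.diff(np.concatenate([[0], offsets])) == 4):
        raise MeshFormatError(f"{path}: non-tetrahedral connectivity offsets")
    tets = conn.reshape(-1, 4)
    region = get_array("CellData", "region", required=False)
    if region is None:
        raise MeshFormatError(f"{path}: missing cell-data label array 'region'")
    region_ids = region.astype(np.int32)

    sidecar = path.with_suffix(path.suffix + ".regions.json")
    if sidecar.exists():
        table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        table = {}
    ncodes = int(region_ids.max()) + 1 if len(region_ids) else 0
    names = [table.get(i, f"region_{i}") for i in range(ncodes)]

    scale = parse_quantity(1.0, unit) if isinstance(unit, str) else float(unit)
    mesh = LabeledTetMesh(pts * scale, tets, region_ids, names)
    mesh.orient_positive()
    return mesh


def read_mesh(
    path: str | Path,
    format: str | None = None,
    unit: str | float = "m",
    voxel_region_names: dict[int, str] | None = None,
) -> LabeledTetMesh:
    """Read a labeled tet mesh.

    ``format``: "vtu" (ASCII VTK XML unstructured grid) or "nifti" (integer
    label volume, converted through the Kuhn voxel subdivision).  Inferred
    from the suffix when None.  ``unit`` declares the length unit of the file
    ("m", "mm", "um", or a numeric scale to meters).

    The returned mesh is validated (positive volumes, conforming faces).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = "".join(path.suffixes).lower()
        if suffix.endswith(".vtu"):
            format = "vtu"
        elif suffix.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")
    if format == "vtu":
        mesh = _read_vtu(path, unit)
    elif format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        scale = parse_quantity(1.0, unit) if isinstance(unit, str) else float(unit)
        from .mesh import voxel_to_tetmesh

        mesh = voxel_to_tetmesh(labels, zooms * scale, region_names=voxel_region_names)
    else:
        raise MeshFormatError(f"unsupported mesh format {format!r}")
    try:
        mesh.validate()
    except MeshValidationError as exc:
        raise MeshValidationError(f"{path}: {exc}") from exc
    return mesh
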