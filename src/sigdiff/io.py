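"""Mesh and trajectory serialization.

Meshes are written as Gmsh MSH (ASCII v2.2) or VTK XML unstructured grids
(``.vtu``, ASCII).  Integer data round-trips bit-exactly and coordinates are
written with 17 significant digits so that read(write(m)) reproduces them to
full double precision.  Free-form mesh metadata (lattice cell types etc.)
is serialized to a ``<path>.meta.json`` sidecar, since neither format has a
standard slot for it.

Trajectories are exported as a VTU time series with a PVD index plus a CSV
of scalar summaries.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Mesh, MeshError

_FLOAT_FMT = "%.17g"


class UnknownFormatError(MeshError):
    """File extension does not correspond to a supported mesh format."""


class CorruptMeshError(MeshError):
    """The file exists but cannot be parsed as a complete mesh."""


# Gmsh element type codes
_GMSH_LINE, _GMSH_TRI, _GMSH_TET = 1, 2, 4
# VTK cell type codes
_VTK_LINE, _VTK_TRI, _VTK_TET = 3, 5, 10


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_mesh(mesh: Mesh, path) -> None:
    """Write a tagged mesh; the format is inferred from the extension."""
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtu":
        _write_vtu_mesh(mesh, path)
    else:
        raise UnknownFormatError(f"unsupported mesh extension {path.suffix!r}")
    if mesh.metadata:
        _meta_path(path).write_text(json.dumps(mesh.metadata, indent=1))


def read_mesh(path) -> Mesh:
    path = Path(path)
    if not path.exists():
        raise CorruptMeshError(f"no such mesh file: {path}")
    if path.suffix == ".msh":
        mesh = _read_msh(path)
    elif path.suffix == ".vtu":
        mesh = _read_vtu_mesh(path)
    else:
        raise UnknownFormatError(f"unsupported mesh extension {path.suffix!r}")
    mp = _meta_path(path)
    if mp.exists():
        mesh.metadata.update(json.loads(mp.read_text()))
    return mesh


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 (ASCII)
# ---------------------------------------------------------------------------


def _write_msh(mesh: Mesh, path: Path) -> None:
    nodes3 = np.zeros((mesh.n_nodes, 3))
    nodes3[:, : mesh.dim] = mesh.nodes
    ftype = _GMSH_LINE if mesh.dim == 2 else _GMSH_TRI
    etype = _GMSH_TRI if mesh.dim == 2 else _GMSH_TET
    region = (
        mesh.region_tags
        if mesh.region_tags is not None
        else np.zeros(mesh.n_elements, dtype=int)
    )
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(nodes3, start=1):
        lines.append(f"{i} {_FLOAT_FMT % p[0]} {_FLOAT_FMT % p[1]} {_FLOAT_FMT % p[2]}")
    lines += ["$EndNodes", "$Elements", str(mesh.boundary_facets.shape[0] + mesh.n_elements)]
    eid = 1
    for facet, tag in zip(mesh.boundary_facets, mesh.facet_tags):
        conn = " ".join(str(v + 1) for v in facet)
        lines.append(f"{eid} {ftype} 2 {int(tag)} {int(tag)} {conn}")
        eid += 1
    for elem, tag in zip(mesh.elements, region):
        conn = " ".join(str(v + 1) for v in elem)
        lines.append(f"{eid} {etype} 2 {int(tag)} {int(tag)} {conn}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> Mesh:
    try:
        text = path.read_text()
        lines = text.splitlines()
        if "$EndElements" not in text:
            raise CorruptMeshError(f"{path}: truncated MSH file (missing $EndElements)")
        i = lines.index("$Nodes")
        n_nodes = int(lines[i + 1])
        nodes3 = np.empty((n_nodes, 3))
        for k in range(n_nodes):
            parts = lines[i + 2 + k].split()
            nodes3[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        j = lines.index("$Elements")
        n_el = int(lines[j + 1])
        by_type: dict[int, list] = {}
        tags_by_type: dict[int, list] = {}
        for k in range(n_el):
            parts = lines[j + 2 + k].split()
            etype, ntags = int(parts[1]), int(parts[2])
            phys = int(parts[3]) if ntags >= 1 else 0
            conn = [int(v) - 1 for v in parts[3 + ntags:]]
            by_type.setdefault(etype, []).append(conn)
            tags_by_type.setdefault(etype, []).append(phys)
    except CorruptMeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - any parse failure is corruption
        raise CorruptMeshError(f"{path}: cannot parse MSH file ({exc})") from exc
    if _GMSH_TET in by_type:
        dim, etype, ftype = 3, _GMSH_TET, _GMSH_TRI
    elif _GMSH_TRI in by_type:
        dim, etype, ftype = 2, _GMSH_TRI, _GMSH_LINE
    else:
        raise CorruptMeshError(f"{path}: no volume elements found")
    elements = np.array(by_type[etype], dtype=int)
    region = np.array(tags_by_type[etype], dtype=int)
    facets = np.array(by_type.get(ftype, []), dtype=int).reshape(-1, dim)
    ftags = np.array(tags_by_type.get(ftype, []), dtype=int)
    return Mesh(
        nodes=nodes3[:, :dim],
        elements=elements,
        boundary_facets=facets,
        facet_tags=ftags,
        dim=dim,
        region_tags=region if np.any(region) else None,
    )


# ---------------------------------------------------------------------------
# VTK XML unstructured grid (ASCII)
# ---------------------------------------------------------------------------


def _data_array(name: str, values, dtype: str, ncomp: int | None = None) -> list[str]:
    comp = f' NumberOfComponents="{ncomp}"' if ncomp else ""
    out = [f'<DataArray type="{dtype}" Name="{name}"{comp} format="ascii">']
    arr = np.asarray(values)
    if arr.dtype.kind == "f":
        body = " ".join(_FLOAT_FMT % v for v in arr.ravel())
    else:
        body = " ".join(str(int(v)) for v in arr.ravel())
    out += [body, "</DataArray>"]
    return out


def _write_vtu(path: Path, points: np.ndarray, cells: list[tuple[np.ndarray, int]],
               cell_data: dict[str, np.ndarray] | None = None,
               point_data: dict[str, np.ndarray] | None = None) -> None:
    n_pts = points.shape[0]
    conn = np.concatenate([c.ravel() for c, _ in cells]) if cells else np.empty(0, int)
    sizes = np.concatenate([[c.shape[1]] * c.shape[0] for c, _ in cells])
    offsets = np.cumsum(sizes)
    types = np.concatenate([[t] * c.shape[0] for c, t in cells])
    n_cells = types.size
    pts3 = np.zeros((n_pts, 3))
    pts3[:, : points.shape[1]] = points
    out = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
    ]
    out += _data_array("Points", pts3, "Float64", 3)
    out += ["</Points>", "<Cells>"]
    out += _data_array("connectivity", conn, "Int64")
    out += _data_array("offsets", offsets, "Int64")
    out += _data_array("types", types, "UInt8")
    out += ["</Cells>"]
    if cell_data:
        out.append("<CellData>")
        for name, vals in cell_data.items():
            dtype = "Float64" if np.asarray(vals).dtype.kind == "f" else "Int64"
            out += _data_array(name, vals, dtype)
        out.append("</CellData>")
    if point_data:
        out.append("<PointData>")
        for name, vals in point_data.items():
            out += _data_array(name, np.asarray(vals, dtype=float), "Float64")
        out.append("</PointData>")
    out += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(out) + "\n")


def _write_vtu_mesh(mesh: Mesh, path: Path) -> None:
    ftype = _VTK_LINE if mesh.dim == 2 else _VTK_TRI
    etype = _VTK_TRI if mesh.dim == 2 else _VTK_TET
    region = (
        mesh.region_tags
        if mesh.region_tags is not None
        else np.zeros(mesh.n_elements, dtype=int)
    )
    tags = np.concatenate([mesh.facet_tags.astype(int), region.astype(int)])
    _write_vtu(
        path,
        mesh.nodes,
        [(mesh.boundary_facets, ftype), (mesh.elements, etype)],
        cell_data={"tag": tags},
    )


def _parse_vtu(path: Path):
    import xml.etree.ElementTree as ET

    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CorruptMeshError(f"{path}: malformed VTU XML ({exc})") from exc
    piece = tree.getroot().find(".//Piece")
    if piece is None:
        raise CorruptMeshError(f"{path}: no <Piece> in VTU file")

    def get(parent_tag, name, dtype):
        parent = piece.find(parent_tag)
        if parent is None:
            raise CorruptMeshError(f"{path}: missing <{parent_tag}>")
        for da in parent.iter("DataArray"):
            if da.get("Name") == name:
                text = da.text or ""
                return np.fromstring(text, sep=" ", dtype=dtype)
        raise CorruptMeshError(f"{path}: missing DataArray {name!r}")

    points = get("Points", "Points", float).reshape(-1, 3)
    conn = get("Cells", "connectivity", int)
    offsets = get("Cells", "offsets", int)
    types = get("Cells", "types", int)
    cell_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.iter("DataArray"):
            kind = float if da.get("type", "").startswith("Float") else int
            cell_data[da.get("Name")] = np.fromstring(da.text or "", sep=" ", dtype=kind)
    return points, conn, offsets, types, cell_data


def _read_vtu_mesh(path: Path) -> Mesh:
    points, conn, offsets, types, cell_data = _parse_vtu(path)
    starts = np.concatenate([[0], offsets[:-1]])
    cells_by_type: dict[int, list] = {}
    idx_by_type: dict[int, list] = {}
    for i, (s, o, t) in enumerate(zip(starts, offsets, types)):
        cells_by_type.setdefault(int(t), []).append(conn[s:o])
        idx_by_type.setdefault(int(t), []).append(i)
    if _VTK_TET in cells_by_type:
        dim, etype, ftype = 3, _VTK_TET, _VTK_TRI
    elif _VTK_TRI in cells_by_type:
        dim, etype, ftype = 2, _VTK_TRI, _VTK_LINE
    else:
        raise CorruptMeshError(f"{path}: no volume cells found")
    elements = np.array(cells_by_type[etype], dtype=int)
    facets = np.array(cells_by_type.get(ftype, []), dtype=int).reshape(-1, dim)
    tags_all = cell_data.get("tag")
    if tags_all is None or tags_all.size != types.size:
        raise CorruptMeshError(f"{path}: missing or inconsistent 'tag' cell data")
    ftags = tags_all[idx_by_type.get(ftype, [])].astype(int)
    rtags = tags_all[idx_by_type[etype]].astype(int)
    return Mesh(
        nodes=points[:, :dim],
        elements=elements,
        boundary_facets=facets,
        facet_tags=ftags,
        dim=dim,
        region_tags=rtags if np.any(rtags) else None,
    )


# ---------------------------------------------------------------------------
# Trajectory export
# ---------------------------------------------------------------------------


def write_trajectory_vtu(trajectory, outdir, basename: str = "state") -> Path:
    """VTU file per output time plus a PVD index; returns the PVD path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = trajectory.model.mesh
    etype = _VTK_TRI if mesh.dim == 2 else _VTK_TET
    entries = []
    for i, state in enumerate(trajectory.states):
        fname = f"{basename}_{i:04d}.vtu"
        _write_vtu(
            outdir / fname,
            mesh.nodes,
            [(mesh.elements, etype)],
            point_data={name: vals for name, vals in state.fields.items()},
        )
        entries.append((state.t, fname))
    pvd = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1" byte_order="LittleEndian">',
        "<Collection>",
    ]
    for t, fname in entries:
        pvd.append(f'<DataSet timestep="{_FLOAT_FMT % t}" part="0" file="{fname}"/>')
    pvd += ["</Collection>", "</VTKFile>"]
    pvd_path = outdir / f"{basename}.pvd"
    pvd_path.write_text("\n".join(pvd) + "\n")
    return pvd_path
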