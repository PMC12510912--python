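"""Artifact I/O: mesh export (Gmsh MSH 4.1, VTU), HDF5 field archives.

All formats are plain text except HDF5.  Boundary markers are written as
cell data named ``boundary_marker`` (1 = pial, 2 = ventricle) in VTU, and as
physical groups of the same names in MSH.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .fem import Field, Mesh, FESpace, build_space, MARKER_NAMES


# ---------------------------------------------------------------------------
# VTU (ASCII XML)
# ---------------------------------------------------------------------------

def write_vtu(path: str | Path, mesh: Mesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Unstructured-grid VTU with triangles + marked boundary lines.

    Boundary facets are appended as VTK_LINE cells after the triangles; the
    ``boundary_marker`` cell array is 0 on triangles and the marker value on
    facet lines.  ``point_data`` arrays must have one value per mesh node.
    """
    nodes, cells, facets = mesh.nodes, mesh.cells, mesh.facets
    n_tri, n_line = len(cells), len(facets)
    n_cells = n_tri + n_line

    def arr(a, fmt="{:.10g}"):
        return " ".join(fmt.format(v) for v in np.asarray(a).ravel())

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(np.column_stack([nodes, np.zeros(len(nodes))])),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(cells, "{:d}") + " " + arr(facets, "{:d}"),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(np.concatenate([3 * np.arange(1, n_tri + 1),
                            3 * n_tri + 2 * np.arange(1, n_line + 1)]), "{:d}"),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.concatenate([np.full(n_tri, 5), np.full(n_line, 3)]), "{:d}"),
        "</DataArray>", "</Cells>",
    ]
    cd = {"boundary_marker": np.concatenate([
        np.zeros(n_tri, dtype=int), mesh.facet_markers])}
    if cell_data:
        for k, v in cell_data.items():
            v = np.asarray(v)
            if len(v) == n_tri:
                v = np.concatenate([v, np.zeros(n_line, dtype=v.dtype)])
            cd[k] = v
    lines.append("<CellData>")
    for k, v in cd.items():
        typ = "Int64" if np.issubdtype(v.dtype, np.integer) else "Float64"
        fmt = "{:d}" if typ == "Int64" else "{:.10g}"
        lines += [f'<DataArray type="{typ}" Name="{k}" format="ascii">',
                  arr(v, fmt), "</DataArray>"]
    lines.append("</CellData>")
    if point_data:
        lines.append("<PointData>")
        for k, v in point_data.items():
            lines += [f'<DataArray type="Float64" Name="{k}" format="ascii">',
                      arr(v), "</DataArray>"]
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def field_point_data(field: Field) -> dict[str, np.ndarray]:
    """Vertex values of each component (P2 fields evaluated at vertices)."""
    n_nodes = field.space.mesh.n_nodes
    return {name: field.component(f)[:n_nodes]
            for f, name in enumerate(field.field_names)}


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII)
# ---------------------------------------------------------------------------

def write_msh41(path: str | Path, mesh: Mesh) -> None:
    """Minimal Gmsh MSH 4.1 export with pial/ventricle physical curves.

    One surface entity holds all nodes and triangles; each marker gets a
    curve entity + physical group of the same name.
    """
    markers = sorted(set(mesh.facet_markers.tolist()))
    out = [
        "$MeshFormat", "4.1 0 8", "$EndMeshFormat",
        "$PhysicalNames", str(len(markers) + 1),
    ]
    for m in markers:
        out.append(f'1 {m} "{MARKER_NAMES[m]}"')
    out.append('2 10 "parenchyma"')
    out.append("$EndPhysicalNames")
    # entities: len(markers) curves, 1 surface
    out += ["$Entities", f"0 {len(markers)} 1 0"]
    for m in markers:
        out.append(f"{m} 0 0 0 0 0 0 1 {m} 0")
    out.append("10 0 0 0 0 0 0 1 10 0")
    out.append("$EndEntities")
    n = mesh.n_nodes
    out += ["$Nodes", f"1 {n} 1 {n}", f"2 10 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [f"{x:.10g} {y:.10g} 0" for x, y in mesh.nodes]
    out.append("$EndNodes")
    n_elem = mesh.n_cells + len(mesh.facets)
    out += ["$Elements", f"{len(markers) + 1} {n_elem} 1 {n_elem}"]
    eid = 1
    for m in markers:
        sel = np.flatnonzero(mesh.facet_markers == m)
        out.append(f"1 {m} 1 {len(sel)}")
        for f in mesh.facets[sel]:
            out.append(f"{eid} {f[0] + 1} {f[1] + 1}")
            eid += 1
    out.append(f"2 10 2 {mesh.n_cells}")
    for c in mesh.cells:
        out.append(f"{eid} {c[0] + 1} {c[1] + 1} {c[2] + 1}")
        eid += 1
    out.append("$EndElements")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# HDF5 archives
# ---------------------------------------------------------------------------

def _write_mesh_group(g: h5py.Group, mesh: Mesh) -> None:
    g.create_dataset("nodes", data=mesh.nodes)
    g.create_dataset("cells", data=mesh.cells)
    g.create_dataset("facets", data=mesh.facets)
    g.create_dataset("facet_markers", data=mesh.facet_markers)
    g.attrs["hash"] = mesh.content_hash()


def _read_mesh_group(g: h5py.Group) -> Mesh:
    return Mesh(g["nodes"][()], g["cells"][()], g["facets"][()],
                g["facet_markers"][()])


def save_field_h5(path: str | Path, field: Field,
                  attrs: dict | None = None) -> None:
    """Archive a solution: coefficients + space metadata + the mesh itself."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs", data=field.coeffs)
        f.attrs["order"] = field.space.order
        f.attrs["n_fields"] = field.space.n_fields
        f.attrs["field_names"] = ",".join(field.field_names)
        _write_mesh_group(f.create_group("mesh"), field.space.mesh)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_field_h5(path: str | Path) -> Field:
    with h5py.File(path, "r") as f:
        mesh = _read_mesh_group(f["mesh"])
        space = build_space(mesh, int(f.attrs["order"]), int(f.attrs["n_fields"]))
        names = tuple(str(f.attrs["field_names"]).split(","))
        return Field(space, f["coeffs"][()], field_names=names)


def save_snapshots_h5(path: str | Path, X: np.ndarray, source_ids,
                      space: FESpace, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=X)
        f.create_dataset("source_ids",
                         data=np.array(list(source_ids), dtype="S64"))
        f.attrs["order"] = space.order
        f.attrs["n_fields"] = space.n_fields
        f.attrs["field_names"] = ""
        _write_mesh_group(f.create_group("mesh"), space.mesh)
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_snapshots_h5(path: str | Path):
    """Returns (X, source_ids, space, attrs)."""
    with h5py.File(path, "r") as f:
        X = f["X"][()]
        ids = tuple(s.decode() for s in f["source_ids"][()])
        mesh = _read_mesh_group(f["mesh"])
        space = build_space(mesh, int(f.attrs["order"]), int(f.attrs["n_fields"]))
        attrs = {k: f.attrs[k] for k in f.attrs}
        return X, ids, space, attrs
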