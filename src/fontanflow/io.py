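"""Mesh and field I/O: Gmsh MSH 4.1 (ASCII) and VTK XML (VTU, ASCII).

Boundary tags travel as Gmsh physical surface groups, or as a ``tag_id``
cell-data array plus a ``boundary_tag_names`` field-data string array in
VTU.  Round-trips preserve nodes, connectivity and tags bit-exactly.
Node indexing is 0-based internally and converted to the 1-based
convention only at the Gmsh format boundary.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import Mesh, MeshError


def write_mesh(mesh: Mesh, path) -> None:
    path = Path(path)
    if path.suffix == ".msh":
        _write_msh(mesh, path)
    elif path.suffix == ".vtu":
        _write_vtu_mesh(mesh, path)
    else:
        raise MeshError(f"unknown mesh format {path.suffix!r} "
                        "(supported: .msh, .vtu)")


def read_mesh(path, tag_map: dict | None = None) -> Mesh:
    """Read a mesh; ``tag_map`` renames foreign boundary tags."""
    path = Path(path)
    if path.suffix == ".msh":
        mesh = _read_msh(path)
    elif path.suffix == ".vtu":
        mesh = _read_vtu_mesh(path)
    else:
        raise MeshError(f"unknown mesh format {path.suffix!r} "
                        "(supported: .msh, .vtu)")
    if tag_map is not None:
        mesh = mesh.retag(tag_map)
    mesh.validate()
    return mesh


# ----------------------------------------------------------------------
# Gmsh MSH 4.1
# ----------------------------------------------------------------------

def _write_msh(mesh: Mesh, path: Path) -> None:
    tags = mesh.tags
    tag_ids = {t: i + 1 for i, t in enumerate(tags)}
    vol_id = len(tags) + 1
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(tags) + 1)]
    for t, i in tag_ids.items():
        lines.append(f'2 {i} "{t}"')
    lines.append(f'3 {vol_id} "fluid"')
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bb = f"{lo[0]} {lo[1]} {lo[2]} {hi[0]} {hi[1]} {hi[2]}"
    lines += ["$Entities", f"0 0 {len(tags)} 1"]
    for t, i in tag_ids.items():
        lines.append(f"{i} {bb} 1 {i} 0")
    lines.append(f"1 {bb} 1 {vol_id} 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes]
    lines.append("$EndNodes")

    n_el = len(mesh.boundary_faces) + mesh.n_tets
    blocks = []
    eid = 1
    for t, i in tag_ids.items():
        fidx = mesh.faces_of(t)
        blocks.append(f"2 {i} 2 {len(fidx)}")
        for f in mesh.boundary_faces[fidx]:
            blocks.append(f"{eid} {f[0]+1} {f[1]+1} {f[2]+1}")
            eid += 1
    blocks.append(f"3 1 4 {mesh.n_tets}")
    for tt in mesh.tets:
        blocks.append(f"{eid} {tt[0]+1} {tt[1]+1} {tt[2]+1} {tt[3]+1}")
        eid += 1
    lines += ["$Elements", f"{len(tags) + 1} {n_el} 1 {n_el}"]
    lines += blocks
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> Mesh:
    text = Path(path).read_text().splitlines()

    def section(name):
        try:
            a = text.index(f"${name}") + 1
            b = text.index(f"$End{name}")
        except ValueError:
            raise MeshError(f"missing ${name} section in {path}")
        return text[a:b]

    fmt = section("MeshFormat")[0].split()
    if not fmt[0].startswith("4"):
        raise MeshError(f"unsupported MSH version {fmt[0]} (need 4.x ASCII)")

    phys = {}
    try:
        ph = section("PhysicalNames")
    except MeshError:
        ph = None
    if ph:
        for line in ph[1:]:
            parts = line.split(maxsplit=2)
            phys[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')

    # entity -> physical id map for surfaces
    ent = section("Entities")
    counts = list(map(int, ent[0].split()))
    surf2phys = {}
    row = 1 + counts[0] + counts[1]
    for k in range(counts[2]):
        parts = ent[row + k].split()
        sid = int(parts[0])
        nphys = int(parts[7])
        if nphys >= 1:
            surf2phys[sid] = int(parts[8])

    nod = section("Nodes")
    header = list(map(int, nod[0].split()))
    n_nodes = header[1]
    coords = np.empty((n_nodes, 3))
    idmap = {}
    row = 1
    filled = 0
    while filled < n_nodes:
        blk = list(map(int, nod[row].split()))
        m = blk[3]
        ids = [int(nod[row + 1 + j]) for j in range(m)]
        for j in range(m):
            xyz = list(map(float, nod[row + 1 + m + j].split()))
            idmap[ids[j]] = filled + j
            coords[filled + j] = xyz
        filled += m
        row += 1 + 2 * m

    elems = section("Elements")
    tris, tri_tags, tets = [], [], []
    row = 1
    n_blocks = int(elems[0].split()[0])
    for _ in range(n_blocks):
        dim, etag, etype, m = map(int, elems[row].split())
        for j in range(1, m + 1):
            parts = list(map(int, elems[row + j].split()))
            nn = [idmap[q] for q in parts[1:]]
            if etype == 2:
                tris.append(nn)
                pid = surf2phys.get(etag)
                name = phys.get((2, pid), f"surface_{etag}") if pid else \
                    f"surface_{etag}"
                tri_tags.append(name)
            elif etype == 4:
                tets.append(nn)
        row += m + 1
    if not tets:
        raise MeshError(f"no tetrahedra in {path}")
    mesh = Mesh(coords, np.array(tets), np.array(tris, dtype=int),
                np.array(tri_tags))
    _check_boundary_cover(mesh)
    return mesh


def _check_boundary_cover(mesh: Mesh) -> None:
    bfaces, _ = mesh.extract_boundary()
    have = {tuple(sorted(f)) for f in mesh.boundary_faces.tolist()}
    missing = [f for f in bfaces.tolist() if tuple(sorted(f)) not in have]
    if missing:
        raise MeshError(
            f"{len(missing)} boundary faces carry no tag (e.g. "
            f"{missing[:3]}); supply a fully tagged surface")
    # adopt outward-oriented topological faces in stored order
    order = {tuple(sorted(f)): f for f in bfaces.tolist()}
    mesh.boundary_faces = np.array(
        [order[tuple(sorted(f))] for f in mesh.boundary_faces.tolist()])


# ----------------------------------------------------------------------
# VTU
# ----------------------------------------------------------------------

def _da(parent, name, data, dtype, ncomp=None):
    el = ET.SubElement(parent, "DataArray",
                       {"type": dtype, "Name": name, "format": "ascii"})
    if ncomp:
        el.set("NumberOfComponents", str(ncomp))
    arr = np.asarray(data)
    if arr.dtype.kind == "f":
        el.text = " ".join(f"{v:.17g}" for v in arr.ravel())
    else:
        el.text = " ".join(str(int(v)) for v in arr.ravel())
    return el


def _vtu_skeleton(mesh: Mesh, include_boundary: bool):
    root = ET.Element("VTKFile", {"type": "UnstructuredGrid",
                                  "version": "1.0",
                                  "byte_order": "LittleEndian"})
    grid = ET.SubElement(root, "UnstructuredGrid")
    ncell = mesh.n_tets + (len(mesh.boundary_faces) if include_boundary
                           else 0)
    piece = ET.SubElement(grid, "Piece",
                          {"NumberOfPoints": str(mesh.n_nodes),
                           "NumberOfCells": str(ncell)})
    pts = ET.SubElement(piece, "Points")
    _da(pts, "Points", mesh.nodes, "Float64", 3)
    cells = ET.SubElement(piece, "Cells")
    conn = [mesh.tets.ravel()]
    offs = [4 * np.arange(1, mesh.n_tets + 1)]
    types = [np.full(mesh.n_tets, 10)]
    if include_boundary:
        conn.append(mesh.boundary_faces.ravel())
        offs.append(4 * mesh.n_tets
                    + 3 * np.arange(1, len(mesh.boundary_faces) + 1))
        types.append(np.full(len(mesh.boundary_faces), 5))
    _da(cells, "connectivity", np.concatenate(conn), "Int64")
    _da(cells, "offsets", np.concatenate(offs), "Int64")
    _da(cells, "types", np.concatenate(types), "UInt8")
    return root, grid, piece


def _write_vtu_mesh(mesh: Mesh, path: Path) -> None:
    tags = mesh.tags
    tag_ids = {t: i for i, t in enumerate(tags)}
    root, grid, piece = _vtu_skeleton(mesh, include_boundary=True)
    fd = ET.SubElement(grid, "FieldData")
    el = ET.SubElement(fd, "DataArray",
                       {"type": "String", "Name": "boundary_tag_names",
                        "NumberOfTuples": str(len(tags)),
                        "format": "ascii"})
    el.text = " ".join(tags)
    cd = ET.SubElement(piece, "CellData")
    ids = np.concatenate([np.full(mesh.n_tets, -1),
                          [tag_ids[t] for t in mesh.face_tags]])
    _da(cd, "tag_id", ids, "Int32")
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtu_mesh(path: Path) -> Mesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshError(f"no <Piece> in {path}")

    def arr(xpath, dtype=float):
        el = piece.find(xpath)
        if el is None or el.text is None:
            raise MeshError(f"missing array {xpath} in {path}")
        return np.fromstring(el.text, sep=" ", dtype=dtype)

    pts = arr("Points/DataArray").reshape(-1, 3)
    conn = arr("Cells/DataArray[@Name='connectivity']", dtype=float
               ).astype(int)
    offsets = arr("Cells/DataArray[@Name='offsets']", dtype=float
                  ).astype(int)
    types = arr("Cells/DataArray[@Name='types']", dtype=float).astype(int)
    tag_el = root.find(".//FieldData/DataArray[@Name='boundary_tag_names']")
    names = tag_el.text.split() if tag_el is not None and tag_el.text \
        else []
    tag_id_el = piece.find("CellData/DataArray[@Name='tag_id']")
    if tag_id_el is None:
        raise MeshError(f"{path} carries no boundary tag data")
    tag_ids = np.fromstring(tag_id_el.text, sep=" ", dtype=float
                            ).astype(int)
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tris, tri_tags = [], [], []
    for ctype, s, e, tid in zip(types, starts, offsets, tag_ids):
        if ctype == 10:
            tets.append(conn[s:e])
        elif ctype == 5:
            tris.append(conn[s:e])
            if tid < 0 or tid >= len(names):
                raise MeshError(f"untagged boundary face in {path}")
            tri_tags.append(names[tid])
    mesh = Mesh(pts, np.array(tets), np.array(tris, dtype=int),
                np.array(tri_tags))
    _check_boundary_cover(mesh)
    return mesh


# ----------------------------------------------------------------------
# field snapshots
# ----------------------------------------------------------------------

def write_vtu_snapshot(mesh: Mesh, path, point_data: dict) -> None:
    """One VTU file with nodal fields (e.g. velocity, pressure, dye)."""
    root, grid, piece = _vtu_skeleton(mesh, include_boundary=False)
    pd = ET.SubElement(piece, "PointData")
    for name, data in point_data.items():
        data = np.asarray(data)
        ncomp = data.shape[1] if data.ndim == 2 else None
        _da(pd, name, data, "Float64", ncomp)
    ET.ElementTree(root).write(Path(path), xml_declaration=True)


def write_vtu_series(mesh: Mesh, directory, basename: str,
                     times, fields_at) -> Path:
    """VTU time series plus a PVD collection file.

    ``fields_at(i)`` returns the point-data dict of snapshot i.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, t in enumerate(times):
        fname = f"{basename}_{i:04d}.vtu"
        write_vtu_snapshot(mesh, directory / fname, fields_at(i))
        entries.append((t, fname))
    pvd = ET.Element("VTKFile", {"type": "Collection", "version": "1.0"})
    coll = ET.SubElement(pvd, "Collection")
    for t, fname in entries:
        ET.SubElement(coll, "DataSet", {"timestep": f"{t:.6g}",
                                        "group": "", "part": "0",
                                        "file": fname})
    out = directory / f"{basename}.pvd"
    ET.ElementTree(pvd).write(out, xml_declaration=True)
    return out
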