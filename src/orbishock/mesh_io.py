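"""Mesh exchange in Gmsh MSH 4.1 ASCII and legacy VTK ASCII.

Both writers carry the full :class:`~orbishock.geometry.ShellMesh` payload:
per-element ``thickness`` (mm) and ``region`` (integer code into
:data:`~orbishock.geometry.REGIONS`), and per-node sets ``fixed``,
``load`` (order-preserving: value k marks the k-th strike node) and
``probe_A``.  ``read_mesh(write_mesh(m))`` reproduces the mesh up to
floating-point text round-trip.

The VTK files are plain ``DATASET UNSTRUCTURED_GRID`` with CELL_DATA /
POINT_DATA scalars and open in any standard VTK viewer; transient results
are exported as one file per snapshot plus a ``.series`` index.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

import numpy as np

from .geometry import REGIONS, ShellMesh
from .dynamics import DisplacementHistory


class MeshIOError(ValueError):
    """Raised for malformed mesh files or missing required data fields."""


_REGION_CODE = {name: i for i, name in enumerate(REGIONS)}


def write_mesh(mesh: ShellMesh, path: str) -> None:
    """Write a mesh as `.msh` (Gmsh 4.1 ASCII) or `.vtk` (legacy ASCII),
    chosen by extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".msh":
        _write_msh(mesh, path)
    elif ext == ".vtk":
        _write_vtk(mesh, path)
    else:
        raise MeshIOError(f"unsupported mesh extension {ext!r} (use .msh or .vtk)")


def read_mesh(path: str) -> ShellMesh:
    """Read a mesh written by :func:`write_mesh` (format by extension)."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".msh":
        return _read_msh(path)
    if ext == ".vtk":
        return _read_vtk(path)
    raise MeshIOError(f"unsupported mesh extension {ext!r} (use .msh or .vtk)")


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 ASCII


def _write_msh(mesh: ShellMesh, path: str) -> None:
    n_nodes, n_elem = mesh.num_nodes, mesh.num_elements
    lines: list[str] = []
    lines += ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    # one 2D discrete entity holds the whole surface
    lines += ["$Entities", "0 0 1 0", "1 0 0 0 0 0 0 0 0", "$EndEntities"]
    lines += ["$Nodes", f"1 {n_nodes} 1 {n_nodes}", f"2 1 0 {n_nodes}"]
    lines += [str(i + 1) for i in range(n_nodes)]
    lines += [
        f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes
    ]
    lines += ["$EndNodes"]
    lines += ["$Elements", f"1 {n_elem} 1 {n_elem}", f"2 1 2 {n_elem}"]
    lines += [
        f"{e + 1} {t[0] + 1} {t[1] + 1} {t[2] + 1}"
        for e, t in enumerate(mesh.triangles)
    ]
    lines += ["$EndElements"]
    lines += _msh_element_data("thickness", mesh.thickness)
    lines += _msh_element_data(
        "region", np.array([_REGION_CODE[r] for r in mesh.region], dtype=float)
    )
    lines += _msh_node_data("fixed", _indicator(mesh.fixed_nodes, n_nodes))
    lines += _msh_node_data("load", _load_order(mesh.load_nodes, n_nodes))
    lines += _msh_node_data("probe_A", _indicator([mesh.probe_A], n_nodes))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _msh_element_data(name: str, values: np.ndarray) -> list[str]:
    lines = ["$ElementData", "1", f'"{name}"', "1", "0.0", "3", "0", "1", str(len(values))]
    lines += [f"{i + 1} {v:.17g}" for i, v in enumerate(values)]
    lines += ["$EndElementData"]
    return lines


def _msh_node_data(name: str, values: np.ndarray) -> list[str]:
    lines = ["$NodeData", "1", f'"{name}"', "1", "0.0", "3", "0", "1", str(len(values))]
    lines += [f"{i + 1} {v:.17g}" for i, v in enumerate(values)]
    lines += ["$EndNodeData"]
    return lines


def _read_msh(path: str) -> ShellMesh:
    with open(path) as fh:
        text = fh.read()
    sections = _msh_sections(text)
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshIOError("MSH file lacks $Nodes or $Elements")

    node_lines = sections["Nodes"]
    num_blocks, n_nodes = int(node_lines[0].split()[0]), int(node_lines[0].split()[1])
    coords = np.zeros((n_nodes, 3))
    row = 1
    for _ in range(num_blocks):
        _, _, _, blk_n = (int(v) for v in node_lines[row].split())
        row += 1
        tags = [int(node_lines[row + i]) for i in range(blk_n)]
        row += blk_n
        for i in range(blk_n):
            coords[tags[i] - 1] = [float(v) for v in node_lines[row + i].split()]
        row += blk_n

    elem_lines = sections["Elements"]
    num_blocks, n_elem = int(elem_lines[0].split()[0]), int(elem_lines[0].split()[1])
    tris = np.zeros((n_elem, 3), dtype=np.int64)
    row = 1
    for _ in range(num_blocks):
        _, _, etype, blk_n = (int(v) for v in elem_lines[row].split())
        if etype != 2:
            raise MeshIOError(f"unsupported MSH element type {etype} (triangles only)")
        row += 1
        for i in range(blk_n):
            parts = [int(v) for v in elem_lines[row + i].split()]
            tris[parts[0] - 1] = [p - 1 for p in parts[1:4]]
        row += blk_n

    edata = {}
    for name, vals in _msh_data_blocks(sections.get("ElementData", []), "ElementData"):
        edata[name] = vals
    ndata = {}
    for name, vals in _msh_data_blocks(sections.get("NodeData", []), "NodeData"):
        ndata[name] = vals
    return _mesh_from_payload(coords, tris, edata, ndata)


def _msh_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            body: list[str] = []
            i += 1
            while i < len(lines) and lines[i].strip() != f"$End{name}":
                body.append(lines[i].strip())
                i += 1
            if name in ("ElementData", "NodeData"):
                sections.setdefault(name, []).append(body)  # type: ignore[arg-type]
            else:
                sections[name] = body
        i += 1
    return sections


def _msh_data_blocks(blocks: Iterable[list[str]], kind: str):
    for body in blocks:
        n_str_tags = int(body[0])
        name = body[1].strip('"')
        rest = body[1 + n_str_tags :]
        n_real = int(rest[0])
        rest = rest[1 + n_real :]
        n_int = int(rest[0])
        n_entries = int(rest[n_int])
        data_lines = rest[n_int + 1 : n_int + 1 + n_entries]
        vals = np.zeros(n_entries)
        for ln in data_lines:
            tag, val = ln.split()
            vals[int(tag) - 1] = float(val)
        yield name, vals


# ---------------------------------------------------------------------------
# legacy VTK ASCII


def _write_vtk(mesh: ShellMesh, path: str) -> None:
    n_nodes, n_elem = mesh.num_nodes, mesh.num_elements
    out: list[str] = [
        "# vtk DataFile Version 3.0",
        "orbital shell mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_nodes} double",
    ]
    out += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes]
    out += [f"CELLS {n_elem} {4 * n_elem}"]
    out += [f"3 {t[0]} {t[1]} {t[2]}" for t in mesh.triangles]
    out += [f"CELL_TYPES {n_elem}"] + ["5"] * n_elem
    out += [f"CELL_DATA {n_elem}"]
    out += _vtk_scalars("thickness", mesh.thickness, "double")
    out += _vtk_scalars(
        "region", [_REGION_CODE[r] for r in mesh.region], "int"
    )
    out += [f"POINT_DATA {n_nodes}"]
    out += _vtk_scalars("fixed", _indicator(mesh.fixed_nodes, n_nodes).astype(int), "int")
    out += _vtk_scalars("load", _load_order(mesh.load_nodes, n_nodes).astype(int), "int")
    out += _vtk_scalars("probe_A", _indicator([mesh.probe_A], n_nodes).astype(int), "int")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def _vtk_scalars(name: str, values, vtype: str) -> list[str]:
    fmt = (lambda v: f"{v:.17g}") if vtype == "double" else (lambda v: str(int(v)))
    return [f"SCALARS {name} {vtype} 1", "LOOKUP_TABLE default"] + [
        fmt(v) for v in values
    ]


def _read_vtk(path: str) -> ShellMesh:
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    # token stream after the 4-line header
    body = tokens_lines[4:]
    i = 0

    def expect(keyword: str) -> list[str]:
        nonlocal i
        while i < len(body) and not body[i].strip():
            i += 1
        if i >= len(body) or not body[i].split() or body[i].split()[0] != keyword:
            raise MeshIOError(f"expected {keyword} in VTK file")
        parts = body[i].split()
        i += 1
        return parts

    parts = expect("POINTS")
    n_nodes = int(parts[1])
    flat: list[float] = []
    while len(flat) < 3 * n_nodes:
        flat += [float(v) for v in body[i].split()]
        i += 1
    coords = np.array(flat).reshape(n_nodes, 3)

    parts = expect("CELLS")
    n_elem = int(parts[1])
    tris = np.zeros((n_elem, 3), dtype=np.int64)
    for e in range(n_elem):
        vals = [int(v) for v in body[i].split()]
        if vals[0] != 3:
            raise MeshIOError("VTK cell is not a triangle")
        tris[e] = vals[1:4]
        i += 1
    expect("CELL_TYPES")
    i += n_elem  # skip type codes (validated implicitly above)

    edata: dict[str, np.ndarray] = {}
    ndata: dict[str, np.ndarray] = {}
    target = None
    count = 0
    while i < len(body):
        line = body[i].strip()
        i += 1
        if not line:
            continue
        parts = line.split()
        if parts[0] == "CELL_DATA":
            target, count = edata, n_elem
        elif parts[0] == "POINT_DATA":
            target, count = ndata, n_nodes
        elif parts[0] == "SCALARS":
            name = parts[1]
            i += 1  # LOOKUP_TABLE line
            vals: list[float] = []
            while len(vals) < count:
                vals += [float(v) for v in body[i].split()]
                i += 1
            if target is None:
                raise MeshIOError("SCALARS outside CELL_DATA/POINT_DATA")
            target[name] = np.array(vals)
    return _mesh_from_payload(coords, tris, edata, ndata)


# ---------------------------------------------------------------------------
# shared payload assembly


def _indicator(nodes, n: int) -> np.ndarray:
    v = np.zeros(n)
    for node in nodes:
        if int(node) >= 0:
            v[int(node)] = 1.0
    return v


def _load_order(load_nodes, n: int) -> np.ndarray:
    v = np.zeros(n)
    for k, node in enumerate(load_nodes):
        v[int(node)] = k + 1
    return v


def _mesh_from_payload(coords, tris, edata, ndata) -> ShellMesh:
    for req in ("thickness", "region"):
        if req not in edata:
            raise MeshIOError(f"mesh file lacks required element field {req!r}")
    for req in ("fixed", "load", "probe_A"):
        if req not in ndata:
            raise MeshIOError(f"mesh file lacks required node field {req!r}")
    codes = np.rint(edata["region"]).astype(int)
    if codes.min() < 0 or codes.max() >= len(REGIONS):
        raise MeshIOError("region codes out of range")
    region = np.array(REGIONS, dtype="<U16")[codes]
    fixed = np.flatnonzero(ndata["fixed"] > 0.5).astype(np.int64)
    order = ndata["load"]
    load_nodes = np.array(
        sorted(np.flatnonzero(order > 0.5), key=lambda ix: order[ix]), dtype=np.int64
    )
    probe_ix = np.flatnonzero(ndata["probe_A"] > 0.5)
    probe = int(probe_ix[0]) if probe_ix.size else -1
    return ShellMesh(
        nodes=coords,
        triangles=tris,
        thickness=np.asarray(edata["thickness"], dtype=float),
        region=region,
        fixed_nodes=fixed,
        load_nodes=load_nodes,
        probe_A=probe,
    )


# ---------------------------------------------------------------------------
# transient VTK series


def write_vtk_series(
    mesh: ShellMesh,
    history: DisplacementHistory,
    out_dir: str,
    basename: str = "snapshot",
    cell_data: dict[str, np.ndarray] | None = None,
) -> list[str]:
    """One legacy-VTK file per snapshot with point data ``displacement`` and
    ``velocity`` (plus optional per-element fields, e.g. von Mises stress),
    and a ``<basename>.series`` JSON index understood by common viewers."""
    os.makedirs(out_dir, exist_ok=True)
    files = []
    n_nodes, n_elem = mesh.num_nodes, mesh.num_elements
    for k, t in enumerate(history.snapshot_times):
        fname = f"{basename}_{k:03d}.vtk"
        out = [
            "# vtk DataFile Version 3.0",
            f"orbital strike response t={t:.6g} s",
            "ASCII",
            "DATASET UNSTRUCTURED_GRID",
            f"POINTS {n_nodes} double",
        ]
        out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
        out += [f"CELLS {n_elem} {4 * n_elem}"]
        out += [f"3 {t0} {t1} {t2}" for t0, t1, t2 in mesh.triangles]
        out += [f"CELL_TYPES {n_elem}"] + ["5"] * n_elem
        out += [f"POINT_DATA {n_nodes}"]
        for field_name, arr in (
            ("displacement", history.displacements[k, :, :3]),
            ("velocity", history.velocities[k, :, :3]),
        ):
            out += [f"VECTORS {field_name} double"]
            out += [f"{vx:.9g} {vy:.9g} {vz:.9g}" for vx, vy, vz in arr]
        if cell_data:
            out += [f"CELL_DATA {n_elem}"]
            for field_name, arr in cell_data.items():
                out += _vtk_scalars(field_name, arr[k], "double")
        fpath = os.path.join(out_dir, fname)
        with open(fpath, "w") as fh:
            fh.write("\n".join(out) + "\n")
        files.append(fname)
    series = {
        "file-series-version": "1.0",
        "files": [
            {"name": f, "time": float(t)}
            for f, t in zip(files, history.snapshot_times)
        ],
    }
    series_path = os.path.join(out_dir, f"{basename}.series")
    with open(series_path, "w") as fh:
        json.dump(series, fh, indent=1)
    return files + [f"{basename}.series"]
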