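"""Readers and writers for the formats the pipeline touches.

Two text formats are supported:

* a minimal Abaqus-INP dialect (``*NODE``, ``*ELEMENT TYPE=C3D4``,
  ``*NSET``, ``*ELSET``) — the exchange format tet4 cranial models arrive
  in.  Node and element ids are 1-based in the file and mapped to the
  0-based internal convention; element orientation is normalised to
  positive volume on read.
* legacy-ASCII VTK unstructured grids, used to export meshes with attached
  stress fields for contour plotting.

Both are line-oriented; parse errors name the offending line.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np

from .mesh import MeshError, TetMesh

__all__ = ["read_mesh", "write_mesh", "write_vtk", "read_vtk", "ParseError"]

DEFAULT_MATERIAL = "bone"


class ParseError(ValueError):
    """Malformed record in a mesh file; message names the line number."""


def _keyword_options(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line.lstrip("*").split(",")]
    keyword = parts[0].upper()
    opts: dict[str, str] = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            opts[k.strip().upper()] = v.strip()
        elif p:
            opts[p.upper()] = ""
    return keyword, opts


def read_mesh(path: str | os.PathLike, format: str = "inp") -> TetMesh:
    """Read a tet4 mesh.

    Parameters
    ----------
    path
        File to read.
    format
        ``"inp"`` for the Abaqus dialect (``"internal"`` is accepted as an
        alias — the internal interchange format *is* the INP dialect).

    Returns a validated :class:`~craniofea.mesh.TetMesh` with 0-based
    indices and positively oriented elements.
    """
    if format not in ("inp", "internal"):
        raise ValueError(f"unknown mesh format {format!r}")
    node_ids: list[int] = []
    coords: list[list[float]] = []
    elem_ids: list[int] = []
    conn: list[list[int]] = []
    materials: list[str] = []
    nsets_raw: dict[str, list[int]] = {}
    elsets_raw: dict[str, list[int]] = {}

    section: str | None = None
    section_opts: dict[str, str] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                keyword, opts = _keyword_options(line)
                if keyword == "NODE":
                    section = "node"
                elif keyword == "ELEMENT":
                    etype = opts.get("TYPE", "").upper()
                    if etype != "C3D4":
                        raise MeshError(
                            f"line {lineno}: unsupported element type {etype!r} "
                            "(only C3D4 tetrahedra are supported)"
                        )
                    section = "element"
                elif keyword == "NSET":
                    if "NSET" not in opts:
                        raise ParseError(f"line {lineno}: *NSET without NSET= name")
                    section = "nset"
                    nsets_raw.setdefault(opts["NSET"], [])
                elif keyword == "ELSET":
                    if "ELSET" not in opts:
                        raise ParseError(f"line {lineno}: *ELSET without ELSET= name")
                    section = "elset"
                    elsets_raw.setdefault(opts["ELSET"], [])
                else:
                    section = None  # ignore unknown keyword blocks
                section_opts = opts
                continue
            if section is None:
                continue
            fields = [f for f in (t.strip() for t in line.split(",")) if f]
            try:
                if section == "node":
                    if len(fields) != 4:
                        raise ValueError("expected 'id, x, y, z'")
                    node_ids.append(int(fields[0]))
                    coords.append([float(f) for f in fields[1:]])
                elif section == "element":
                    if len(fields) != 5:
                        raise ValueError("expected 'id, n1, n2, n3, n4'")
                    elem_ids.append(int(fields[0]))
                    conn.append([int(f) for f in fields[1:]])
                    materials.append(section_opts.get("ELSET", DEFAULT_MATERIAL))
                elif section == "nset":
                    if "GENERATE" in section_opts:
                        start, stop, step = (int(fields[i]) for i in range(3))
                        nsets_raw[section_opts["NSET"]].extend(
                            range(start, stop + 1, step)
                        )
                    else:
                        nsets_raw[section_opts["NSET"]].extend(int(f) for f in fields)
                elif section == "elset":
                    elsets_raw[section_opts["ELSET"]].extend(int(f) for f in fields)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed record ({exc})") from None

    if not node_ids:
        raise ParseError(f"{path}: no *NODE block found")
    if not elem_ids:
        raise ParseError(f"{path}: no *ELEMENT block found")

    node_map = {nid: i for i, nid in enumerate(node_ids)}
    elem_map = {eid: i for i, eid in enumerate(elem_ids)}
    try:
        elements = np.array(
            [[node_map[n] for n in row] for row in conn], dtype=np.int64
        )
    except KeyError as exc:
        raise ParseError(f"element references unknown node id {exc}") from None
    node_sets = {
        name: np.unique([node_map[i] for i in ids])
        for name, ids in nsets_raw.items()
        if ids
    }
    element_sets = {
        name: np.unique([elem_map[i] for i in ids])
        for name, ids in elsets_raw.items()
        if ids
    }
    mesh = TetMesh(
        nodes=np.array(coords, dtype=np.float64),
        elements=elements,
        element_material=np.array(materials, dtype=object),
        node_sets=node_sets,
        element_sets=element_sets,
    )
    mesh.normalize_orientation()
    return mesh


def write_mesh(mesh: TetMesh, path: str | os.PathLike) -> None:
    """Write a mesh in the INP dialect (1-based ids, 17 significant digits)."""
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.17g}, {y:.17g}, {z:.17g}\n")
        # one *ELEMENT block per contiguous material run, preserving order
        prev = None
        for eid, label in enumerate(mesh.element_material):
            if label != prev:
                fh.write(f"*ELEMENT, TYPE=C3D4, ELSET={label}\n")
                prev = label
            n = mesh.elements[eid] + 1
            fh.write(f"{eid + 1}, {n[0]}, {n[1]}, {n[2]}, {n[3]}\n")
        for name in sorted(mesh.node_sets):
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, mesh.node_sets[name] + 1)
        for name in sorted(mesh.element_sets):
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, mesh.element_sets[name] + 1)


def _write_id_lines(fh, ids: Iterable[int], per_line: int = 8) -> None:
    ids = list(int(i) for i in ids)
    for start in range(0, len(ids), per_line):
        fh.write(", ".join(str(i) for i in ids[start : start + per_line]) + "\n")


# -- VTK ------------------------------------------------------------------


def write_vtk(
    mesh: TetMesh,
    path: str | os.PathLike,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "craniofea export",
) -> None:
    """Write a legacy-ASCII VTK unstructured grid (VTK cell type 10 = tetra).

    ``cell_data``/``point_data`` are mappings of array name to 1-D scalar or
    ``(n, 3)`` vector arrays over elements / nodes respectively.
    """
    cell_data = cell_data or {}
    point_data = point_data or {}
    for name, arr in cell_data.items():
        if len(arr) != mesh.n_elements:
            raise ValueError(f"cell array {name!r} has wrong length")
    for name, arr in point_data.items():
        if len(arr) != mesh.n_nodes:
            raise ValueError(f"point array {name!r} has wrong length")

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(title.replace("\n", " ")[:255] + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for row in mesh.elements:
            fh.write(f"4 {row[0]} {row[1]} {row[2]} {row[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, arr in cell_data.items():
                _write_vtk_array(fh, name, np.asarray(arr, dtype=np.float64))
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_vtk_array(fh, name, np.asarray(arr, dtype=np.float64))


def _write_vtk_array(fh, name: str, arr: np.ndarray) -> None:
    safe = name.replace(" ", "_")
    if arr.ndim == 1:
        fh.write(f"SCALARS {safe} double 1\nLOOKUP_TABLE default\n")
        for v in arr:
            fh.write(f"{v:.17g}\n")
    elif arr.ndim == 2 and arr.shape[1] == 3:
        fh.write(f"VECTORS {safe} double\n")
        for x, y, z in arr:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    else:
        raise ValueError(f"array {safe!r} must be scalar or 3-vector valued")


def read_vtk(path: str | os.PathLike) -> dict:
    """Read back a file written by :func:`write_vtk` (round-trip checks).

    Returns ``{"points", "cells", "cell_data", "point_data"}``.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def next_line() -> str:
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        line = tokens[i]
        i += 1
        return line

    out: dict = {"cell_data": {}, "point_data": {}}
    next_line()  # version
    next_line()  # title
    assert next_line().strip() == "ASCII"
    assert next_line().strip() == "DATASET UNSTRUCTURED_GRID"
    n_pts = int(next_line().split()[1])
    out["points"] = np.array(
        [[float(v) for v in next_line().split()] for _ in range(n_pts)]
    )
    n_cells = int(next_line().split()[1])
    out["cells"] = np.array(
        [[int(v) for v in next_line().split()[1:]] for _ in range(n_cells)]
    )
    n_types = int(next_line().split()[1])  # CELL_TYPES block
    for _ in range(n_types):
        next_line()

    current: dict[str, np.ndarray] | None = None
    current_n = 0
    while i < len(tokens):
        stripped = tokens[i].strip()
        if not stripped:
            i += 1
            continue
        head = stripped.split()
        if head[0] == "CELL_DATA":
            current, current_n = out["cell_data"], int(head[1])
            i += 1
        elif head[0] == "POINT_DATA":
            current, current_n = out["point_data"], int(head[1])
            i += 1
        elif head[0] == "SCALARS":
            name = head[1]
            i += 2  # SCALARS line + LOOKUP_TABLE line
            vals = [float(tokens[i + k]) for k in range(current_n)]
            i += current_n
            current[name] = np.array(vals)
        elif head[0] == "VECTORS":
            name = head[1]
            i += 1
            vals = [[float(v) for v in tokens[i + k].split()] for k in range(current_n)]
            i += current_n
            current[name] = np.array(vals)
        else:
            i += 1
    return out
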