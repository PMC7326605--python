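"""Plain-text mesh, surface and data-field readers/writers.

Two mesh dialects are supported:

* the CARP-style multi-file format: ``<base>.pts`` (point count header,
  then ``x y z`` per line), ``<base>.elem`` (element count header, then
  ``Tt v0 v1 v2 v3 tag`` per tetrahedron / ``Tr v0 v1 v2 tag`` per
  triangle, 0-based indices) and optional ``<base>.lon`` (per-element fiber
  triples after a header giving the number of directions, which must be 1);
* VTK legacy ASCII unstructured grids (cell types 10 = tet, 5 = triangle,
  integer ``CELL_DATA`` scalars named ``tags``, optional ``VECTORS fibers``).

Surfaces travel as a ``.surf``/``.vtx`` pair, node/element data as ``.dat``
(one scalar per line) or ``.vec`` (three numbers per line).  Coordinates are
written with shortest-round-trip precision by default, so
``read(write(mesh))`` reproduces every array exactly and a second write is
byte-identical.  Readers reorder the vertices of negative-volume tets (the
count is logged) so that all stored tets have positive signed volume.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    DataField,
    FormatError,
    Mesh,
    Surface,
    UnsupportedElementError,
    orient_tets_positive,
)

log = logging.getLogger(__name__)

_ELEM_TOKENS = {"Tt": 4, "Tr": 3}
_VTK_CELL_TYPES = {10: 4, 5: 3}
_VTK_CELL_OF_ETYPE = {4: 10, 3: 5}


def _fmt(x: float, precision: Optional[int]) -> str:
    if precision is None:
        return repr(float(x))
    return f"{float(x):.{precision}g}"


def _finish_mesh(mesh: Mesh, source: str) -> Mesh:
    mesh.validate()
    n = orient_tets_positive(mesh)
    if n:
        log.info("%s: reoriented %d negative-volume tetrahedra", source, n)
    return mesh


# ---------------------------------------------------------------------------
# CARP multi-file dialect
# ---------------------------------------------------------------------------

def _read_counted_lines(path: Path) -> tuple[int, list]:
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not lines:
        raise FormatError(f"{path}: empty file, expected a count header")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line 1: expected a count header") from exc
    body = [l for l in lines[1:]]
    # trailing blank lines are tolerated, internal ones are not
    while body and not body[-1].strip():
        body.pop()
    if len(body) != count:
        raise FormatError(
            f"{path}: header declares {count} entries but line "
            f"{len(body) + 2} {'is missing' if len(body) < count else 'is extra'}"
        )
    return count, body


def read_carp_mesh(basename) -> Mesh:
    """Read ``<basename>.pts`` / ``.elem`` (and ``.lon`` when present)."""
    base = Path(basename)
    npts, plines = _read_counted_lines(base.with_suffix(".pts"))
    points = np.empty((npts, 3))
    for i, line in enumerate(plines):
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"{base}.pts: line {i + 2}: expected 'x y z'")
        points[i] = [float(v) for v in parts]

    nel, elines = _read_counted_lines(base.with_suffix(".elem"))
    conn = np.full((nel, 4), -1, dtype=np.int64)
    etype = np.empty(nel, dtype=np.int8)
    tags = np.zeros(nel, dtype=np.int64)
    for i, line in enumerate(elines):
        parts = line.split()
        if not parts:
            raise FormatError(f"{base}.elem: line {i + 2}: empty element line")
        token = parts[0]
        if token not in _ELEM_TOKENS:
            raise UnsupportedElementError(
                f"{base}.elem: line {i + 2}: unsupported element token {token!r} "
                "(only Tt tetrahedra and Tr triangles are supported)"
            )
        k = _ELEM_TOKENS[token]
        if len(parts) not in (k + 1, k + 2):
            raise FormatError(
                f"{base}.elem: line {i + 2}: expected {k} indices and an "
                f"optional tag after {token!r}"
            )
        conn[i, :k] = [int(v) for v in parts[1:1 + k]]
        etype[i] = k
        if len(parts) == k + 2:
            tags[i] = int(parts[k + 1])

    fibers = None
    lon = base.with_suffix(".lon")
    if lon.exists():
        lines = lon.read_text().splitlines()
        if not lines:
            raise FormatError(f"{lon}: empty file")
        ndir = int(lines[0].split()[0])
        if ndir != 1:
            raise FormatError(f"{lon}: {ndir} fiber directions per element; only 1 supported")
        body = [l for l in lines[1:] if l.strip()]
        if len(body) != nel:
            raise FormatError(f"{lon}: {len(body)} fiber lines for {nel} elements")
        fibers = np.empty((nel, 3))
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{lon}: line {i + 2}: expected a 3-vector")
            fibers[i] = [float(v) for v in parts]

    return _finish_mesh(Mesh(points, conn, etype, tags, fibers), str(base))


def write_carp_mesh(mesh: Mesh, basename, precision: Optional[int] = None) -> None:
    """Write ``.pts``/``.elem`` (and ``.lon`` when fibers are present).

    ``precision`` is the number of significant digits; ``None`` (default)
    writes shortest-round-trip representations.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{mesh.n_points}\n")
        for p in mesh.points:
            f.write(" ".join(_fmt(v, precision) for v in p) + "\n")
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_elems}\n")
        for e in range(mesh.n_elems):
            k = mesh.etype[e]
            token = "Tt" if k == 4 else "Tr"
            idx = " ".join(str(v) for v in mesh.conn[e, :k])
            f.write(f"{token} {idx} {mesh.tags[e]}\n")
    if mesh.fibers is not None:
        with open(base.with_suffix(".lon"), "w") as f:
            f.write("1\n")
            for v in mesh.fibers:
                f.write(" ".join(_fmt(x, precision) for x in v) + "\n")


# ---------------------------------------------------------------------------
# VTK legacy ASCII unstructured grid
# ---------------------------------------------------------------------------

def read_vtk_legacy(path) -> Mesh:
    """Read a VTK legacy ASCII unstructured grid (tets and triangles only)."""
    path = Path(path)
    try:
        text = path.read_text(errors="replace")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    tokens = text.split()
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(n=1):
        nonlocal pos
        if pos + n > len(tokens):
            raise FormatError(f"{path}: unexpected end of file")
        out = tokens[pos:pos + n]
        pos += n
        return out if n > 1 else out[0]

    upper = [t.upper() for t in tokens]
    if "BINARY" in upper[:20]:
        raise FormatError(
            f"{path}: BINARY VTK files are not supported; convert to ASCII first"
        )
    if "UNSTRUCTURED_GRID" not in upper:
        raise FormatError(f"{path}: DATASET UNSTRUCTURED_GRID expected")

    points = None
    cells = None
    cell_types = None
    tags = None
    fibers = None
    while pos < len(tokens):
        kw = take().upper()
        if kw == "POINTS":
            n = int(take())
            take()  # dtype
            vals = [float(v) for v in take(3 * n)] if n else []
            points = np.array(vals).reshape(n, 3)
        elif kw == "CELLS":
            n = int(take())
            total = int(take())
            raw = [int(v) for v in take(total)] if total else []
            cells = []
            i = 0
            for _ in range(n):
                k = raw[i]
                cells.append(raw[i + 1:i + 1 + k])
                i += 1 + k
        elif kw == "CELL_TYPES":
            n = int(take())
            cell_types = [int(take()) for _ in range(n)]
        elif kw == "CELL_DATA":
            take()  # count, validated against cells below
        elif kw == "SCALARS":
            name = take()
            take()  # dtype
            if peek() and peek().isdigit():
                take()
            if peek() and peek().upper() == "LOOKUP_TABLE":
                take(2)
            n = len(cells) if cells is not None else 0
            vals = [int(float(take())) for _ in range(n)]
            if name.lower() == "tags":
                tags = np.array(vals, dtype=np.int64)
        elif kw == "VECTORS":
            name = take()
            take()  # dtype
            n = len(cells) if cells is not None else 0
            vals = [float(take()) for _ in range(3 * n)]
            if name.lower() == "fibers":
                fibers = np.array(vals).reshape(n, 3)
        # other keywords (headers, titles) are skipped token by token

    if points is None or cells is None or cell_types is None:
        raise FormatError(f"{path}: POINTS, CELLS and CELL_TYPES are all required")
    if len(cells) != len(cell_types):
        raise FormatError(f"{path}: CELLS and CELL_TYPES counts disagree")
    ne = len(cells)
    conn = np.full((ne, 4), -1, dtype=np.int64)
    etype = np.empty(ne, dtype=np.int8)
    for i, (cell, ct) in enumerate(zip(cells, cell_types)):
        if ct not in _VTK_CELL_TYPES:
            raise UnsupportedElementError(
                f"{path}: cell {i} has VTK type {ct}; only 10 (tetra) and "
                "5 (triangle) are supported"
            )
        k = _VTK_CELL_TYPES[ct]
        if len(cell) != k:
            raise FormatError(f"{path}: cell {i} lists {len(cell)} vertices for type {ct}")
        conn[i, :k] = cell
        etype[i] = k
    if tags is None:
        tags = np.zeros(ne, dtype=np.int64)
    return _finish_mesh(Mesh(points, conn, etype, tags, fibers), str(path))


def write_vtk_legacy(mesh: Mesh, path, precision: Optional[int] = None) -> None:
    """Write a VTK legacy ASCII unstructured grid with a ``tags`` array."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmeshkit mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_points} double\n")
        for p in mesh.points:
            f.write(" ".join(_fmt(v, precision) for v in p) + "\n")
        sizes = mesh.etype.astype(np.int64) + 1
        f.write(f"CELLS {mesh.n_elems} {int(sizes.sum())}\n")
        for e in range(mesh.n_elems):
            k = mesh.etype[e]
            f.write(f"{k} " + " ".join(str(v) for v in mesh.conn[e, :k]) + "\n")
        f.write(f"CELL_TYPES {mesh.n_elems}\n")
        for e in range(mesh.n_elems):
            f.write(f"{_VTK_CELL_OF_ETYPE[int(mesh.etype[e])]}\n")
        f.write(f"CELL_DATA {mesh.n_elems}\n")
        f.write("SCALARS tags int 1\nLOOKUP_TABLE default\n")
        for t in mesh.tags:
            f.write(f"{t}\n")
        if mesh.fibers is not None:
            f.write("VECTORS fibers double\n")
            for v in mesh.fibers:
                f.write(" ".join(_fmt(x, precision) for x in v) + "\n")


# ---------------------------------------------------------------------------
# dialect dispatch
# ---------------------------------------------------------------------------

def detect_dialect(path) -> str:
    """``'vtk'`` for ``.vtk`` paths, ``'carp_txt'`` otherwise."""
    return "vtk" if str(path).endswith(".vtk") else "carp_txt"


def read_mesh(path, fmt: Optional[str] = None) -> Mesh:
    fmt = fmt or detect_dialect(path)
    if fmt in ("vtk", "vtk_bin", "vtk_ascii"):
        return read_vtk_legacy(path)
    if fmt == "carp_txt":
        base = str(path)
        for suf in (".pts", ".elem"):
            if base.endswith(suf):
                base = base[: -len(suf)]
        return read_carp_mesh(base)
    raise FormatError(f"unknown mesh dialect {fmt!r}")


def write_mesh(mesh: Mesh, path, fmt: Optional[str] = None,
               precision: Optional[int] = None) -> None:
    fmt = fmt or detect_dialect(path)
    if fmt in ("vtk", "vtk_bin", "vtk_ascii"):
        write_vtk_legacy(mesh, path, precision)
    elif fmt == "carp_txt":
        write_carp_mesh(mesh, path, precision)
    else:
        raise FormatError(f"unknown mesh dialect {fmt!r}")


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

def read_surface(path_surf, path_vtx=None) -> Surface:
    """Read a ``.surf`` face list (and optional ``.vtx`` vertex list)."""
    path_surf = Path(path_surf)
    nf, lines = _read_counted_lines(path_surf)
    faces = np.empty((nf, 3), dtype=np.int64)
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) != 4 or parts[0] != "Tr":
            raise FormatError(f"{path_surf}: line {i + 2}: expected 'Tr v0 v1 v2'")
        faces[i] = [int(v) for v in parts[1:]]
    parent = int(faces.max()) + 1 if nf else 0
    vset = None
    if path_vtx is not None and Path(path_vtx).exists():
        path_vtx = Path(path_vtx)
        lines = path_vtx.read_text().splitlines()
        if len(lines) < 2:
            raise FormatError(f"{path_vtx}: expected a count line and a domain keyword")
        nv = int(lines[0].split()[0])
        body = [l for l in lines[2:] if l.strip()]
        if len(body) != nv:
            raise FormatError(f"{path_vtx}: header declares {nv} vertices, found {len(body)}")
        vset = np.array(sorted(int(l.split()[0]) for l in body), dtype=np.int64)
        in_faces = np.unique(faces)
        extra = np.setdiff1d(vset, in_faces)
        if len(extra):
            warnings.warn(
                f"{path_vtx}: {len(extra)} vertex/vertices absent from all faces "
                "(retained in the vertex set)",
                stacklevel=2,
            )
            vset = np.union1d(vset, in_faces)
            parent = max(parent, int(vset.max()) + 1)
        else:
            vset = None  # identical to the recomputed set
    s = Surface(faces, parent, _vertex_set=vset)
    return s.validate()


def write_surface(surface: Surface, basename) -> None:
    """Write ``<basename>.surf`` and ``<basename>.vtx``.

    The vertex set is recomputed from the faces; the ``intra`` domain
    keyword in the ``.vtx`` file is a compatibility token without semantics
    here (and is ignored on read).
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".surf"), "w") as f:
        f.write(f"{surface.n_faces}\n")
        for a, b, c in surface.faces:
            f.write(f"Tr {a} {b} {c}\n")
    vset = np.unique(surface.faces)
    with open(base.with_suffix(".vtx"), "w") as f:
        f.write(f"{len(vset)}\nintra\n")
        for v in vset:
            f.write(f"{v}\n")


# ---------------------------------------------------------------------------
# data fields
# ---------------------------------------------------------------------------

def read_data(path, attachment: str = "node") -> DataField:
    """Read ``.dat`` (scalar per line) or ``.vec`` (3-vector per line).

    Length is validated against a mesh only at attach time
    (:meth:`meshkit.core.DataField.validate_against`), not at read time.
    """
    path = Path(path)
    width = 3 if path.suffix == ".vec" else 1
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    vals = []
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) != width:
            raise FormatError(
                f"{path}: line {i + 1}: expected {width} value(s), found {len(parts)}"
            )
        vals.append([float(v) for v in parts])
    arr = np.array(vals) if vals else np.empty((0, width))
    return DataField(attachment, arr[:, 0] if width == 1 else arr)


def write_data(field: DataField, path, precision: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = field.values if field.width == 3 else field.values[:, None]
    with open(path, "w") as f:
        for row in vals:
            f.write(" ".join(_fmt(v, precision) for v in row) + "\n")
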