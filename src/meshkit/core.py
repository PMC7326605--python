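"""Core containers for labeled unstructured meshes and elementary geometry.

A :class:`Mesh` holds vertex coordinates plus a mixed list of tetrahedra and
triangles, each carrying an integer region tag (inherited from multi-label
image segmentation, e.g. tissue vs. blood pool) and, optionally, a per-element
fiber direction.  A :class:`Surface` is a set of oriented triangular faces
referencing the vertex indexing of a parent mesh.  Indexing is 0-based
everywhere; file-format conversions live in :mod:`meshkit.formats`.

Coordinates are treated as opaque length units: all thresholds taking a
length (edge sizes, merge tolerances, traversal distances) are interpreted in
the units of the input coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: number-of-vertices codes used in ``Mesh.etype``
TETRA = 4
TRIA = 3


class MeshError(Exception):
    """Base class for all errors raised by meshkit."""


class ValidationError(MeshError):
    """A container violates one of its structural invariants."""


class GeometryError(MeshError):
    """Geometric precondition violated (degenerate or open geometry)."""


class FormatError(MeshError):
    """Malformed or unsupported input file."""


class UnsupportedElementError(FormatError):
    """An element kind other than tetrahedra or triangles was encountered."""


class EmptySelectionError(MeshError):
    """A tag selection matched no elements."""


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def signed_tet_volume(p0, p1, p2, p3):
    """Signed volume of the tetrahedron (p0, p1, p2, p3).

    ``dot(p1 - p0, cross(p2 - p0, p3 - p0)) / 6``; the sign encodes
    orientation (positive for a right-handed vertex order).  Accepts single
    coordinates or broadcastable ``(..., 3)`` stacks.  Degenerate (coplanar)
    inputs return 0.
    """
    p0 = np.asarray(p0, dtype=float)
    a = np.asarray(p1, dtype=float) - p0
    b = np.asarray(p2, dtype=float) - p0
    c = np.asarray(p3, dtype=float) - p0
    return np.einsum("...i,...i->...", a, np.cross(b, c)) / 6.0


def triangle_normal(p0, p1, p2):
    """Unit normal of an oriented triangle; raises on zero area.

    Orientation follows the vertex order (right-hand rule on
    ``cross(p1 - p0, p2 - p0)``).
    """
    p0 = np.asarray(p0, dtype=float)
    n = np.cross(np.asarray(p1, dtype=float) - p0, np.asarray(p2, dtype=float) - p0)
    nrm = np.linalg.norm(n, axis=-1)
    if np.any(nrm == 0.0):
        raise GeometryError("degenerate (zero-area) triangle has no normal")
    return n / (nrm[..., None] if n.ndim > 1 else nrm)


def triangle_normals(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit normals for a face array; zero-area faces yield zero vectors."""
    p = points[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm = np.linalg.norm(n, axis=1)
    nz = nrm > 0
    out = np.zeros_like(n)
    out[nz] = n[nz] / nrm[nz, None]
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Labeled mixed tetrahedral/triangular mesh.

    Parameters
    ----------
    points
        ``(n_points, 3)`` float coordinates.
    conn
        ``(n_elems, 4)`` int connectivity; triangles use columns 0..2 and
        hold ``-1`` in column 3.
    etype
        ``(n_elems,)`` per-element vertex count, ``TETRA`` (4) or ``TRIA`` (3).
    tags
        ``(n_elems,)`` integer region labels.
    fibers
        optional ``(n_elems, 3)`` per-element fiber direction, carried as an
        opaque payload through all operations.
    """

    points: np.ndarray
    conn: np.ndarray
    etype: np.ndarray
    tags: np.ndarray
    fibers: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float).reshape(-1, 3)
        self.conn = np.ascontiguousarray(self.conn, dtype=np.int64)
        if self.conn.size == 0:
            self.conn = self.conn.reshape(0, 4)
        if self.conn.shape[1] == 3:  # triangle-only input convenience
            pad = np.full((len(self.conn), 1), -1, dtype=np.int64)
            self.conn = np.hstack([self.conn, pad])
        self.etype = np.ascontiguousarray(self.etype, dtype=np.int8)
        self.tags = np.ascontiguousarray(self.tags, dtype=np.int64)
        if self.fibers is not None:
            self.fibers = np.ascontiguousarray(self.fibers, dtype=float).reshape(-1, 3)

    # -- basic queries ------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_elems(self) -> int:
        return len(self.conn)

    @property
    def tet_mask(self) -> np.ndarray:
        return self.etype == TETRA

    @property
    def tri_mask(self) -> np.ndarray:
        return self.etype == TRIA

    def tets(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices and ``(n, 4)`` connectivity of the tetrahedra."""
        idx = np.flatnonzero(self.tet_mask)
        return idx, self.conn[idx, :4]

    def tris(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices and ``(n, 3)`` connectivity of the standalone triangles."""
        idx = np.flatnonzero(self.tri_mask)
        return idx, self.conn[idx, :3]

    def centroids(self) -> np.ndarray:
        """Per-element centroid (mean of the element's vertices)."""
        out = np.empty((self.n_elems, 3))
        ti, tc = self.tets()
        if len(ti):
            out[ti] = self.points[tc].mean(axis=1)
        ri, rc = self.tris()
        if len(ri):
            out[ri] = self.points[rc].mean(axis=1)
        return out

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes of the tetrahedra (in tet order of :meth:`tets`)."""
        _, tc = self.tets()
        p = self.points
        return signed_tet_volume(p[tc[:, 0]], p[tc[:, 1]], p[tc[:, 2]], p[tc[:, 3]])

    def copy(self) -> "Mesh":
        return Mesh(
            self.points.copy(),
            self.conn.copy(),
            self.etype.copy(),
            self.tags.copy(),
            None if self.fibers is None else self.fibers.copy(),
        )

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> "Mesh":
        """Check the structural invariants; raises :class:`ValidationError`."""
        ne = self.n_elems
        if not (len(self.etype) == len(self.tags) == ne):
            raise ValidationError("etype/tags length differs from element count")
        if self.fibers is not None and len(self.fibers) != ne:
            raise ValidationError("fibers length differs from element count")
        bad = ~np.isin(self.etype, (TETRA, TRIA))
        if bad.any():
            raise ValidationError(f"unsupported element kinds at {np.flatnonzero(bad)[:5]}")
        for idx, cn in (self.tets(), self.tris()):
            if len(idx) == 0:
                continue
            if cn.min(initial=0) < 0 or cn.max(initial=0) >= self.n_points:
                raise ValidationError("connectivity index out of range")
            k = cn.shape[1]
            for i in range(k):
                for j in range(i + 1, k):
                    dup = cn[:, i] == cn[:, j]
                    if dup.any():
                        raise ValidationError(
                            f"repeated vertex in element(s) {idx[np.flatnonzero(dup)[:5]]}"
                        )
        return self


def orient_tets_positive(mesh: Mesh) -> int:
    """Reorder vertices of negative-volume tets in place; returns the count.

    Keeps "inverted element" detection a simple sign test downstream: a valid
    mesh stores every tetrahedron with positive signed volume.
    """
    ti, tc = mesh.tets()
    if len(ti) == 0:
        return 0
    vol = mesh.tet_volumes()
    neg = vol < 0
    if neg.any():
        rows = ti[neg]
        mesh.conn[rows, 2], mesh.conn[rows, 3] = (
            mesh.conn[rows, 3].copy(),
            mesh.conn[rows, 2].copy(),
        )
    return int(neg.sum())


@dataclass
class Surface:
    """Oriented triangular faces referencing a parent mesh's vertex indexing."""

    faces: np.ndarray
    parent_point_count: int
    _vertex_set: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.parent_point_count = int(self.parent_point_count)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertex_set(self) -> np.ndarray:
        """Sorted unique vertex indices appearing in the faces."""
        if self._vertex_set is None:
            self._vertex_set = np.unique(self.faces)
        return self._vertex_set

    def validate(self) -> "Surface":
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.parent_point_count):
            raise ValidationError("face index outside parent point range")
        used = np.unique(self.faces)
        if self._vertex_set is not None:
            extra = np.setdiff1d(self._vertex_set, used)
            if len(np.setdiff1d(used, self._vertex_set)):
                raise ValidationError("vertex_set misses face vertices")
            if len(extra) and (extra.min() < 0 or extra.max() >= self.parent_point_count):
                raise ValidationError("vertex_set index outside parent point range")
        return self

    def face_keys(self) -> np.ndarray:
        """Canonical face identities: sorted vertex triples, ``(n, 3)``."""
        return np.sort(self.faces, axis=1)


def surface_from_triangles(mesh: Mesh) -> Surface:
    """The standalone triangles of a mesh viewed as a Surface (as stored)."""
    _, tri = mesh.tris()
    return Surface(tri.copy(), mesh.n_points)


def enclosed_volume(surface: Surface, points: np.ndarray) -> float:
    """Volume enclosed by a closed, consistently oriented surface.

    Sums the signed volumes of the tetrahedra spanned by each face and the
    origin; positive for outward orientation, translation-invariant for
    closed surfaces.  Raises :class:`GeometryError` if any edge is not shared
    by exactly two faces with opposite direction (open or inconsistently
    oriented surface).
    """
    faces = surface.faces
    if len(faces) == 0:
        raise GeometryError("empty surface is not closed")
    # directed edges must each appear exactly once for closed + consistent
    de = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    order = np.lexsort((de[:, 1], de[:, 0]))
    de_sorted = de[order]
    if len(de_sorted) != len(np.unique(de_sorted, axis=0)):
        raise GeometryError("surface has duplicated directed edges (inconsistent orientation)")
    und = np.sort(de, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise GeometryError("open surface: an edge is not shared by exactly 2 faces")
    points = np.asarray(points, dtype=float)
    p = points[faces]
    return float(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0)


@dataclass
class DataField:
    """Scalar or 3-vector data attached to the nodes or elements of a mesh."""

    attachment: str  # "node" or "element"
    values: np.ndarray

    def __post_init__(self):
        if self.attachment not in ("node", "element"):
            raise ValidationError("attachment must be 'node' or 'element'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2 and self.values.shape[1] == 1:
            self.values = self.values[:, 0]
        if self.values.ndim not in (1, 2) or (
            self.values.ndim == 2 and self.values.shape[1] != 3
        ):
            raise ValidationError("values must be (n,) scalars or (n, 3) vectors")

    @property
    def width(self) -> int:
        return 1 if self.values.ndim == 1 else 3

    def __len__(self) -> int:
        return len(self.values)

    def validate_against(self, mesh: Mesh) -> "DataField":
        n = mesh.n_points if self.attachment == "node" else mesh.n_elems
        if len(self.values) != n:
            raise ValidationError(
                f"{self.attachment} field of length {len(self.values)} does not match "
                f"mesh with {n} {self.attachment}s"
            )
        return self

    def copy(self) -> "DataField":
        return DataField(self.attachment, self.values.copy())


@dataclass
class IndexMapping:
    """Injective node and element maps from a submesh into its parent."""

    node_map: np.ndarray
    elem_map: np.ndarray

    def __post_init__(self):
        self.node_map = np.ascontiguousarray(self.node_map, dtype=np.int64)
        self.elem_map = np.ascontiguousarray(self.elem_map, dtype=np.int64)

    def validate(self, parent: Optional[Mesh] = None) -> "IndexMapping":
        for name, m in (("node_map", self.node_map), ("elem_map", self.elem_map)):
            if len(np.unique(m)) != len(m):
                raise ValidationError(f"{name} is not injective")
            if len(m) and m.min() < 0:
                raise ValidationError(f"{name} holds a negative index")
        if parent is not None:
            if len(self.node_map) and self.node_map.max() >= parent.n_points:
                raise ValidationError("node_map exceeds parent point count")
            if len(self.elem_map) and self.elem_map.max() >= parent.n_elems:
                raise ValidationError("elem_map exceeds parent element count")
        return self
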