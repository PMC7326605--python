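"""Deterministic generators of labeled test meshes.

These emulate the kinds of inputs an image-based cardiac modeling pipeline
produces — multi-label tetrahedral volumes, a two-label "tissue around a
blood pool" ball, a closed device-like rod surface — without any external
mesher or data download.  All randomness is seed-parameterized.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import Mesh, Surface, ValidationError, orient_tets_positive
from .topology import POINT, ManifoldLabeling, decompose_manifolds

# the six tetrahedra of the Kuhn subdivision of the unit cube; each row lists
# corner ids in (x + 2 y + 4 z) bit order, sharing the 0-7 diagonal
_KUHN_TETS = np.array([
    [0, 1, 3, 7],
    [0, 3, 2, 7],
    [0, 2, 6, 7],
    [0, 6, 4, 7],
    [0, 4, 5, 7],
    [0, 5, 1, 7],
])


def box_tet_mesh(
    nx: int,
    ny: int,
    nz: int,
    h: float = 1.0,
    label_planes: Sequence[tuple[int, float]] = (),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Mesh:
    """Structured box of ``nx*ny*nz`` cubes, each split into 6 tetrahedra.

    All tets share the cube diagonal, so the mesh is conforming, and all are
    stored with positive volume.  ``label_planes`` is a sequence of
    ``(axis, position)`` pairs; an element's tag is ``1 +`` the number of
    planes its centroid lies above, so planes along one axis slice the box
    into tagged slabs.
    """
    if min(nx, ny, nz) < 1:
        raise ValidationError("box needs at least one cube per axis")
    o = np.asarray(origin, dtype=float)
    xs = o[0] + h * np.arange(nx + 1)
    ys = o[1] + h * np.arange(ny + 1)
    zs = o[2] + h * np.arange(nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack(
        [vid(I + (c & 1), J + ((c >> 1) & 1), K + ((c >> 2) & 1)) for c in range(8)],
        axis=1,
    )
    conn = corners[:, _KUHN_TETS].reshape(-1, 4)
    ne = len(conn)
    mesh = Mesh(points, conn, np.full(ne, 4, dtype=np.int8),
                np.ones(ne, dtype=np.int64))
    orient_tets_positive(mesh)
    if label_planes:
        cent = mesh.centroids()
        tags = np.ones(ne, dtype=np.int64)
        for axis, posn in label_planes:
            tags += (cent[:, axis] > posn).astype(np.int64)
        mesh.tags = tags
    return mesh.validate()


def shell_with_cavity(
    radius_outer: float = 1.0,
    radius_inner: float = 0.5,
    refinement: int = 4,
    cavity_tag: int = 1,
    tissue_tag: int = 2,
) -> Mesh:
    """Two-label tetrahedralized ball: a cavity inside shell tissue.

    A ``(2 n)^3`` cube grid centered at the origin is warped radially so
    that every L-infinity lattice shell maps onto a sphere; elements with
    centroid radius below ``radius_inner`` get ``cavity_tag`` ("blood
    pool"), the rest ``tissue_tag``.  ``radius_inner`` is rounded to the
    nearest lattice shell so the interface is an exactly spherical,
    conforming surface.  No external mesher is involved.
    """
    n = int(refinement)
    if n < 2:
        raise ValidationError("refinement must be >= 2")
    if not 0 < radius_inner < radius_outer:
        raise ValidationError("need 0 < radius_inner < radius_outer")
    box = box_tet_mesh(2 * n, 2 * n, 2 * n, h=1.0 / n, origin=(-1.0, -1.0, -1.0))
    p = box.points
    linf = np.abs(p).max(axis=1)
    l2 = np.linalg.norm(p, axis=1)
    scale = np.ones(len(p))
    nz = l2 > 0
    scale[nz] = linf[nz] / l2[nz]
    box.points = p * scale[:, None] * radius_outer
    orient_tets_positive(box)

    # snap the interface radius onto a lattice shell
    k = int(round(radius_inner / radius_outer * n))
    k = min(max(k, 1), n - 1)
    r_in = radius_outer * k / n
    cent = box.centroids()
    inside = np.linalg.norm(cent, axis=1) < r_in
    box.tags = np.where(inside, cavity_tag, tissue_tag).astype(np.int64)
    return box.validate()


def rod_surface(
    length: float = 4.0,
    radius: float = 0.5,
    segments: int = 32,
    rings: int = 8,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    axis: int = 2,
) -> tuple[Surface, np.ndarray]:
    """Closed triangulated cylinder with end caps, oriented outward.

    Emulates a CAD-derived device ("coil") surface.  Returns the surface
    and its own point array; faces index into those points.
    """
    if segments < 3 or rings < 1:
        raise ValidationError("need segments >= 3 and rings >= 1")
    ang = 2 * np.pi * np.arange(segments) / segments
    zs = np.linspace(-length / 2, length / 2, rings + 1)
    pts = []
    for z in zs:
        for a in ang:
            pts.append([radius * np.cos(a), radius * np.sin(a), z])
    bot_c = len(pts)
    pts.append([0.0, 0.0, zs[0]])
    top_c = len(pts)
    pts.append([0.0, 0.0, zs[-1]])
    pts = np.array(pts)

    faces = []
    for r in range(rings):
        for s in range(segments):
            a = r * segments + s
            b = r * segments + (s + 1) % segments
            c = (r + 1) * segments + s
            d = (r + 1) * segments + (s + 1) % segments
            faces.append([a, b, d])  # outward for CCW-when-seen-from-outside
            faces.append([a, d, c])
    for s in range(segments):  # bottom cap, normal -z
        a, b = s, (s + 1) % segments
        faces.append([bot_c, b, a])
    for s in range(segments):  # top cap, normal +z
        a = rings * segments + s
        b = rings * segments + (s + 1) % segments
        faces.append([top_c, a, b])
    faces = np.array(faces, dtype=np.int64)

    if axis != 2:
        order = {0: [2, 1, 0], 1: [0, 2, 1]}[axis]
        pts = pts[:, order]
        faces = faces[:, [0, 2, 1]]  # axis swap mirrors; restore orientation
    pts = pts + np.asarray(center, dtype=float)
    return Surface(faces, len(pts)), pts


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> Mesh:
    """Triangle mesh of a sphere by icosahedron subdivision.

    Level 3 has 642 vertices, level 4 has 2562.  Faces are oriented
    outward; all tags are 1.
    """
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        cache: dict = {}
        vlist = list(verts)

        def midpoint(a, b):
            key = (a, b) if a < b else (b, a)
            if key not in cache:
                m = vlist[a] + vlist[b]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    points = verts * radius
    ne = len(faces)
    return Mesh(points, faces, np.full(ne, 3, dtype=np.int8),
                np.ones(ne, dtype=np.int64)).validate()


def jitter(
    mesh: Mesh,
    sigma: float,
    seed: int,
    labeling: Optional[ManifoldLabeling] = None,
) -> Mesh:
    """Add iid Gaussian displacement (std ``sigma``) to all non-POINT vertices.

    Creates the rough interfaces that smoothing is meant to clean up.
    Corner (POINT) vertices stay put, so the nominal extent of the object is
    preserved.  Reproducible for a fixed seed.
    """
    out = mesh.copy()
    if sigma == 0.0:
        return out
    if labeling is None:
        labeling = decompose_manifolds(mesh)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=out.points.shape)
    movable = labeling.vertex_class != POINT
    out.points[movable] += noise[movable]
    return out
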