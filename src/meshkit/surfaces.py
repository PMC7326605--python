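"""Surface extraction by tag-set algebra and seeded edge traversal.

Landmark surfaces of anatomical meshes (epicardium, endocardium, base, ...)
are defined as set operations on the boundary surfaces of labeled submeshes:
e.g. the endocardium is the intersection of the tissue boundary and the
blood-pool boundary.  The results can be restricted further to the region
reachable along surface edges from seed locations, with traversal blocked
across sharply creased edges.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .core import (
    EmptySelectionError,
    GeometryError,
    Mesh,
    Surface,
    ValidationError,
    triangle_normals,
)
from .topology import TET_FACES


def extract_boundary_surface(mesh: Mesh, tag_set: Iterable[int]) -> Surface:
    """Boundary surface of the submesh selected by a set of region tags.

    Collects the faces occurring exactly once among the tetrahedra whose tag
    is in ``tag_set``, oriented outward from that submesh (tets are stored
    with positive volume, so the canonical face ordering points away from the
    opposite vertex).  Faces are returned sorted by their canonical key for
    determinism.
    """
    tag_set = sorted(set(int(t) for t in tag_set))
    if not tag_set:
        raise EmptySelectionError("empty tag set")
    ti, tc = mesh.tets()
    sel = np.isin(mesh.tags[ti], tag_set)
    if not sel.any():
        raise EmptySelectionError(f"no tetrahedra carry tags {tag_set}")
    tc = tc[sel]
    faces = tc[:, TET_FACES].reshape(-1, 3)
    keys = np.sort(faces, axis=1)
    order = np.lexsort(keys.T[::-1])
    keys_s, faces_s = keys[order], faces[order]
    uniq, start, counts = np.unique(keys_s, axis=0, return_index=True, return_counts=True)
    boundary = faces_s[start[counts == 1]]
    return Surface(boundary, mesh.n_points)


def _check_compatible(a: Surface, b: Surface):
    if a.parent_point_count != b.parent_point_count:
        raise ValidationError(
            "surfaces reference different parent meshes "
            f"({a.parent_point_count} vs {b.parent_point_count} points)"
        )


def _key_dict(s: Surface) -> dict:
    return {tuple(k): f for k, f in zip(s.face_keys(), s.faces)}


def _from_keys(keys, lookup_a: dict, lookup_b: dict, parent: int) -> Surface:
    faces = [lookup_a.get(k, lookup_b.get(k)) for k in sorted(keys)]
    if faces:
        return Surface(np.array(faces, dtype=np.int64), parent)
    return Surface(np.empty((0, 3), dtype=np.int64), parent)


def surface_union(a: Surface, b: Surface) -> Surface:
    """Set union over canonical face keys; orientation from ``a`` wins."""
    _check_compatible(a, b)
    da, db = _key_dict(a), _key_dict(b)
    return _from_keys(set(da) | set(db), da, db, a.parent_point_count)


def surface_intersection(a: Surface, b: Surface) -> Surface:
    """Set intersection over canonical face keys; orientation from ``a``."""
    _check_compatible(a, b)
    da, db = _key_dict(a), _key_dict(b)
    return _from_keys(set(da) & set(db), da, db, a.parent_point_count)


def surface_difference(a: Surface, b: Surface) -> Surface:
    """Faces of ``a`` absent from ``b`` (canonical keys)."""
    _check_compatible(a, b)
    da, db = _key_dict(a), _key_dict(b)
    return _from_keys(set(da) - set(db), da, db, a.parent_point_count)


def restrict_by_traversal(
    surface: Surface,
    points: np.ndarray,
    seeds: Sequence,
    max_edge_distance: Optional[float] = None,
    block_angle_deg: Optional[float] = None,
    snap_radius: Optional[float] = None,
) -> Surface:
    """Restrict a surface to the region reachable from seed locations.

    Each seed coordinate is snapped to the nearest surface vertex; shortest
    paths are grown over surface edges with Euclidean edge weights.  An edge
    is impassable when the normals of its two adjacent faces deviate by more
    than ``block_angle_deg`` (or when it is non-manifold and blocking is on).
    A face is kept when all three of its vertices were reached within
    ``max_edge_distance`` (``None`` = unlimited) *and* the face itself is
    reachable from the seed's incident faces by crossing passable edges
    only — so a sharp crease confines the traversal to its patch even
    though the crease's rim vertices belong to both sides.  The result is
    the union over seeds.

    A seed farther than ``snap_radius`` from the surface (default: the
    longest surface edge, i.e. anything within the sampling density of the
    surface snaps silently) is still snapped, with a warning.
    """
    if surface.n_faces == 0:
        raise GeometryError("cannot traverse an empty surface")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.shape[0] == 0:
        raise ValidationError("at least one seed location is required")
    points = np.asarray(points, dtype=float)
    verts = surface.vertex_set
    vpos = points[verts]

    # compact vertex indexing
    remap = {v: i for i, v in enumerate(verts)}
    faces_local = np.vectorize(remap.get)(surface.faces)

    edges = np.sort(
        np.concatenate(
            [faces_local[:, [0, 1]], faces_local[:, [1, 2]], faces_local[:, [2, 0]]]
        ),
        axis=1,
    )
    fowners = np.concatenate([np.arange(surface.n_faces)] * 3)
    order = np.lexsort(edges.T[::-1])
    edges_s, fowners_s = edges[order], fowners[order]
    uedges, start = np.unique(edges_s, axis=0, return_index=True)
    bounds = np.append(start, len(edges_s))
    edge_len = np.linalg.norm(vpos[uedges[:, 0]] - vpos[uedges[:, 1]], axis=1)

    if snap_radius is None:
        snap_radius = float(edge_len.max()) if len(edge_len) else np.inf
    tree = cKDTree(vpos)
    dist, local_seed = tree.query(seeds)
    far = dist > snap_radius
    if far.any():
        warnings.warn(
            f"{int(far.sum())} seed(s) farther than snap radius {snap_radius:g} "
            f"from the surface (max distance {dist.max():g}); snapped to the "
            "nearest surface vertex",
            stacklevel=2,
        )

    passable = np.ones(len(uedges), dtype=bool)
    if block_angle_deg is not None:
        normals = triangle_normals(points, surface.faces)
        cos_thresh = np.cos(np.radians(block_angle_deg))
        for i in range(len(uedges)):
            g = fowners_s[bounds[i]:bounds[i + 1]]
            if len(g) == 2:
                if normals[g[0]] @ normals[g[1]] < cos_thresh:
                    passable[i] = False
            elif len(g) > 2:
                passable[i] = False

    n = len(verts)
    pe = uedges[passable]
    w = edge_len[passable]
    g = csr_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([pe[:, 0], pe[:, 1]]), np.concatenate([pe[:, 1], pe[:, 0]]))),
        shape=(n, n),
    )
    # face adjacency across passable edges, for patch confinement
    nf = surface.n_faces
    fa_rows, fa_cols = [], []
    for i in np.flatnonzero(passable):
        grp = fowners_s[bounds[i]:bounds[i + 1]]
        if len(grp) == 2:
            fa_rows += [grp[0], grp[1]]
            fa_cols += [grp[1], grp[0]]
    fgraph = csr_matrix(
        (np.ones(len(fa_rows)), (fa_rows, fa_cols)), shape=(nf, nf))

    vert_faces = [[] for _ in range(n)]
    for f, tri in enumerate(faces_local):
        for v in tri:
            vert_faces[v].append(f)

    limit = np.inf if max_edge_distance is None else float(max_edge_distance)
    seed_verts = np.unique(local_seed)
    d = np.atleast_2d(dijkstra(g, directed=False, indices=seed_verts))
    keep = np.zeros(nf, dtype=bool)
    from scipy.sparse.csgraph import breadth_first_order

    for row, sv in enumerate(seed_verts):
        reached = d[row] <= limit
        ok = reached[faces_local].all(axis=1)
        # faces reachable from the seed's incident faces via passable edges
        comp = np.zeros(nf, dtype=bool)
        for f0 in vert_faces[sv]:
            if comp[f0]:
                continue
            order_ = breadth_first_order(fgraph, f0, directed=False,
                                         return_predecessors=False)
            comp[order_] = True
        keep |= ok & comp
    return Surface(surface.faces[keep].copy(), surface.parent_point_count)


def euler_characteristic(surface: Surface) -> int:
    """V - E + F of a surface (2 for a closed topological sphere)."""
    f = surface.faces
    v = len(np.unique(f))
    e = len(np.unique(np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1), axis=0))
    return v - e + surface.n_faces
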