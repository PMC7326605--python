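"""Mesh-derived adjacency graphs and the manifold decomposition.

Smoothing a labeled volumetric mesh naively drags material interfaces and
feature lines around.  The decomposition implemented here classifies every
vertex as volume-interior, surface/interface, line (feature or patch
junction) or fixed point, and restricts the averaging neighborhood of each
vertex to its own manifold: surface vertices average only over their
interface patch, line vertices only along their line, and point vertices
never move.  The class ordering is VOLUME < SURFACE < LINE < POINT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    TETRA,
    TRIA,
    Mesh,
    ValidationError,
    triangle_normals,
)

# vertex classes, ordered
VOLUME, SURFACE, LINE, POINT = 0, 1, 2, 3
CLASS_NAMES = {VOLUME: "VOLUME", SURFACE: "SURFACE", LINE: "LINE", POINT: "POINT"}

#: pseudo-tag identifying the outside of the mesh in interface patch ids
OUTSIDE_TAG = -1

_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRI_EDGES = [(0, 1), (0, 2), (1, 2)]
# faces of a positively oriented tet, outward-facing vertex order
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


@dataclass
class MeshGraph:
    """Adjacency structures derived from mesh connectivity.

    All listings are sorted, so a graph built twice from the same mesh is
    bit-identical.
    """

    n_points: int
    node_to_elems: list  # per-node sorted ndarray of incident element ids
    unique_edges: np.ndarray  # (E, 2) with lo < hi, lexicographically sorted
    edge_to_elems: list  # per-edge sorted ndarray of incident element ids
    elem_to_elems: list  # face-sharing (tets) / edge-sharing (tris) neighbors

    def vertex_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR (indptr, indices) of the vertex-vertex edge graph."""
        e = self.unique_edges
        both = np.concatenate([e, e[:, ::-1]])
        order = np.lexsort((both[:, 1], both[:, 0]))
        both = both[order]
        counts = np.bincount(both[:, 0], minlength=self.n_points)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        return indptr, both[:, 1].copy()

    def edge_lengths(self, points: np.ndarray) -> np.ndarray:
        d = points[self.unique_edges[:, 0]] - points[self.unique_edges[:, 1]]
        return np.linalg.norm(d, axis=1)


def _element_edges(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """All (edge, element) incidences; edges as sorted (lo, hi) pairs."""
    chunks, owners = [], []
    ti, tc = mesh.tets()
    if len(ti):
        for a, b in _TET_EDGES:
            chunks.append(np.sort(tc[:, [a, b]], axis=1))
            owners.append(ti)
    ri, rc = mesh.tris()
    if len(ri):
        for a, b in _TRI_EDGES:
            chunks.append(np.sort(rc[:, [a, b]], axis=1))
            owners.append(ri)
    if not chunks:
        return np.empty((0, 2), dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(chunks), np.concatenate(owners)


def _group_by_key(keys: np.ndarray, values: np.ndarray):
    """Sort (key row, value) pairs and yield unique keys with grouped values."""
    order = np.lexsort(keys.T[::-1])
    k, v = keys[order], values[order]
    uniq, start = np.unique(k, axis=0, return_index=True)
    bounds = np.append(start, len(k))
    return uniq, [np.sort(v[bounds[i]:bounds[i + 1]]) for i in range(len(uniq))]


def build_graph(mesh: Mesh) -> MeshGraph:
    """Build the full adjacency graph of a mesh (deterministic ordering)."""
    npts = mesh.n_points
    # node -> elements
    node_to_elems = [np.empty(0, dtype=np.int64)] * npts
    verts, owners = [], []
    for idx, cn in (mesh.tets(), mesh.tris()):
        if len(idx):
            verts.append(cn.ravel())
            owners.append(np.repeat(idx, cn.shape[1]))
    if verts:
        verts = np.concatenate(verts)
        owners = np.concatenate(owners)
        order = np.lexsort((owners, verts))
        verts, owners = verts[order], owners[order]
        uniq, start = np.unique(verts, return_index=True)
        bounds = np.append(start, len(verts))
        for i, v in enumerate(uniq):
            node_to_elems[v] = owners[bounds[i]:bounds[i + 1]]

    edges, eowners = _element_edges(mesh)
    if len(edges):
        unique_edges, edge_to_elems = _group_by_key(edges, eowners)
    else:
        unique_edges, edge_to_elems = np.empty((0, 2), dtype=np.int64), []

    # element adjacency: tets via shared faces, triangles via shared edges
    elem_to_elems = [np.empty(0, dtype=np.int64)] * mesh.n_elems
    neigh = [[] for _ in range(mesh.n_elems)]
    ti, tc = mesh.tets()
    if len(ti):
        faces = np.sort(tc[:, TET_FACES].reshape(-1, 3), axis=1)
        fowners = np.repeat(ti, 4)
        ukeys, groups = _group_by_key(faces, fowners)
        for g in groups:
            if len(g) == 2:
                neigh[g[0]].append(g[1])
                neigh[g[1]].append(g[0])
    ri, rc = mesh.tris()
    if len(ri):
        tedges = np.sort(np.concatenate([rc[:, [a, b]] for a, b in _TRI_EDGES]), axis=1)
        towners = np.concatenate([ri] * 3)
        _, groups = _group_by_key(tedges, towners)
        for g in groups:
            for i in range(len(g)):
                for j in range(i + 1, len(g)):
                    neigh[g[i]].append(g[j])
                    neigh[g[j]].append(g[i])
    for e, lst in enumerate(neigh):
        if lst:
            elem_to_elems[e] = np.unique(np.array(lst, dtype=np.int64))

    return MeshGraph(npts, node_to_elems, unique_edges, edge_to_elems, elem_to_elems)


@dataclass
class ManifoldLabeling:
    """Per-vertex manifold class and restricted smoothing neighborhoods."""

    vertex_class: np.ndarray  # (n_points,) codes VOLUME/SURFACE/LINE/POINT
    vertex_patches: list  # per-vertex tuple of interface patch ids (tag pairs)
    neighbor_sets: list  # per-vertex sorted ndarray of averaging neighbors

    @property
    def n_points(self) -> int:
        return len(self.vertex_class)

    def neighbors_csr(self) -> tuple[np.ndarray, np.ndarray]:
        counts = np.fromiter((len(s) for s in self.neighbor_sets), dtype=np.int64,
                             count=self.n_points)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        if indptr[-1] == 0:
            return indptr, np.empty(0, dtype=np.int64)
        return indptr, np.concatenate([s for s in self.neighbor_sets if len(s)])

    def class_counts(self) -> dict:
        return {CLASS_NAMES[c]: int((self.vertex_class == c).sum())
                for c in (VOLUME, SURFACE, LINE, POINT)}


def interface_faces(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Oriented interface/boundary faces of a labeled mesh with patch ids.

    For a tetrahedral mesh the interface faces are the tet faces that either
    lie on the outer boundary (patch ``(tag, OUTSIDE_TAG)`` sorted descending
    as (tag, -1)) or separate two differently tagged tets (patch = sorted tag
    pair).  Boundary faces are oriented outward; internal interface faces are
    oriented away from the lower-tagged side.  For a triangle-only mesh every
    triangle is an interface face of patch ``(tag, tag)``.

    Returns ``(faces, patches)`` with faces ``(n, 3)`` oriented and patches
    ``(n, 2)``.
    """
    ti, tc = mesh.tets()
    if len(ti):
        faces = tc[:, TET_FACES].reshape(-1, 3)
        keys = np.sort(faces, axis=1)
        owners = np.repeat(ti, 4)
        order = np.lexsort(keys.T[::-1])
        keys_s, faces_s, owners_s = keys[order], faces[order], owners[order]
        uniq, start = np.unique(keys_s, axis=0, return_index=True)
        bounds = np.append(start, len(keys_s))
        out_faces, out_patches = [], []
        tags = mesh.tags
        for i in range(len(uniq)):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo == 1:
                out_faces.append(faces_s[lo])
                out_patches.append((tags[owners_s[lo]], OUTSIDE_TAG))
            elif hi - lo == 2:
                t0, t1 = tags[owners_s[lo]], tags[owners_s[lo + 1]]
                if t0 != t1:
                    # orient away from the lower-tagged tet
                    j = lo if t0 < t1 else lo + 1
                    out_faces.append(faces_s[j])
                    out_patches.append((min(t0, t1), max(t0, t1)))
            else:
                raise ValidationError("non-conforming mesh: face shared by >2 tets")
        if out_faces:
            return np.array(out_faces, dtype=np.int64), np.array(out_patches, dtype=np.int64)
        return np.empty((0, 3), dtype=np.int64), np.empty((0, 2), dtype=np.int64)
    # triangle-only: the mesh itself is the surface manifold
    ri, rc = mesh.tris()
    patches = np.stack([mesh.tags[ri], mesh.tags[ri]], axis=1)
    return rc.copy(), patches


def decompose_manifolds(
    mesh: Mesh,
    graph: Optional[MeshGraph] = None,
    feature_angle_deg: Optional[float] = 40.0,
) -> ManifoldLabeling:
    """Classify vertices into volume/surface/line/point manifolds.

    A vertex is VOLUME when it lies on no boundary or interface face,
    SURFACE when its incident interface faces all belong to one patch and no
    incident surface edge is a feature edge, LINE when it sits on a line of
    feature edges (patch junctions, open-surface rims, or edges whose
    adjacent face normals deviate by more than ``feature_angle_deg``), and
    POINT where line branches meet (any number of incident line edges other
    than exactly two pins the vertex).

    ``feature_angle_deg=None`` disables the angle-based feature test (useful
    for noisy but nominally smooth surfaces); patch junctions and
    open-surface rims still yield LINE vertices.
    """
    if graph is None:
        graph = build_graph(mesh)
    npts = mesh.n_points
    faces, patches = interface_faces(mesh)
    vclass = np.zeros(npts, dtype=np.int8)
    vpatches = [()] * npts
    nbr: list = [None] * npts

    if len(faces) == 0:
        # no surface at all: pure volume graph
        indptr, indices = graph.vertex_adjacency()
        for v in range(npts):
            nbr[v] = indices[indptr[v]:indptr[v + 1]]
        return ManifoldLabeling(vclass, vpatches, nbr)

    normals = triangle_normals(mesh.points, faces)
    # unique patch ids -> integers for fast grouping
    upatch, patch_idx = np.unique(patches, axis=0, return_inverse=True)

    # surface edges with incident faces
    fedges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    fowners = np.concatenate([np.arange(len(faces))] * 3)
    uedges, egroups = _group_by_key(fedges, fowners)

    cos_thresh = (None if feature_angle_deg is None
                  else np.cos(np.radians(feature_angle_deg)))
    line_edge = np.zeros(len(uedges), dtype=bool)
    edge_patches = []
    for i, g in enumerate(egroups):
        pids = np.unique(patch_idx[g])
        edge_patches.append(pids)
        if len(pids) > 1 or len(g) != 2:
            line_edge[i] = True
        elif cos_thresh is not None:
            if normals[g[0]] @ normals[g[1]] < cos_thresh:
                line_edge[i] = True

    on_surface = np.zeros(npts, dtype=bool)
    on_surface[np.unique(faces)] = True
    vclass[on_surface] = SURFACE

    # per-vertex patch sets
    vp_sets = [set() for _ in range(npts)]
    for pid in range(len(upatch)):
        for v in np.unique(faces[patch_idx == pid]):
            vp_sets[v].add(pid)

    # line-edge incidence per vertex
    n_line = np.zeros(npts, dtype=np.int64)
    line_nbrs: list = [[] for _ in range(npts)]
    le = uedges[line_edge]
    for a, b in le:
        n_line[a] += 1
        n_line[b] += 1
        line_nbrs[a].append(b)
        line_nbrs[b].append(a)
    vclass[n_line == 2] = LINE
    vclass[(n_line > 0) & (n_line != 2)] = POINT

    def patch_tuple(v):
        return tuple(map(tuple, upatch[sorted(vp_sets[v])]))

    # neighbor sets per class
    indptr, indices = graph.vertex_adjacency()
    # surface-edge adjacency restricted per patch: vertex -> {nbr} if the
    # connecting edge carries a face of the vertex's (single) patch
    surf_adj = [set() for _ in range(npts)]
    for i, (a, b) in enumerate(uedges):
        for pid in edge_patches[i]:
            surf_adj[a].add((b, pid))
            surf_adj[b].add((a, pid))

    for v in range(npts):
        c = vclass[v]
        if c == VOLUME:
            nbr[v] = indices[indptr[v]:indptr[v + 1]]
        elif c == SURFACE:
            pids = vp_sets[v]
            vpatches[v] = patch_tuple(v)
            nbr[v] = np.unique(np.array(
                [u for (u, pid) in surf_adj[v] if pid in pids], dtype=np.int64))
        elif c == LINE:
            vpatches[v] = patch_tuple(v)
            nbr[v] = np.unique(np.array(line_nbrs[v], dtype=np.int64))
        else:  # POINT: pinned
            vpatches[v] = patch_tuple(v)
            nbr[v] = np.empty(0, dtype=np.int64)
    return ManifoldLabeling(vclass, vpatches, nbr)
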