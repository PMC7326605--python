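"""Submesh extraction/insertion, data transfer, overlap extraction, merging.

The extraction/insertion pair enables the standard model-functionalization
loop: pull a tagged region out of a reference mesh (with an invertible index
mapping), manipulate it or data defined on it, and push the result back.
Overlap extraction selects the elements of one mesh lying within a given
distance of another mesh (e.g. the blood-pool volume around an implanted
device), returning the complement alongside; merging fuses two meshes with
vertex unification on shared interfaces.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    DataField,
    EmptySelectionError,
    IndexMapping,
    Mesh,
    MeshError,
    ValidationError,
)


class MappingStaleError(MeshError):
    """The submesh topology no longer matches the mapping (re-extract)."""


def _extract_by_elem_mask(mesh: Mesh, mask: np.ndarray) -> tuple[Mesh, IndexMapping]:
    elem_map = np.flatnonzero(mask)
    sub_conn = mesh.conn[elem_map]
    sub_etype = mesh.etype[elem_map]
    used = np.unique(sub_conn)
    used = used[used >= 0]
    node_map = used  # ascending: preserves relative vertex order
    remap = np.full(mesh.n_points, -1, dtype=np.int64)
    remap[node_map] = np.arange(len(node_map))
    new_conn = sub_conn.copy()
    pos = new_conn >= 0
    new_conn[pos] = remap[new_conn[pos]]
    sub = Mesh(
        mesh.points[node_map].copy(),
        new_conn,
        sub_etype.copy(),
        mesh.tags[elem_map].copy(),
        None if mesh.fibers is None else mesh.fibers[elem_map].copy(),
    )
    return sub, IndexMapping(node_map.copy(), elem_map)


def extract_submesh(mesh: Mesh, tag_set: Iterable[int]) -> tuple[Mesh, IndexMapping]:
    """Extract the elements carrying a tag in ``tag_set``.

    Vertices are renumbered compactly preserving their relative order; the
    returned mapping allows lossless re-insertion via
    :func:`insert_submesh` as long as the submesh topology is unchanged.
    """
    tag_set = sorted(set(int(t) for t in tag_set))
    mask = np.isin(mesh.tags, tag_set)
    if not mask.any():
        raise EmptySelectionError(f"no elements carry tags {tag_set}")
    return _extract_by_elem_mask(mesh, mask)


def insert_submesh(parent: Mesh, sub: Mesh, mapping: IndexMapping) -> Mesh:
    """Write a (topology-preserving) edited submesh back into its parent.

    Mapped node coordinates, element tags and fibers are overwritten from
    the submesh; everything else is untouched.  Raises
    :class:`MappingStaleError` when the submesh size no longer matches the
    mapping (e.g. after resampling — re-extract in that case).
    """
    mapping.validate(parent)
    if sub.n_points != len(mapping.node_map) or sub.n_elems != len(mapping.elem_map):
        raise MappingStaleError(
            f"submesh has {sub.n_points} points / {sub.n_elems} elements but the "
            f"mapping covers {len(mapping.node_map)} / {len(mapping.elem_map)}; "
            "re-extract after topology-changing edits"
        )
    out = parent.copy()
    out.points[mapping.node_map] = sub.points
    out.tags[mapping.elem_map] = sub.tags
    if sub.fibers is not None:
        if out.fibers is None:
            out.fibers = np.zeros((out.n_elems, 3))
        out.fibers[mapping.elem_map] = sub.fibers
    return out


def extract_data(field: DataField, mapping: IndexMapping) -> DataField:
    """Gather a parent-mesh data field onto a submesh through the mapping."""
    m = mapping.node_map if field.attachment == "node" else mapping.elem_map
    if len(field.values) <= (m.max() if len(m) else -1):
        raise ValidationError("field shorter than mapping target range")
    return DataField(field.attachment, field.values[m].copy())


def insert_data(parent_field: DataField, sub_field: DataField,
                mapping: IndexMapping) -> DataField:
    """Scatter a submesh data field back into a copy of the parent field."""
    if parent_field.attachment != sub_field.attachment:
        raise ValidationError("attachment mismatch between parent and submesh fields")
    m = mapping.node_map if sub_field.attachment == "node" else mapping.elem_map
    if len(sub_field.values) != len(m):
        raise ValidationError(
            f"submesh field length {len(sub_field.values)} does not match "
            f"mapping length {len(m)}"
        )
    out = parent_field.copy()
    out.values[m] = sub_field.values
    return out


def extract_overlap(msh1: Mesh, msh2: Mesh, size: float) -> tuple:
    """Split ``msh1`` into the part near ``msh2`` and the rest.

    An element of ``msh1`` belongs to the overlap when its centroid lies
    within distance ``size`` of any vertex of ``msh2`` (spatial-index
    accelerated).  Returns ``((overlap, overlap_mapping), (complement,
    complement_mapping))``; the two element sets partition ``msh1`` exactly.
    An empty overlap is legal (the complement is then all of ``msh1``).
    """
    if size < 0:
        raise ValidationError("size must be non-negative")
    cent = msh1.centroids()
    tree = cKDTree(msh2.points)
    d, _ = tree.query(cent)
    mask = d <= size
    overlap = _extract_by_elem_mask(msh1, mask) if mask.any() else (
        Mesh(np.empty((0, 3)), np.empty((0, 4), dtype=np.int64),
             np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)),
        IndexMapping(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)),
    )
    complement = _extract_by_elem_mask(msh1, ~mask) if (~mask).any() else (
        Mesh(np.empty((0, 3)), np.empty((0, 4), dtype=np.int64),
             np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)),
        IndexMapping(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)),
    )
    return overlap, complement


def default_merge_tolerance(msh1: Mesh, msh2: Mesh) -> float:
    """1e-6 of the joint bounding-box diagonal (scale-free unification)."""
    pts = [m.points for m in (msh1, msh2) if m.n_points]
    if not pts:
        return 0.0
    allp = np.vstack(pts)
    return 1e-6 * float(np.linalg.norm(allp.max(axis=0) - allp.min(axis=0)))


def merge_meshes(msh1: Mesh, msh2: Mesh, tolerance: Optional[float] = None) -> Mesh:
    """Concatenate two meshes, unifying near-coincident vertices.

    Every ``msh2`` vertex within ``tolerance`` of a ``msh1`` vertex is
    replaced by its nearest ``msh1`` vertex (ties broken towards the lowest
    ``msh1`` index); the remaining ``msh2`` vertices are appended.  ``msh1``
    entities keep their indices.  Raises :class:`~meshkit.core.ValidationError`
    when unification would produce an element with repeated vertices.
    """
    if tolerance is None:
        tolerance = default_merge_tolerance(msh1, msh2)
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    n1 = msh1.n_points
    vmap = np.arange(msh2.n_points, dtype=np.int64)
    keep = np.ones(msh2.n_points, dtype=bool)
    if n1 and msh2.n_points:
        tree = cKDTree(msh1.points)
        # k=2 so exact-distance ties resolve to the lowest msh1 index
        d, idx = tree.query(msh2.points, k=min(2, n1))
        d = np.atleast_2d(d.T).T
        idx = np.atleast_2d(idx.T).T
        near = d[:, 0] <= tolerance
        target = idx[:, 0].copy()
        if idx.shape[1] > 1:
            tie = near & (d[:, 1] == d[:, 0])
            target[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
        keep[near] = False
        vmap[near] = target[near]
    new_index = np.empty(msh2.n_points, dtype=np.int64)
    new_index[keep] = n1 + np.arange(int(keep.sum()))
    vmap[keep] = new_index[keep]

    points = np.vstack([msh1.points, msh2.points[keep]]) if msh2.n_points else msh1.points.copy()
    conn2 = msh2.conn.copy()
    pos = conn2 >= 0
    conn2[pos] = vmap[conn2[pos]]
    # degenerate elements from two msh2 vertices funneling into one msh1 vertex
    bad_ids = []
    for e in range(len(conn2)):
        k = msh2.etype[e]
        if len(set(conn2[e, :k])) != k:
            bad_ids.append(e)
    if bad_ids:
        raise ValidationError(
            f"merge tolerance {tolerance:g} unifies neighboring vertices of "
            f"msh2 element(s) {bad_ids[:10]} into one: degenerate elements"
        )
    conn = np.vstack([msh1.conn, conn2]) if len(conn2) else msh1.conn.copy()
    etype = np.concatenate([msh1.etype, msh2.etype])
    tags = np.concatenate([msh1.tags, msh2.tags])
    fibers = None
    if msh1.fibers is not None or msh2.fibers is not None:
        f1 = msh1.fibers if msh1.fibers is not None else np.zeros((msh1.n_elems, 3))
        f2 = msh2.fibers if msh2.fibers is not None else np.zeros((msh2.n_elems, 3))
        fibers = np.vstack([f1, f2])
    return Mesh(points, conn, etype, tags, fibers).validate()
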