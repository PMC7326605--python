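"""Mesh resolution change by edge bisection and guarded edge collapse.

The resampler runs two phases: first every edge longer than the maximum
target length is bisected (longest edge first; every element incident to
the edge is subdivided, so the mesh stays conforming), then every edge
shorter than the minimum target length is collapsed (shortest first).  A
collapse merges one endpoint into the other and deletes the elements that
become degenerate; it is dismissed when it would invert or over-degrade an
incident tetrahedron, rotate a boundary/interface face normal beyond a
threshold, pull a vertex off its manifold (volume vertices collapse into
surface vertices, surface into line, line into point — never the other way),
or cross the boundary of a tag restriction.  Short edges whose collapse is
dismissed are reported, not an error: the minimum size may not be
enforceable everywhere.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    TETRA,
    TRIA,
    DataField,
    Mesh,
    MeshError,
    ValidationError,
)
from .smoothing import QualityReport, quality_report, volume_edge_ratio
from .topology import (
    LINE,
    POINT,
    SURFACE,
    VOLUME,
    ManifoldLabeling,
    decompose_manifolds,
)

_TET_EDGE_IDX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_TRI_EDGE_IDX = [(0, 1), (0, 2), (1, 2)]
_TET_FACE_IDX = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]


@dataclass
class ResampleSpec:
    """Target edge-length range and safeguards for resampling.

    ``tag_restriction`` (a set of region tags, ``None`` = whole mesh)
    confines the operation: elements entirely outside the restriction and
    not touching its boundary are passed through bit-identically.
    ``normal_change_max_deg`` bounds the rotation any boundary or interface
    face normal may undergo in a collapse (shape preservation);
    ``quality_floor`` is the volume-edge-ratio below which a collapse may
    not drag an incident tetrahedron.
    """

    min_edge: Optional[float] = None
    max_edge: Optional[float] = None
    tag_restriction: Optional[frozenset] = None
    normal_change_max_deg: float = 25.0
    quality_floor: float = 0.05

    def __post_init__(self):
        if self.min_edge is not None and self.min_edge <= 0:
            raise ValidationError("min_edge must be positive")
        if self.max_edge is not None and self.max_edge <= 0:
            raise ValidationError("max_edge must be positive")
        if self.min_edge is not None and self.max_edge is not None:
            if not self.min_edge < self.max_edge:
                raise ValidationError("need min_edge < max_edge")
        if not 0.0 < self.normal_change_max_deg < 180.0:
            raise ValidationError("normal_change_max_deg must lie in (0, 180)")
        if not 0.0 <= self.quality_floor <= 1.0:
            raise ValidationError("quality_floor must lie in [0, 1]")
        if self.tag_restriction is not None:
            self.tag_restriction = frozenset(int(t) for t in self.tag_restriction)

    @classmethod
    def from_average(cls, avg_edge: float, **kw) -> "ResampleSpec":
        """Bracket a desired average edge length as ``[0.7 a, 1.4 a]``.

        The bracket is wide enough that both phases engage without fighting
        each other (splitting a 1.4a edge yields 0.7a, exactly the floor).
        """
        if avg_edge <= 0:
            raise ValidationError("average edge length must be positive")
        return cls(min_edge=0.7 * avg_edge, max_edge=1.4 * avg_edge, **kw)


@dataclass
class ResampleReport:
    """Before/after statistics of a resampling run."""

    n_elems_before: int
    n_elems_after: int
    edge_stats_before: tuple  # (min, mean, max)
    edge_stats_after: tuple
    n_splits: int = 0
    n_collapses: int = 0
    n_uncollapsible: int = 0
    quality_before: Optional[QualityReport] = None
    quality_after: Optional[QualityReport] = None


def _edge_stats(mesh: Mesh) -> tuple:
    from .topology import _element_edges

    edges, _ = _element_edges(mesh)
    if len(edges) == 0:
        return (math.nan, math.nan, math.nan)
    ue = np.unique(edges, axis=0)
    ln = np.linalg.norm(mesh.points[ue[:, 0]] - mesh.points[ue[:, 1]], axis=1)
    return (float(ln.min()), float(ln.mean()), float(ln.max()))


def _ekey(a: int, b: int) -> tuple:
    return (a, b) if a < b else (b, a)


class _Workspace:
    """Mutable mesh with incremental edge (and optional face) bookkeeping."""

    def __init__(self, mesh: Mesh, fields: Sequence[DataField] = (),
                 track_nodes: bool = False, track_faces: bool = False):
        mesh.validate()
        n = mesh.n_points
        cap = max(16, 2 * n)
        self.points = np.empty((cap, 3))
        self.points[:n] = mesh.points
        self.n_points = n
        self.point_alive = [True] * n
        self.conn = [tuple(int(v) for v in mesh.conn[e, : mesh.etype[e]])
                     for e in range(mesh.n_elems)]
        self.etype = list(map(int, mesh.etype))
        self.tags = list(map(int, mesh.tags))
        self.fibers = None if mesh.fibers is None else [tuple(f) for f in mesh.fibers]
        self.alive = [True] * mesh.n_elems
        self.node_fields = []
        self.elem_fields = []
        for f in fields:
            f.validate_against(mesh)
            vals = [np.array(v, dtype=float, ndmin=1) for v in f.values]
            (self.node_fields if f.attachment == "node" else self.elem_fields).append(vals)
        self.track_nodes = track_nodes
        self.track_faces = track_faces
        self.edge_elems: dict = {}
        self.face_elems: dict = {} if track_faces else None
        self.node_elems = [set() for _ in range(n)] if track_nodes else None
        for e in range(mesh.n_elems):
            self._register(e)

    # -- bookkeeping --------------------------------------------------------
    def _elem_edges(self, e: int):
        cn = self.conn[e]
        idx = _TET_EDGE_IDX if self.etype[e] == TETRA else _TRI_EDGE_IDX
        return [_ekey(cn[i], cn[j]) for i, j in idx]

    def _elem_faces(self, e: int):
        if self.etype[e] != TETRA:
            return []
        cn = self.conn[e]
        return [tuple(sorted((cn[i], cn[j], cn[k]))) for i, j, k in _TET_FACE_IDX]

    def _register(self, e: int):
        for k in self._elem_edges(e):
            self.edge_elems.setdefault(k, set()).add(e)
        if self.track_faces:
            for k in self._elem_faces(e):
                self.face_elems.setdefault(k, set()).add(e)
        if self.track_nodes:
            for v in self.conn[e]:
                self.node_elems[v].add(e)

    def _unregister(self, e: int):
        for k in self._elem_edges(e):
            s = self.edge_elems.get(k)
            if s is not None:
                s.discard(e)
                if not s:
                    del self.edge_elems[k]
        if self.track_faces:
            for k in self._elem_faces(e):
                s = self.face_elems.get(k)
                if s is not None:
                    s.discard(e)
                    if not s:
                        del self.face_elems[k]
        if self.track_nodes:
            for v in self.conn[e]:
                self.node_elems[v].discard(e)

    def add_point(self, p: np.ndarray) -> int:
        if self.n_points == len(self.points):
            grown = np.empty((2 * len(self.points), 3))
            grown[: self.n_points] = self.points[: self.n_points]
            self.points = grown
        i = self.n_points
        self.points[i] = p
        self.n_points += 1
        self.point_alive.append(True)
        if self.track_nodes:
            self.node_elems.append(set())
        return i

    def add_elem(self, conn, etype, tag, fiber, efield_vals) -> int:
        e = len(self.conn)
        self.conn.append(tuple(conn))
        self.etype.append(etype)
        self.tags.append(tag)
        if self.fibers is not None:
            self.fibers.append(fiber)
        self.alive.append(True)
        for vals, v in zip(self.elem_fields, efield_vals):
            vals.append(v)
        self._register(e)
        return e

    def kill_elem(self, e: int):
        self._unregister(e)
        self.alive[e] = False

    def edge_length(self, a: int, b: int) -> float:
        return float(np.linalg.norm(self.points[a] - self.points[b]))

    # -- export -------------------------------------------------------------
    def to_mesh(self) -> tuple[Mesh, list]:
        keep_e = [e for e in range(len(self.conn)) if self.alive[e]]
        # all surviving points are kept (a mesh may carry unreferenced points)
        used = [v for v in range(self.n_points) if self.point_alive[v]]
        remap = {v: i for i, v in enumerate(used)}
        pts = self.points[used]
        ne = len(keep_e)
        conn = np.full((ne, 4), -1, dtype=np.int64)
        etype = np.empty(ne, dtype=np.int8)
        tags = np.empty(ne, dtype=np.int64)
        fibers = None if self.fibers is None else np.empty((ne, 3))
        for i, e in enumerate(keep_e):
            cn = self.conn[e]
            for j, v in enumerate(cn):
                conn[i, j] = remap[v]
            etype[i] = self.etype[e]
            tags[i] = self.tags[e]
            if fibers is not None:
                fibers[i] = self.fibers[e]
        mesh = Mesh(pts, conn, etype, tags, fibers)
        fields = []
        for vals in self.node_fields:
            arr = np.array([vals[v] for v in used])
            fields.append(DataField("node", arr[:, 0] if arr.shape[1] == 1 else arr))
        for vals in self.elem_fields:
            arr = np.array([vals[e] for e in keep_e])
            fields.append(DataField("element", arr[:, 0] if arr.shape[1] == 1 else arr))
        return mesh, fields


# ---------------------------------------------------------------------------
# split phase
# ---------------------------------------------------------------------------

def _edge_eligible(ws: _Workspace, key: tuple, restrict) -> bool:
    if restrict is None:
        return True
    return any(ws.tags[e] in restrict for e in ws.edge_elems[key])


def _split(ws: _Workspace, max_edge: float, restrict) -> int:
    heap = []
    for (a, b) in ws.edge_elems:
        ln = ws.edge_length(a, b)
        if ln > max_edge:
            heapq.heappush(heap, (-ln, a, b))
    n_splits = 0
    while heap:
        negl, a, b = heapq.heappop(heap)
        key = (a, b)
        if key not in ws.edge_elems:
            continue  # edge vanished in an earlier split
        if -negl <= max_edge:
            continue
        if not _edge_eligible(ws, key, restrict):
            continue
        mid = 0.5 * (ws.points[a] + ws.points[b])
        m = ws.add_point(mid)
        for vals in ws.node_fields:
            vals.append(0.5 * (vals[a] + vals[b]))
        for e in sorted(ws.edge_elems[key]):
            cn = ws.conn[e]
            et, tag = ws.etype[e], ws.tags[e]
            fib = ws.fibers[e] if ws.fibers is not None else None
            ef = [vals[e] for vals in ws.elem_fields]
            ws.kill_elem(e)
            child1 = tuple(m if v == b else v for v in cn)
            child2 = tuple(m if v == a else v for v in cn)
            for child in (child1, child2):
                ws.add_elem(child, et, tag, fib, ef)
        n_splits += 1
        # only edges touching the new midpoint are new or changed
        for v in (a, b):
            k = _ekey(v, m)
            ln = ws.edge_length(*k)
            if ln > max_edge:
                heapq.heappush(heap, (-ln, *k))
        # opposite-vertex edges of the children
        for e in list(_incident_elems(ws, m)):
            for k in ws._elem_edges(e):
                if m in k and k != _ekey(a, m) and k != _ekey(b, m):
                    ln = ws.edge_length(*k)
                    if ln > max_edge:
                        heapq.heappush(heap, (-ln, *k))
    return n_splits


def _incident_elems(ws: _Workspace, v: int):
    if ws.track_nodes:
        return ws.node_elems[v]
    found = set()
    for k, elems in ws.edge_elems.items():
        if v in k:
            found |= elems
    return found


def split_long_edges(mesh: Mesh, spec: ResampleSpec, fields=None):
    """Bisect edges longer than ``spec.max_edge``, longest first.

    Every element incident to a split edge is subdivided (tet -> 2 tets,
    triangle -> 2 triangles), so conformity is maintained even across the
    boundary of a tag restriction; children inherit the parent's tag and
    fiber, node data fields are midpoint-interpolated.  Returns the new mesh
    (and the transported fields when ``fields`` is given).
    """
    if spec.max_edge is None:
        raise ValidationError("split requires spec.max_edge")
    ws = _Workspace(mesh, fields or (), track_nodes=True)
    _split(ws, spec.max_edge, spec.tag_restriction)
    out, new_fields = ws.to_mesh()
    return out if fields is None else (out, new_fields)


# ---------------------------------------------------------------------------
# collapse phase
# ---------------------------------------------------------------------------

def _tri_normal_area(p0, p1, p2):
    n = np.cross(p1 - p0, p2 - p0)
    a = np.linalg.norm(n)
    return (n / a if a > 0 else n), 0.5 * a


def _check_collapse(ws: _Workspace, a: int, b: int, spec: ResampleSpec,
                    vclass, vpatch):
    """Decide whether edge (a, b) may collapse; returns (src, dst, target)."""
    ca, cb = vclass[a], vclass[b]
    if ca == POINT and cb == POINT:
        return None
    key = _ekey(a, b)
    if spec.tag_restriction is not None:
        if any(ws.tags[e] not in spec.tag_restriction for e in ws.edge_elems[key]):
            return None  # edge touches the restriction boundary
    if ca == cb:
        if ca in (SURFACE, LINE) and vpatch[a] != vpatch[b]:
            return None
        src, dst = a, b
        target = 0.5 * (ws.points[a] + ws.points[b])
    elif ca < cb:
        src, dst, target = a, b, ws.points[b].copy()
    else:
        src, dst, target = b, a, ws.points[a].copy()

    dead = ws.edge_elems[key]
    affected = (ws.node_elems[a] | ws.node_elems[b]) - dead
    new_pos = {src: target, dst: target}

    def pos_of(v):
        return new_pos.get(v, ws.points[v])

    # a collapse may not stretch a surviving edge beyond the max target
    if spec.max_edge is not None:
        seen_v = set()
        for e in affected:
            for v in ws.conn[e]:
                if v in (src, dst) or v in seen_v:
                    continue
                seen_v.add(v)
                if np.linalg.norm(ws.points[v] - target) > spec.max_edge:
                    return None

    cosmax = math.cos(math.radians(spec.normal_change_max_deg))
    for e in affected:
        cn = ws.conn[e]
        new_cn = tuple(dst if v == src else v for v in cn)
        if ws.etype[e] == TETRA:
            old = np.array([ws.points[v] for v in cn])
            new = np.array([pos_of(v) for v in new_cn])
            av, bv, cv = new[1] - new[0], new[2] - new[0], new[3] - new[0]
            vol = float(av @ np.cross(bv, cv)) / 6.0
            if vol <= 0.0:
                return None
            q_new = volume_edge_ratio(new)
            if q_new < spec.quality_floor and q_new < volume_edge_ratio(old):
                return None
        else:  # standalone triangle: a surface element
            old = np.array([ws.points[v] for v in cn])
            new = np.array([pos_of(v) for v in new_cn])
            n_old, a_old = _tri_normal_area(*old)
            n_new, a_new = _tri_normal_area(*new)
            if a_new <= 1e-14 * max(a_old, 1e-300):
                return None  # degenerate triangle
            if float(n_old @ n_new) < cosmax:
                return None
    # boundary/interface face normal rotation (tets only)
    if ws.track_faces:
        seen = set()
        for e in affected:
            if ws.etype[e] != TETRA:
                continue
            for fkey in ws._elem_faces(e):
                if fkey in seen or (src not in fkey and dst not in fkey):
                    continue
                seen.add(fkey)
                incident = ws.face_elems[fkey]
                surviving = incident - dead
                if not surviving:
                    continue
                is_boundary = len(incident) == 1
                is_interface = (len(incident) == 2 and
                                len({ws.tags[t] for t in incident}) == 2)
                if not (is_boundary or is_interface):
                    continue
                old = np.array([ws.points[v] for v in fkey])
                new = np.array([pos_of(dst if v == src else v) for v in fkey])
                n_old, a_old = _tri_normal_area(*old)
                n_new, a_new = _tri_normal_area(*new)
                if a_new <= 0 or float(n_old @ n_new) < cosmax:
                    return None
    return src, dst, target


def _collapse(ws: _Workspace, spec: ResampleSpec, labeling: ManifoldLabeling) -> dict:
    vclass = list(labeling.vertex_class)
    vpatch = list(labeling.vertex_patches)
    min_edge = spec.min_edge
    heap = []
    for (a, b) in ws.edge_elems:
        ln = ws.edge_length(a, b)
        if ln < min_edge:
            heapq.heappush(heap, (ln, a, b))
    n_collapses = 0
    while heap:
        ln, a, b = heapq.heappop(heap)
        key = _ekey(a, b)
        if key not in ws.edge_elems:
            continue
        cur = ws.edge_length(a, b)
        if abs(cur - ln) > 1e-12 * (1.0 + cur):
            continue  # stale entry; the up-to-date one was pushed separately
        if cur >= min_edge:
            continue
        decision = _check_collapse(ws, a, b, spec, vclass, vpatch)
        if decision is None:
            continue
        src, dst, target = decision
        dead = sorted(ws.edge_elems[key])
        survivors = sorted(ws.node_elems[src] - set(dead))
        for e in dead:
            ws.kill_elem(e)
        for e in survivors:
            ws._unregister(e)
            ws.conn[e] = tuple(dst if v == src else v for v in ws.conn[e])
            ws._register(e)
        ws.points[dst] = target
        ws.point_alive[src] = False
        if vclass[src] == vclass[dst]:  # midpoint collapse: blend node data
            for vals in ws.node_fields:
                vals[dst] = 0.5 * (vals[src] + vals[dst])
        n_collapses += 1
        # edges touching dst changed length (dst may have moved) or identity
        for e in ws.node_elems[dst]:
            for k in ws._elem_edges(e):
                if dst in k:
                    ln2 = ws.edge_length(*k)
                    if ln2 < min_edge:
                        heapq.heappush(heap, (ln2, *k))
    n_short = sum(1 for (a, b) in ws.edge_elems if ws.edge_length(a, b) < min_edge)
    return {"n_collapses": n_collapses, "n_uncollapsible": n_short}


def collapse_short_edges(mesh: Mesh, spec: ResampleSpec, fields=None,
                         labeling: Optional[ManifoldLabeling] = None,
                         stats_out: Optional[dict] = None):
    """Collapse edges shorter than ``spec.min_edge``, shortest first.

    The manifold labeling (computed on the input mesh when not supplied)
    steers the collapse direction: a volume vertex is absorbed into a
    surface vertex, surface into line, line into point; equal classes on
    the same patch collapse to the edge midpoint, and point-point edges
    never collapse.  Dismissal conditions are documented on the module.
    ``stats_out``, when given, receives ``n_collapses`` and
    ``n_uncollapsible`` (short edges that survived).
    """
    if spec.min_edge is None:
        raise ValidationError("collapse requires spec.min_edge")
    if labeling is None:
        labeling = decompose_manifolds(mesh)
    if labeling.n_points != mesh.n_points:
        raise ValidationError("labeling does not match mesh")
    ws = _Workspace(mesh, fields or (), track_nodes=True,
                    track_faces=bool(mesh.tet_mask.any()))
    stats = _collapse(ws, spec, labeling)
    if stats_out is not None:
        stats_out.update(stats)
    out, new_fields = ws.to_mesh()
    return out if fields is None else (out, new_fields)


# ---------------------------------------------------------------------------
# combined driver
# ---------------------------------------------------------------------------

def resample(mesh: Mesh, spec: ResampleSpec, fields=None):
    """Split phase followed by collapse phase, with a statistics report.

    Returns ``(mesh, report)`` — or ``(mesh, fields, report)`` when data
    fields are transported.
    """
    if spec.min_edge is None and spec.max_edge is None:
        raise ValidationError("resample requires min_edge and/or max_edge")
    has_tets = bool(mesh.tet_mask.any())
    report = ResampleReport(
        n_elems_before=mesh.n_elems,
        n_elems_after=mesh.n_elems,
        edge_stats_before=_edge_stats(mesh),
        edge_stats_after=(math.nan,) * 3,
        quality_before=quality_report(mesh) if has_tets else None,
    )
    cur, cur_fields = mesh, fields
    if spec.max_edge is not None:
        ws = _Workspace(cur, cur_fields or (), track_nodes=True)
        report.n_splits = _split(ws, spec.max_edge, spec.tag_restriction)
        cur, out_fields = ws.to_mesh()
        cur_fields = out_fields if fields is not None else None
    if spec.min_edge is not None:
        labeling = decompose_manifolds(cur)
        stats: dict = {}
        res = collapse_short_edges(cur, spec, fields=cur_fields,
                                   labeling=labeling, stats_out=stats)
        if cur_fields is not None:
            cur, cur_fields = res
        else:
            cur = res
        report.n_collapses = stats["n_collapses"]
        report.n_uncollapsible = stats["n_uncollapsible"]
    report.n_elems_after = cur.n_elems
    report.edge_stats_after = _edge_stats(cur)
    if has_tets and cur.tet_mask.any():
        report.quality_after = quality_report(cur)
    if fields is not None:
        return cur, cur_fields, report
    return cur, report
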