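"""Shrinkage-free (Taubin) smoothing of meshes and data, with quality guards.

Plain Laplacian (Gaussian) smoothing contracts every quantity towards its
local average; applied to vertex coordinates this is seen as volume
shrinkage.  Taubin's scheme alternates a forward step towards the local
average (factor ``lambda > 0``) with a backward step away from it (factor
``mu < -lambda``), which acts as a low-pass filter on the mesh and leaves
the enclosed volume nearly unchanged.

When smoothing volumetric meshes, vertex averages are restricted by a
:class:`~meshkit.topology.ManifoldLabeling` so that interfaces stay on their
interface and feature lines stay on their line.  Optionally every update is
guarded by a tetrahedron quality metric: an update that would drag an
incident tet's quality below the threshold (or further down when already
below) is reverted for the offending vertices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix

from .core import DataField, Mesh, MeshError, ValidationError
from .topology import ManifoldLabeling, MeshGraph

VOLUME_EDGE_RATIO = "volume_edge_ratio"
MIN_DIHEDRAL_SINE = "min_dihedral_sine"

# dihedral angle of the regular tetrahedron: arccos(1/3) = 70.5288 deg
_SIN_REGULAR_DIHEDRAL = np.sqrt(8.0) / 3.0


@dataclass
class SmoothingParams:
    """Parameters of the two-step low-pass smoother.

    One iteration is one forward pass (``lambda_step``) followed by one
    backward pass (``mu_step``).  ``lambda_step + mu_step < 0`` is required;
    the defaults (0.5 / -0.53) give a pass-band ``1/lambda + 1/mu ~ 0.1`` in
    the usual transfer-function parametrization.  Setting ``mu_step`` to 0
    degrades the scheme to plain Laplacian smoothing (useful for
    comparisons; the pass-band condition is then waived).
    """

    lambda_step: float = 0.5
    mu_step: float = -0.53
    iterations: int = 100
    quality_threshold: Optional[float] = None
    metric: str = VOLUME_EDGE_RATIO

    def __post_init__(self):
        if not 0.0 < self.lambda_step < 1.0:
            raise ValidationError("lambda_step must lie in (0, 1)")
        if self.mu_step != 0.0 and self.lambda_step + self.mu_step >= 0.0:
            raise ValidationError("need mu_step < -lambda_step (low-pass condition)")
        if self.iterations < 0:
            raise ValidationError("iterations must be non-negative")
        if self.quality_threshold is not None and not 0.0 <= self.quality_threshold <= 1.0:
            raise ValidationError("quality_threshold must lie in [0, 1]")
        if self.metric not in (VOLUME_EDGE_RATIO, MIN_DIHEDRAL_SINE):
            raise ValidationError(f"unknown quality metric {self.metric!r}")


# ---------------------------------------------------------------------------
# tetrahedron quality metrics (scale-invariant, 1 = regular tet, 0 = flat)
# ---------------------------------------------------------------------------

def _tet_arrays(coords):
    c = np.asarray(coords, dtype=float)
    single = c.ndim == 2
    c = c.reshape(-1, 4, 3)
    return c, single


def volume_edge_ratio(coords) -> np.ndarray | float:
    """Quality ``q = 6*sqrt(2)*V / l_rms^3`` of tetrahedra.

    ``V`` is the unsigned volume and ``l_rms`` the root-mean-square of the
    six edge lengths; the normalization makes the regular tetrahedron score
    exactly 1.  Accepts one ``(4, 3)`` tet or an ``(n, 4, 3)`` stack.
    """
    c, single = _tet_arrays(coords)
    a, b, d = c[:, 1] - c[:, 0], c[:, 2] - c[:, 0], c[:, 3] - c[:, 0]
    vol = np.abs(np.einsum("ij,ij->i", a, np.cross(b, d))) / 6.0
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    l2 = np.stack([((c[:, i] - c[:, j]) ** 2).sum(axis=1) for i, j in pairs])
    lrms3 = np.maximum(l2.mean(axis=0), 0.0) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(lrms3 > 0, 6.0 * np.sqrt(2.0) * vol / lrms3, 0.0)
    q = np.clip(q, 0.0, 1.0)
    return float(q[0]) if single else q


def min_dihedral_sine(coords) -> np.ndarray | float:
    """Minimum dihedral sine quality of tetrahedra.

    Uses ``sin(theta_ij) = 3 V |e_ij| / (2 A_k A_l)`` for the dihedral angle
    along edge ij between the faces of areas ``A_k, A_l``; the minimum over
    the six edges is normalized by the regular tet's dihedral sine
    (``sin 70.5288... deg = 2*sqrt(2)/3``) and clipped to [0, 1].
    """
    c, single = _tet_arrays(coords)
    a, b, d = c[:, 1] - c[:, 0], c[:, 2] - c[:, 0], c[:, 3] - c[:, 0]
    vol = np.abs(np.einsum("ij,ij->i", a, np.cross(b, d))) / 6.0
    # face areas, face f = all vertices but f
    areas = np.empty((4, len(c)))
    face_verts = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    for f, (i, j, k) in enumerate(face_verts):
        areas[f] = 0.5 * np.linalg.norm(
            np.cross(c[:, j] - c[:, i], c[:, k] - c[:, i]), axis=1)
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    sins = np.empty((6, len(c)))
    for e, (i, j) in enumerate(pairs):
        k, l = (x for x in range(4) if x not in (i, j))
        elen = np.linalg.norm(c[:, i] - c[:, j], axis=1)
        denom = 2.0 * areas[l] * areas[k]  # faces opposite k and l contain edge ij
        with np.errstate(divide="ignore", invalid="ignore"):
            sins[e] = np.where(denom > 0, 3.0 * vol * elen / denom, 0.0)
    q = np.clip(sins.min(axis=0) / _SIN_REGULAR_DIHEDRAL, 0.0, 1.0)
    return float(q[0]) if single else q


_METRICS = {VOLUME_EDGE_RATIO: volume_edge_ratio, MIN_DIHEDRAL_SINE: min_dihedral_sine}


def tet_quality(mesh: Mesh, metric: str = VOLUME_EDGE_RATIO) -> np.ndarray:
    """Per-tetrahedron quality values (in the order of ``mesh.tets()``)."""
    _, tc = mesh.tets()
    if len(tc) == 0:
        raise MeshError("mesh contains no tetrahedra")
    return _METRICS[metric](mesh.points[tc])


@dataclass
class QualityReport:
    """Element-quality summary of a tetrahedral mesh."""

    metric: str
    per_elem: np.ndarray
    min: float
    mean: float
    histogram: np.ndarray  # counts over uniform bins on [0, 1]
    bin_edges: np.ndarray

    def __str__(self):
        return (f"quality[{self.metric}]: min={self.min:.4f} mean={self.mean:.4f} "
                f"n={len(self.per_elem)}")


def quality_report(mesh: Mesh, metric: str = VOLUME_EDGE_RATIO, bins: int = 20) -> QualityReport:
    """Quality metric map, min/mean and histogram over the tetrahedra."""
    q = tet_quality(mesh, metric)
    hist, edges = np.histogram(q, bins=bins, range=(0.0, 1.0))
    return QualityReport(metric, q, float(q.min()), float(q.mean()), hist, edges)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _averaging_operator(indptr, indices, n):
    counts = np.diff(indptr)
    data = np.ones(indptr[-1])
    nz = counts > 0
    inv = np.zeros(n)
    inv[nz] = 1.0 / counts[nz]
    A = csr_matrix((data, indices, indptr), shape=(n, n))
    return A, inv, nz


def _passes(params: SmoothingParams):
    steps = [params.lambda_step]
    if params.mu_step != 0.0:
        steps.append(params.mu_step)
    return steps


def taubin_smooth(mesh: Mesh, labeling: ManifoldLabeling, params: SmoothingParams) -> Mesh:
    """Low-pass smooth vertex coordinates, restricted by the manifold labeling.

    Each pass displaces every movable vertex by ``step * (mean(neighbors) -
    position)`` using the neighbor sets of ``labeling`` (Jacobi-style: all
    averages are taken at the positions from the start of the pass, so the
    result is independent of vertex ordering).  POINT vertices never move.

    With ``params.quality_threshold`` set, after each pass the vertices
    incident to any tetrahedron whose quality would cross below the
    threshold (or decrease while already below it) are reverted to their
    pre-pass position; the revert loop repeats until no violation remains,
    so the final mesh satisfies ``min quality >= min(threshold, initial
    min quality)``.
    """
    if labeling.n_points != mesh.n_points:
        raise ValidationError("labeling does not match mesh point count")
    out = mesh.copy()
    if params.iterations == 0:
        return out
    n = mesh.n_points
    indptr, indices = labeling.neighbors_csr()
    A, inv, movable = _averaging_operator(indptr, indices, n)

    guard = params.quality_threshold is not None and mesh.tet_mask.any()
    if guard:
        _, tc = out.tets()
        metric = _METRICS[params.metric]
        thr = params.quality_threshold
        # only tets touching a movable vertex can change
        active = movable[tc].any(axis=1)
        tc_a = tc[active]

    pos = out.points
    for _ in range(params.iterations):
        for step in _passes(params):
            avg = A @ pos
            prop = pos.copy()
            prop[movable] += step * (avg[movable] * inv[movable, None] - pos[movable])
            if guard and len(tc_a):
                q_old = metric(pos[tc_a])
                while True:
                    q_new = metric(prop[tc_a])
                    bad = (q_new < thr) & ((q_old >= thr) | (q_new < q_old))
                    if not bad.any():
                        break
                    verts = np.unique(tc_a[bad])
                    if np.array_equal(prop[verts], pos[verts]):
                        break
                    prop[verts] = pos[verts]
            pos = prop
    out.points = pos
    return out


def smooth_data(field: DataField, graph: MeshGraph, params: SmoothingParams) -> DataField:
    """Low-pass smooth a nodal data field over the mesh edge graph.

    The same forward/backward passes as :func:`taubin_smooth`, applied
    componentwise to scalar or 3-vector node data; element data is not
    supported.
    """
    if field.attachment != "node":
        raise MeshError("only node-attached data can be smoothed")
    if len(field) != graph.n_points:
        raise ValidationError("field length does not match graph point count")
    indptr, indices = graph.vertex_adjacency()
    A, inv, movable = _averaging_operator(indptr, indices, graph.n_points)
    vals = field.values.astype(float).copy()
    flat = vals.ndim == 1
    if flat:
        vals = vals[:, None]
    for _ in range(params.iterations):
        for step in _passes(params):
            avg = A @ vals
            vals = vals.copy()
            vals[movable] += step * (avg[movable] * inv[movable, None] - vals[movable])
    return DataField(field.attachment, vals[:, 0] if flat else vals)
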