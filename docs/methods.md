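# Methods

This note records the models, algorithms and numerical choices behind
meshkit, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Mesh model

A mesh is a flat array of 3D vertex coordinates plus a mixed element list of
tetrahedra and triangles, each with an integer region tag (the label field
inherited from multi-label segmentation) and optionally a per-element fiber
vector. Indexing is 0-based everywhere; file formats convert at the
boundary. Only tets and triangles are representable — readers reject other
element kinds explicitly, since every algorithm here (bisection, collapse,
quality metrics, manifold decomposition) is formulated for simplices.

Tetrahedra are always stored with positive signed volume; readers reorder
the vertices of negative tets and log the count. This makes inversion
detection during collapse and smoothing a plain sign test, and gives
boundary faces a canonical outward orientation (the face ordering of a
positive tet points away from the opposite vertex).

Fiber vectors are opaque payload: splits copy the parent's fiber to both
children, collapses keep the surviving element's fiber, merges concatenate.
No fiber math is performed. Coordinates are likewise opaque lengths — every
threshold that takes a length (edge targets, merge tolerance, traversal
distance, overlap size) is in the units of the input coordinates.

## Manifold decomposition

Smoothing a labeled volume must not let material interfaces drift. The
decomposition classifies vertices by the interface faces around them:

* *interface faces* are tet faces with multiplicity 1 among all tets (outer
  boundary; patch id `(tag, OUTSIDE)`) or multiplicity 2 with two distinct
  tags (patch id = the sorted tag pair). In a triangle-only mesh every
  triangle is an interface face of its tag's patch.
* an edge of the interface is a *line edge* when its incident faces belong
  to more than one patch, when it is non-manifold or open (≠ 2 faces), or
  when the two adjacent face normals deviate by more than the feature angle
  (default 40°, chosen to separate the fixtures' 90° creases from smoothly
  curved patches with margin; `None` disables the geometric test, which is
  the right setting for noisy but nominally smooth surfaces, where noise
  would otherwise be misread as feature lines and pinned).
* vertex classes: VOLUME (no interface face), SURFACE (one patch, no line
  edge), LINE (exactly two incident line edges — the interior of a line),
  POINT (any other line-edge count: junctions and endpoints; also corners).

Averaging neighborhoods follow the class: volume vertices average over all
edge neighbors, surface vertices only over neighbors across faces of their
own patch, line vertices only over their two line neighbors, and point
vertices are pinned. Classes are totally ordered VOLUME < SURFACE < LINE <
POINT and every neighborhood only contains vertices of equal or higher
class, so smoothing can never pull a constraint vertex off its manifold.

## Two-step low-pass smoothing

Each iteration applies two Jacobi-style passes over positions `x_i`:

    x_i <- x_i + s * (mean_{j in N(i)} x_j - x_i),   s = λ then s = μ,

with defaults λ = 0.5, μ = −0.53 (the widely used parameter pair; pass-band
`1/λ + 1/μ ≈ 0.11` in the usual transfer-function form). Setting μ = 0
degrades to plain Laplacian smoothing, kept as an explicit comparison mode
because the volume-preservation claim is defined against it. Updates are
synchronous (computed from the pass-start positions), so results are
independent of vertex ordering and exactly reproducible.

One property worth documenting: the per-mode gain `f(k) = (1 − λk)(1 − μk)`
slightly exceeds 1 for frequencies below the pass-band, so very long
smoothing runs *inflate* smooth low-frequency geometry instead of shrinking
it. On a 2562-vertex noisy icosphere, 200 iterations change the enclosed
volume by about +5% (the clean sphere drifts identically, so this is the
filter, not the noise), while 200 pure-Laplacian iterations destroy ~57% of
the volume. The package asserts the *relative* property (the two-step
scheme always loses strictly less volume than plain averaging at equal
iteration counts, tested at 10/50/200 iterations); absolute drift depends
on iteration count and mesh density and is reported, not hidden. The
implementation was cross-checked against an independent Taubin filter and
agrees to floating-point round-off.

With a quality threshold `q_thr` set, after every pass the tets whose
volume-edge ratio would fall below `q_thr` — or decrease further while
already below it — have their vertices reverted to the pass-start
positions, repeating until no violation remains (the reverted set grows
monotonically, so this terminates). The guarantee is exactly `min q after ≥
min(q_thr, min q before)`. Reverting (rather than step-clamping) was chosen
because it needs no line search and keeps the guarantee exact. Quality
tracking applies to tetrahedral meshes only.

Data smoothing applies the same passes componentwise to scalar or 3-vector
node data over the plain edge graph; element data is out of scope.

## Tetrahedron quality metrics

* volume-edge ratio: `q = 6√2 · V / l_rms³` with `l_rms` the RMS of the six
  edge lengths; scale-invariant, 1 for the regular tet, 0 for degenerate.
* minimum dihedral sine: `sin θ_ij = 3 V |e_ij| / (2 A_k A_l)` per edge,
  minimized over the six edges and normalized by the regular tet's dihedral
  sine `sin 70.5288° = 2√2/3`, clipped to [0, 1].

Both are vectorized over element stacks; degenerate inputs score 0 rather
than raising, because the metrics are used inside guards where degeneracy
is an expected intermediate state.

## Resampling

Strict two phases (split, then collapse), each a priority queue:

* **Split** bisects the longest eligible edge above `max_edge` at its
  midpoint; every incident element is subdivided (tet → 2 tets, triangle →
  2 triangles), including elements outside a tag restriction, which is what
  keeps the mesh conforming across the restriction boundary. Children
  inherit tag and fiber; node data is midpoint-interpolated. New edge
  lengths never exceed the current maximum, so the longest-first order
  terminates.
* **Collapse** merges the endpoints of the shortest edge below `min_edge`.
  Direction follows the manifold classes (volume collapses into surface
  into line into point; equal classes on the same patch collapse to the
  midpoint; point–point edges never collapse, preserving corners). A
  candidate is dismissed when any surviving incident tet would invert or
  fall below the quality floor while getting worse, when a
  boundary/interface face normal would rotate beyond the shape threshold,
  when a surviving edge would be stretched beyond `max_edge` (this is what
  keeps "no edge above the maximum" true after the collapse phase), or when
  the edge touches elements outside the tag restriction. Dismissed short
  edges are counted and reported — the minimum target is best-effort by
  construction. Every successful collapse removes at least one element, so
  the phase terminates. Manifold classes are computed once at phase start;
  they are conservative labels, not re-derived mid-phase.

Defaults: normal change ≤ 25°, quality floor 0.05 — permissive enough that
ordinary coarsening proceeds, strict enough that the constructed
inversion/flip cases are all rejected. A user-supplied *average* target `a`
maps to the bracket `[0.7a, 1.4a]`: bisecting a 1.4a edge lands exactly on
the 0.7a floor, so the phases do not fight each other.

Edge eligibility under a tag restriction: an edge is split-eligible if any
incident element is in the restriction (boundary edges included, since all
incident elements get subdivided anyway), and collapse-eligible only if all
incident elements are in the restriction. Elements entirely outside the
restriction and not incident to its boundary pass through bit-identically.

## Surface operations

Boundary surfaces are face-multiplicity-1 sets over the selected tets,
oriented outward from the selection. Set algebra works on canonical face
keys (sorted vertex triples); orientation is taken from the first operand;
output ordering is sorted by key for determinism.

Seeded traversal snaps each seed coordinate to the nearest surface vertex
(warning beyond a snap radius defaulting to the longest surface edge),
computes edge-graph shortest paths with Euclidean weights, and keeps a face
when (a) all three vertices were reached within the distance budget and
(b) the face is connected to the seed's incident faces through *passable*
edges. An edge is impassable when its two adjacent face normals deviate by
more than the blocking angle. Condition (b) matters: rim vertices of a
crease belong to both sides, so a purely vertex-based cut would leak around
sharp edges; requiring face connectivity across passable edges confines the
result to the seeded patch exactly. Distances are geodesics along edges
(metric, not hop count). The all-vertices-reached rule is the conservative
reading; with an unlimited budget it reduces to the seed's edge-connected
component.

## Submeshes, overlap, merging

Extraction renumbers vertices compactly in ascending parent order and
returns injective node/element maps; insertion requires the submesh to have
unchanged counts (a stale mapping after resampling is an explicit error
telling the user to re-extract). Overlap extraction marks the elements of
one mesh whose centroid lies within a given distance of any vertex of the
other (k-d tree accelerated; verified against the all-pairs oracle in
tests); overlap and complement always partition the input exactly. Merging
appends the second mesh, unifying each of its vertices within the tolerance
of a first-mesh vertex (nearest wins, exact ties to the lowest index;
default tolerance 1e-6 of the joint bounding-box diagonal, i.e. scale-free
bit-near-identity). Unification that would degenerate an element is a hard
error naming the elements.

## File formats

CARP text (`.pts/.elem/.lon`, 0-based indices, `Tt`/`Tr` rows), VTK legacy
ASCII unstructured grids (cell types 10/5, integer `SCALARS tags`, optional
`VECTORS fibers`), `.surf/.vtx` surface pairs (the `intra` keyword is a
compatibility token with no semantics here) and `.dat/.vec` data files.
Coordinates are written in shortest-round-trip decimal by default (a fixed
significant-digit count is available), so read∘write is the identity on
every array and a second write is byte-identical — this is what the
round-trip and bit-stability tests assert. Binary VTK is deliberately out
of scope (ASCII keeps the artifacts diffable and exactly testable); a
`vtk_bin`/`vtk` format flag is accepted and maps to ASCII.

## Synthetic fixtures and what they show

* `box_tet_mesh`: structured cubes split into 6 tets (Kuhn), tags by
  axis-aligned planes. Exercises conforming splits/collapses, interfaces,
  corners and flat patches with exactly known counts and volumes.
* `shell_with_cavity`: a cube grid warped so that every L∞ lattice shell
  maps onto a sphere; the inner radius snaps to a lattice shell, so the
  cavity/tissue interface is an exactly spherical, conforming surface —
  which is why the interface-reconstruction checks can demand exact
  set equality.
* `rod_surface` / `icosphere`: closed oriented triangle surfaces with known
  enclosed volumes.
* `jitter`: seeded iid Gaussian vertex noise, corners pinned.

These fixtures have exact interfaces, uniform sizing and noise that is
truly iid — real image-derived meshes have none of those properties
(staircase interfaces, graded sizing, spatially correlated segmentation
error). Passing the suite therefore demonstrates the *contracts*
(conformity, guards, invariants, exact set algebra, round trips), not
fidelity on any particular anatomy. Fixture sizes in the default test and
acceptance runs (≈2.5k-vertex spheres, ≈10k–30k-tet boxes) were chosen as
the smallest sizes at which every phenomenon of interest (guard
activations, dismissed collapses, distinct per-region targets) actually
occurs.

## Numerical choices and edge cases

* Strict inequality `volume ≤ 0` rejects a collapse; no epsilon slack — the
  fixtures are scaled O(1) and the metrics are scale-invariant.
* Heap entries are lazily invalidated: an entry is discarded when its edge
  no longer exists or its stored length disagrees with the recomputed one
  (a fresh entry is pushed whenever an endpoint moves).
* Degenerate triangles have no normal; `triangle_normal` raises, while the
  vectorized `triangle_normals` returns a zero vector (callers treat zero
  area as "dismiss").
* `enclosed_volume` validates closedness and orientation (every directed
  edge exactly once) before integrating, so a silently open surface cannot
  produce a plausible-looking number.
* Ties in merge unification are broken toward the lowest first-mesh index
  by querying the two nearest candidates.

## Known limitations

* No edge flips, Delaunay refinement, or sizing fields: resolution control
  is purely bisection/collapse, so anisotropic targets are out of reach.
* Volumetric mesh *generation* (meshing the inside of surfaces) is out of
  scope; the device-integration pipeline demonstrates the surrounding
  machinery with a relabeled stand-in for the re-meshed region.
* Manifold labels are frozen during a collapse phase; pathological inputs
  where a collapse changes the interface topology mid-phase could be
  over-permissive (the geometric guards still apply).
* Tensor-valued data, element-data smoothing, hexahedra/prisms/pyramids,
  binary and XML VTK are unsupported by design.
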