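"""Landmark surface extraction by set algebra and seeded traversal.

Builds a two-label ball (tissue shell around a blood-pool cavity), then
constructs the "endocardium" as the set intersection of the tissue boundary
and the cavity boundary, and isolates one flat patch of a box with a
crease-blocking traversal — the two ways anatomical landmark surfaces are
cut out of labeled meshes.
"""

import numpy as np

import meshkit as mk
from meshkit import synth

shell = synth.shell_with_cavity(radius_outer=1.0, radius_inner=0.5, refinement=4)
tissue = mk.extract_boundary_surface(shell, {2})     # outer + cavity spheres
pool = mk.extract_boundary_surface(shell, {1})       # cavity sphere
endo = mk.surface_intersection(tissue, pool)         # their shared faces

print(f"tissue boundary: {tissue.n_faces} faces (two closed spheres)")
print(f"cavity boundary: {pool.n_faces} faces")
print(f"endocardium = intersection: {endo.n_faces} faces, "
      f"Euler characteristic {mk.euler_characteristic(endo)}")
r = np.linalg.norm(shell.points[endo.vertex_set], axis=1)
print(f"endocardial vertices sit at radius {r.min():.6f}..{r.max():.6f}")
# Euler characteristic 2 says the interface is a single closed sphere; the
# radius range confirms it is exactly the labeled cavity interface.

box = synth.box_tet_mesh(4, 4, 4)
outer = mk.extract_boundary_surface(box, {1})
patch = mk.restrict_by_traversal(outer, box.points, seeds=[[2.0, 2.0, 0.0]],
                                 block_angle_deg=45.0)
print(f"\nbox boundary: {outer.n_faces} faces; "
      f"seeded traversal with 45 deg blocking keeps {patch.n_faces} "
      "(exactly the seeded bottom face)")
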