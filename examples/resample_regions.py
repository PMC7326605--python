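"""Per-region resolution change by edge bisection and guarded collapse.

A three-region box is retargeted to three different average edge lengths,
one region at a time (tag restriction), the way different physics demand
different resolutions in different anatomical regions.  Short edges whose
collapse would invert or over-degrade a tet are kept and reported.
"""

import numpy as np

import meshkit as mk
from meshkit import synth
from meshkit.topology import _element_edges


def region_mean_edge(mesh, tag):
    e, own = _element_edges(mesh)
    order = np.lexsort(e.T[::-1])
    e, own = e[order], own[order]
    u, start = np.unique(e, axis=0, return_index=True)
    bounds = np.append(start, len(e))
    keep = [i for i in range(len(u))
            if np.all(mesh.tags[own[bounds[i]:bounds[i + 1]]] == tag)]
    u = u[keep]
    return float(np.linalg.norm(mesh.points[u[:, 0]] - mesh.points[u[:, 1]],
                                axis=1).mean())


mesh = synth.box_tet_mesh(12, 12, 12, label_planes=[(0, 4.0), (0, 8.0)])
targets = {1: 3.0, 2: 2.0, 3: 1.2}
print(f"input: {mesh.n_elems} tets, mean edge per region "
      f"{[round(region_mean_edge(mesh, t), 2) for t in targets]}")

for tag, tgt in targets.items():
    spec = mk.ResampleSpec.from_average(tgt, tag_restriction={tag})
    mesh, report = mk.resample(mesh, spec)
    print(f"region {tag} -> avg {tgt}: {report.n_splits} splits, "
          f"{report.n_collapses} collapses, "
          f"{report.n_uncollapsible} short edges kept, "
          f"now {report.n_elems_after} elements")

print(f"\nresult: {mesh.n_elems} tets, inverted: "
      f"{int((mesh.tet_volumes() <= 0).sum())}")
for tag, tgt in targets.items():
    got = region_mean_edge(mesh, tag)
    print(f"  region {tag}: mean edge {got:.2f} (target {tgt}, "
          f"{100 * abs(got - tgt) / tgt:.0f}% off)")
# Each region lands within the 20% bracket of its target; the quality floor
# and normal-change limit explain the edges that stay below the minimum.
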