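"""Shrinkage-free smoothing: two-step low-pass vs plain averaging.

Jitters an icosphere and smooths it 200 iterations two ways.  The forward/
backward (Taubin) scheme keeps the enclosed volume within a few percent;
plain forward averaging (the mu=0 degenerate case) collapses the sphere
toward its centroid.
"""

import meshkit as mk
from meshkit import synth

ico = synth.icosphere(radius=1.0, subdivisions=4)   # 2562 vertices
ref = mk.surface_from_triangles(ico)
v0 = mk.enclosed_volume(ref, ico.points)

noisy = synth.jitter(ico, sigma=0.02, seed=7)
labeling = mk.decompose_manifolds(noisy, feature_angle_deg=None)

taubin = mk.taubin_smooth(noisy, labeling, mk.SmoothingParams(0.5, -0.53, 200))
laplace = mk.taubin_smooth(noisy, labeling, mk.SmoothingParams(0.5, 0.0, 200))

vt = mk.enclosed_volume(ref, taubin.points)
vl = mk.enclosed_volume(ref, laplace.points)
print(f"clean sphere volume:        {v0:.4f}")
print(f"after 200 Taubin iters:     {vt:.4f}  ({100 * abs(vt - v0) / v0:.1f}% change)")
print(f"after 200 Laplacian iters:  {vl:.4f}  ({100 * abs(vl - v0) / v0:.1f}% change)")
# The Laplacian run loses over half the volume; the low-pass run keeps it to
# a few percent (a slight inflation: the scheme's pass-band gain is
# marginally above 1, which compounds over hundreds of iterations).
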