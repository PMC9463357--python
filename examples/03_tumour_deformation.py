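"""The radial tumour mass-effect warp and its closed-form inverse.

A 10 mm spherical tumour sits off-centre in an ellipsoidal brain.  The
decay factor k falls from 1 at the tumour centre to 0 at the brain
surface; lambda controls how localised the push is; lambda_max is the
largest value for which the lesion fully evacuates its own interior.
The Lambert-W inverse lets images be deformed by exact pull-back.
"""

import numpy as np

from tractfinder.deformation import (
    DeformationParams,
    RadialGeometry,
    forward_warp,
    inverse_warp,
    k_factor,
    lambda_max,
)
from tractfinder.synthetic import PhantomSpec, make_phantom_masks

spec = PhantomSpec()
brain, tumour = make_phantom_masks(spec)
geom = RadialGeometry(brain, tumour)
print(f"tumour centre of mass S = {geom.S} mm")

print("\ndecay factor along the +x ray (D_b = distance S to brain surface):")
d = np.array([[1.0, 0.0, 0.0]])
D_t, D_b = geom.ray_distances(d)
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    print(f"  D_p/D_b = {frac:.2f}:  k = {k_factor(frac * D_b[0], D_b[0], 2.0):.5f}")

lm = lambda_max(D_t[0], D_b[0])
print(f"\nalong +x: D_t = {D_t[0]:.1f} mm, D_b = {D_b[0]:.1f} mm, lambda_max = {lm:.3f}")
print("(larger lambda would leave original tissue inside the lesion boundary)")

params = DeformationParams("auto")  # lambda = lambda_max per ray
rng = np.random.default_rng(0)
pts = rng.uniform(-1, 1, size=(5000, 3)) * [38, 28, 28]
pts = pts[np.sum((pts / [40, 30, 30]) ** 2, axis=1) < 0.9]
round_trip = inverse_warp(forward_warp(pts, geom, params), geom, params)
print(f"\nwarp round-trip over {len(pts)} brain points: "
      f"max |f^-1(f(P)) - P| = {np.abs(round_trip - pts).max():.2e} mm")
print("-> the Lambert-W inverse reproduces sources to numerical precision,")
print("   so atlases can be deformed by pull-back without numerical inversion.")
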