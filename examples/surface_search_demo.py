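"""Optimal-surface search and convex-hull BM estimation on toy inputs.

The single-surface graph search returns the globally cheapest height map
under a hard smoothness bound; Bruch's membrane is then the lower convex
hull boundary of the (possibly arched) RPE floor trace.
"""

import numpy as np

from pedseg import estimate_bm, single_surface_search
from pedseg.io import Surface
from pedseg.layers import SurfaceSearchSpec

# four columns, three depths; the cheap voxels trace a step the surface
# must follow while never jumping more than delta_x = 1 between columns
cost = np.array(
    [[5, 1, 5], [5, 1, 5], [5, 5, 1], [5, 5, 1]], dtype=float
)[:, None, :]
surface = single_surface_search(cost, SurfaceSearchSpec(delta_x=1))
print("optimal surface z(x):", surface.heights.ravel().tolist())
# -> [1, 1, 2, 2]: total cost 4, the minimum over all smooth surfaces

# an arch in the RPE floor (z decreases upward) is bridged by the hull
rpe = Surface("RPE_FLOOR", np.array([[30, 30, 24, 22, 24, 30, 30]]).T)
bm = estimate_bm(rpe)
print("RPE floor trace:     ", rpe.heights.ravel().tolist())
print("estimated BM baseline:", bm.heights.ravel().tolist())
# the PED candidate region is the slab between the two lines
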