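"""Build the coarse-grained homodimer and its ninefold ring.

The local bonding rules (center-to-center and torsion vectors with a 40°
spoke angle) force a planar ring of exactly nine homodimers whose hub
matches the ~23 nm cartwheel hub.
"""

import math

import numpy as np

from cartwheel.geometry import (
    GeometryClosureError,
    RigidTransform,
    assemble_ideal_ring,
    build_homodimer,
    hub_diameter,
)

model = build_homodimer()
print(f"beads per homodimer : {len(model.beads)} "
      f"(N-term R = {model.beads[0].radius} nm, coiled-coil R = {model.beads[2].radius} nm)")

step = model.bound_step()
t = RigidTransform.identity()
for _ in range(9):
    t = t.compose(step)
d_trans, d_rot = t.deviation_from_identity()
print(f"9-fold closure residual : {d_trans:.2e} nm / {math.degrees(d_rot):.2e} deg")

ring = assemble_ideal_ring(9)
pts = ring.world_n_term_centers()
print(f"hub diameter            : {hub_diameter(ring):.2f} nm  (cartwheel hub ~23 nm)")
print(f"ring planarity (z range): {np.ptp(pts[:, 2]):.2e} nm")

for n in (8, 10):
    try:
        assemble_ideal_ring(n)
    except GeometryClosureError as exc:
        print(f"n = {n:2d}: {exc}")
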