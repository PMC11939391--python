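"""Build a pinned fascia sheet and let it settle under gravity.

The sheet is a triangulated grid with distance (stretch) and dihedral
(bending) constraints; the perimeter is pinned and gravity pulls the interior
down until the constraint projection balances it.
"""

import numpy as np

from imasim import anatomy, pbd

spec = anatomy.FasciaSpec(width=0.08, height=0.08, resolution=(8, 8),
                          total_mass=0.02)
mesh, constraints, system = anatomy.build_fascia(spec)
print(f"fascia: {len(mesh.vertices)} vertices, {len(mesh.faces)} faces, "
      f"{len(constraints.distance)} stretch + {len(constraints.dihedral)} "
      "bending constraints")

cfg = pbd.SolverConfig()  # dt = 5 ms, 5 iterations, gravity, viscous damping
for k in range(1500):
    pbd.step(system, constraints, cfg)

sag = -system.positions[:, 2].min()
res = pbd.constraint_residuals(system, constraints)
stretch = res[:len(constraints.distance)].max()
bend = res[len(constraints.distance):].max()
print(f"after {1500 * cfg.dt:.1f} s simulated: max sag {sag * 1000:.2f} mm, "
      f"worst stretch residual {stretch * 1000:.3f} mm, "
      f"worst bend residual {np.degrees(bend):.1f} deg")
print("-> the interior hangs below the pinned rim: the inextensible stretch "
      "constraints stay almost exact while the softer bending constraints "
      "carry the gravity load as a residual fold angle.")
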