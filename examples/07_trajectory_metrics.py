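"""Spatial Asymmetry Index: synthetic trajectories and group statistics.

The SAI is the mean signed perpendicular distance of 60 Hz tool samples from
the vessel centerline, normalized by the 2 mm safety radius — positive means
the operator keeps the tool away from the heart. The bimodal sampler
generates tool positions whose expected SAI hits a requested target, standing
in for unpublished operator trajectories; the shipped per-trial reference
values are then summarized exactly.
"""

import numpy as np

from imasim import metrics
from imasim.mesh_core import PolylineMesh

cl = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
cfg = metrics.SAIConfig(
    centerline=PolylineMesh(cl, np.array([[0, 1]]), np.array([0.003, 0.003])),
    cardiac_side_vector=np.array([1.0, 0.0, 0.0]))

for target in (0.0, 0.25, 0.589):
    traj = metrics.sample_tool_positions(target, n=50_000, seed=42, config=cfg)
    got = metrics.compute_sai(traj, cfg)
    print(f"sampler target {target:.3f} -> recovered SAI {got:.3f} "
          f"from {traj.n} samples")

ra, rb = metrics.group_stats(metrics.REFERENCE_SAI_DYNAMIC,
                             metrics.REFERENCE_SAI_STATIC)
print(f"\nreference trials — dynamic: {ra.mean:.3f} ± {ra.sd:.3f}, "
      f"static: {rb.mean:.3f} ± {rb.sd:.3f}")
print(f"mean difference {ra.mean_difference:.3f}, Welch t = "
      f"{ra.t_statistic:.2f}, p = {ra.p_value:.1e}")
print("-> the beating-heart condition pushes the operator ~0.34 safety radii "
      "further onto the non-cardiac side of the vessel.")
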