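"""Segment-resolved RMSD and COM-distance series on a synthetic trajectory.

Builds an ideal helix, lets a terminal segment drift away from the core
while everything fluctuates, and tracks (a) the core-fitted RMSD time
series with smoothing and (b) the distance between the centers of mass of
the tail and the core — the diagnostic used to watch a C-terminal tail
dock into or leave a binding groove.
"""

import numpy as np

from ncsmd import build_helix, com, com_distance_series, make_trajectory, rmsd_series, select, smooth_series
from ncsmd.structures import SegmentTable
from ncsmd.synthetic import SynthSpec

table = SegmentTable({"CORE": (1, 12), "TAIL": (13, 16)})
base = build_helix(["ALA"] * 16, label="toy-protein")
tail = select(base, "TAIL", "all", table=table)
core = select(base, "CORE", "all", table=table)

away = com(base, tail) - com(base, core)
away = 4.0 * away / np.linalg.norm(away)
spec = SynthSpec(
    n_frames=60, dt=50.0, fluctuation_amplitude=0.15, seed=42,
    drift_segment="TAIL", drift_vector=tuple(away), segments=table,
)
traj = make_trajectory(spec, base)

fit = select(base, "CORE", "backbone", table=table)
series = rmsd_series(traj, base, fit)
smoothed = smooth_series(series, window=11)
dist = com_distance_series(traj, tail, core)

print(f"frames: {traj.n_frames}, dt = {traj.dt} ps, span = {traj.times[-1]:.0f} ps")
print(f"core RMSD: mean {series.values.mean():.2f} A, max {series.values.max():.2f} A")
print(f"smoothed core RMSD at end: {smoothed.values[-1]:.2f} A")
print(f"tail-core COM distance: {dist.values[0]:.2f} -> {dist.values[-1]:.2f} A")
print()
print("The core RMSD stays at the fluctuation level (the core is rigid),")
print("while the COM distance grows by ~4 A: the tail, not the core, moved.")
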