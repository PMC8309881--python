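"""Sub-technique usage as a function of speed.

Distance and dwell time in every 0.25 m/s speed bin are attributed to the
sub-technique used there, yielding the usage distribution over speed and
occupancy-weighted summaries for a low (2.75-4.75 m/s) and a high
(7-10 m/s) speed range.

Run:  python examples/04_speed_distribution.py
"""

import numpy as np

from skitrace import (
    SessionRecording,
    SkierSpec,
    align_imu,
    bin_by_speed,
    classify_windows,
    default_course,
    default_training_set,
    derive_speed,
    interpolate_by_distance,
    labels_to_distance,
    make_windows,
    range_summary,
    simulate_race,
    split_laps,
)

sim = simulate_race(default_course(), SkierSpec(), n_laps=4, seed=8)
traj = derive_speed(sim.gnss)
laps = split_laps(traj, sim.lap_length, sim.n_laps)
series = interpolate_by_distance(laps, 5.0, sim.lap_length)

rec = align_imu(SessionRecording("demo", traj, sim.imu, n_laps=sim.n_laps))
track = classify_windows(default_training_set(seed=42), make_windows(rec.imu), k=5)
labels = labels_to_distance(track, series.d, sim.lap_length)

dist = bin_by_speed(labels, series)
pct = dist.pct("distance")
print("distance-weighted usage per occupied speed bin:")
print(f"  {'bin (m/s)':12s} {'m':>6s}   DP%   DK%  DIA%  OTH%")
e = dist.binning.edges
for b in np.nonzero(dist.used)[0]:
    row = " ".join(f"{v:5.0f}" for v in np.nan_to_num(pct[b]))
    print(f"  {e[b]:.2f}-{e[b + 1]:.2f}  {dist.occupancy_m[b]:6.0f}  {row}")

print("\nspeed-range summary (occupancy-weighted):")
print(range_summary(dist).round(1).to_string())
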