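# skitrace

Micro-sensor race analysis for classical cross-country skiing.

A body-worn race tracker records two streams: a 10 Hz GNSS position/altitude
track and a 100 Hz tri-axial accelerometer + gyroscope stream. `skitrace`
turns them into the standard race-analysis products:

- **Course segmentation** — a terrain model of the lap (uphill / flat /
  downhill segments) detected from the elevation profile with a minimum
  elevation-difference rule.
- **Lap performance** — lap splits, distance-interpolated speed, and
  terrain-resolved comparisons of a skier against a reference group
  (relative speed difference, accumulated time difference, time in terrain).
- **Sub-technique classification** — the classical sub-techniques (double
  poling DP, kick double poling DK, diagonal stride DIA, and OTHER for
  tuck/turns) classified by a k-nearest-neighbour model over 13
  time/frequency features of sliding 2 s IMU windows.
- **Usage distributions** — distance- and time-weighted sub-technique usage
  across 0.25 m/s speed bins, with occupancy-weighted summaries for a low
  (2.75–4.75 m/s) and a high (7–10 m/s) speed range.
- **Race simulator** — a full generative model (course geometry, grade-driven
  speed dynamics, correlated GNSS noise, technique-specific cyclic IMU
  signatures) with exact ground truth, so every stage is testable end to end
  without field data.

## Quick start

```python
from skitrace import (
    SkierSpec, default_course, simulate_race,
    derive_speed, build_profile, detect_segments, terrain_composition,
)

sim = simulate_race(default_course(), SkierSpec(), n_laps=4, seed=1)
traj = derive_speed(sim.gnss)
model = detect_segments(build_profile(traj, sim.lap_length))
for t, f in terrain_composition(model).items():
    print(f"{t.value:8s} {100 * f:.1f}%")
```

recovers the built-in 2.5 km course's 10 segments (3 uphill, 3 flat,
4 downhill) and its composition — 37 % uphill, 15 % flat, 48 % downhill —
from the noisy simulated track to within half a percentage point.

The `examples/` directory walks through each capability as a narrative
script:

| script | shows |
| --- | --- |
| `01_simulate_and_segment.py` | simulation + terrain-model recovery |
| `02_pacing_comparison.py` | skier vs reference group, per terrain |
| `03_subtechnique_classification.py` | IMU windowing, KNN labels, accuracy vs truth |
| `04_speed_distribution.py` | usage over speed bins and range summaries |
| `05_full_pipeline.py` | the YAML-configured end-to-end pipeline |

## Command line

The same pipeline is exposed as a thin CLI:

```sh
skitrace simulate --laps 4 --seed 7 --out race/
skitrace segment-course --gnss race/gnss.gpx --lap-length 2465 --out course.json
skitrace analyze-race --skier race/gnss.gpx --reference ref1.gpx --reference ref2.gpx
skitrace classify --gnss race/gnss.gpx --imu race/imu.csv
skitrace run-all --config analysis.yaml
```

`run-all` reads every parameter from a YAML file (see
`examples/05_full_pipeline.py` for a complete config) and writes a bundle of
plain CSV/JSON outputs; a re-run with the same inputs is byte-identical.

## Data formats

- GNSS: GPX 1.1 track files or CSV with columns `t, lat, lon, alt`
  (`t` as seconds or ISO-8601 timestamps).
- IMU: CSV with columns `t, ax, ay, az, gx, gy, gz` (m/s² and rad/s).
- Training sets for the classifier: CSV with feature columns `f0..f12` and a
  `label` column; the packaged default is generated deterministically from
  the simulator's technique templates.

## Testing and reproduction

```sh
python -m pytest
```

The suite covers each module against independent oracles (closed-form
kinematics, brute-force KNN, quadrature lap times, simulator ground truth)
and includes end-to-end acceptance tests in `tests/test_acceptance.py`.

The headline course-composition figures can be reproduced from scratch with

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which builds the reference course, segments its elevation profile and
writes the uphill / flat / downhill lap shares (37 / 15 / 48 %).

`docs/methods.md` documents the algorithms, parameter defaults and the
simulator's scope and limits.
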