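"""The whole analysis in one call, driven by a YAML config.

Simulates a race to disk, writes a config file, and runs run_pipeline —
exactly what `skitrace run-all --config analysis.yaml` does from the
shell.  The output directory holds the complete CSV/JSON bundle plus
plots.

Run:  python examples/05_full_pipeline.py
"""

import tempfile
from pathlib import Path

from skitrace import SkierSpec, default_course, simulate_race, write_gpx, write_imu_csv
from skitrace.pipeline import AnalysisConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="skitrace_demo_"))

# a skier of interest and two reference athletes
sim = simulate_race(default_course(), SkierSpec(flat_speed=6.5, seed=2),
                    n_laps=4, seed=2)
write_gpx(sim.gnss, workdir / "skier.gpx")
write_imu_csv(sim.imu, workdir / "imu.csv")
for s in (21, 22):
    ref = simulate_race(default_course(), SkierSpec(seed=s), n_laps=4, seed=s)
    write_gpx(ref.gnss, workdir / f"ref{s}.gpx")

config = workdir / "analysis.yaml"
config.write_text(f"""\
gnss: {workdir / 'skier.gpx'}
imu: {workdir / 'imu.csv'}
reference:
  - {workdir / 'ref21.gpx'}
  - {workdir / 'ref22.gpx'}
lap_length: 2465.0
n_laps: 4
out_dir: {workdir / 'out'}
make_plots: true
""")
print(f"config written to {config}\n")

paths = run_pipeline(AnalysisConfig.from_yaml(config))
print("pipeline outputs:")
for name, path in paths.items():
    print(f"  {name:16s} {path}")
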