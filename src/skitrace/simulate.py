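"""Race simulator with known ground truth for every pipeline stage.

Simulates a classical-technique race on an undulating loop: a piecewise-
linear course profile, a skier whose speed responds to grade with
autocorrelated (AR(1)) physiological noise, a 10 Hz GNSS track with
Gauss–Markov receiver error, and a 100 Hz IMU stream built from cyclic,
technique-specific signal templates on the frontal-axis channels.

The built-in course is a 2.5 km competition lap of ten legs (three uphill,
three flat and four downhill by the 4 m elevation-difference rule, 37/15/48%
of the length) with six turns, matching the layout of a national-level
classical sprint-distance loop.  The ground-truth technique assignment is a
speed/incline threshold rule: diagonal stride on steep climbs, kick double
poling on moderate inclines, double poling elsewhere, and tuck (OTHER) on
downhills and at high speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from skitrace import course as course_mod
from skitrace.course import CourseModel, CourseSegment, ElevationProfile, Terrain
from skitrace.subtechnique import (
    CLASSES,
    FilterSpec,
    TrainingSet,
    featurize,
    make_windows,
)
from skitrace.track_io import ImuSeries, LocalProjection, SessionRecording, Trajectory, trajectory_from_arrays

TRUTH_GRID_M = 5.0
BASE_LAT, BASE_LON = 61.0, 8.5
BASE_ALT = 150.0

#: the built-in reference lap: (horizontal length m, incline range % lo, hi)
DEFAULT_COURSE_LEGS = (
    (131.0, -2.6, 1.6),
    (543.0, 1.7, 12.4),
    (509.0, -11.7, 0.2),
    (100.0, 0.7, 2.8),
    (156.0, -6.0, 0.0),
    (166.0, 1.3, 12.7),
    (339.0, -8.5, -0.4),
    (200.0, 1.2, 16.0),
    (183.0, -10.1, -1.0),
    (138.0, 0.0, 1.6),
)
DEFAULT_TURNS = (250.0, 700.0, 1150.0, 1600.0, 2000.0, 2350.0)


@dataclass(frozen=True)
class CourseSpec:
    """Course as ordered legs of (horizontal length m, incline %)."""

    legs: tuple[tuple[float, float], ...]
    turns: tuple[float, ...] = ()

    def __post_init__(self):
        for length, incline in self.legs:
            if length <= 0:
                raise ValueError("leg lengths must be positive")
            if abs(incline) > 20:
                raise ValueError("inclines limited to ±20%")

    @property
    def lap_length(self) -> float:
        return float(sum(length for length, _ in self.legs))

    def net_climb_m(self) -> float:
        return float(sum(L * g / 100.0 for L, g in self.legs))

    def closed(self) -> "CourseSpec":
        """Detrended copy whose lap starts and ends at the same altitude.

        A lap raced repeatedly is a closed loop, but leg inclines quoted as
        range midpoints need not sum to zero climb.  Subtracting the
        constant trend (here well under 0.5%) closes the loop without
        changing any segment's terrain label.
        """
        trend = 100.0 * self.net_climb_m() / self.lap_length
        return CourseSpec(
            legs=tuple((L, g - trend) for L, g in self.legs), turns=self.turns
        )

    @classmethod
    def from_ranges(cls, legs, turns=()) -> "CourseSpec":
        """Build from (length, incline_lo, incline_hi) using range midpoints."""
        return cls(
            legs=tuple((float(L), (lo + hi) / 2.0) for L, lo, hi in legs),
            turns=tuple(turns),
        )


def default_course() -> CourseSpec:
    """The built-in 2.5 km reference lap (incline-range midpoints)."""
    return CourseSpec.from_ranges(DEFAULT_COURSE_LEGS, DEFAULT_TURNS)


@dataclass(frozen=True)
class TechniqueRule:
    """Speed/incline thresholds mapping race state to a sub-technique.

    Tuck (OTHER) above ``tuck_min_speed`` or at grades at or below
    ``tuck_max_grade``; diagonal stride at or above ``dia_min_grade``;
    kick double poling at or above ``dk_min_grade``; double poling
    otherwise.  Grades in percent, speeds in m/s.
    """

    tuck_min_speed: float = 7.2
    tuck_max_grade: float = -2.5
    dia_min_grade: float = 4.0
    dk_min_grade: float = 1.0

    def label(self, speed: float, grade: float) -> str:
        if speed >= self.tuck_min_speed or grade <= self.tuck_max_grade:
            return "OTHER"
        if grade >= self.dia_min_grade:
            return "DIA"
        if grade >= self.dk_min_grade:
            return "DK"
        return "DP"

    def label_arrays(self, speed: np.ndarray, grade: np.ndarray) -> np.ndarray:
        out = np.full(len(speed), "DP", dtype=object)
        out[(np.asarray(grade) >= self.dk_min_grade)] = "DK"
        out[(np.asarray(grade) >= self.dia_min_grade)] = "DIA"
        other = (np.asarray(speed) >= self.tuck_min_speed) | (
            np.asarray(grade) <= self.tuck_max_grade
        )
        out[other] = "OTHER"
        return out


#: cyclic-signal parameters per class: cadence Hz, acc harmonics amps,
#: gyr amplitude, gyr phase offset (rad)
_TEMPLATES = {
    "DP": dict(cadence=0.9, acc=(3.0, 1.5, 0.0), gyr_amp=1.2, gyr_phase=0.0),
    "DK": dict(cadence=0.65, acc=(2.8, 1.2, 1.5), gyr_amp=1.8, gyr_phase=0.0),
    "DIA": dict(cadence=1.5, acc=(2.0, 0.0, 0.0), gyr_amp=2.5, gyr_phase=np.pi / 2),
    "OTHER": dict(cadence=0.0, acc=(0.0, 0.0, 0.0), gyr_amp=0.0, gyr_phase=0.0),
}


@dataclass(frozen=True)
class SkierSpec:
    """Skier dynamics and signal-generation parameters.

    ``flat_speed`` is the base speed on level ground; speed drops by
    ``uphill_sensitivity`` m/s per percent grade and is capped at
    ``downhill_cap`` on descents.  Speed noise is AR(1) (coefficient 0.9)
    with the given innovation SD, emulating autocorrelated pacing.
    """

    flat_speed: float = 6.8
    uphill_sensitivity: float = 0.38
    downhill_cap: float = 10.0
    speed_noise_sd: float = 0.15
    technique_rule: TechniqueRule = field(default_factory=TechniqueRule)
    imu_noise_sd: float = 0.3
    amplitude_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if min(self.flat_speed, self.downhill_cap) <= 0:
            raise ValueError("speeds must be positive")


@dataclass
class RaceSimulation:
    """A simulated race with every ground-truth array the pipeline estimates."""

    gnss: Trajectory
    imu: ImuSeries
    truth_course: CourseModel
    profile: ElevationProfile
    truth_s: np.ndarray  # race-axis grid, 5 m spacing, 0 .. n_laps*lap + overrun
    truth_speed: np.ndarray  # m/s at each truth_s
    truth_labels: np.ndarray  # one label per grid cell (len(truth_s) - 1)
    lap_length: float
    n_laps: int
    skier: SkierSpec

    def truth_time(self) -> np.ndarray:
        """Elapsed time at each truth_s grid point (trapezoidal in 1/v)."""
        ds = np.diff(self.truth_s)
        v_mid = 0.5 * (self.truth_speed[:-1] + self.truth_speed[1:])
        return np.concatenate(([0.0], np.cumsum(ds / v_mid)))

    def truth_lap_times(self) -> np.ndarray:
        t = self.truth_time()
        marks = np.arange(0, self.n_laps + 1) * self.lap_length
        tt = np.interp(marks, self.truth_s, t)
        return np.diff(tt)

    def truth_lap_labels(self) -> np.ndarray:
        """Majority ground-truth label per 5 m cell of the lap axis."""
        ncell = int(round(self.lap_length / TRUTH_GRID_M))
        centres = np.mod(
            0.5 * (self.truth_s[:-1] + self.truth_s[1:]), self.lap_length
        )
        cell = np.minimum((centres // TRUTH_GRID_M).astype(int), ncell - 1)
        out = np.empty(ncell, dtype=object)
        rank = {c: i for i, c in enumerate(CLASSES)}
        counts = np.zeros((ncell, len(CLASSES)), dtype=int)
        valid = self.truth_s[:-1] < self.n_laps * self.lap_length
        for ci, lab in zip(cell[valid], self.truth_labels[valid]):
            counts[ci, rank[lab]] += 1
        for i in range(ncell):
            out[i] = CLASSES[int(np.argmax(counts[i]))]
        return out

    def truth_lap_series(self, grid_m: float = TRUTH_GRID_M):
        """Ground-truth lap series: per-lap speed/time interpolated onto the
        lap grid and averaged across laps — the estimand of the pipeline's
        distance-interpolation stage, computed from truth arrays."""
        from skitrace.performance import LapSeries

        t = self.truth_time()
        d = np.arange(0.0, self.lap_length + grid_m / 2, grid_m)
        sp, tm = [], []
        for k in range(self.n_laps):
            lo = k * self.lap_length
            sp.append(np.interp(d + lo, self.truth_s, self.truth_speed))
            tk = np.interp(d + lo, self.truth_s, t)
            tm.append(tk - tk[0])
        sp, tm = np.vstack(sp), np.vstack(tm)
        return LapSeries(d=d, speed=sp.mean(axis=0), time=tm.mean(axis=0),
                         per_lap_speed=sp, per_lap_time=tm)

    def truth_distribution(self, binning=None):
        """Simulator-bookkeeping distribution oracle on the lap axis."""
        from skitrace.distribution import SpeedBinning, bin_by_speed

        series = self.truth_lap_series()
        return bin_by_speed(self.truth_lap_labels(), series, binning or SpeedBinning())

    def recording(self, athlete_id: str = "sim", **kw) -> SessionRecording:
        return SessionRecording(
            athlete_id=athlete_id,
            trajectory=self.gnss,
            imu=self.imu,
            n_laps=self.n_laps,
            **kw,
        )


def simulate_course(
    spec: CourseSpec, grid_m: float = course_mod.DEFAULT_GRID_M
) -> tuple[ElevationProfile, CourseModel]:
    """Piecewise-linear elevation profile and ground-truth terrain model.

    Each leg climbs (or drops) by length x incline; truth segments are the
    legs labelled by the minimum elevation-difference rule and merged where
    adjacent legs are individually sub-threshold.
    """
    lengths = np.array([L for L, _ in spec.legs])
    inclines = np.array([g for _, g in spec.legs])
    bounds = np.concatenate(([0.0], np.cumsum(lengths)))
    dz = lengths * inclines / 100.0
    z_nodes = BASE_ALT + np.concatenate(([0.0], np.cumsum(dz)))
    lap = float(bounds[-1])
    d = np.arange(0.0, lap + grid_m / 2, grid_m)
    z = np.interp(d, bounds, z_nodes)
    profile = ElevationProfile(d=d, z=z)

    segs = [
        CourseSegment(
            start_m=float(bounds[i]),
            end_m=float(bounds[i + 1]),
            terrain=course_mod._label(dz[i], course_mod.DEFAULT_MIN_ELEV_DIFF_M),
            elev_diff=float(dz[i]),
            incline_min=float(inclines[i]),
            incline_max=float(inclines[i]),
        )
        for i in range(len(lengths))
    ]
    merged = course_mod.merge_undulating(segs, course_mod.DEFAULT_MIN_ELEV_DIFF_M)
    return profile, CourseModel(lap_length=lap, segments=merged, turns=list(spec.turns))


def _grade_at(spec: CourseSpec, s_lap: np.ndarray) -> np.ndarray:
    lengths = np.array([L for L, _ in spec.legs])
    inclines = np.array([g for _, g in spec.legs])
    bounds = np.cumsum(lengths)
    idx = np.minimum(np.searchsorted(bounds, s_lap, side="right"), len(inclines) - 1)
    return inclines[idx]


def simulate_skier(
    spec: CourseSpec,
    skier: SkierSpec,
    n_laps: int,
    overrun_m: float = 30.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth speed v(s) on a 5 m race-axis grid.

    v(s) = clip(flat_speed − sensitivity·grade(s), 0.5, downhill_cap) plus
    AR(1) noise (coefficient 0.9, innovation SD ``speed_noise_sd``); the
    overrun past the final lap mark lets a measured track cross the finish
    under noise, like a skier skiing through the line.
    """
    rng = rng or np.random.default_rng(skier.seed)
    lap = spec.lap_length
    s = np.arange(0.0, n_laps * lap + overrun_m + TRUTH_GRID_M / 2, TRUTH_GRID_M)
    grade = _grade_at(spec, np.mod(s, lap))
    base = np.clip(
        skier.flat_speed - skier.uphill_sensitivity * grade, 0.5, skier.downhill_cap
    )
    noise = np.zeros(len(s))
    innov = rng.normal(0.0, skier.speed_noise_sd, size=len(s))
    for i in range(1, len(s)):
        noise[i] = 0.9 * noise[i - 1] + innov[i]
    return s, np.maximum(base + noise, 0.3)


def _time_of_distance(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    ds = np.diff(s)
    v_mid = 0.5 * (v[:-1] + v[1:])
    return np.concatenate(([0.0], np.cumsum(ds / v_mid)))


def _gauss_markov(n: int, dt: float, sd: float, tau_s: float, rng) -> np.ndarray:
    """Stationary first-order Gauss-Markov noise with marginal SD ``sd``."""
    if sd <= 0:
        return np.zeros(n)
    rho = np.exp(-dt / tau_s)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    steps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + steps[i]
    return e


def render_gnss(
    spec: CourseSpec,
    profile: ElevationProfile,
    truth_s: np.ndarray,
    truth_speed: np.ndarray,
    rate_hz: float = 10.0,
    pos_noise_sd_m: float = 0.5,
    alt_noise_sd_m: float = 1.0,
    noise_tau_s: float = 60.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Emit a 10 Hz GNSS trajectory for a simulated speed profile.

    The lap is laid out as a closed loop (circle of circumference
    lap_length) so repeated laps overlay geographically; receiver error is
    Gauss–Markov per axis (GNSS error is strongly autocorrelated — a white
    per-fix error would corrupt summed step lengths unrealistically).
    """
    rng = rng or np.random.default_rng(0)
    lap = spec.lap_length
    t_grid = _time_of_distance(truth_s, truth_speed)
    dt = 1.0 / rate_hz
    t_fix = np.arange(0.0, t_grid[-1], dt)
    s_fix = np.interp(t_fix, t_grid, truth_s)
    theta = 2 * np.pi * np.mod(s_fix, lap) / lap
    r = lap / (2 * np.pi)
    x = r * np.sin(theta)
    y = r * (1.0 - np.cos(theta))
    z = np.interp(np.mod(s_fix, lap), profile.d, profile.z)
    n = len(t_fix)
    x = x + _gauss_markov(n, dt, pos_noise_sd_m, noise_tau_s, rng)
    y = y + _gauss_markov(n, dt, pos_noise_sd_m, noise_tau_s, rng)
    z = z + _gauss_markov(n, dt, alt_noise_sd_m, noise_tau_s, rng)
    proj = LocalProjection(BASE_LAT, BASE_LON)
    lat, lon = proj.inverse(x, y)
    return trajectory_from_arrays(t_fix, lat, lon, z)


def render_imu(
    truth_s: np.ndarray,
    truth_speed: np.ndarray,
    truth_labels: np.ndarray,
    skier: SkierSpec,
    rate_hz: float = 100.0,
    rng: np.random.Generator | None = None,
) -> ImuSeries:
    """Synthesize the 100 Hz IMU stream from per-cell technique labels.

    Frontal-axis channels follow per-technique cyclic templates: double
    poling gives synchronized biphasic acc/gyr pulses at its cadence; kick
    double poling adds one leg-kick harmonic per cycle; diagonal stride is
    a faster alternating pattern with the gyroscope a quarter-cycle out of
    phase; tuck/OTHER has no cyclic content.  Per-cycle amplitude jitter
    and additive Gaussian noise are applied; off-axis channels carry noise
    only.
    """
    rng = rng or np.random.default_rng(0)
    for lab in np.unique(np.asarray(truth_labels, dtype=object)):
        if lab not in _TEMPLATES:
            raise ValueError(f"unknown technique label {lab!r}")
    t_grid = _time_of_distance(truth_s, truth_speed)
    dt = 1.0 / rate_hz
    t = np.arange(0.0, t_grid[-1], dt)
    s_t = np.interp(t, t_grid, truth_s)
    cell = np.clip(
        np.searchsorted(truth_s, s_t, side="right") - 1, 0, len(truth_labels) - 1
    )
    labels_t = np.asarray(truth_labels, dtype=object)[cell]

    cadence = np.array([_TEMPLATES[l]["cadence"] for l in labels_t])
    phase = np.concatenate(([0.0], np.cumsum(2 * np.pi * cadence[:-1] * dt)))
    cycle = np.floor(phase / (2 * np.pi)).astype(int)
    n_cycles = int(cycle.max()) + 1
    jitter_per_cycle = 1.0 + skier.amplitude_jitter * rng.normal(size=n_cycles)
    j = jitter_per_cycle[cycle]

    acc_z = np.zeros(len(t))
    gyr_z = np.zeros(len(t))
    for lab, tpl in _TEMPLATES.items():
        m = labels_t == lab
        if not m.any():
            continue
        a1, a2, a3 = tpl["acc"]
        ph = phase[m]
        acc_z[m] = j[m] * (
            a1 * np.sin(ph) + a2 * np.sin(2 * ph) + a3 * np.sin(3 * ph)
        )
        gyr_z[m] = j[m] * tpl["gyr_amp"] * np.sin(ph + tpl["gyr_phase"])
    acc_z = acc_z + rng.normal(0.0, skier.imu_noise_sd, len(t))
    gyr_z = gyr_z + rng.normal(0.0, 0.3 * skier.imu_noise_sd, len(t))
    small = 0.2 * skier.imu_noise_sd
    return ImuSeries(
        t=t,
        acc_x=rng.normal(0.0, small, len(t)),
        acc_y=rng.normal(9.81, small, len(t)),
        acc_z=acc_z,
        gyr_x=rng.normal(0.0, small, len(t)),
        gyr_y=rng.normal(0.0, small, len(t)),
        gyr_z=gyr_z,
    )


def simulate_race(
    course_spec: CourseSpec | None = None,
    skier: SkierSpec | None = None,
    n_laps: int = 4,
    seed: int | None = None,
    pos_noise_sd_m: float = 0.5,
    alt_noise_sd_m: float = 1.0,
    overrun_m: float = 30.0,
) -> RaceSimulation:
    """Simulate one full race; deterministic in ``seed``."""
    course_spec = course_spec or default_course()
    skier = skier or SkierSpec()
    if seed is None:
        seed = skier.seed
    ss = np.random.SeedSequence(seed)
    rng_speed, rng_gnss, rng_imu = (np.random.default_rng(c) for c in ss.spawn(3))

    # the raced world must be altitude-closed over a lap
    closed = course_spec.closed()
    profile, truth_course = simulate_course(closed)
    s, v = simulate_skier(closed, skier, n_laps, overrun_m, rng=rng_speed)
    grade_mid = _grade_at(closed, np.mod(0.5 * (s[:-1] + s[1:]), closed.lap_length))
    v_mid = 0.5 * (v[:-1] + v[1:])
    labels = skier.technique_rule.label_arrays(v_mid, grade_mid)
    gnss = render_gnss(
        closed, profile, s, v,
        pos_noise_sd_m=pos_noise_sd_m, alt_noise_sd_m=alt_noise_sd_m, rng=rng_gnss,
    )
    imu = render_imu(s, v, labels, skier, rng=rng_imu)
    return RaceSimulation(
        gnss=gnss,
        imu=imu,
        truth_course=truth_course,
        profile=profile,
        truth_s=s,
        truth_speed=v,
        truth_labels=labels,
        lap_length=course_spec.lap_length,
        n_laps=n_laps,
        skier=skier,
    )


#: constant speeds used to render single-technique training streams (m/s);
#: chosen inside each technique's natural operating range
_TRAINING_SPEEDS = {"DP": 6.0, "DK": 5.5, "DIA": 3.8, "OTHER": 9.0}


def training_windows(
    seed: int = 42,
    windows_per_class: int = 60,
    spec: FilterSpec | None = None,
    duration_s: float = 90.0,
) -> TrainingSet:
    """Simulator-rendered labelled windows for the packaged KNN classifier.

    For each class a constant-speed, single-technique IMU stream is
    rendered and windowed; ``windows_per_class`` windows are taken evenly
    spaced through the stream so heavily overlapping neighbours do not
    dominate the exemplar pool.
    """
    rng = np.random.default_rng(seed)
    skier = SkierSpec(seed=seed)
    X, y = [], []
    for cls in CLASSES:
        v = _TRAINING_SPEEDS[cls]
        s = np.arange(0.0, duration_s * v + TRUTH_GRID_M, TRUTH_GRID_M)
        speeds = np.full(len(s), v)
        labels = np.full(len(s) - 1, cls, dtype=object)
        imu = render_imu(s, speeds, labels, skier, rng=rng)
        imu.speed = np.full(len(imu.t), v)
        imu.cum_dist = v * imu.t
        wins = make_windows(imu, spec)
        take = np.linspace(0, len(wins) - 1, windows_per_class).astype(int)
        for i in take:
            X.append(featurize(wins[i]))
            y.append(cls)
    return TrainingSet(X=np.vstack(X), y=y)
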