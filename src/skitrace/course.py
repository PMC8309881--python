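"""Terrain model of a race lap: elevation profile and segment detection.

A lap is partitioned into uphill, flat and downhill segments.  A segment
begins and ends at an evident change in course gradient; uphill and
downhill segments must show a minimum elevation difference (default 4 m)
between their start and end, and runs of adjacent sub-threshold segments
are merged into a single flat segment.  Composition fractions use
horizontal segment lengths; the 3-D ("actual") length of a segment is
exposed separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from skitrace.track_io import Trajectory

DEFAULT_MIN_ELEV_DIFF_M = 4.0
DEFAULT_GRID_M = 5.0
DEFAULT_SMOOTH_M = 30.0
DEFAULT_HYSTERESIS_M = 20.0


class Terrain(str, Enum):
    UPHILL = "UPHILL"
    FLAT = "FLAT"
    DOWNHILL = "DOWNHILL"


@dataclass
class ElevationProfile:
    """Smoothed altitude z(d) on a uniform distance grid over one lap."""

    d: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.d) != len(self.z):
            raise ValueError("d and z must have equal length")
        if len(self.d) >= 2 and not np.all(np.diff(self.d) > 0):
            raise ValueError("d must be strictly increasing")

    @property
    def grid_m(self) -> float:
        return float(self.d[1] - self.d[0])

    def gradient_pct(self) -> np.ndarray:
        """Grade in percent at each grid point (100 * dz/dd)."""
        return 100.0 * np.gradient(self.z, self.d)


@dataclass
class CourseSegment:
    start_m: float
    end_m: float
    terrain: Terrain
    elev_diff: float
    incline_min: float = float("nan")
    incline_max: float = float("nan")

    @property
    def length_m(self) -> float:
        return self.end_m - self.start_m

    @property
    def actual_length(self) -> float:
        return actual_distance(self)


@dataclass
class CourseModel:
    lap_length: float
    segments: list[CourseSegment]
    turns: list[float] = field(default_factory=list)
    gap: tuple[float, float] | None = None

    def terrain_at(self, d: float) -> Terrain | None:
        """Terrain label at lap distance d, or None inside the gap."""
        if self.gap is not None and self.gap[0] <= d < self.gap[1]:
            return None
        for seg in self.segments:
            if seg.start_m <= d < seg.end_m:
                return seg.terrain
        if self.segments and d >= self.segments[-1].end_m:
            return self.segments[-1].terrain
        return None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "lap_length": self.lap_length,
            "turns": list(self.turns),
            "gap": list(self.gap) if self.gap else None,
            "segments": [
                {
                    "start_m": s.start_m,
                    "end_m": s.end_m,
                    "terrain": s.terrain.value,
                    "elev_diff": s.elev_diff,
                    "incline_min": None if np.isnan(s.incline_min) else s.incline_min,
                    "incline_max": None if np.isnan(s.incline_max) else s.incline_max,
                    "actual_length": s.actual_length,
                }
                for s in self.segments
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CourseModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        segs = [
            CourseSegment(
                start_m=s["start_m"],
                end_m=s["end_m"],
                terrain=Terrain(s["terrain"]),
                elev_diff=s["elev_diff"],
                incline_min=s["incline_min"] if s["incline_min"] is not None else float("nan"),
                incline_max=s["incline_max"] if s["incline_max"] is not None else float("nan"),
            )
            for s in payload["segments"]
        ]
        gap = tuple(payload["gap"]) if payload.get("gap") else None
        return cls(payload["lap_length"], segs, payload.get("turns", []), gap)


def build_profile(
    traj: Trajectory,
    lap_length: float,
    grid_m: float = DEFAULT_GRID_M,
    smooth_m: float = DEFAULT_SMOOTH_M,
) -> ElevationProfile:
    """Reference elevation profile of one lap from a multi-lap trajectory.

    Altitude is resampled onto a uniform grid per lap and median-aggregated
    across laps (robust to per-lap GNSS altitude error), then smoothed with
    a moving average of ``smooth_m`` metres — shorter than the shortest
    plausible terrain segment, so real gradient changes survive.
    """
    if lap_length <= 0:
        raise ValueError("lap_length must be positive")
    if traj.cum_dist is None:
        raise ValueError("trajectory needs cumulative distance")
    total = float(traj.cum_dist[-1])
    if total < lap_length * 0.98:
        raise ValueError("trajectory does not cover one lap")
    d = np.arange(0.0, lap_length + grid_m / 2, grid_m)
    n_laps = max(1, int(np.floor(total / lap_length + 0.02)))
    samples = []
    for k in range(n_laps):
        lo, hi = k * lap_length, (k + 1) * lap_length
        zk = np.interp(
            d + lo,
            traj.cum_dist,
            traj.alt,
            left=np.nan,
            right=np.nan,
        )
        # only keep laps that fully cover the grid
        mask = (d + lo >= traj.cum_dist[0]) & (d + lo <= traj.cum_dist[-1])
        zk = np.where(mask, zk, np.nan)
        samples.append(zk)
    zmat = np.vstack(samples)
    z = np.nanmedian(zmat, axis=0)
    if np.isnan(z).any():
        raise ValueError("elevation grid not fully covered by the trajectory")
    z = _moving_average(z, max(1, int(round(smooth_m / grid_m))))
    return ElevationProfile(d=d, z=z)


def _moving_average(z: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return z
    kernel = np.ones(n)
    return np.convolve(z, kernel, "same") / np.convolve(np.ones_like(z), kernel, "same")


def _nanreduce(fn, values) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(fn(vals)) if vals else float("nan")


def _label(elev_diff: float, thr: float) -> Terrain:
    if elev_diff >= thr:
        return Terrain.UPHILL
    if elev_diff <= -thr:
        return Terrain.DOWNHILL
    return Terrain.FLAT


def detect_segments(
    profile: ElevationProfile,
    min_elev_diff_m: float = DEFAULT_MIN_ELEV_DIFF_M,
    hysteresis_m: float = DEFAULT_HYSTERESIS_M,
) -> CourseModel:
    """Partition a lap profile into uphill / flat / downhill segments.

    Candidate breakpoints are placed where the smoothed gradient changes
    sign and the new sign persists for at least ``hysteresis_m`` metres
    (gradient noise cannot spawn micro-segments).  Candidates are labelled
    from their endpoint elevation difference against the threshold, then
    sub-threshold runs are merged into flat segments.
    """
    d, z = profile.d, profile.z
    if d[-1] - d[0] < 2 * hysteresis_m:
        raise ValueError("profile shorter than twice the hysteresis distance")
    g = np.gradient(z, d)
    sign = np.sign(g)
    # carry forward through exact zeros
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    if sign[0] == 0:
        nz = np.nonzero(sign)[0]
        sign[0] = sign[nz[0]] if len(nz) else 1.0

    # runs of constant gradient sign; a sign change only registers a new
    # run if it persists for at least the hysteresis distance
    run_starts = [0]
    for i in range(1, len(sign)):
        if sign[i] != sign[i - 1]:
            run_starts.append(i)
    run_starts.append(len(sign))
    registered: list[list] = []  # [start_idx, end_idx_exclusive, sign, confirmed]
    for a, b in zip(run_starts[:-1], run_starts[1:]):
        length_m = float(d[b - 1] - d[a])
        confirmed = length_m >= hysteresis_m
        if not registered:
            registered.append([a, b, sign[a], confirmed])
        elif sign[a] == registered[-1][2] or not confirmed:
            registered[-1][1] = b  # same sign, or a transient blip: absorb
        elif not registered[-1][3]:
            # previous run never reached the hysteresis length: take it over
            registered[-1] = [registered[-1][0], b, sign[a], True]
        else:
            registered.append([a, b, sign[a], True])

    # candidate segments span from each registered run start to the next;
    # boundaries are then refined by a free-knot two-line fit, because the
    # profile smoothing biases gradient zero-crossings into weak-gradient
    # (short flat) segments by up to half the smoothing window
    bounds = [r[0] for r in registered] + [len(d) - 1]
    bounds = _refine_breakpoints(d, z, bounds)
    candidates = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        ed = float(z[b] - z[a])
        candidates.append(
            CourseSegment(float(d[a]), float(d[b]), _label(ed, min_elev_diff_m), ed)
        )
    merged = merge_undulating(candidates, min_elev_diff_m)

    grad_pct = 100.0 * g
    for seg in merged:
        sel = (d >= seg.start_m) & (d <= seg.end_m)
        seg.incline_min = float(np.min(grad_pct[sel]))
        seg.incline_max = float(np.max(grad_pct[sel]))
    return CourseModel(lap_length=float(d[-1]), segments=merged)


def _refine_breakpoints(
    d: np.ndarray, z: np.ndarray, bounds: list[int], search_m: float = 60.0
) -> list[int]:
    """Relocate each interior breakpoint to the best two-line fit knot.

    For every interior boundary the knot is moved within ``search_m`` of its
    initial position (never past the neighbouring boundaries) to minimise
    the summed squared residual of straight-line fits to the elevation on
    either side — the least-squares notion of "where the gradient changes".
    """
    grid = float(d[1] - d[0])
    span = max(1, int(round(search_m / grid)))
    out = list(bounds)
    for i in range(1, len(out) - 1):
        lo = max(out[i - 1] + 2, out[i] - span)
        hi = min(bounds[i + 1] - 2, out[i] + span)
        if hi <= lo:
            continue
        best, best_k = np.inf, out[i]
        for k in range(lo, hi + 1):
            sse = 0.0
            for a, b in ((out[i - 1], k), (k, bounds[i + 1])):
                xx, yy = d[a : b + 1], z[a : b + 1]
                A = np.vstack([xx, np.ones_like(xx)]).T
                coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
                r = yy - A @ coef
                sse += float(r @ r)
            if sse < best:
                best, best_k = sse, k
        out[i] = best_k
    return out


def merge_undulating(
    segments: list[CourseSegment], min_elev_diff_m: float = DEFAULT_MIN_ELEV_DIFF_M
) -> list[CourseSegment]:
    """Merge undulating terrain into single flat segments.

    Maximal runs of consecutive segments whose individual elevation
    differences are all below the threshold become one FLAT segment (the
    run keeps the FLAT label even if its summed elevation change crosses
    the threshold — undulation is flat by definition).  Adjacent surviving
    segments with equal labels are then collapsed.
    """
    if not segments:
        return []
    out: list[CourseSegment] = []
    i = 0
    while i < len(segments):
        if abs(segments[i].elev_diff) < min_elev_diff_m:
            j = i
            while j < len(segments) and abs(segments[j].elev_diff) < min_elev_diff_m:
                j += 1
            run = segments[i:j]
            out.append(
                CourseSegment(
                    start_m=run[0].start_m,
                    end_m=run[-1].end_m,
                    terrain=Terrain.FLAT,
                    elev_diff=float(sum(s.elev_diff for s in run)),
                    incline_min=_nanreduce(min, [s.incline_min for s in run]),
                    incline_max=_nanreduce(max, [s.incline_max for s in run]),
                )
            )
            i = j
        else:
            seg = segments[i]
            out.append(
                CourseSegment(
                    seg.start_m, seg.end_m, _label(seg.elev_diff, min_elev_diff_m),
                    seg.elev_diff, seg.incline_min, seg.incline_max,
                )
            )
            i += 1
    # collapse adjacent same-label segments
    collapsed = [out[0]]
    for seg in out[1:]:
        prev = collapsed[-1]
        if seg.terrain == prev.terrain:
            collapsed[-1] = CourseSegment(
                start_m=prev.start_m,
                end_m=seg.end_m,
                terrain=prev.terrain,
                elev_diff=prev.elev_diff + seg.elev_diff,
                incline_min=_nanreduce(min, [prev.incline_min, seg.incline_min]),
                incline_max=_nanreduce(max, [prev.incline_max, seg.incline_max]),
            )
        else:
            collapsed.append(seg)
    return collapsed


def actual_distance(seg: CourseSegment) -> float:
    """3-D segment length from horizontal length and elevation difference."""
    return float(np.hypot(seg.end_m - seg.start_m, seg.elev_diff))


def terrain_composition(model: CourseModel) -> dict[Terrain, float]:
    """Fraction of the segmented course in each terrain (horizontal lengths)."""
    if not model.segments:
        raise ValueError("course model has no segments")
    totals = {t: 0.0 for t in Terrain}
    for seg in model.segments:
        totals[seg.terrain] += seg.length_m
    grand = sum(totals.values())
    return {t: totals[t] / grand for t in Terrain}
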