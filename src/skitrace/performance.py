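"""Lap splitting, distance interpolation and between-skier pacing metrics.

Speed and elapsed time are interpolated by distance for each lap and then
averaged over a skier's laps; group references are pointwise means with
sample (n−1) standard deviations.  Comparisons report continuous speed and
accumulated-time differences along the lap and per-terrain aggregates:
terrain mean speed, relative speed difference (% of the reference), time
loss per lap (positive = skier slower), and the proportion of skiing time
spent in each terrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skitrace.course import CourseModel, Terrain
from skitrace.track_io import SessionRecording, Trajectory

DEFAULT_GRID_M = 5.0


@dataclass
class LapTrace:
    """One lap, re-zeroed: distance from lap start, time from lap start."""

    d: np.ndarray
    t: np.ndarray
    speed: np.ndarray


@dataclass
class LapSeries:
    """A skier's speed/time on a common lap distance grid, lap-averaged."""

    d: np.ndarray
    speed: np.ndarray
    time: np.ndarray
    per_lap_speed: np.ndarray | None = None  # (n_laps, n_grid)
    per_lap_time: np.ndarray | None = None

    @property
    def n_laps(self) -> int:
        return 0 if self.per_lap_speed is None else self.per_lap_speed.shape[0]


@dataclass
class GroupReference:
    d: np.ndarray
    mean_speed: np.ndarray
    sd_speed: np.ndarray
    mean_time: np.ndarray
    sd_time: np.ndarray
    n_members: int = 0


@dataclass
class ComparisonResult:
    d: np.ndarray
    abs_speed_diff: np.ndarray  # reference − skier (m/s, positive = slower)
    rel_speed_diff: np.ndarray  # % of reference speed
    accum_time_diff: np.ndarray  # skier − reference (s, positive = slower)
    per_terrain: pd.DataFrame
    time_in_terrain: dict[str, float]


def split_laps(
    rec: SessionRecording | Trajectory, lap_length: float, n_laps: int | None = None
) -> list[LapTrace]:
    """Split a recording into laps at crossings of multiples of lap_length.

    Boundary times come from linear interpolation of cumulative distance,
    and each lap trace is re-zeroed in both distance and time.  Interior
    laps span exactly [0, lap_length]; the last lap ends at the smaller of
    the recorded distance and n_laps * lap_length.
    """
    traj = rec.trajectory if isinstance(rec, SessionRecording) else rec
    if n_laps is None:
        n_laps = rec.n_laps if isinstance(rec, SessionRecording) else 1
    if traj.cum_dist is None or traj.speed is None:
        raise ValueError("trajectory needs cum_dist and speed (run derive_speed first)")
    total = float(traj.cum_dist[-1])
    if total < 0.95 * n_laps * lap_length:
        raise ValueError(
            f"recorded distance {total:.0f} m is less than 95% of "
            f"{n_laps} x {lap_length:.0f} m: incomplete race"
        )
    cd, t, v = traj.cum_dist, traj.t, traj.speed
    laps: list[LapTrace] = []
    for k in range(n_laps):
        lo = k * lap_length
        hi = min((k + 1) * lap_length, total)
        # inner points plus interpolated exact boundary points
        inside = (cd > lo) & (cd < hi)
        d_k = np.concatenate(([lo], cd[inside], [hi]))
        t_k = np.concatenate(
            ([np.interp(lo, cd, t)], t[inside], [np.interp(hi, cd, t)])
        )
        v_k = np.concatenate(
            ([np.interp(lo, cd, v)], v[inside], [np.interp(hi, cd, v)])
        )
        # guard against duplicate distances (stationary fixes)
        keep = np.concatenate(([True], np.diff(d_k) > 0))
        laps.append(LapTrace(d=d_k[keep] - lo, t=t_k[keep] - t_k[0], speed=v_k[keep]))
    return laps


def interpolate_by_distance(
    laps: list[LapTrace], grid_m: float = DEFAULT_GRID_M, lap_length: float | None = None
) -> LapSeries:
    """Resample each lap's speed and elapsed time onto a common distance
    grid and average pointwise across laps."""
    if not laps:
        raise ValueError("no laps")
    shortest = min(float(lp.d[-1]) for lp in laps)
    if lap_length is None:
        lap_length = shortest
    d = np.arange(0.0, lap_length + grid_m / 2, grid_m)
    if d[-1] > shortest + 1e-9:
        raise ValueError("grid extends beyond the shortest lap")
    sp = np.vstack([np.interp(d, lp.d, lp.speed) for lp in laps])
    tm = np.vstack([np.interp(d, lp.d, lp.t) for lp in laps])
    return LapSeries(
        d=d,
        speed=sp.mean(axis=0),
        time=tm.mean(axis=0),
        per_lap_speed=sp,
        per_lap_time=tm,
    )


def group_reference(members: list[LapSeries]) -> GroupReference:
    """Pointwise group mean and SD (sample, n−1; a single member gets SD 0)."""
    if not members:
        raise ValueError("empty group")
    d = members[0].d
    for m in members[1:]:
        if len(m.d) != len(d) or not np.allclose(m.d, d):
            raise ValueError("group members must share the distance grid")
    sp = np.vstack([m.speed for m in members])
    tm = np.vstack([m.time for m in members])
    ddof = 1 if len(members) > 1 else 0
    sd_sp = sp.std(axis=0, ddof=ddof) if len(members) > 1 else np.zeros_like(d)
    sd_tm = tm.std(axis=0, ddof=ddof) if len(members) > 1 else np.zeros_like(d)
    return GroupReference(
        d=d,
        mean_speed=sp.mean(axis=0),
        sd_speed=sd_sp,
        mean_time=tm.mean(axis=0),
        sd_time=sd_tm,
        n_members=len(members),
    )


def _cell_terrains(d: np.ndarray, course: CourseModel) -> list[Terrain | None]:
    """Terrain label of each grid cell [d_i, d_i+1), by cell midpoint;
    None for cells inside the configured gap."""
    mids = 0.5 * (d[:-1] + d[1:])
    return [course.terrain_at(float(m)) for m in mids]


def time_in_terrain(skier: LapSeries, course: CourseModel) -> dict[str, float]:
    """Percent of lap time accrued in each terrain (gap cells excluded)."""
    terr = _cell_terrains(skier.d, course)
    dt = np.diff(skier.time)
    totals = {t.value: 0.0 for t in Terrain}
    for trn, cell_dt in zip(terr, dt):
        if trn is not None:
            totals[trn.value] += float(cell_dt)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no elapsed time accrued on the grid")
    return {k: 100.0 * v / grand for k, v in totals.items()}


def compare(skier: LapSeries, ref: GroupReference, course: CourseModel) -> ComparisonResult:
    """Continuous and per-terrain comparison of a skier against a reference.

    Sign conventions: positive speed difference and positive time loss both
    mean the skier is slower than the reference.
    """
    if len(skier.d) != len(ref.d) or not np.allclose(skier.d, ref.d):
        raise ValueError("skier and reference must share the distance grid")
    d = skier.d
    abs_diff = ref.mean_speed - skier.speed
    rel_diff = 100.0 * abs_diff / ref.mean_speed
    accum = skier.time - ref.mean_time

    terr = _cell_terrains(d, course)
    cell_len = np.diff(d)
    dt_skier = np.diff(skier.time)
    dt_ref = np.diff(ref.mean_time)
    # pointwise relative difference evaluated at cell midpoints
    rel_mid = 0.5 * (rel_diff[:-1] + rel_diff[1:])
    v_mid = 0.5 * (skier.speed[:-1] + skier.speed[1:])

    rows = []
    order = [Terrain.UPHILL, Terrain.FLAT, Terrain.DOWNHILL]
    sel_all = np.array([trn is not None for trn in terr])
    for label, sel in [(t.value, np.array([trn == t for trn in terr])) for t in order] + [
        ("OVERALL", sel_all)
    ]:
        if not sel.any():
            rows.append({"terrain": label, "mean_speed": np.nan,
                         "rel_speed_diff_pct": np.nan, "rel_speed_diff_sd": np.nan,
                         "time_loss_s": 0.0, "distance_m": 0.0})
            continue
        w = cell_len[sel]
        rows.append(
            {
                "terrain": label,
                "mean_speed": float(np.average(v_mid[sel], weights=w)),
                "rel_speed_diff_pct": float(np.average(rel_mid[sel], weights=w)),
                "rel_speed_diff_sd": float(np.sqrt(np.average(
                    (rel_mid[sel] - np.average(rel_mid[sel], weights=w)) ** 2, weights=w))),
                "time_loss_s": float(np.sum(dt_skier[sel] - dt_ref[sel])),
                "distance_m": float(w.sum()),
            }
        )
    per_terrain = pd.DataFrame(rows).set_index("terrain")
    return ComparisonResult(
        d=d,
        abs_speed_diff=abs_diff,
        rel_speed_diff=rel_diff,
        accum_time_diff=accum,
        per_terrain=per_terrain,
        time_in_terrain=time_in_terrain(skier, course),
    )
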