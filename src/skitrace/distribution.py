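"""Sub-technique usage distributions across speed bins.

Each distance-grid cell of a lap contributes its length (distance
weighting) and its dwell time (time weighting) to the speed bin containing
its speed.  Within every occupied bin, the four class percentages sum to
100 for both weightings.  Bins the skier barely or never used are flagged
rather than zero-filled, mirroring how usage plots blank out unused speed
intervals.  Range summaries aggregate the bins inside a named speed range
(defaults: low 2.75–4.75 m/s, high 7–10 m/s) with occupancy weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skitrace.performance import LapSeries
from skitrace.subtechnique import CLASSES

#: bins a skier occupies for less than this many metres are "not used"
MIN_OCCUPANCY_M = 5.0


@dataclass(frozen=True)
class SpeedBinning:
    """Uniform speed bins plus the two named summary ranges (m/s)."""

    edges: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 11.0 + 1e-9, 0.25)
    )
    low_range: tuple[float, float] = (2.75, 4.75)
    high_range: tuple[float, float] = (7.0, 10.0)

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        for lo, hi in (self.low_range, self.high_range):
            for v in (lo, hi):
                if np.min(np.abs(self.edges - v)) > 1e-9:
                    raise ValueError(f"range endpoint {v} is not a bin edge")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def range_mask(self, rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        return (mids > lo) & (mids < hi)


@dataclass
class SubTechDistribution:
    """Per-bin class shares by distance and by time, with occupancies."""

    binning: SpeedBinning
    dist_m: np.ndarray  # (n_bins, n_classes) metres
    time_s: np.ndarray  # (n_bins, n_classes) seconds

    @property
    def occupancy_m(self) -> np.ndarray:
        return self.dist_m.sum(axis=1)

    @property
    def occupancy_s(self) -> np.ndarray:
        return self.time_s.sum(axis=1)

    @property
    def used(self) -> np.ndarray:
        return self.occupancy_m >= MIN_OCCUPANCY_M

    def pct(self, weighting: str = "distance") -> np.ndarray:
        """(n_bins, n_classes) class percentages; NaN rows for unused bins."""
        mat = self.dist_m if weighting == "distance" else self.time_s
        tot = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * mat / tot
        pct[~self.used] = np.nan
        return pct

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (bin, class)."""
        e = self.binning.edges
        pd_dist, pd_time = self.pct("distance"), self.pct("time")
        rows = []
        for b in range(self.binning.n_bins):
            for c, cls in enumerate(CLASSES):
                rows.append(
                    {
                        "bin_low": e[b],
                        "bin_high": e[b + 1],
                        "class": cls,
                        "pct_distance": pd_dist[b, c],
                        "pct_time": pd_time[b, c],
                        "meters": self.dist_m[b, c],
                        "seconds": self.time_s[b, c],
                        "used": bool(self.used[b]),
                    }
                )
        return pd.DataFrame(rows)


def bin_by_speed(
    labels: np.ndarray, series: LapSeries, binning: SpeedBinning | None = None
) -> SubTechDistribution:
    """Accumulate cell length and dwell time into speed bins per class.

    ``labels`` holds one class per grid cell (len(series.d) - 1 entries);
    cell speed is the mean of its endpoint speeds, cell dwell the elapsed
    time across it.
    """
    binning = binning or SpeedBinning()
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(series.d) - 1:
        raise ValueError("labels must have one entry per grid cell")
    cell_len = np.diff(series.d)
    cell_dt = np.diff(series.time)
    cell_v = 0.5 * (series.speed[:-1] + series.speed[1:])
    bin_idx = np.searchsorted(binning.edges, cell_v, side="right") - 1
    dist_m = np.zeros((binning.n_bins, len(CLASSES)))
    time_s = np.zeros_like(dist_m)
    cls_idx = {c: i for i, c in enumerate(CLASSES)}
    for b, lab, ln, dt in zip(bin_idx, labels, cell_len, cell_dt):
        if 0 <= b < binning.n_bins:
            c = cls_idx[str(lab)]
            dist_m[b, c] += ln
            time_s[b, c] += dt
    return SubTechDistribution(binning=binning, dist_m=dist_m, time_s=time_s)


def range_summary(dist: SubTechDistribution) -> pd.DataFrame:
    """Distance-share per class over the low and high speed ranges.

    Bins inside a range are aggregated with occupancy weighting (summing
    raw metres, equivalent to weighting bin percentages by bin occupancy).
    A range with zero occupancy is flagged missing (NaN percentages).
    """
    rows = []
    for name, rng in (("low", dist.binning.low_range), ("high", dist.binning.high_range)):
        mask = dist.binning.range_mask(rng)
        meters = dist.dist_m[mask].sum(axis=0)
        total = meters.sum()
        row = {"range": name, "speed_lo": rng[0], "speed_hi": rng[1], "meters": total}
        for c, cls in enumerate(CLASSES):
            row[cls] = 100.0 * meters[c] / total if total > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("range")


def group_distribution(members: list[SubTechDistribution]) -> SubTechDistribution:
    """Average a group's distributions: unweighted mean of member
    percentages per bin/class, skipping members for whom a bin is unused.

    The returned object carries synthetic per-bin masses chosen so that its
    pct() reproduces the group-mean percentages (mean percentage times the
    summed group occupancy), keeping one common representation.
    """
    if not members:
        raise ValueError("empty member list")
    binning = members[0].binning
    for m in members[1:]:
        if not np.allclose(m.binning.edges, binning.edges):
            raise ValueError("members must share the binning")
    def _avg(attr: str) -> np.ndarray:
        pcts = np.stack([m.pct(attr) for m in members])  # (m, bins, classes)
        # bins unused by every member stay NaN; silence the expected warning
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_pct = np.nanmean(pcts, axis=0)
        return mean_pct

    mean_pct_d = _avg("distance")
    mean_pct_t = _avg("time")
    occ_m = np.sum([m.occupancy_m for m in members], axis=0)
    occ_s = np.sum([m.occupancy_s for m in members], axis=0)
    dist_m = np.nan_to_num(mean_pct_d / 100.0) * occ_m[:, None]
    time_s = np.nan_to_num(mean_pct_t / 100.0) * occ_s[:, None]
    return SubTechDistribution(binning=binning, dist_m=dist_m, time_s=time_s)
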