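"""Reading, validation, synchronisation and kinematics of GNSS/IMU recordings.

The measurement model is a single body-worn unit producing a 10 Hz GNSS
stream (time, latitude, longitude, altitude) and a 100 Hz IMU stream
(tri-axial accelerometer and gyroscope, z axis pointing in the skier's
frontal direction).  Both streams share one clock.  Speed is derived by
time differentiation of position, so positions are first mapped into a
local planar frame; over a 2.5 km loop the planar approximation error is
negligible compared with receiver noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

#: WGS84 semi-major axis, metres.
_EARTH_RADIUS = 6378137.0

GNSS_CSV_COLUMNS = ("t", "lat", "lon", "alt")
IMU_CSV_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


@dataclass(frozen=True)
class GnssFix:
    """One GNSS fix: seconds since session start, WGS84 degrees, metres."""

    t: float
    lat: float
    lon: float
    alt: float


@dataclass(frozen=True)
class LocalProjection:
    """Planar projection centred on a reference fix.

    Equirectangular about (lat0, lon0): x is easting, y is northing, in
    metres.  The inverse is closed-form, so round-tripping a coordinate is
    exact to floating-point precision.
    """

    lat0: float
    lon0: float

    def forward(self, lat, lon):
        klat = math.radians(1.0) * _EARTH_RADIUS
        klon = klat * math.cos(math.radians(self.lat0))
        x = (np.asarray(lon, dtype=float) - self.lon0) * klon
        y = (np.asarray(lat, dtype=float) - self.lat0) * klat
        return x, y

    def inverse(self, x, y):
        klat = math.radians(1.0) * _EARTH_RADIUS
        klon = klat * math.cos(math.radians(self.lat0))
        lon = np.asarray(x, dtype=float) / klon + self.lon0
        lat = np.asarray(y, dtype=float) / klat + self.lat0
        return lat, lon


@dataclass
class Trajectory:
    """A GNSS track with derived planar coordinates and kinematics.

    All fields are 1-D arrays of equal length.  ``speed`` is horizontal
    speed in m/s (NaN until :func:`derive_speed` has run); ``cum_dist`` is
    the cumulative horizontal distance in metres.
    """

    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    alt: np.ndarray
    x: np.ndarray
    y: np.ndarray
    projection: LocalProjection
    speed: np.ndarray | None = None
    cum_dist: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fixes(self) -> list[GnssFix]:
        return [
            GnssFix(float(t), float(la), float(lo), float(al))
            for t, la, lo, al in zip(self.t, self.lat, self.lon, self.alt)
        ]

    def validate(self) -> None:
        if len(self.t) < 2:
            raise ValueError("trajectory needs at least 2 fixes")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("fix times must be strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("latitude/longitude out of range")


@dataclass
class ImuSeries:
    """100 Hz IMU samples; acc in m/s^2, gyr in rad/s.

    ``speed`` and ``cum_dist`` are attached per sample by :func:`align_imu`.
    """

    t: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    gyr_x: np.ndarray
    gyr_y: np.ndarray
    gyr_z: np.ndarray
    speed: np.ndarray | None = None
    cum_dist: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t)

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class SessionRecording:
    """One athlete's race recording plus metadata."""

    athlete_id: str
    trajectory: Trajectory
    imu: ImuSeries | None = None
    group: Literal["PARA", "AB"] = "AB"
    sex: Literal["F", "M"] = "F"
    class_label: str = ""
    n_laps: int = 4


def trajectory_from_arrays(t, lat, lon, alt, projection: LocalProjection | None = None) -> Trajectory:
    """Build a Trajectory from raw arrays: sort, dedup, project, accumulate."""
    t = np.asarray(t, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    alt = np.asarray(alt, dtype=float)
    order = np.argsort(t, kind="stable")
    t, lat, lon, alt = t[order], lat[order], lon[order], alt[order]
    # collapse duplicate timestamps, keeping the first occurrence
    keep = np.concatenate(([True], np.diff(t) > 0))
    if not keep.all():
        logger.warning("collapsed %d duplicate timestamps", int((~keep).sum()))
        t, lat, lon, alt = t[keep], lat[keep], lon[keep], alt[keep]
    if len(t) < 2:
        raise ValueError("trajectory needs at least 2 fixes")
    if projection is None:
        med = len(t) // 2
        projection = LocalProjection(float(lat[med]), float(lon[med]))
    x, y = projection.forward(lat, lon)
    traj = Trajectory(t=t, lat=lat, lon=lon, alt=alt, x=x, y=y, projection=projection)
    traj.validate()
    return cumulative_distance(traj)


def _parse_times(values) -> np.ndarray:
    """Accept float seconds or ISO timestamps; return seconds from start."""
    try:
        return np.asarray(values, dtype=float)
    except (TypeError, ValueError):
        ts = pd.to_datetime(list(values), utc=True)
        sec = (ts - ts[0]).total_seconds()
        return np.asarray(sec, dtype=float)


def read_gnss(path: str | Path, fmt: Literal["gpx", "csv"] | None = None) -> Trajectory:
    """Read a GNSS track from GPX 1.1 or CSV (columns t, lat, lon, alt).

    Fixes are returned time-sorted with duplicate timestamps collapsed
    (first kept).  Altitude is required: the terrain model cannot be built
    without it.  Times are converted to seconds since the first fix.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gpx" if path.suffix.lower() == ".gpx" else "csv"
    if fmt == "gpx":
        t, lat, lon, alt = _read_gpx(path)
    elif fmt == "csv":
        df = pd.read_csv(path)
        missing = [c for c in GNSS_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"GNSS CSV missing columns {missing}")
        if df["alt"].isna().any():
            raise ValueError("altitude required for every fix")
        t = _parse_times(df["t"].to_numpy())
        lat, lon, alt = (df[c].to_numpy(dtype=float) for c in ("lat", "lon", "alt"))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    t = t - t.min()
    return trajectory_from_arrays(t, lat, lon, alt)


def _read_gpx(path: Path):
    tree = etree.parse(str(path))
    pts = tree.findall(".//{*}trkpt")
    if not pts:
        raise ValueError(f"no track points in {path}")
    lat, lon, alt, times = [], [], [], []
    for p in pts:
        lat.append(float(p.get("lat")))
        lon.append(float(p.get("lon")))
        ele = p.find("{*}ele")
        if ele is None or ele.text is None:
            raise ValueError("GPX track point without elevation; altitude is required")
        alt.append(float(ele.text))
        tm = p.find("{*}time")
        if tm is None or tm.text is None:
            raise ValueError("GPX track point without timestamp")
        times.append(tm.text)
    t = _parse_times(times)
    return t, np.asarray(lat), np.asarray(lon), np.asarray(alt)


def write_gpx(traj: Trajectory, path: str | Path, t0: str = "2021-01-01T10:00:00Z") -> None:
    """Write a trajectory as GPX 1.1 (trkpt lat/lon/ele/time)."""
    ns = "http://www.topografix.com/GPX/1/1"
    gpx = etree.Element(f"{{{ns}}}gpx", version="1.1", creator="skitrace")
    seg = etree.SubElement(etree.SubElement(gpx, f"{{{ns}}}trk"), f"{{{ns}}}trkseg")
    base = pd.Timestamp(t0)
    for i in range(len(traj)):
        pt = etree.SubElement(
            seg, f"{{{ns}}}trkpt", lat=f"{traj.lat[i]:.8f}", lon=f"{traj.lon[i]:.8f}"
        )
        etree.SubElement(pt, f"{{{ns}}}ele").text = f"{traj.alt[i]:.3f}"
        stamp = base + pd.to_timedelta(traj.t[i], unit="s")
        etree.SubElement(pt, f"{{{ns}}}time").text = stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
    etree.ElementTree(gpx).write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def write_gnss_csv(traj: Trajectory, path: str | Path) -> None:
    df = pd.DataFrame({"t": traj.t, "lat": traj.lat, "lon": traj.lon, "alt": traj.alt})
    if traj.speed is not None:
        df["speed"] = traj.speed
    if traj.cum_dist is not None:
        df["cum_dist"] = traj.cum_dist
    df.to_csv(path, index=False)


def read_imu_csv(path: str | Path) -> ImuSeries:
    """Read an IMU stream from CSV (columns t, ax, ay, az, gx, gy, gz)."""
    df = pd.read_csv(path)
    missing = [c for c in IMU_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IMU CSV missing columns {missing}")
    t = _parse_times(df["t"].to_numpy())
    if not np.all(np.diff(t) > 0):
        raise ValueError("IMU sample times must be strictly increasing")
    return ImuSeries(
        t=t,
        acc_x=df["ax"].to_numpy(dtype=float),
        acc_y=df["ay"].to_numpy(dtype=float),
        acc_z=df["az"].to_numpy(dtype=float),
        gyr_x=df["gx"].to_numpy(dtype=float),
        gyr_y=df["gy"].to_numpy(dtype=float),
        gyr_z=df["gz"].to_numpy(dtype=float),
    )


def write_imu_csv(imu: ImuSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": imu.t,
            "ax": imu.acc_x,
            "ay": imu.acc_y,
            "az": imu.acc_z,
            "gx": imu.gyr_x,
            "gy": imu.gyr_y,
            "gz": imu.gyr_z,
        }
    ).to_csv(path, index=False)


def derive_speed(traj: Trajectory, smooth_window_s: float = 1.0) -> Trajectory:
    """Horizontal speed from time differentiation of planar position.

    Central finite differences at interior fixes, one-sided at the ends,
    then a centred moving average of ``smooth_window_s`` seconds (set 0 to
    disable).  10 Hz differentiated positions are noisy; the 1 s default is
    much shorter than any terrain segment so it does not bias the pacing
    analysis.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 fixes to differentiate")
    if not np.all(np.diff(traj.t) > 0):
        raise ValueError("fix times must be strictly increasing")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    if smooth_window_s > 0:
        dt = float(np.median(np.diff(traj.t)))
        n = max(1, int(round(smooth_window_s / dt)))
        if n > 1:
            kernel = np.ones(n)
            num = np.convolve(speed, kernel, mode="same")
            den = np.convolve(np.ones_like(speed), kernel, mode="same")
            speed = num / den
    return replace(traj, speed=speed)


def cumulative_distance(traj: Trajectory) -> Trajectory:
    """Cumulative horizontal distance: running sum of planar step lengths."""
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    return replace(traj, cum_dist=cum)


def align_imu(rec: SessionRecording) -> SessionRecording:
    """Synchronise the IMU stream to the GNSS track.

    IMU samples outside the GNSS time span are trimmed; each remaining
    sample gets a speed and cumulative distance linearly interpolated from
    the GNSS-derived series.
    """
    traj, imu = rec.trajectory, rec.imu
    if imu is None:
        raise ValueError("recording has no IMU stream")
    if traj.speed is None or traj.cum_dist is None:
        raise ValueError("run derive_speed/cumulative_distance on the trajectory first")
    t0, t1 = traj.t[0], traj.t[-1]
    if imu.t[-1] < t0 or imu.t[0] > t1:
        raise ValueError("IMU and GNSS time ranges do not overlap")
    keep = (imu.t >= t0) & (imu.t <= t1)
    trimmed = ImuSeries(
        t=imu.t[keep],
        acc_x=imu.acc_x[keep],
        acc_y=imu.acc_y[keep],
        acc_z=imu.acc_z[keep],
        gyr_x=imu.gyr_x[keep],
        gyr_y=imu.gyr_y[keep],
        gyr_z=imu.gyr_z[keep],
        speed=np.interp(imu.t[keep], traj.t, traj.speed),
        cum_dist=np.interp(imu.t[keep], traj.t, traj.cum_dist),
    )
    return replace_recording(rec, imu=trimmed)


def replace_recording(rec: SessionRecording, **kw) -> SessionRecording:
    params = dict(
        athlete_id=rec.athlete_id,
        trajectory=rec.trajectory,
        imu=rec.imu,
        group=rec.group,
        sex=rec.sex,
        class_label=rec.class_label,
        n_laps=rec.n_laps,
    )
    params.update(kw)
    return SessionRecording(**params)
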