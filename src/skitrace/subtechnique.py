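"""Classical sub-technique classification from body-worn IMU signals.

The classifier follows the established sliding-window scheme for
classical-style skiing: the frontal-axis (z) accelerometer and gyroscope
channels are low-pass filtered, cut into 2 s windows of 200 samples with
95% overlap (a 10-sample hop at 100 Hz), summarised into per-window
features, and labelled by a k-nearest-neighbour vote against a fixed
training set shared across skiers.  Classes are DP (double poling), DK
(kick double poling), DIA (diagonal stride, folding in herringbone) and
OTHER (tuck, turns, unclassifiable cycles).  Automatic labels can be
overridden by a manual-correction pass, mirroring the visual inspection an
analyst performs on unfamiliar movement patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.neighbors import NearestNeighbors

CLASSES = ("DP", "DK", "DIA", "OTHER")
_CLASS_RANK = {c: i for i, c in enumerate(CLASSES)}

WINDOW_SAMPLES = 200
HOP_SAMPLES = 10  # 95% overlap of a 200-sample window
DEFAULT_RATE_HZ = 100.0
N_FEATURES = 13


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass filter: cutoff in Hz, Butterworth order."""

    cutoff_hz: float = 5.0
    order: int = 4

    def __post_init__(self):
        if not 0 < self.cutoff_hz < DEFAULT_RATE_HZ / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        if self.order < 2:
            raise ValueError("order must be >= 2")


@dataclass
class ImuWindow:
    start_idx: int
    acc_z: np.ndarray
    gyr_z: np.ndarray
    speed: float = float("nan")
    cum_dist: float = float("nan")


@dataclass
class TrainingSet:
    """Labelled feature vectors plus the z-scoring statistics they imply."""

    X: np.ndarray  # (n, 13)
    y: list[str]
    mean: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X and y are inconsistent")
        if len(self.y) == 0:
            raise ValueError("empty training set")
        unknown = set(self.y) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown labels {unknown}")
        self.mean = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        self.scale = np.where(sd > 0, sd, 1.0)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class SubTechniqueTrack:
    """Per-window labels plus optional per-distance labels and corrections."""

    window_labels: list[str]
    window_dists: np.ndarray  # cum_dist of window centres, metres
    window_speeds: np.ndarray | None = None
    dist_labels: np.ndarray | None = None
    corrections: list[tuple[int, int, str]] = field(default_factory=list)
    correction_fraction: float = 0.0


def lowpass(x: np.ndarray, spec: FilterSpec, rate_hz: float = DEFAULT_RATE_HZ) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if spec.cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff at or above Nyquist")
    if len(x) < 3 * spec.order:
        raise ValueError("signal too short to filter")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def make_windows(imu, spec: FilterSpec | None = None) -> list[ImuWindow]:
    """Cut an aligned IMU series into 200-sample windows, 10-sample hop.

    The z channels are low-pass filtered once over the whole series before
    windowing; window count is floor((N-200)/10)+1.
    """
    n = len(imu.t)
    if n < WINDOW_SAMPLES:
        raise ValueError(f"need at least {WINDOW_SAMPLES} samples, got {n}")
    spec = spec or FilterSpec()
    rate = 1.0 / float(np.median(np.diff(imu.t)))
    acc = lowpass(imu.acc_z, spec, rate)
    gyr = lowpass(imu.gyr_z, spec, rate)
    speed = imu.speed if imu.speed is not None else np.full(n, np.nan)
    cdist = imu.cum_dist if imu.cum_dist is not None else np.full(n, np.nan)
    windows = []
    for start in range(0, n - WINDOW_SAMPLES + 1, HOP_SAMPLES):
        stop = start + WINDOW_SAMPLES
        centre = start + WINDOW_SAMPLES // 2
        windows.append(
            ImuWindow(
                start_idx=start,
                acc_z=acc[start:stop],
                gyr_z=gyr[start:stop],
                speed=float(np.nanmean(speed[start:stop])),
                cum_dist=float(cdist[centre]),
            )
        )
    return windows


def _channel_features(x: np.ndarray, rate_hz: float) -> list[float]:
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    sd = float(x.std())
    rms = float(np.sqrt(np.mean(x**2)))
    centred = x - mean
    # dominant frequency on a zero-padded grid (raw 2 s windows only resolve
    # 0.5 Hz; skiing cadences differ by less)
    nfft = 1024
    spec = np.abs(np.fft.rfft(centred, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate_hz)
    total = float(spec[1:].sum())
    if total <= 0:
        dom_f, share = 0.0, 0.0
    else:
        k = 1 + int(np.argmax(spec[1:]))
        dom_f = float(freqs[k])
        share = float(spec[k] / total)
    crossings = np.count_nonzero(np.diff(np.signbit(centred)))
    zcr = crossings * rate_hz / max(len(x) - 1, 1)  # crossings per second
    return [mean, sd, rms, dom_f, share, zcr]


def featurize(window: ImuWindow, rate_hz: float = DEFAULT_RATE_HZ) -> np.ndarray:
    """13-dim feature vector for one window.

    Per channel (acc_z then gyr_z): mean, SD, RMS, dominant frequency and
    its spectral power share, zero-crossing rate; plus the lag (seconds) of
    the peak of the acc/gyr cross-correlation — the phase relation between
    trunk acceleration and rotation separates synchronous-pole techniques
    from alternating ones.
    """
    feats = _channel_features(window.acc_z, rate_hz) + _channel_features(
        window.gyr_z, rate_hz
    )
    a = window.acc_z - window.acc_z.mean()
    g = window.gyr_z - window.gyr_z.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(g**2))
    if denom <= 0:
        lag_s = 0.0
    else:
        cc = sps.correlate(a, g, mode="full")
        lags = sps.correlation_lags(len(a), len(g), mode="full")
        # restrict to ±1 s: cadence periods are shorter than that
        max_lag = int(rate_hz)
        sel = np.abs(lags) <= max_lag
        lag_s = float(lags[sel][np.argmax(cc[sel])] / rate_hz)
    feats.append(lag_s)
    out = np.asarray(feats, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature computed")
    return out


def knn_classify(train: TrainingSet, features: np.ndarray, k: int = 5) -> str:
    """Majority label among the k nearest training exemplars.

    Features are z-scored with the training statistics.  Vote ties break
    first by smaller mean neighbour distance, then by the fixed class
    order DP < DK < DIA < OTHER, so the result is deterministic.
    """
    return classify_features(train, np.atleast_2d(features), k)[0]


def classify_features(train: TrainingSet, X: np.ndarray, k: int = 5) -> list[str]:
    """Vectorised KNN over many feature rows (same contract as knn_classify)."""
    if len(train) == 0:
        raise ValueError("empty training set")
    if k > len(train):
        raise ValueError("k exceeds training set size")
    Xs = train.standardize(np.atleast_2d(X))
    Ts = train.standardize(train.X)
    nn = NearestNeighbors(n_neighbors=k).fit(Ts)
    dist, idx = nn.kneighbors(Xs)
    y = np.asarray(train.y)
    labels = []
    for drow, irow in zip(dist, idx):
        votes: dict[str, list[float]] = {}
        for d, i in zip(drow, irow):
            votes.setdefault(y[i], []).append(float(d))
        best = min(
            votes.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), _CLASS_RANK[kv[0]]),
        )
        labels.append(best[0])
    return labels


def classify_windows(
    train: TrainingSet, windows: list[ImuWindow], k: int = 5,
    rate_hz: float = DEFAULT_RATE_HZ,
) -> SubTechniqueTrack:
    """Featurize and label every window; returns a per-window label track."""
    X = np.vstack([featurize(w, rate_hz) for w in windows])
    labels = classify_features(train, X, k)
    return SubTechniqueTrack(
        window_labels=labels,
        window_dists=np.array([w.cum_dist for w in windows]),
        window_speeds=np.array([w.speed for w in windows]),
    )


def labels_to_distance(
    track: SubTechniqueTrack, grid: np.ndarray, lap_length: float | None = None
) -> np.ndarray:
    """Majority label per distance-grid cell.

    Cell i covers [grid[i], grid[i+1]); a window votes in the cell holding
    its centre.  With ``lap_length`` given, window distances are folded
    onto the lap axis first.  Cells no window covers inherit the label of
    the nearest labelled cell.  Returns len(grid)-1 labels.
    """
    grid = np.asarray(grid, dtype=float)
    dists = track.window_dists.copy()
    if lap_length is not None:
        dists = np.mod(dists, lap_length)
    ncell = len(grid) - 1
    counts = np.zeros((ncell, len(CLASSES)), dtype=int)
    cell_idx = np.searchsorted(grid, dists, side="right") - 1
    for ci, lab in zip(cell_idx, track.window_labels):
        if 0 <= ci < ncell:
            counts[ci, _CLASS_RANK[lab]] += 1
    labels = np.empty(ncell, dtype=object)
    covered = counts.sum(axis=1) > 0
    for i in np.nonzero(covered)[0]:
        labels[i] = CLASSES[int(np.argmax(counts[i]))]  # argmax ties -> class order
    if not covered.any():
        raise ValueError("no window covers the grid")
    empty = np.nonzero(~covered)[0]
    if len(empty):
        cov_idx = np.nonzero(covered)[0]
        for i in empty:
            labels[i] = labels[cov_idx[np.argmin(np.abs(cov_idx - i))]]
    return labels


def apply_corrections(
    track: SubTechniqueTrack, corrections: list[tuple[int, int, str]] | None = None
) -> SubTechniqueTrack:
    """Overwrite window labels with manual corrections, in list order.

    A correction is (start_window, end_window_exclusive, label).  Later
    corrections win on overlaps.  The returned track records the fraction
    of windows touched, the analyst's correction-effort figure.
    """
    corrections = list(corrections if corrections is not None else track.corrections)
    labels = list(track.window_labels)
    n = len(labels)
    touched = np.zeros(n, dtype=bool)
    for start, stop, lab in corrections:
        if not (0 <= start < stop <= n):
            raise ValueError(f"correction range ({start}, {stop}) outside 0..{n}")
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}")
        if touched[start:stop].any():
            import logging

            logging.getLogger(__name__).warning(
                "overlapping correction (%d, %d): later range wins", start, stop
            )
        labels[start:stop] = [lab] * (stop - start)
        touched[start:stop] = True
    return SubTechniqueTrack(
        window_labels=labels,
        window_dists=track.window_dists,
        window_speeds=track.window_speeds,
        dist_labels=None,
        corrections=corrections,
        correction_fraction=float(touched.sum()) / n if n else 0.0,
    )


def default_training_set(
    seed: int = 42, windows_per_class: int = 60, spec: FilterSpec | None = None
) -> TrainingSet:
    """The packaged training set: simulator-generated exemplar windows.

    Deterministic in ``seed``; each class contributes ``windows_per_class``
    windows rendered from that class's cyclic signal template at a
    representative speed.  Users with labelled field data should build
    their own TrainingSet instead.
    """
    from skitrace.simulate import training_windows

    return training_windows(seed=seed, windows_per_class=windows_per_class, spec=spec)


def training_set_to_csv(train: TrainingSet, path) -> None:
    """Persist a training set as CSV: 13 feature columns plus a label."""
    import pandas as pd

    df = pd.DataFrame(train.X, columns=[f"f{i}" for i in range(train.X.shape[1])])
    df["label"] = train.y
    df.to_csv(path, index=False)


def training_set_from_csv(path) -> TrainingSet:
    import pandas as pd

    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("training CSV needs a 'label' column")
    X = df.drop(columns=["label"]).to_numpy(dtype=float)
    return TrainingSet(X=X, y=list(df["label"]))


def per_distance_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of distance cells whose label matches the ground truth."""
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ValueError("label arrays differ in length")
    return float(np.mean(pred == truth))
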