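"""Filtering, windowing, features and the KNN sub-technique classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skitrace.subtechnique import (
    CLASSES,
    HOP_SAMPLES,
    WINDOW_SAMPLES,
    FilterSpec,
    ImuWindow,
    SubTechniqueTrack,
    TrainingSet,
    apply_corrections,
    classify_features,
    featurize,
    knn_classify,
    labels_to_distance,
    lowpass,
    make_windows,
    training_set_from_csv,
    training_set_to_csv,
)
from skitrace.track_io import ImuSeries


def _imu(acc_z, gyr_z=None, rate=100.0):
    n = len(acc_z)
    t = np.arange(n) / rate
    z = np.zeros(n)
    g = gyr_z if gyr_z is not None else z
    return ImuSeries(t=t, acc_x=z, acc_y=z, acc_z=np.asarray(acc_z, float),
                     gyr_x=z, gyr_y=z, gyr_z=np.asarray(g, float),
                     speed=np.full(n, 5.0), cum_dist=5.0 * t)


def _fft_amplitude(x, freq, rate=100.0):
    n = len(x)
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, 1 / rate)
    k = np.argmin(np.abs(freqs - freq))
    return 2 * np.abs(spec[k]) / n


class TestLowpass:
    def test_dc_passes_unchanged(self):
        x = np.full(1000, 3.7)
        y = lowpass(x, FilterSpec(5.0, 4))
        assert np.allclose(y, x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, FilterSpec(5.0, 4))
        assert abs(_fft_amplitude(y, 1.0) - 1.0) < 0.01

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 20.0 * t)
        y = lowpass(x, FilterSpec(5.0, 4))
        assert _fft_amplitude(y, 20.0) < 0.05

    def test_cutoff_at_nyquist_errors(self):
        with pytest.raises(ValueError):
            FilterSpec(cutoff_hz=50.0)
        with pytest.raises(ValueError):
            lowpass(np.zeros(100), FilterSpec(10.0, 4), rate_hz=20.0)


class TestMakeWindows:
    @pytest.mark.parametrize("n,expected", [(200, 1), (209, 1), (210, 2), (1000, 81)])
    def test_window_counts(self, n, expected):
        wins = make_windows(_imu(np.random.default_rng(0).normal(size=n)))
        assert len(wins) == expected

    def test_windows_advance_by_hop(self):
        wins = make_windows(_imu(np.zeros(400)))
        starts = [w.start_idx for w in wins]
        assert starts == list(range(0, 201, HOP_SAMPLES))
        assert all(len(w.acc_z) == WINDOW_SAMPLES for w in wins)

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            make_windows(_imu(np.zeros(199)))

    @settings(derandomize=True, max_examples=60)
    @given(n=st.integers(200, 5000))
    def test_count_formula_property(self, n):
        wins = make_windows(_imu(np.zeros(n)))
        assert len(wins) == (n - WINDOW_SAMPLES) // HOP_SAMPLES + 1


class TestFeaturize:
    def _window(self, acc, gyr):
        return ImuWindow(0, np.asarray(acc, float), np.asarray(gyr, float), 5.0, 10.0)

    def test_constant_window_degenerate_features(self):
        f = featurize(self._window(np.full(200, 2.0), np.full(200, -1.0)))
        assert len(f) == 13
        assert f[1] == 0.0 and f[5] == 0.0  # acc SD and zero-crossing rate
        assert f[3] == 0.0  # dominant frequency reported 0
        assert np.all(np.isfinite(f))

    def test_sinusoid_dominant_frequency(self):
        t = np.arange(200) / 100.0
        f = featurize(self._window(np.sin(2 * np.pi * 1.2 * t), np.zeros(200)))
        assert abs(f[3] - 1.2) < 0.1  # zero-padded FFT grid resolution

    def test_identical_channels_zero_lag(self):
        t = np.arange(200) / 100.0
        x = np.sin(2 * np.pi * 0.9 * t)
        f = featurize(self._window(x, x))
        assert f[12] == 0.0

    def test_quarter_cycle_lag_detected(self):
        t = np.arange(200) / 100.0
        freq = 1.0
        acc = np.sin(2 * np.pi * freq * t)
        gyr = np.cos(2 * np.pi * freq * t)
        f = featurize(self._window(acc, gyr))
        assert abs(abs(f[12]) - 0.25) < 0.05  # quarter period of 1 Hz


def brute_force_knn(train, feats, k):
    """Independent oracle: full distance sort with the same tie-breaks."""
    X = train.standardize(train.X)
    q = train.standardize(np.atleast_2d(feats))[0]
    d = np.sqrt(((X - q) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    by_class = {}
    for i in order:
        by_class.setdefault(train.y[i], []).append(d[i])
    rank = {c: j for j, c in enumerate(CLASSES)}
    return min(
        by_class.items(),
        key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), rank[kv[0]]),
    )[0]


def _random_train(rng, n=40):
    X = rng.normal(size=(n, 13))
    y = [CLASSES[i] for i in rng.integers(0, 4, n)]
    # ensure every class occurs
    for j, c in enumerate(CLASSES):
        y[j] = c
    return TrainingSet(X=X, y=y)


class TestKnnClassify:
    def test_query_equal_to_exemplar_k1(self, rng):
        train = _random_train(rng)
        for i in (0, 5, 17):
            assert knn_classify(train, train.X[i], k=1) == train.y[i]

    def test_k_equals_n_with_uniform_labels(self, rng):
        X = rng.normal(size=(10, 13))
        train = TrainingSet(X=X, y=["DK"] * 10)
        assert knn_classify(train, rng.normal(size=13), k=10) == "DK"

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            train = _random_train(rng)
            q = rng.normal(size=13)
            assert knn_classify(train, q, k=5) == brute_force_knn(train, q, 5)

    def test_deterministic(self, rng):
        train = _random_train(rng)
        q = rng.normal(size=13)
        labels = {knn_classify(train, q, k=5) for _ in range(5)}
        assert len(labels) == 1

    def test_empty_or_oversized_k_errors(self, rng):
        train = _random_train(rng, n=8)
        with pytest.raises(ValueError):
            knn_classify(train, rng.normal(size=13), k=9)
        with pytest.raises(ValueError):
            TrainingSet(X=np.zeros((0, 13)), y=[])


class TestLabelsToDistance:
    def _track(self, labels, dists):
        return SubTechniqueTrack(
            window_labels=list(labels), window_dists=np.asarray(dists, float)
        )

    def test_all_dp_everywhere(self):
        grid = np.arange(0, 101.0, 5.0)
        track = self._track(["DP"] * 30, np.linspace(1, 99, 30))
        assert all(lab == "DP" for lab in labels_to_distance(track, grid))

    def test_majority_in_cell(self):
        grid = np.array([0.0, 5.0])
        track = self._track(["DP", "DP", "DIA"], [1.0, 2.0, 3.0])
        assert labels_to_distance(track, grid)[0] == "DP"

    def test_empty_cells_inherit_nearest(self):
        grid = np.arange(0, 21.0, 5.0)  # 4 cells
        track = self._track(["DIA"], [2.0])
        labels = labels_to_distance(track, grid)
        assert all(lab == "DIA" for lab in labels)

    def test_randomized_against_vote_oracle(self, rng):
        grid = np.arange(0, 201.0, 5.0)
        for _ in range(20):
            n = rng.integers(5, 80)
            dists = rng.uniform(0, 200, n)
            labs = [CLASSES[i] for i in rng.integers(0, 4, n)]
            got = labels_to_distance(self._track(labs, dists), grid)
            rank = {c: j for j, c in enumerate(CLASSES)}
            for i in range(len(grid) - 1):
                votes = [l for l, d in zip(labs, dists) if grid[i] <= d < grid[i + 1]]
                if votes:
                    counts = {c: votes.count(c) for c in set(votes)}
                    exp = min(counts.items(), key=lambda kv: (-kv[1], rank[kv[0]]))[0]
                    assert got[i] == exp

    def test_folding_onto_lap_axis(self):
        grid = np.array([0.0, 5.0, 10.0])
        track = self._track(["DP", "DIA"], [102.0, 7.0])  # 102 folds to 2
        labels = labels_to_distance(track, grid, lap_length=100.0)
        assert list(labels) == ["DP", "DIA"]


class TestApplyCorrections:
    def _track(self, n=20):
        return SubTechniqueTrack(
            window_labels=["DP"] * n, window_dists=np.arange(n, dtype=float)
        )

    def test_empty_corrections_identity(self):
        out = apply_corrections(self._track(), [])
        assert out.window_labels == ["DP"] * 20
        assert out.correction_fraction == 0.0

    def test_range_corrected_and_fraction(self):
        out = apply_corrections(self._track(), [(0, 10, "OTHER")])
        assert out.window_labels[:10] == ["OTHER"] * 10
        assert out.window_labels[10:] == ["DP"] * 10
        assert np.isclose(out.correction_fraction, 0.5)

    def test_overlapping_later_wins(self):
        out = apply_corrections(self._track(), [(0, 10, "DIA"), (5, 15, "DK")])
        assert out.window_labels[0:5] == ["DIA"] * 5
        assert out.window_labels[5:15] == ["DK"] * 10

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            apply_corrections(self._track(), [(15, 25, "DK")])


def test_training_set_csv_round_trip(tmp_path, training_set):
    p = tmp_path / "train.csv"
    training_set_to_csv(training_set, p)
    back = training_set_from_csv(p)
    assert np.allclose(back.X, training_set.X)
    assert back.y == training_set.y


def test_packaged_training_set_is_deterministic_and_balanced(training_set):
    from skitrace.subtechnique import default_training_set

    again = default_training_set(seed=42, windows_per_class=60)
    assert np.array_equal(again.X, training_set.X)
    for c in CLASSES:
        assert training_set.y.count(c) == 60


def test_training_classes_are_separable(training_set):
    # leave-one-out self-classification of the exemplars
    labels = classify_features(training_set, training_set.X, k=5)
    acc = np.mean([a == b for a, b in zip(labels, training_set.y)])
    assert acc > 0.95
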