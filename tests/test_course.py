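"""Elevation profile construction and terrain segmentation rules."""

import numpy as np
import pytest

from skitrace.course import (
    CourseModel,
    CourseSegment,
    ElevationProfile,
    Terrain,
    actual_distance,
    build_profile,
    detect_segments,
    merge_undulating,
    terrain_composition,
)
from skitrace.simulate import (
    DEFAULT_COURSE_LEGS,
    CourseSpec,
    default_course,
    simulate_course,
    simulate_race,
)
from skitrace.track_io import LocalProjection, trajectory_from_arrays


def _traj_from_profile(d, z, laps=1, speed=5.0):
    """Trajectory riding along x with the given altitude profile per lap."""
    lap = d[-1]
    s = np.arange(0.0, laps * lap + 0.5, speed / 10.0)
    t = s / speed
    alt = np.interp(np.mod(s, lap), d, z)
    proj = LocalProjection(61.0, 8.5)
    lat, lon = proj.inverse(s, np.zeros_like(s))
    return trajectory_from_arrays(t, lat, lon, alt)


class TestBuildProfile:
    def test_flat_track_constant_profile(self):
        d = np.arange(0, 1001.0, 5.0)
        traj = _traj_from_profile(d, np.full(len(d), 100.0))
        prof = build_profile(traj, 1000.0)
        assert np.allclose(prof.z, 100.0, atol=1e-9)

    def test_grid_point_count(self):
        d = np.arange(0, 2465.1, 5.0)
        traj = _traj_from_profile(d, np.full(len(d), 100.0))
        prof = build_profile(traj, 2465.0, grid_m=5.0)
        assert len(prof.d) == 494  # floor(2465/5) + 1

    def test_nonpositive_lap_length_errors(self):
        d = np.arange(0, 1001.0, 5.0)
        traj = _traj_from_profile(d, np.full(len(d), 100.0))
        with pytest.raises(ValueError):
            build_profile(traj, -1.0)

    def test_multilap_median_beats_single_lap(self):
        # 4 laps with independent altitude noise: the aggregated profile
        # should beat a single noisy lap (Monte-Carlo, fixed seed)
        rng = np.random.default_rng(99)
        d = np.arange(0, 1001.0, 5.0)
        z_true = 100.0 + 10 * np.sin(2 * np.pi * d / 1000.0)
        wins = 0
        for _ in range(20):
            lap = d[-1]
            s = np.arange(0.0, 4 * lap + 0.5, 0.5)
            alt_true = np.interp(np.mod(s, lap), d, z_true)
            alt = alt_true + rng.normal(0, 2.0, len(s))
            proj = LocalProjection(61.0, 8.5)
            lat, lon = proj.inverse(s, np.zeros_like(s))
            traj = trajectory_from_arrays(s / 5.0, lat, lon, alt)
            prof4 = build_profile(traj, lap)
            one = trajectory_from_arrays(
                s[s <= lap] / 5.0, lat[s <= lap], lon[s <= lap], alt[s <= lap]
            )
            prof1 = build_profile(one, lap)
            ref = np.interp(prof4.d, d, z_true)
            rmse4 = np.sqrt(np.mean((prof4.z - ref) ** 2))
            rmse1 = np.sqrt(np.mean((prof1.z - ref) ** 2))
            wins += rmse4 < rmse1
        assert wins >= 16  # clearly better on average


class TestDetectSegments:
    def test_monotone_ramp_single_uphill(self):
        d = np.arange(0, 501.0, 5.0)
        prof = ElevationProfile(d=d, z=100 + 20 * d / 500.0)
        model = detect_segments(prof)
        assert len(model.segments) == 1
        assert model.segments[0].terrain is Terrain.UPHILL
        assert np.isclose(model.segments[0].elev_diff, 20.0)

    def test_sawtooth_breakpoints_recovered(self):
        # alternating +-10 m legs of 200 m: breakpoints known by construction
        legs = 6
        d = np.arange(0, legs * 200 + 1.0, 5.0)
        z = 100 + 10 * np.abs(((d / 200.0) % 2) - 1)  # triangle wave
        model = detect_segments(ElevationProfile(d=d, z=z))
        assert len(model.segments) == legs
        expected = [Terrain.DOWNHILL if k % 2 == 0 else Terrain.UPHILL for k in range(legs)]
        assert [s.terrain for s in model.segments] == expected
        for k, seg in enumerate(model.segments):
            assert abs(seg.start_m - 200.0 * k) <= 10.0

    def test_reference_course_counts_and_composition(self):
        # profile of the built-in 2.5 km lap: 3 uphill, 3 flat, 4 downhill,
        # 37/15/48% of the length
        prof, _ = simulate_course(default_course())
        model = detect_segments(prof)
        counts = {t: 0 for t in Terrain}
        for s in model.segments:
            counts[s.terrain] += 1
        assert counts == {Terrain.UPHILL: 3, Terrain.FLAT: 3, Terrain.DOWNHILL: 4}
        comp = terrain_composition(model)
        assert round(100 * comp[Terrain.UPHILL]) == 37
        assert round(100 * comp[Terrain.FLAT]) == 15
        assert round(100 * comp[Terrain.DOWNHILL]) == 48

    def test_short_profile_errors(self):
        d = np.arange(0, 31.0, 5.0)
        with pytest.raises(ValueError):
            detect_segments(ElevationProfile(d=d, z=np.zeros(len(d))))

    def test_partition_tiles_the_lap(self, race_sim):
        from skitrace.track_io import derive_speed

        traj = derive_speed(race_sim.gnss)
        model = detect_segments(build_profile(traj, race_sim.lap_length))
        assert model.segments[0].start_m == 0.0
        for a, b in zip(model.segments[:-1], model.segments[1:]):
            assert abs(a.end_m - b.start_m) < 1e-6
        assert abs(model.segments[-1].end_m - race_sim.lap_length) < 1e-6

    def test_threshold_compliance_random_profiles(self):
        # every surviving uphill/downhill satisfies the 4 m rule
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = np.arange(0, 801.0, 5.0)
            z = np.cumsum(rng.normal(0, 0.25, len(d))) + 100
            model = detect_segments(ElevationProfile(d=d, z=z))
            for seg in model.segments:
                if seg.terrain is Terrain.UPHILL:
                    assert seg.elev_diff >= 4.0
                elif seg.terrain is Terrain.DOWNHILL:
                    assert seg.elev_diff <= -4.0

    def test_idempotent_on_own_piecewise_profile(self):
        prof, _ = simulate_course(default_course())
        m1 = detect_segments(prof)
        # rebuild a piecewise-linear profile from the detected segments
        knots = [m1.segments[0].start_m] + [s.end_m for s in m1.segments]
        zk = np.interp(knots, prof.d, prof.z)
        z2 = np.interp(prof.d, knots, zk)
        m2 = detect_segments(ElevationProfile(d=prof.d, z=z2))
        assert [s.terrain for s in m1.segments] == [s.terrain for s in m2.segments]
        assert np.allclose(
            [s.end_m for s in m1.segments], [s.end_m for s in m2.segments], atol=5.0
        )


def _seg(start, end, ed):
    return CourseSegment(start, end, _lbl(ed), ed)


def _lbl(ed, thr=4.0):
    if ed >= thr:
        return Terrain.UPHILL
    if ed <= -thr:
        return Terrain.DOWNHILL
    return Terrain.FLAT


class TestMergeUndulating:
    def test_subthreshold_run_becomes_flat(self):
        segs = [_seg(0, 100, 3.0), _seg(100, 180, -2.0), _seg(180, 300, 3.0)]
        out = merge_undulating(segs, 4.0)
        assert len(out) == 1
        assert out[0].terrain is Terrain.FLAT
        assert (out[0].start_m, out[0].end_m) == (0, 300)

    def test_no_subthreshold_identity(self):
        segs = [_seg(0, 100, 6.0), _seg(100, 200, -5.0), _seg(200, 300, 8.0)]
        out = merge_undulating(segs, 4.0)
        assert [(s.start_m, s.end_m, s.terrain) for s in out] == [
            (s.start_m, s.end_m, s.terrain) for s in segs
        ]

    def test_randomized_against_run_merging_oracle(self, rng):
        def oracle(eds, bounds):
            # brute-force scan: group maximal sub-threshold runs, then
            # collapse equal neighbouring labels
            items = []
            i = 0
            while i < len(eds):
                if abs(eds[i]) < 4.0:
                    j = i
                    while j < len(eds) and abs(eds[j]) < 4.0:
                        j += 1
                    items.append((bounds[i], bounds[j], Terrain.FLAT))
                    i = j
                else:
                    items.append((bounds[i], bounds[i + 1], _lbl(eds[i])))
                    i += 1
            merged = [items[0]]
            for it in items[1:]:
                if it[2] == merged[-1][2]:
                    merged[-1] = (merged[-1][0], it[1], it[2])
                else:
                    merged.append(it)
            return merged

        for _ in range(50):
            n = rng.integers(1, 21)
            eds = rng.normal(0, 5, n)
            bounds = np.concatenate(([0.0], np.cumsum(rng.uniform(50, 300, n))))
            segs = [_seg(bounds[i], bounds[i + 1], eds[i]) for i in range(n)]
            out = merge_undulating(segs, 4.0)
            exp = oracle(list(eds), list(bounds))
            assert [(s.start_m, s.end_m, s.terrain) for s in out] == exp


class TestActualDistance:
    @pytest.mark.parametrize(
        "horiz,ed,expected",
        [(100.0, 0.0, 100.0), (4.0, 3.0, 5.0), (543.0, 38.0, 544.3279)],
    )
    def test_formula(self, horiz, ed, expected):
        seg = CourseSegment(0.0, horiz, Terrain.FLAT, ed)
        assert np.isclose(actual_distance(seg), expected, atol=5e-4)


class TestTerrainComposition:
    def test_printed_reference_lengths(self):
        # the ten legs labelled by length x midpoint incline and the 4 m rule
        _, model = simulate_course(default_course())
        comp = terrain_composition(model)
        assert round(100 * comp[Terrain.UPHILL]) == 37
        assert round(100 * comp[Terrain.FLAT]) == 15
        assert round(100 * comp[Terrain.DOWNHILL]) == 48

    def test_single_flat_segment(self):
        model = CourseModel(100.0, [CourseSegment(0, 100, Terrain.FLAT, 0.0)])
        comp = terrain_composition(model)
        assert comp[Terrain.FLAT] == 1.0
        assert comp[Terrain.UPHILL] == 0.0

    def test_random_partitions_match_length_sums(self, rng):
        for _ in range(20):
            n = rng.integers(1, 12)
            lens = rng.uniform(50, 400, n)
            bounds = np.concatenate(([0.0], np.cumsum(lens)))
            kinds = list(Terrain)
            terr = [kinds[i] for i in rng.integers(0, len(kinds), n)]
            segs = [
                CourseSegment(bounds[i], bounds[i + 1], terr[i], 0.0) for i in range(n)
            ]
            comp = terrain_composition(CourseModel(bounds[-1], list(segs)))
            for t in Terrain:
                exp = lens[[x is t for x in terr]].sum() / lens.sum()
                assert np.isclose(comp[t], exp)

    def test_empty_model_errors(self):
        with pytest.raises(ValueError):
            terrain_composition(CourseModel(100.0, []))


def test_course_model_json_round_trip(tmp_path):
    _, model = simulate_course(default_course())
    p = tmp_path / "course.json"
    model.to_json(p)
    back = CourseModel.from_json(p)
    assert back.lap_length == model.lap_length
    assert [s.terrain for s in back.segments] == [s.terrain for s in model.segments]
    assert np.allclose([s.elev_diff for s in back.segments],
                       [s.elev_diff for s in model.segments])
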