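import numpy as np
import pandas as pd
import pytest

from sonarwake import dive, synthetic
from sonarwake.dive import (
    DisjointRecordsError,
    NotADiveError,
    RateBounds,
    build_depth_series,
    classify_dive,
    compute_iddis,
    dive_table,
    estimate_dive_kinematics,
    interpolate_profile,
    summarize_dive_metrics,
)

T0 = pd.Timestamp("2021-08-11 12:00:00-10:00")


def _entry(depth, dur_min, shape, start_min=0.0):
    start = T0 + pd.Timedelta(minutes=start_min)
    return {
        "start": start,
        "end": start + pd.Timedelta(minutes=dur_min),
        "depth_min_m": depth,
        "depth_max_m": depth,
        "duration_min_s": dur_min * 60.0,
        "duration_max_s": dur_min * 60.0,
        "shape": shape,
    }


class TestKinematics:
    def test_v_shape_hand_oracle(self):
        # V: bottom fraction 0.10 -> 1 min bottom, 4.5 min each leg,
        # 200 m / 270 s = 0.741 m/s
        kin = estimate_dive_kinematics(_entry(200.0, 10.0, "V"))
        assert np.isclose(kin.bottom_s, 60.0)
        assert np.isclose(kin.descent_s, 270.0)
        assert np.isclose(kin.ascent_s, 270.0)
        assert np.isclose(kin.descent_rate_ms, 0.7407, atol=1e-4)
        assert not kin.flagged

    def test_square_shape_symmetric_split(self):
        # rates within bounds: the "remaining time divided by two" rule
        # makes descent and ascent exactly equal
        kin = estimate_dive_kinematics(_entry(800.0, 60.0, "square"))
        assert kin.descent_s == kin.ascent_s == 585.0

    def test_deep_reference_dive_conserves_duration(self):
        # the study's median deep dive scale: 1200 m for 50.7 min
        kin = estimate_dive_kinematics(_entry(1200.0, 50.7, "U"))
        assert np.isclose(kin.descent_s + kin.bottom_s + kin.ascent_s, 50.7 * 60.0, atol=1e-6)
        assert kin.dive_class == "deep"
        assert RateBounds().descent[0] <= kin.descent_rate_ms <= RateBounds().descent[1]

    def test_slow_rates_clamped_time_returned_to_bottom(self):
        # 100 m over 30 min, V-shape: raw rates ~0.12/0.10 m/s fall below
        # the descent bound; clamping shortens the legs and grows the bottom
        # raw legs 810 s -> descent rate 0.123 m/s < 0.2 clamps to 500 s;
        # the ascent rate 0.123 is inside its own (0.1, 1.5) bound
        kin = estimate_dive_kinematics(_entry(100.0, 30.0, "V"))
        assert np.isclose(kin.descent_rate_ms, 0.2)
        assert np.isclose(kin.descent_s, 500.0)
        assert np.isclose(kin.ascent_s, 810.0)
        assert np.isclose(kin.bottom_s, 1800.0 - 500.0 - 810.0)
        assert np.isclose(kin.descent_s + kin.bottom_s + kin.ascent_s, 1800.0)
        assert not kin.flagged

    def test_impossible_dive_flagged_not_fatal(self):
        # 1200 m in 20 min square-shaped cannot fit even extreme rates
        kin = estimate_dive_kinematics(_entry(1200.0, 20.0, "square"))
        assert kin.flagged
        assert kin.bottom_s == 0.0
        assert np.isclose(kin.descent_s + kin.ascent_s, 20.0 * 60.0)

    @pytest.mark.parametrize(
        "depth,expected",
        [(1424.0, "deep"), (300.5, "deep"), (300.0, "intermediate"), (50.0, "intermediate")],
    )
    def test_classification_boundaries(self, depth, expected):
        assert classify_dive(depth) == expected

    def test_below_fifty_meters_is_not_a_dive(self):
        with pytest.raises(NotADiveError):
            classify_dive(49.9)


class TestInterpolation:
    def test_sixty_points_spacing_and_plateau(self):
        kin = estimate_dive_kinematics(_entry(1000.0, 50.0, "square"))
        prof = interpolate_profile(kin)
        assert len(prof) == 60
        assert np.allclose(np.diff(prof.rel_s), 50.0 * 60.0 / 59.0)
        plateau = prof[(prof.rel_s > kin.descent_s) & (prof.rel_s < kin.descent_s + kin.bottom_s)]
        assert np.allclose(plateau.depth_m, 1000.0)
        assert 0.0 <= prof.depth_m.iloc[0] < 1000.0
        assert 0.0 <= prof.depth_m.iloc[-1] < 1000.0

    def test_short_dive_spacing(self):
        kin = estimate_dive_kinematics(_entry(150.0, 10.0, "U"))
        prof = interpolate_profile(kin)
        assert np.isclose(np.diff(prof.rel_s)[0], 600.0 / 59.0)  # ~10 s

    def test_profile_area_matches_trapezoid_closed_form(self):
        kin = estimate_dive_kinematics(_entry(900.0, 45.0, "U"))
        prof = interpolate_profile(kin, n_points=60)
        sampled = np.trapezoid(prof.depth_m, prof.rel_s)
        d0 = dive.DIVE_TRIGGER_DEPTH_M
        exact = (
            kin.descent_s * (d0 + kin.depth_m) / 2.0
            + kin.bottom_s * kin.depth_m
            + kin.ascent_s * (kin.depth_m + d0) / 2.0
        )
        assert abs(sampled - exact) / exact < 0.01

    def test_monotone_descent_plateau_ascent(self):
        kin = estimate_dive_kinematics(_entry(700.0, 40.0, "U"))
        prof = interpolate_profile(kin)
        d = prof.depth_m.to_numpy()
        desc = prof.rel_s <= kin.descent_s
        asc = prof.rel_s >= kin.descent_s + kin.bottom_s
        assert (np.diff(d[desc]) >= -1e-9).all()
        assert (np.diff(d[asc.to_numpy()]) <= 1e-9).all()


def _toy_log_and_track():
    """surface | deep dive | gap | surface tiling with a 5-min lattice."""
    rows = [
        {"kind": "surface", "start": T0, "end": T0 + pd.Timedelta(minutes=60)},
        {
            "kind": "dive",
            "start": T0 + pd.Timedelta(minutes=60),
            "end": T0 + pd.Timedelta(minutes=110),
            "depth_min_m": 975.0,
            "depth_max_m": 1025.0,
            "duration_min_s": 2940.0,
            "duration_max_s": 3060.0,
            "shape": "U",
            "dive_id": 0,
        },
        {"kind": "gap", "start": T0 + pd.Timedelta(minutes=110), "end": T0 + pd.Timedelta(minutes=170)},
        {"kind": "surface", "start": T0 + pd.Timedelta(minutes=170), "end": T0 + pd.Timedelta(minutes=240)},
    ]
    log = pd.DataFrame(rows)
    lattice = pd.DataFrame(
        {
            "timestamp": T0 + pd.to_timedelta(np.arange(0, 241, 5), "m"),
            "observed": False,
        }
    )
    lattice.loc[[0, 4, 40], "observed"] = True
    return log, lattice


class TestDepthSeries:
    def test_statuses_and_gap_uplink_window(self):
        log, lattice = _toy_log_and_track()
        uplink = [T0 + pd.Timedelta(minutes=140)]
        series = build_depth_series(log, lattice, uplink_times=uplink)
        gap = series[series.status.str.startswith("gap")]
        shallow = gap[gap.status == "gap-assumed-shallow"]
        # exactly the lattice samples within +/-1 min of the uplink
        assert list(shallow.timestamp) == [T0 + pd.Timedelta(minutes=140)]
        assert (gap.drop(shallow.index).status == "gap-unknown").all()
        assert series.status.isin(
            ["in-dive", "surface-observed", "surface-interpolated",
             "gap-assumed-shallow", "gap-unknown"]
        ).all()

    def test_no_gap_entries_no_gap_samples(self):
        log, lattice = _toy_log_and_track()
        log = log[log.kind != "gap"]
        series = build_depth_series(log, lattice)
        assert not series.status.str.startswith("gap").any()

    def test_dive_samples_use_mean_binned_depth(self):
        log, lattice = _toy_log_and_track()
        series = build_depth_series(log, lattice)
        in_dive = series[series.status == "in-dive"]
        assert len(in_dive) == 60
        assert np.isclose(in_dive.depth_m.max(), 1000.0)  # mean of 975/1025

    def test_disjoint_ranges_error(self):
        log, lattice = _toy_log_and_track()
        lattice["timestamp"] = lattice.timestamp + pd.Timedelta(days=30)
        with pytest.raises(DisjointRecordsError):
            build_depth_series(log, lattice)


def _log_from_sequence(seq):
    """seq: list of (kind, dur_min, depth or None, shape) tiled in time."""
    rows, t = [], T0
    for i, (kind, dur, depth, shape) in enumerate(seq):
        end = t + pd.Timedelta(minutes=dur)
        row = {"kind": kind, "start": t, "end": end}
        if kind == "dive":
            row.update(
                depth_min_m=depth, depth_max_m=depth,
                duration_min_s=dur * 60.0, duration_max_s=dur * 60.0,
                shape=shape, dive_id=i,
            )
        rows.append(row)
        t = end
    return pd.DataFrame(rows)


class TestIddis:
    def test_deep_surface_deep_single_empty_iddi(self):
        log = _log_from_sequence(
            [("surface", 10, None, None), ("dive", 50, 1000.0, "U"),
             ("surface", 90, None, None), ("dive", 45, 950.0, "U"),
             ("surface", 10, None, None)]
        )
        iddis = compute_iddis(log)
        interior = iddis[~iddis.truncated]
        assert len(interior) == 1
        assert interior.n_intermediate.iloc[0] == 0
        assert np.isclose(interior.duration_min.iloc[0], 90.0)

    def test_known_structure_recovered_exactly(self):
        log = _log_from_sequence(
            [("surface", 10, None, None),
             ("dive", 50, 1100.0, "U"),
             ("surface", 20, None, None),
             ("dive", 10, 150.0, "V"),
             ("surface", 15, None, None),
             ("dive", 12, 200.0, "U"),
             ("surface", 30, None, None),
             ("dive", 55, 1200.0, "square"),
             ("surface", 25, None, None),
             ("dive", 48, 900.0, "U"),
             ("surface", 10, None, None)]
        )
        iddis = compute_iddis(log)
        interior = iddis[~iddis.truncated].reset_index(drop=True)
        assert list(interior.n_intermediate) == [2, 0]
        assert np.allclose(interior.duration_min, [20 + 10 + 15 + 12 + 30, 25.0])
        assert np.isclose(interior.mean_int_depth_m.iloc[0], 175.0)
        assert np.isclose(interior.max_int_depth_m.iloc[0], 200.0)
        assert np.isclose(interior.mean_int_duration_min.iloc[0], 11.0)

    def test_no_deep_dives_empty(self):
        log = _log_from_sequence(
            [("surface", 10, None, None), ("dive", 10, 150.0, "V"), ("surface", 10, None, None)]
        )
        assert len(compute_iddis(log)) == 0

    def test_gap_marks_iddi_truncated(self):
        log = _log_from_sequence(
            [("surface", 10, None, None), ("dive", 50, 1000.0, "U"),
             ("gap", 60, None, None), ("dive", 50, 1000.0, "U"),
             ("surface", 10, None, None)]
        )
        iddis = compute_iddis(log)
        mid = iddis[(iddis.n_intermediate == 0) & (iddis.duration_min == 60.0)]
        assert mid.truncated.all()


class TestSummaries:
    def test_single_dive_min_equals_max(self):
        log = _log_from_sequence(
            [("surface", 10, None, None), ("dive", 50, 1000.0, "U"), ("surface", 10, None, None)]
        )
        s = summarize_dive_metrics(log)
        stats = s["classes"]["deep"]["duration_min"]
        assert stats["min"] == stats["median"] == stats["max"] == 50.0

    def test_percent_rounding_matches_reference_convention(self):
        # 45/175 deep -> 26%; 59/249 -> 24% under the same rounding
        assert int(round(100 * 45 / 175)) == 26
        seq = [("surface", 5, None, None)]
        for i in range(45):
            seq += [("dive", 50, 1000.0, "U"), ("surface", 5, None, None)]
        for i in range(130):
            seq += [("dive", 10, 150.0, "V"), ("surface", 5, None, None)]
        s = summarize_dive_metrics(_log_from_sequence(seq))
        assert s["classes"]["deep"]["percent"] == 26
        assert s["classes"]["intermediate"]["percent"] == 74

    def test_summary_matches_brute_force(self, small_config):
        dives = synthetic.simulate_dive_sequence(small_config)
        cfg = synthetic.SimConfig(seed=small_config.seed, duration_h=small_config.duration_h,
                                  gap_fraction=0.0)
        log = synthetic.encode_behavior_log(dives, cfg)
        s = summarize_dive_metrics(log)
        tab = dive_table(log)
        for cls in s["classes"]:
            grp = tab[tab.dive_class == cls]
            assert np.isclose(s["classes"][cls]["depth_m"]["median"], np.median(grp.depth_m))
            assert np.isclose(s["classes"][cls]["duration_min"]["mean"], np.mean(grp.duration_min))
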