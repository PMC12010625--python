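import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sonarwake import reference_data, stats
from sonarwake.stats import (
    assign_phases,
    baseline_percentiles,
    compare_track_variants,
    compute_step_metrics,
    filter_gap_steps,
    flag_exposure_metrics,
    kruskal_wallis,
    mark_anomalous_intermediates,
    tukey_kramer,
)


class TestPhases:
    def test_phase_durations_from_schedule(self):
        sched = reference_data.scc_phase_schedule(2021)
        b = sched[sched.label == "Phase B"].iloc[0]
        assert (b.end - b.start).total_seconds() / 3600.0 == 57.5

    def test_after_truncated_to_three_days(self):
        sched = pd.DataFrame(
            [
                {"label": "Phase B", "start": pd.Timestamp("2022-08-23 12:00"),
                 "end": pd.Timestamp("2022-08-24 16:00")},
                {"label": "After", "start": pd.Timestamp("2022-08-24 16:00"),
                 "end": pd.Timestamp("2022-09-11 00:00")},  # 17.3 days
            ]
        )
        ts = pd.date_range("2022-08-24 16:00", "2022-09-10 23:00", freq="1h")
        labels = assign_phases(ts, sched)
        labeled = ts[(labels == "After").to_numpy()]
        span_h = (labeled.max() - labeled.min()).total_seconds() / 3600.0
        assert span_h == 71.0  # 72 hourly stamps spanning exactly 3 days

    def test_before_truncation_keeps_trailing_days(self):
        sched = pd.DataFrame(
            [{"label": "Before", "start": pd.Timestamp("2021-08-01 00:00"),
              "end": pd.Timestamp("2021-08-11 18:00")}]
        )
        ts = pd.to_datetime(["2021-08-05 00:00", "2021-08-09 00:00"])
        labels = assign_phases(ts, sched)
        assert list(labels) == ["", "Before"]

    def test_empty_schedule_all_unlabeled(self):
        sched = pd.DataFrame(columns=["label", "start", "end"])
        labels = assign_phases(pd.to_datetime(["2021-08-05"]), sched)
        assert list(labels) == [""]


class TestPercentiles:
    def test_type7_median_of_four(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
        p = baseline_percentiles(df)
        assert p.loc[50.0, "m"] == 2.5
        assert p.loc[25.0, "m"] == 1.75

    def test_degenerate_identical_values(self):
        df = pd.DataFrame({"m": [7.0] * 6})
        p = baseline_percentiles(df)
        assert (p.m == 7.0).all()

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40))
    def test_monotone_in_level(self, vals):
        p = baseline_percentiles(pd.DataFrame({"m": vals}))
        assert (np.diff(p.m.to_numpy()) >= -1e-9).all()

    def test_requires_four_cycles(self):
        with pytest.raises(ValueError):
            baseline_percentiles(pd.DataFrame({"m": [1.0, 2.0]}))


class TestFlags:
    def _baseline(self):
        return pd.DataFrame({"m": [10.0, 25.0, 50.0, 75.0, 90.0]},
                            index=pd.Index([2.5, 25.0, 50.0, 75.0, 97.5]))

    @pytest.mark.parametrize(
        "value,band,direction",
        [
            (50.0, "inside-IQR", ""),
            (25.0, "inside-IQR", ""),  # IQR bounds inclusive
            (75.0, "inside-IQR", ""),
            (20.0, "outside-IQR", "below"),
            (80.0, "outside-IQR", "above"),
            (9.0, "outside-95", "below"),
            (91.0, "outside-95", "above"),
        ],
    )
    def test_band_assignment_exhaustive_and_exclusive(self, value, band, direction):
        flags = flag_exposure_metrics(pd.DataFrame({"m": [value]}), self._baseline())
        assert len(flags) == 1
        assert flags.band.iloc[0] == band
        assert flags.direction.iloc[0] == direction

    def test_missing_value_reported_not_dropped(self):
        flags = flag_exposure_metrics(pd.DataFrame({"m": [np.nan]}), self._baseline())
        assert flags.band.iloc[0] == "missing"

    def test_published_worked_example_single_outlier(self):
        """Across the published exposure dive cycles, exactly one metric
        (an IDDI max intermediate depth) is outside the central 95%."""
        base = reference_data.baseline_dive_percentile_table()
        expo = reference_data.exposure_dive_metric_table()
        all_flags = []
        for tag in ("MdTag020", "MdTag021"):
            flags = flag_exposure_metrics(expo.xs(tag, level="tag"), base.loc[tag])
            all_flags.append(flags)
        flags = pd.concat(all_flags)
        out95 = flags[flags.band == "outside-95"]
        assert len(out95) == 1
        assert out95.value.iloc[0] == 255.50
        assert out95.metric.iloc[0] == "iddi_max_depth_m"
        assert out95.direction.iloc[0] == "above"

    def test_anomalous_intermediate_mask(self):
        mask = mark_anomalous_intermediates([150.0, 303.5, 511.5])
        assert list(mask) == [False, True, True]


def _two_point_track(lat0=22.0, north_m=100.0):
    dlat = north_m / 111_194.9
    return pd.DataFrame(
        {
            "imputation": 0,
            "timestamp": pd.to_datetime(["2021-08-17 05:00", "2021-08-17 05:05"]),
            "lon": [-159.9, -159.9],
            "lat": [lat0, lat0 + dlat],
        }
    )


class TestStepMetrics:
    def test_due_north_step_oracle(self):
        steps = compute_step_metrics(_two_point_track())
        assert len(steps) == 1
        assert np.isclose(steps.bearing_deg.iloc[0], 0.0, atol=1e-6)
        assert np.isclose(steps.step_m.iloc[0], 100.0, atol=0.2)
        assert np.isclose(steps.speed_ms.iloc[0], 100.0 / 300.0, atol=1e-3)

    def test_constant_bearing_zero_turn(self):
        t = pd.DataFrame(
            {
                "imputation": 0,
                "timestamp": pd.date_range("2021-08-17", periods=4, freq="5min"),
                "lon": -159.9,
                "lat": 22.0 + np.arange(4) * 1e-3,
            }
        )
        steps = compute_step_metrics(t)
        assert np.allclose(steps.turn_rad.iloc[1:], 0.0, atol=1e-9)

    def test_turning_angle_wraps_across_north(self):
        # bearings ~350 then ~10 degrees: turn is +20 deg = 0.349 rad
        lat, lon = [22.0], [-159.9]
        for b in (350.0, 10.0):
            rad = np.radians(b)
            lat.append(lat[-1] + 1e-3 * np.cos(rad))
            lon.append(lon[-1] + 1e-3 * np.sin(rad) / np.cos(np.radians(22.0)))
        t = pd.DataFrame(
            {
                "imputation": 0,
                "timestamp": pd.date_range("2021-08-17", periods=3, freq="5min"),
                "lon": lon,
                "lat": lat,
            }
        )
        steps = compute_step_metrics(t)
        assert np.isclose(steps.turn_rad.iloc[1], np.radians(20.0), atol=1e-3)


class TestGapFilter:
    def _steps_with_gap(self):
        ts = pd.date_range("2021-08-17", periods=13, freq="5min")
        pred = pd.DataFrame({"timestamp": ts, "enclosing_gap_h": 0.25})
        pred.loc[4:8, "enclosing_gap_h"] = 3.0  # samples inside a 3-h hole
        tracks = pd.DataFrame(
            {"imputation": 0, "timestamp": ts, "lon": -159.9, "lat": 22.0 + np.arange(13) * 1e-3}
        )
        return compute_step_metrics(tracks, predicted=pred)

    def test_interior_steps_removed_boundary_retained(self):
        steps = self._steps_with_gap()
        kept = filter_gap_steps(steps, max_gap_h=1.0)
        # steps 4..7 have both endpoints inside the hole; 3 and 8 are boundary
        assert len(steps) == 12
        assert len(kept) == 8
        assert 3 in kept.index_or(None) if hasattr(kept, "index_or") else True

    def test_infinite_limit_is_identity(self):
        steps = self._steps_with_gap()
        assert len(filter_gap_steps(steps, max_gap_h=np.inf)) == len(steps)

    def test_dense_fixes_nothing_removed(self):
        ts = pd.date_range("2021-08-17", periods=6, freq="5min")
        pred = pd.DataFrame({"timestamp": ts, "enclosing_gap_h": 1.0 / 12.0})
        tracks = pd.DataFrame(
            {"imputation": 0, "timestamp": ts, "lon": -159.9, "lat": 22.0 + np.arange(6) * 1e-3}
        )
        steps = compute_step_metrics(tracks, predicted=pred)
        assert len(filter_gap_steps(steps)) == len(steps)


class TestKruskalWallis:
    def test_two_group_hand_rank_oracle(self):
        r = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        # ranks 1..6; H = 12/42 * (3*1.5^2 + 3*1.5^2) = 3.857
        assert np.isclose(r["H"], 3.857, atol=1e-3)
        assert r["df"] == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=30), rng.normal(1.0, 2.0, 25), rng.normal(-1.0, 0.5, 40)]
        h1 = kruskal_wallis(groups)["H"]
        h2 = kruskal_wallis([np.exp(g) for g in groups])["H"]
        assert np.isclose(h1, h2)

    def test_all_identical_degenerates(self):
        r = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert r["H"] == 0.0 and r["p"] == 1.0


class TestTukeyKramer:
    def test_identical_groups_p_near_one(self):
        g = np.arange(30.0)
        tab = tukey_kramer({"a": g, "b": g.copy(), "c": g + 500.0})
        assert tab.loc["a", "b"] > 0.99
        assert tab.loc["a", "c"] < 0.01

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        tab = tukey_kramer({k: rng.normal(size=20) for k in "abcd"})
        assert np.allclose(tab.values, tab.values.T)
        assert np.allclose(np.diag(tab.values), 1.0)

    def test_conservative_vs_unadjusted_pairwise(self):
        """The studentized-range reference with k groups never yields a
        smaller p than the two-group normal reference on the same mean-rank
        statistic."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            groups = {k: rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(5, 30))
                      for k in "abcde"}
            tab = tukey_kramer(groups)
            labels = list(groups)
            pooled = np.concatenate([groups[k] for k in labels])
            ranks = sps.rankdata(pooled)
            N = len(pooled)
            i0, mr, ns = 0, {}, {}
            for k in labels:
                n = len(groups[k])
                mr[k] = ranks[i0 : i0 + n].mean()
                ns[k] = n
                i0 += n
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    se = np.sqrt(N * (N + 1) / 12.0 * (1 / ns[a] + 1 / ns[b]))
                    z = abs(mr[a] - mr[b]) / se
                    p_unadj = 2.0 * sps.norm.sf(z)
                    assert tab.loc[a, b] >= p_unadj - 1e-12

    def test_empty_group_excluded_with_note(self):
        tab = tukey_kramer({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": []})
        assert tab.attrs["excluded"] == ["c"]
        assert list(tab.columns) == ["a", "b"]

    def test_shifted_phase_detected_with_high_power(self):
        """A +3 SD speed shift in one phase at n = 200 steps/phase is
        flagged against every other phase in nearly all replicates."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 25
        for _ in range(reps):
            groups = {f"P{i}": rng.normal(0.0, 1.0, 200) for i in range(4)}
            groups["shifted"] = rng.normal(3.0, 1.0, 200)
            tab = tukey_kramer(groups)
            if all(tab.loc["shifted", k] < 0.05 for k in groups if k != "shifted"):
                hits += 1
        assert hits / reps > 0.9


class TestConcordance:
    def test_identical_results_full_concordance(self):
        res = pd.DataFrame({"metric": ["a", "b"], "p": [0.01, 0.6]})
        rep = compare_track_variants(res, res.copy())
        assert rep.attrs["concordance"] == 1.0
        assert rep.agree.all()

    def test_each_metric_listed_once(self):
        full = pd.DataFrame({"metric": ["a", "b", "c"], "p": [0.01, 0.6, 0.2]})
        filt = pd.DataFrame({"metric": ["a", "b", "c"], "p": [0.04, 0.03, 0.3]})
        rep = compare_track_variants(full, filt)
        assert sorted(rep.metric) == ["a", "b", "c"]
        assert rep.attrs["concordance"] == pytest.approx(2.0 / 3.0)
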