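"""Published reference values from the PMRF Blainville's beaked whale
satellite-tagging study, used as worked-example inputs.

All timestamps are Hawaiian Standard Time (UTC-10, no DST). Only the 2014
and 2021 exercise schedules are included: the printed 2022 rows are
mutually inconsistent (phases overlap and printed durations do not match
their own timestamps) and cannot be validated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HST = "-10:00"

DIVE_METRIC_COLUMNS = [
    "deep_dive_duration_min",
    "deep_dive_depth_m",
    "iddi_duration_min",
    "n_intermediate",
    "mean_int_duration_min",
    "mean_int_max_depth_m",
    "iddi_max_depth_m",
]


def _ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(f"{s}{HST}")


def scc_phase_schedule(year: int) -> pd.DataFrame:
    """Exercise phase schedule (label, start, end, printed duration in
    hours) for the 2014 or 2021 Submarine Command Course."""
    if year == 2014:
        rows = [
            ("Before", "2014-02-11 15:30", "2014-02-12 18:00", 26.5),
            ("Phase A", "2014-02-12 18:00", "2014-02-14 21:00", 51.0),
            ("Interphase", "2014-02-14 21:00", "2014-02-17 19:00", 70.0),
            ("Phase B", "2014-02-17 19:00", "2014-02-20 17:30", 70.5),
            ("After", "2014-02-20 17:30", "2014-02-20 22:30", 6.0),
        ]
    elif year == 2021:
        rows = [
            ("Before", "2021-08-08 18:00", "2021-08-11 17:59", 72.0),
            ("Phase A", "2021-08-11 18:00", "2021-08-13 10:20", 40.3),
            ("Interphase", "2021-08-13 10:21", "2021-08-17 04:59", 90.6),
            ("Phase B", "2021-08-17 05:00", "2021-08-19 14:30", 57.5),
            ("After", "2021-08-19 14:31", "2021-08-22 14:30", 72.0),
        ]
    else:
        raise ValueError(f"no validated schedule for year {year}")
    return pd.DataFrame(
        [
            {"label": lab, "start": _ts(s), "end": _ts(e), "printed_duration_h": d}
            for lab, s, e, d in rows
        ]
    )


def movement_model_aics() -> pd.DataFrame:
    """Per-tag CTCRW and BM AIC values from the published model
    comparison (lower is better)."""
    rows = [
        ("MdTag017", 3267.60, 3285.15),
        ("MdTag020", 4950.95, 4948.49),
        ("MdTag021", 6783.62, 6781.61),
        ("MdTag022", 16890.91, 16893.33),
    ]
    return pd.DataFrame(rows, columns=["tag", "aic_ctcrw", "aic_bm"]).set_index("tag")


def dive_counts() -> pd.DataFrame:
    """Published per-tag dive counts (total, deep > 300 m, intermediate)."""
    rows = [("MdTag020", 175, 45, 130), ("MdTag021", 249, 59, 190)]
    return pd.DataFrame(rows, columns=["tag", "total", "deep", "intermediate"]).set_index("tag")


def baseline_dive_percentile_table() -> pd.DataFrame:
    """Published baseline (pre-sonar) dive-metric percentiles per tag.

    MultiIndex (tag, percentile level); columns are the seven dive-cycle
    metrics: deep dive duration (min), deep dive depth (m), IDDI duration
    (min), number of following intermediate dives, mean intermediate dive
    duration (min), mean intermediate dive max depth (m), IDDI max
    depth (m).
    """
    data = {
        ("MdTag020", 2.5): [17.3, 349.7, 3.2, 0.0, 4.0, 56.7, 62.0],
        ("MdTag021", 2.5): [35.9, 830.5, 39.0, 0.0, 4.9, 51.3, 51.3],
        ("MdTag020", 25.0): [47.4, 955.5, 74.7, 2.0, 8.3, 97.5, 119.5],
        ("MdTag021", 25.0): [46.8, 991.5, 81.4, 1.5, 8.7, 76.5, 107.1],
        ("MdTag020", 50.0): [51.1, 1263.5, 108.6, 3.0, 10.3, 110.3, 135.5],
        ("MdTag021", 50.0): [50.3, 1103.5, 110.6, 3.0, 10.3, 101.5, 123.5],
        ("MdTag020", 75.0): [54.6, 1327.5, 137.8, 4.0, 11.2, 130.8, 163.5],
        ("MdTag021", 75.0): [53.0, 1231.5, 132.1, 4.0, 11.4, 117.5, 147.5],
        ("MdTag020", 97.5): [59.2, 1389.9, 256.9, 7.7, 15.9, 193.8, 225.8],
        ("MdTag021", 97.5): [61.3, 1327.5, 237.1, 8.4, 14.1, 140.3, 209.0],
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=DIVE_METRIC_COLUMNS)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["tag", "percentile"])
    return df.sort_index()


def exposure_dive_metric_table() -> pd.DataFrame:
    """Published dive-cycle metrics for the five dive cycles during sonar
    bouts (MultiIndex (cycle start HST, tag)); NaN where the tag's record
    is missing."""
    nan = np.nan
    rows = [
        ("2021-08-17 16:29", "MdTag020", [53.43, 1263.5, 122.20, 3, 8.19, 96.83, 151.5]),
        ("2021-08-17 16:29", "MdTag021", [51.87, 991.50, 122.17, 3, 8.39, 88.83, 123.5]),
        ("2021-08-17 19:25", "MdTag020", [55.57, 1231.5, 128.37, 2, 10.80, 136.50, 223.5]),
        ("2021-08-17 19:25", "MdTag021", [55.67, 1103.50, 128.33, 2, 13.70, 117.50, 183.5]),
        ("2021-08-17 22:29", "MdTag020", [50.0, 911.5, 30.0, 2, 11.05, 171.5, 175.5]),
        ("2021-08-17 22:29", "MdTag021", [50.03, 943.50, 170.70, 5, 11.71, 139.10, 255.50]),
        ("2021-08-18 02:09", "MdTag020", [nan] * 7),
        ("2021-08-18 02:09", "MdTag021", [59.07, 863.50, 201.97, 3, 12.43, 121.50, 171.50]),
        ("2021-08-19 00:04", "MdTag020", [nan] * 7),
        ("2021-08-19 00:04", "MdTag021", [nan, nan, 75.63, 5, 12.98, 105.10, 195.5]),
    ]
    df = pd.DataFrame(
        [r[2] for r in rows],
        index=pd.MultiIndex.from_tuples([(r[0], r[1]) for r in rows],
                                        names=["cycle", "tag"]),
        columns=DIVE_METRIC_COLUMNS,
    )
    return df


def gvp_timing_medians() -> dict:
    """Published GVP click timing relative to the tagged dives (minutes)."""
    return {
        "onset_delay_median_min": 5.8,
        "onset_delay_range_min": (1.1, 8.5),
        "cessation_lead_median_min": 12.7,
        "cessation_lead_range_min": (3.1, 23.4),
    }
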