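"""Exposure-response statistics.

Two strands, mirroring how long-duration tag studies quantify response:

* Dive behavior: empirical percentiles (2.5/25/50/75/97.5) of baseline
  (pre-sonar) dive-cycle metrics per whale, against which exposure-period
  metrics are banded — inside the interquartile range, outside the IQR but
  inside the central 95%, or outside the central 95% (atypical).
* Horizontal movement: bearing, step length, speed and turning angle per
  5-min step on 30 imputed tracks, compared across exercise phases with
  Kruskal-Wallis tests and Tukey-Kramer multiple comparisons on mean
  ranks; run on the full tracks and on tracks restricted to <= 1 h
  between observed fixes, and the two result sets compared.

Bearing is analyzed as a linear variable in [0, 360), matching the use of
rank tests on bearing despite its circularity; a circular alternative can
be built from the same step table but is not the default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _geo

PERCENTILE_LEVELS = (2.5, 25.0, 50.0, 75.0, 97.5)
ANOMALOUS_INTERMEDIATE_DEPTH_M = 300.0


# ---------------------------------------------------------------------------
# phases


def assign_phases(timestamps, schedule: pd.DataFrame, truncate_days: float = 3.0) -> pd.Series:
    """Label each timestamp with its exercise phase.

    Before phases are truncated to the trailing ``truncate_days`` adjoining
    the exercise; After phases to the leading ``truncate_days``. Timestamps
    outside every (truncated) phase get the empty label.
    """
    ts = pd.Series(timestamps).reset_index(drop=True)
    t_ns = _geo.time_ns(ts)
    labels = pd.Series("", index=ts.index, dtype=object)
    trunc = pd.Timedelta(days=truncate_days)
    for row in schedule.itertuples():
        start, end = row.start, row.end
        name = str(row.label)
        if name.lower().startswith("before"):
            start = max(start, end - trunc)
        if name.lower().startswith("after"):
            end = min(end, start + trunc)
        m = (t_ns >= _geo.time_ns(start)) & (t_ns < _geo.time_ns(end))
        labels[m] = row.label
    return labels


# ---------------------------------------------------------------------------
# dive-metric percentile flagging


def baseline_percentiles(metrics: pd.DataFrame, levels=PERCENTILE_LEVELS) -> pd.DataFrame:
    """Empirical percentiles (linear interpolation between order
    statistics, the type-7 definition) per metric column; rows are levels."""
    if len(metrics) < 4:
        raise ValueError("need >= 4 baseline dive cycles")
    out = {}
    for col in metrics.columns:
        vals = metrics[col].dropna().to_numpy(dtype=float)
        out[col] = np.percentile(vals, levels) if vals.size else np.full(len(levels), np.nan)
    df = pd.DataFrame(out, index=list(levels))
    df.index.name = "percentile"
    df.attrs["method"] = "linear (type-7)"
    return df


def flag_exposure_metrics(exposure: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Band each exposure metric value against the baseline percentiles.

    inside-IQR: within [25th, 75th] (inclusive); outside-IQR: outside the
    IQR but within [2.5th, 97.5th]; outside-95: beyond the central 95%.
    Missing values are reported with band 'missing'.
    """
    rows = []
    for cycle_id, rec in exposure.iterrows():
        for metric in exposure.columns:
            if metric not in baseline.columns:
                continue
            v = rec[metric]
            p = baseline[metric]
            if pd.isna(v):
                rows.append({"cycle": cycle_id, "metric": metric, "value": np.nan,
                             "band": "missing", "direction": ""})
                continue
            lo95, lo_iqr, hi_iqr, hi95 = p[2.5], p[25.0], p[75.0], p[97.5]
            if lo_iqr <= v <= hi_iqr:
                band, direction = "inside-IQR", ""
            elif lo95 <= v <= hi95:
                band = "outside-IQR"
                direction = "below" if v < lo_iqr else "above"
            else:
                band = "outside-95"
                direction = "below" if v < lo95 else "above"
            rows.append({"cycle": cycle_id, "metric": metric, "value": float(v),
                         "band": band, "direction": direction})
    return pd.DataFrame(rows)


def mark_anomalous_intermediates(depths_m, threshold: float = ANOMALOUS_INTERMEDIATE_DEPTH_M):
    """Boolean mask of anomalously deep intermediate dives (> threshold),
    excluded from IDDI percentile analyses as a labeled filter."""
    return np.asarray(depths_m, dtype=float) > threshold


# ---------------------------------------------------------------------------
# step metrics


def compute_step_metrics(tracks: pd.DataFrame, schedule: pd.DataFrame | None = None,
                         predicted: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-step movement metrics on imputed 5-min tracks.

    tracks: long frame with columns imputation, timestamp, lon, lat.
    Returns one row per step (assigned to the step's start time) with
    bearing (deg, [0,360)), step length (m, geodesic), speed (m/s),
    turning angle (rad, (-pi, pi]), phase label, and the enclosing
    observed-fix gap of both endpoints when ``predicted`` (with
    enclosing_gap_h) is given.
    """
    frames = []
    for imp, grp in tracks.groupby("imputation"):
        g = grp.sort_values("timestamp").reset_index(drop=True)
        lon, lat = g.lon.to_numpy(), g.lat.to_numpy()
        dt_s = g.timestamp.diff().dt.total_seconds().to_numpy()[1:]
        step = _geo.haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
        bearing = _geo.initial_bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
        turn = np.full(step.shape, np.nan)
        turn[1:] = _geo.wrap_angle_rad(np.radians(np.diff(bearing)))
        out = pd.DataFrame(
            {
                "imputation": imp,
                "timestamp": g.timestamp.to_numpy()[:-1],
                "end_timestamp": g.timestamp.to_numpy()[1:],
                "bearing_deg": bearing,
                "step_m": step,
                "speed_ms": step / dt_s,
                "turn_rad": turn,
            }
        )
        frames.append(out)
    steps = pd.concat(frames, ignore_index=True)
    if predicted is not None and "enclosing_gap_h" in predicted:
        gap = predicted.set_index("timestamp").enclosing_gap_h
        steps["gap_start_h"] = gap.reindex(steps.timestamp).to_numpy()
        steps["gap_end_h"] = gap.reindex(steps.end_timestamp).to_numpy()
    if schedule is not None:
        steps["phase"] = assign_phases(steps.timestamp, schedule).to_numpy()
    return steps


def filter_gap_steps(steps: pd.DataFrame, max_gap_h: float = 1.0) -> pd.DataFrame:
    """Drop steps lying inside an observed-fix gap longer than max_gap:
    a step is removed when the enclosing gap at *both* endpoints exceeds
    the limit, so boundary steps adjoining a fix are retained."""
    if "gap_start_h" not in steps or "gap_end_h" not in steps:
        raise ValueError("steps need gap_start_h/gap_end_h (pass predicted= to compute_step_metrics)")
    drop = (steps.gap_start_h > max_gap_h) & (steps.gap_end_h > max_gap_h)
    return steps[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(groups) -> dict:
    """Kruskal-Wallis H (midranks, tie-corrected), df = k-1, chi-square p.
    ``groups``: mapping label -> values or sequence of arrays. All values
    identical degenerates to H = 0, p = 1."""
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    vals = [np.asarray(v, dtype=float) for v in vals if len(v)]
    if len(vals) < 2:
        raise ValueError("need >= 2 non-empty groups")
    df = len(vals) - 1
    pooled = np.concatenate(vals)
    if np.all(pooled == pooled[0]):
        return {"H": 0.0, "df": df, "p": 1.0}
    H, p = sps.kruskal(*vals)
    return {"H": float(H), "df": df, "p": float(p)}


def tukey_kramer(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer multiple comparisons on mean ranks.

    Pairwise statistic |Rbar_i - Rbar_j| / sqrt((N(N+1)/12)(1/n_i + 1/n_j)),
    referred to the studentized-range distribution (q = stat * sqrt(2))
    with k groups and infinite df. Returns a symmetric p-value table;
    empty groups are excluded (noted in .attrs['excluded']).
    """
    labels = [k for k in groups if len(groups[k])]
    excluded = [k for k in groups if not len(groups[k])]
    vals = [np.asarray(groups[k], dtype=float) for k in labels]
    k = len(labels)
    if k < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(vals)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    i0 = 0
    for v in vals:
        mean_ranks.append(ranks[i0 : i0 + v.size].mean())
        i0 += v.size
    table = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    var_base = N * (N + 1) / 12.0
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / vals[i].size + 1.0 / vals[j].size))
            stat = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(sps.studentized_range.sf(stat * np.sqrt(2.0), k, np.inf))
            table.iloc[i, j] = table.iloc[j, i] = min(max(p, 0.0), 1.0)
    table.attrs["excluded"] = excluded
    table.attrs["alpha"] = alpha
    return table


def phase_tests(steps: pd.DataFrame, metrics=("bearing_deg", "step_m", "speed_ms", "turn_rad"),
                phase_col: str = "phase", alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis per movement metric across phases (pooling the 30
    imputations), with the Tukey-Kramer pairwise table attached per metric
    in .attrs['pairwise']."""
    rows = []
    pairwise = {}
    labeled = steps[steps[phase_col] != ""]
    for metric in metrics:
        groups = {
            ph: g[metric].dropna().to_numpy()
            for ph, g in labeled.groupby(phase_col)
        }
        groups = {ph: v for ph, v in groups.items() if v.size}
        if len(groups) < 2:
            continue
        kw = kruskal_wallis(groups)
        rows.append({"metric": metric, "H": kw["H"], "df": kw["df"], "p": kw["p"],
                     "significant": kw["p"] < alpha})
        pairwise[metric] = tukey_kramer(groups, alpha)
    out = pd.DataFrame(rows)
    out.attrs["pairwise"] = pairwise
    return out


def compare_track_variants(full: pd.DataFrame, filtered: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Significance concordance between the full-track and gap-filtered
    test results (one row per metric; headline concordance fraction in
    .attrs['concordance'])."""
    f = full.set_index("metric")
    g = filtered.set_index("metric")
    metrics = sorted(set(f.index) & set(g.index))
    rows = []
    for m in metrics:
        sig_f = bool(f.loc[m, "p"] < alpha)
        sig_g = bool(g.loc[m, "p"] < alpha)
        rows.append({"metric": m, "p_full": float(f.loc[m, "p"]),
                     "p_filtered": float(g.loc[m, "p"]),
                     "significant_full": sig_f, "significant_filtered": sig_g,
                     "agree": sig_f == sig_g})
    out = pd.DataFrame(rows)
    out.attrs["concordance"] = float(out.agree.mean()) if len(out) else np.nan
    return out
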