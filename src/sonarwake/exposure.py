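"""Sonar bout definition, per-bin transmission selection, and received-level
(RL) estimation over the whale's positional error ellipse and depth regimes.

RL = SL - TL, with SL the nominal source level (hull 235, helicopter dip
217, sonobuoy 201 dB re 1 uPa at 1 m) and TL from a pluggable propagation
function. The default TL is a geometric-spreading stand-in,
``k*log10(range) + alpha*range_km + duct(depth)``: it preserves the
monotone range structure the analysis needs while leaving a hook for a
high-fidelity parabolic-equation model; its outputs are order-of-magnitude
plausible, not site-accurate.

When the behavior log provides a modeled animal depth it is used directly;
when depth is unknown (log gap, or a tag without a behavior log) RLs are
reported for two depth regimes: shallow (0-54 m) and the remainder of the
water column down to 1125 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geo

BOUT_BREAK_MIN = 30.0
SHIP_JOIN_MAX_DT_S = 1.0
SHIP_JOIN_MAX_DIST_M = 400.0
BIN_WINDOW_MIN = 2.5

SHALLOW_REGIME_M = (0.0, 54.0)
DEEP_REGIME_M = (54.0, 1125.0)


@dataclass
class PropagationConfig:
    """Geometric-spreading transmission-loss stand-in.

    k: spreading coefficient (20 = spherical), alpha: absorption dB/km,
    duct: optional callable depth_m -> dB offset (default 0).
    """

    k: float = 20.0
    alpha_db_per_km: float = 0.0
    duct: object = None

    def duct_db(self, depth_m):
        if self.duct is None:
            return np.zeros_like(np.asarray(depth_m, dtype=float))
        return np.asarray(self.duct(depth_m), dtype=float)


def propagation_loss(range_m, depth_m=0.0, config: PropagationConfig = PropagationConfig()):
    """TL (dB) at given range and receiver depth; ranges below the 1-m
    reference are capped at 1 m. Monotone non-decreasing in range for
    alpha >= 0."""
    r = np.maximum(np.asarray(range_m, dtype=float), 1.0)
    return (config.k * np.log10(r) + config.alpha_db_per_km * r / 1000.0
            + config.duct_db(depth_m))


def define_bouts(tx: pd.DataFrame) -> pd.DataFrame:
    """Greedy chaining of transmissions: gaps of >= 30 min split bouts
    (within a bout every inter-emission break is < 30 min). Multi-source
    bouts are allowed. Returns tx with a ``bout`` column plus a per-bout
    summary as ``.attrs['bouts']``."""
    tx = tx.sort_values("timestamp").reset_index(drop=True).copy()
    if tx.empty:
        tx["bout"] = pd.Series(dtype=int)
        tx.attrs["bouts"] = pd.DataFrame(columns=["bout", "start", "end",
                                                  "n_transmissions", "source_types"])
        return tx
    gaps_min = tx.timestamp.diff().dt.total_seconds().fillna(0.0) / 60.0
    tx["bout"] = (gaps_min >= BOUT_BREAK_MIN).cumsum()
    summary = (
        tx.groupby("bout")
        .agg(start=("timestamp", "min"), end=("timestamp", "max"),
             n_transmissions=("timestamp", "size"),
             source_types=("source_type", lambda s: sorted(s.unique())))
        .reset_index()
    )
    tx.attrs["bouts"] = summary
    return tx


def join_ship_positions(tx: pd.DataFrame, ships: pd.DataFrame) -> pd.DataFrame:
    """Attach a ship id to each hull transmission with a ship fix within
    1 s and 400 m; nearest distance wins if several ships qualify (ties
    flagged). Non-hull rows and unjoinable hull rows get ship_id = ''."""
    tx = tx.copy().reset_index(drop=True)
    tx["ship_id"] = ""
    tx["ship_join_tied"] = False
    if ships.empty:
        return tx
    ships = ships.sort_values("timestamp").reset_index(drop=True)
    st = _geo.time_ns(ships.timestamp)
    dt_ns = int(SHIP_JOIN_MAX_DT_S * 1e9)
    for i, row in enumerate(tx.itertuples()):
        if row.source_type != "hull":
            continue
        t = _geo.time_ns(row.timestamp)
        lo = np.searchsorted(st, t - dt_ns)
        hi = np.searchsorted(st, t + dt_ns, side="right")
        cand = ships.iloc[lo:hi]
        if cand.empty:
            continue
        d = np.hypot(cand.x.to_numpy() - row.x, cand.y.to_numpy() - row.y)
        ok = d <= SHIP_JOIN_MAX_DIST_M
        if not ok.any():
            continue
        cand = cand[ok]
        d = d[ok]
        best = cand.ship_id.to_numpy()[np.argsort(d, kind="stable")]
        dmin = d.min()
        qualifying = set(cand.ship_id[np.isclose(d, dmin)])
        tx.loc[i, "ship_id"] = best[0]
        tx.loc[i, "ship_join_tied"] = len(qualifying) > 1
    return tx


def select_bin_transmissions(tx: pd.DataFrame, track: pd.DataFrame,
                             window_min: float = BIN_WINDOW_MIN) -> pd.DataFrame:
    """One transmission per (5-min bin, source unit): among transmissions
    within +/-window of the bin's track time, the lexicographic minimum of
    (|time difference|, distance to the whale position)."""
    tx = tx.reset_index(drop=True)
    unit_col = "unit_id" if "unit_id" in tx else "ship_id"
    tt = _geo.time_ns(tx.timestamp).astype(float)
    rows = []
    for b in track.itertuples():
        bt = float(_geo.time_ns(b.timestamp))
        dt_min = np.abs(tt - bt) / 60e9
        in_win = dt_min <= window_min
        if not in_win.any():
            continue
        cand = tx[in_win].copy()
        cand["abs_dt_min"] = dt_min[in_win]
        cand["dist_m"] = np.hypot(cand.x - b.x, cand.y - b.y)
        for unit, grp in cand.groupby(unit_col):
            pick = grp.sort_values(["abs_dt_min", "dist_m"], kind="stable").iloc[0]
            rows.append(
                {
                    "bin_time": b.timestamp,
                    "bin_x": b.x,
                    "bin_y": b.y,
                    "se_x": getattr(b, "se_x", 0.0),
                    "se_y": getattr(b, "se_y", 0.0),
                    "unit_id": unit,
                    "source_type": pick.source_type,
                    "tx_time": pick.timestamp,
                    "tx_x": pick.x,
                    "tx_y": pick.y,
                    "source_level_db": pick.source_level_db,
                    "abs_dt_min": pick.abs_dt_min,
                    "dist_m": pick.dist_m,
                    "n_in_window": len(grp),
                }
            )
    return pd.DataFrame(rows)


def sample_ellipse_radials(cx, cy, se_x, se_y, n_azimuths: int = 36) -> np.ndarray:
    """Systematic radial sampling of the 95% error ellipse: for each of n
    azimuths (0, 360/n, ...) the boundary point and the radial midpoint,
    plus the center — 2n+1 positions, shape (2n+1, 2)."""
    az = np.radians(np.arange(n_azimuths) * 360.0 / n_azimuths)
    ux, uy = np.sin(az), np.cos(az)
    A = _geo.CHI2_95_SCALE * se_x
    B = _geo.CHI2_95_SCALE * se_y
    r = _geo.ellipse_support_radius(A, B, ux, uy)
    pts = np.empty((2 * n_azimuths + 1, 2))
    pts[0] = (cx, cy)
    pts[1 : n_azimuths + 1, 0] = cx + r * ux
    pts[1 : n_azimuths + 1, 1] = cy + r * uy
    pts[n_azimuths + 1 :, 0] = cx + 0.5 * r * ux
    pts[n_azimuths + 1 :, 1] = cy + 0.5 * r * uy
    return pts


def _depth_for_bin(depth_series, bin_time):
    """(mode, depths) for a bin: modeled depth when the reconstructed
    series has a usable sample, else both regime midpoints."""
    regimes = [("regime-shallow", np.mean(SHALLOW_REGIME_M)),
               ("regime-deep", np.mean(DEEP_REGIME_M))]
    if depth_series is None or depth_series.empty:
        return regimes
    ts = _geo.time_ns(depth_series.timestamp)
    t = _geo.time_ns(bin_time)
    i = np.searchsorted(ts, t)
    i = min(max(i, 0), ts.size - 1)
    j = max(i - 1, 0)
    i = i if abs(ts[i] - t) <= abs(ts[j] - t) else j
    row = depth_series.iloc[i]
    if abs(ts[i] - t) > 300e9:
        return regimes
    if row.status in ("gap-unknown",):
        return regimes
    if row.status == "gap-assumed-shallow":
        return [("modeled", np.mean(SHALLOW_REGIME_M))]
    return [("modeled", float(row.depth_m) if np.isfinite(row.depth_m) else 0.0)]


def estimate_rl(
    selections: pd.DataFrame,
    depth_series: pd.DataFrame | None = None,
    config: PropagationConfig = PropagationConfig(),
    n_azimuths: int = 36,
) -> pd.DataFrame:
    """Received-level distribution per (bin, source unit): RL computed at
    every ellipse sample position (and per depth regime when depth is
    unknown); median, 5th/95th percentiles, SD, and range extrema
    reported. Percentiles are over the full ellipse-sample set (recorded
    in output metadata)."""
    rows = []
    for s in selections.itertuples():
        pts = sample_ellipse_radials(s.bin_x, s.bin_y, s.se_x, s.se_y, n_azimuths)
        ranges = np.hypot(pts[:, 0] - s.tx_x, pts[:, 1] - s.tx_y)
        for mode, depth in _depth_for_bin(depth_series, s.bin_time):
            tl = propagation_loss(ranges, depth, config)
            rl = s.source_level_db - tl
            rows.append(
                {
                    "bin_time": s.bin_time,
                    "unit_id": s.unit_id,
                    "source_type": s.source_type,
                    "depth_source": mode,
                    "depth_m": depth,
                    "rl_median_db": float(np.median(rl)),
                    "rl_p05_db": float(np.percentile(rl, 5)),
                    "rl_p95_db": float(np.percentile(rl, 95)),
                    "rl_sd_db": float(np.std(rl)),
                    "range_center_m": float(ranges[0]),
                    "range_min_m": float(ranges.min()),
                    "range_max_m": float(ranges.max()),
                    "n_in_window": getattr(s, "n_in_window", np.nan),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["percentiles_over"] = "ellipse samples (center, radial midpoints, boundary)"
    return out


def stoplight(rl: pd.DataFrame, thresholds: tuple | None = None) -> pd.DataFrame:
    """Categorize bins by MFAS activity (transmission count per bin):
    green low, yellow moderate, red high. Default thresholds are tertiles
    of the nonzero per-bin counts; zero-transmission bins are left
    uncategorized."""
    out = rl.copy()
    counts = out.groupby("bin_time").n_in_window.transform("sum")
    nz = counts[counts > 0]
    if thresholds is None:
        if nz.empty:
            out["stoplight"] = None
            return out
        t1, t2 = np.percentile(nz.unique(), [100 / 3.0, 200 / 3.0])
    else:
        t1, t2 = thresholds
    cat = np.where(counts <= t1, "green", np.where(counts <= t2, "yellow", "red"))
    out["stoplight"] = np.where(counts > 0, cat, None)
    return out
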