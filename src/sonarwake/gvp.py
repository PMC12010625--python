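"""Matching acoustically detected group vocal periods (GVPs) to modeled
deep dives.

A GVP is an interval of echolocation clicks from a presumed foraging group
detected on one or more bottom-mounted hydrophones. A hydrophone is a
candidate for a tagged whale when some 5-min predicted track position
within +/-10 min of the GVP interval places the hydrophone within 6 km of
the whale's 95% confidence error ellipse. A candidate GVP is accepted when
its click interval is strictly contained in a deep dive's start/end times;
click start/end depths are then read off the reconstructed dive profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _geo
from .dive import DiveKinematics, dive_depth_at


@dataclass
class GvpMatch:
    dive_id: object
    dive_start: pd.Timestamp
    dive_end: pd.Timestamp
    click_start: pd.Timestamp
    click_end: pd.Timestamp
    hydrophone_ids: list
    onset_delay_min: float
    cessation_lead_min: float
    click_start_depth_m: float = np.nan
    click_end_depth_m: float = np.nan
    ambiguous: bool = False
    gvp_indices: list = field(default_factory=list)

    @property
    def n_hydrophones(self) -> int:
        return len(self.hydrophone_ids)


def candidate_hydrophones(
    track: pd.DataFrame,
    hydrophones: pd.DataFrame,
    gvp_start: pd.Timestamp,
    gvp_end: pd.Timestamp,
    radius_km: float = 6.0,
    window_min: float = 10.0,
) -> list:
    """Hydrophone ids whose distance to the 95% error ellipse of some
    track sample within +/-window of the GVP interval is <= radius.

    "Within window" is measured from the track sample time to the nearest
    point of the GVP interval; ellipse distance is
    max(0, center distance - ellipse support in that direction) with
    semi-axes ``CHI2_95_SCALE * (se_x, se_y)``.
    """
    ts = _geo.time_ns(track.timestamp).astype(float)
    g0, g1 = float(_geo.time_ns(gvp_start)), float(_geo.time_ns(gvp_end))
    minute_ns = 60e9
    dist_to_interval = np.maximum((g0 - ts) / minute_ns, (ts - g1) / minute_ns)
    near = np.clip(dist_to_interval, 0.0, None) <= window_min
    if not near.any():
        return []
    sub = track[near]
    sx = _geo.CHI2_95_SCALE * sub.se_x.to_numpy()
    sy = _geo.CHI2_95_SCALE * sub.se_y.to_numpy()
    ids = []
    for h in hydrophones.itertuples():
        d = _geo.distance_to_ellipse(
            h.x, h.y, sub.x.to_numpy(), sub.y.to_numpy(), sx, sy
        )
        if (d <= radius_km * 1000.0).any():
            ids.append(h.hydrophone_id)
    return ids


def match_gvps_to_dives(
    gvps: pd.DataFrame,
    dives: pd.DataFrame,
    track: pd.DataFrame | None = None,
    hydrophones: pd.DataFrame | None = None,
    radius_km: float = 6.0,
    window_min: float = 10.0,
    clock_tolerance_s: float = 0.0,
) -> list:
    """Associate GVP detections with deep dives.

    gvps: rows with hydrophone_id, start, end (and hydro_x/hydro_y when the
    spatial candidate test is requested via track+hydrophones).
    dives: per-dive table with dive_id, start, end, dive_class.
    Acceptance requires dive start <= click start and click end <= dive end
    (with an optional symmetric clock tolerance, default 0). GVPs on
    different hydrophones matching the same dive merge into one match.
    A GVP containable in several dives is reported on each, flagged
    ambiguous.
    """
    deep = dives[dives.dive_class == "deep"].reset_index(drop=True)
    tol = pd.Timedelta(seconds=clock_tolerance_s)
    per_dive: dict = {}
    for g in gvps.reset_index().itertuples():
        if track is not None and hydrophones is not None:
            hyd = hydrophones[hydrophones.hydrophone_id == g.hydrophone_id]
            cands = candidate_hydrophones(track, hyd, g.start, g.end,
                                          radius_km, window_min)
            if not cands:
                continue
        containing = deep[(deep.start <= g.start + tol) & (g.end - tol <= deep.end)]
        for d in containing.itertuples():
            key = d.dive_id
            rec = per_dive.setdefault(
                key,
                {
                    "dive": d,
                    "hydros": [],
                    "click_start": g.start,
                    "click_end": g.end,
                    "ambiguous": len(containing) > 1,
                    "indices": [],
                },
            )
            if g.hydrophone_id not in rec["hydros"]:
                rec["hydros"].append(g.hydrophone_id)
            rec["click_start"] = min(rec["click_start"], g.start)
            rec["click_end"] = max(rec["click_end"], g.end)
            rec["ambiguous"] = rec["ambiguous"] or len(containing) > 1
            rec["indices"].append(g.index)
    matches = []
    for key, rec in per_dive.items():
        d = rec["dive"]
        matches.append(
            GvpMatch(
                dive_id=key,
                dive_start=d.start,
                dive_end=d.end,
                click_start=rec["click_start"],
                click_end=rec["click_end"],
                hydrophone_ids=sorted(rec["hydros"]),
                onset_delay_min=(rec["click_start"] - d.start).total_seconds() / 60.0,
                cessation_lead_min=(d.end - rec["click_end"]).total_seconds() / 60.0,
                ambiguous=rec["ambiguous"],
                gvp_indices=rec["indices"],
            )
        )
    matches.sort(key=lambda m: m.dive_start)
    return matches


def estimate_click_depths(match: GvpMatch, kin: DiveKinematics) -> tuple:
    """Depth of the reconstructed profile at click start and end (linear
    in each dive phase). Returns (start_depth_m, end_depth_m) and stores
    them on the match."""
    rel0 = (match.click_start - match.dive_start).total_seconds()
    rel1 = (match.click_end - match.dive_start).total_seconds()
    d0, d1 = dive_depth_at(kin, [rel0, rel1])
    match.click_start_depth_m = float(d0)
    match.click_end_depth_m = float(d1)
    return float(d0), float(d1)


def repeated_site_use(matches: list) -> list:
    """Runs (length >= 2) of consecutive matched dives sharing at least one
    hydrophone — repeated diving at the same location.

    Returns a list of dicts with the shared hydrophones and run length.
    """
    runs = []
    if not matches:
        return runs
    ms = sorted(matches, key=lambda m: m.dive_start)
    run_shared = set(ms[0].hydrophone_ids)
    run_len = 1
    run_start = 0
    for i in range(1, len(ms)):
        shared = run_shared & set(ms[i].hydrophone_ids)
        if shared:
            run_shared = shared
            run_len += 1
        else:
            if run_len >= 2:
                runs.append({"hydrophones": sorted(run_shared), "length": run_len,
                             "first_dive": ms[run_start].dive_id})
            run_shared = set(ms[i].hydrophone_ids)
            run_len = 1
            run_start = i
    if run_len >= 2:
        runs.append({"hydrophones": sorted(run_shared), "length": run_len,
                     "first_dive": ms[run_start].dive_id})
    return runs
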