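"""End-to-end orchestration: configuration, schedule parsing, stage
sequencing, and the run report.

The pipeline runs simulate (optional) -> track -> dive -> gvp -> rl ->
stats on one animal's tables, writing every intermediate artifact plus a
JSON run report to the output directory. All timestamps carry an explicit
fixed UTC offset (field convention HST = UTC-10); reruns with the same
config and seed reproduce the same outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dive, exposure, gvp, stats, synthetic, track

log = logging.getLogger("sonarwake")


class ScheduleError(ValueError):
    pass


def parse_schedule(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a phase schedule (label, start, end) and emit computed
    durations in hours for cross-checking against any printed column."""
    req = {"label", "start", "end"}
    if not req.issubset(table.columns):
        raise ScheduleError(f"schedule needs columns {sorted(req)}")
    sched = table.copy()
    sched["start"] = pd.to_datetime(sched.start)
    sched["end"] = pd.to_datetime(sched.end)
    if (sched.end <= sched.start).any():
        raise ScheduleError("every phase must have end > start")
    s = sched.sort_values("start")
    if (s.start.to_numpy()[1:] < s.end.to_numpy()[:-1]).any():
        raise ScheduleError("phases overlap")
    sched["duration_h"] = (sched.end - sched.start).dt.total_seconds() / 3600.0
    return sched


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "sonarwake_run"
    sim: synthetic.SimConfig | None = None  # None -> read input tables
    input_dir: str | None = None
    n_imputations: int = 30
    interval_min: float = 5.0
    max_speed_ms: float = 3.0
    schedule: pd.DataFrame | None = None
    propagation: exposure.PropagationConfig = field(default_factory=exposure.PropagationConfig)

    def validated(self) -> "RunConfig":
        if self.sim is None and self.input_dir is None:
            raise ValueError("either sim config or input_dir is required")
        if self.schedule is not None:
            self.schedule = parse_schedule(self.schedule)
        return self


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    selected_model: dict = field(default_factory=dict)
    dive_summary: dict = field(default_factory=dict)
    gvp_summary: dict = field(default_factory=dict)
    rl_summary: dict = field(default_factory=dict)
    stats_summary: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (pd.Timestamp, pd.Timedelta)):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(dataclasses.asdict(self), indent=1, default=default)


def _read_inputs(indir: Path) -> dict:
    data = {}
    for name in ("locations", "behavior_log", "gvps", "mfas", "ships", "uplinks"):
        p = indir / f"{name}.csv"
        if p.exists():
            df = pd.read_csv(p)
            for col in ("timestamp", "start", "end"):
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col], format="mixed", utc=True)
            data[name] = df
    return data


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages; artifacts and the report land in config.outdir."""
    config = config.validated()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    if config.sim is not None:
        data = synthetic.generate_dataset(config.sim)
        synthetic.write_dataset(config.sim, outdir / "inputs")
        hydros = data["hydrophones"]
    else:
        data = _read_inputs(Path(config.input_dir))
        hydros = None
    report.counts["locations_raw"] = len(data.get("locations", []))

    # --- track -------------------------------------------------------------
    locs = track.prefilter_locations(data["locations"], config.max_speed_ms)
    report.counts["locations_filtered"] = len(locs)
    report.counts["locations_removed"] = report.counts["locations_raw"] - len(locs)
    m_ctcrw = track.fit_ctcrw(locs, config.interval_min)
    m_bm = track.fit_bm(locs, config.interval_min)
    best = track.select_model(m_ctcrw, m_bm)
    report.selected_model = {
        "kind": best.kind,
        "aic_ctcrw": m_ctcrw.aic,
        "aic_bm": m_bm.aic,
        "beta": best.beta,
        "sigma": best.sigma,
    }
    predicted = track.predict_track(best)
    predicted.to_csv(outdir / "predicted_track.csv", index=False)
    imputed = track.impute_tracks(best, n=config.n_imputations, seed=config.seed)
    imputed.to_frame().to_csv(outdir / "imputed_tracks.csv", index=False)
    report.counts["predicted_positions"] = len(predicted)

    # --- dive --------------------------------------------------------------
    behavior = data.get("behavior_log")
    series = None
    if behavior is not None and len(behavior):
        uplinks = data.get("uplinks")
        series = dive.build_depth_series(
            behavior, predicted,
            uplink_times=uplinks.timestamp if uplinks is not None else None,
            interval_min=config.interval_min,
        )
        series.to_csv(outdir / "depth_series.csv", index=False)
        iddis = dive.compute_iddis(behavior)
        iddis.to_csv(outdir / "iddis.csv", index=False)
        report.dive_summary = dive.summarize_dive_metrics(behavior)
    else:
        report.notices.append("behavior log absent: dive stage skipped")

    # --- gvp ---------------------------------------------------------------
    gvps = data.get("gvps")
    if gvps is not None and len(gvps) and behavior is not None and len(behavior):
        dives_tab = dive.dive_table(behavior)
        matches = gvp.match_gvps_to_dives(gvps, dives_tab)
        report.gvp_summary = {
            "n_gvps": len(gvps),
            "n_matches": len(matches),
            "repeated_site_runs": gvp.repeated_site_use(matches),
        }
    else:
        report.notices.append("GVP table or behavior log absent: GVP stage skipped")

    # --- rl ----------------------------------------------------------------
    tx = data.get("mfas")
    if tx is not None and len(tx):
        tx = exposure.define_bouts(tx)
        tx = exposure.join_ship_positions(tx, data.get("ships", pd.DataFrame()))
        sel = exposure.select_bin_transmissions(tx, predicted)
        rl = exposure.estimate_rl(sel, series, config.propagation)
        rl = exposure.stoplight(rl)
        rl.to_csv(outdir / "received_levels.csv", index=False)
        report.rl_summary = {
            "n_bouts": int(tx.bout.nunique()),
            "n_bins": int(sel.bin_time.nunique()) if len(sel) else 0,
            "rl_median_max_db": float(rl.rl_median_db.max()) if len(rl) else np.nan,
        }
    else:
        report.notices.append("MFAS table absent: RL stage skipped")

    # --- stats -------------------------------------------------------------
    if config.schedule is not None:
        steps = stats.compute_step_metrics(imputed.to_frame(), config.schedule, predicted)
        full_tests = stats.phase_tests(steps)
        filtered = stats.filter_gap_steps(steps)
        filt_tests = stats.phase_tests(filtered)
        concordance = stats.compare_track_variants(full_tests, filt_tests)
        full_tests.to_csv(outdir / "kw_full.csv", index=False)
        filt_tests.to_csv(outdir / "kw_filtered.csv", index=False)
        report.stats_summary = {
            "kw_full": full_tests.to_dict("records"),
            "kw_filtered": filt_tests.to_dict("records"),
            "concordance": concordance.attrs.get("concordance"),
        }
    else:
        report.notices.append("no phase schedule: movement stats skipped")

    (outdir / "run_report.json").write_text(report.to_json())
    cfg_dict = dataclasses.asdict(config)
    (outdir / "run_config.json").write_text(json.dumps(cfg_dict, default=str, indent=1))
    return report
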