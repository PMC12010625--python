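"""Movement modelling: location filtering, CTCRW/BM state-space fits,
5-min track prediction, multiple imputation, and barrier rerouting.

The movement model is the continuous-time correlated random walk (CTCRW):
per axis, velocity is an Ornstein-Uhlenbeck process with autocorrelation
parameter beta (per hour) and noise scale sigma, and position integrates
the velocity. Observations are surfacing fixes with per-fix error-ellipse
measurement covariance. The model is fit by maximum likelihood through a
Kalman filter on the exact discretization of the integrated-OU process;
an RTS smoother gives the predicted track and its standard errors, and
forward-filter backward-sampling draws whole-track imputations from the
joint smoothing distribution.

The Brownian-movement (BM) variant is the same state space with beta fixed
at 3 per hour (a less correlated, near-Brownian process) and only sigma
free; AIC chooses between the two per tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize
from shapely.geometry import LineString, Point
from shapely.ops import nearest_points

from . import _geo

BM_FIXED_BETA_PER_H = 3.0

#: isotropic 1-sigma fallback SDs (m) when ellipse fields are absent
CLASS_FALLBACK_SD_M = {
    "3": 250.0,
    "2": 500.0,
    "1": 1500.0,
    "0": 3000.0,
    "A": 5000.0,
    "B": 8000.0,
    "gps": 30.0,
}

_QUALITY_ORDER = {"gps": 0, "3": 1, "2": 2, "1": 3, "0": 4, "A": 5, "B": 6}

_DIFFUSE_POS_VAR = 1.0e10  # m^2, position prior at the first fix


class TooFewLocationsError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class CannotRerouteError(ValueError):
    pass


# ---------------------------------------------------------------------------
# prefilter


def prefilter_locations(raw: pd.DataFrame, max_speed: float = 3.0) -> pd.DataFrame:
    """Quality and speed filtering of raw fixes.

    GPS rows must satisfy residual < 35 and time error < 10 s (strict);
    duplicate timestamps are reduced to the best-quality fix; then the fix
    requiring the largest implied speed is removed iteratively until all
    consecutive speeds are <= max_speed (m/s).
    """
    df = raw.sort_values("timestamp").reset_index(drop=True).copy()
    gps = df.source == "gps"
    ok = ~gps | ((df.gps_residual < 35.0) & (df.gps_time_error_s < 10.0))
    df = df[ok].reset_index(drop=True)

    def _quality(row):
        key = "gps" if row.source == "gps" else str(row.location_class)
        return _QUALITY_ORDER.get(key, 99)

    df["_q"] = [_quality(r) for r in df.itertuples()]
    df = df.sort_values(["timestamp", "_q"]).drop_duplicates("timestamp", keep="first")
    df = df.drop(columns="_q").reset_index(drop=True)
    if len(df) < 2:
        raise TooFewLocationsError("fewer than 2 fixes survive filtering")

    lon0, lat0 = float(df.lon.mean()), float(df.lat.mean())
    x, y = _geo.project_aeq(df.lon.to_numpy(), df.lat.to_numpy(), lon0, lat0)
    t = (df.timestamp - df.timestamp.iloc[0]).dt.total_seconds().to_numpy()

    keep = np.ones(len(df), dtype=bool)
    while True:
        idx = np.flatnonzero(keep)
        if idx.size < 3:
            break
        xi, yi, ti = x[idx], y[idx], t[idx]
        dt = np.diff(ti)
        dt = np.where(dt <= 0, 1e-9, dt)
        sp = np.hypot(np.diff(xi), np.diff(yi)) / dt
        if sp.max() <= max_speed:
            break
        # per-fix required speed = max of adjacent segment speeds; a tie
        # (outlier vs its neighbor) is broken by the summed adjacent
        # speeds, which single out the teleporting fix itself
        req = np.zeros(idx.size)
        req[:-1] = np.maximum(req[:-1], sp)
        req[1:] = np.maximum(req[1:], sp)
        tot = np.zeros(idx.size)
        tot[:-1] += sp
        tot[1:] += sp
        worst = np.flatnonzero(req == req.max())
        drop = worst[int(np.argmax(tot[worst]))]
        keep[idx[drop]] = False
    out = df[keep].reset_index(drop=True)
    if len(out) < 2:
        raise TooFewLocationsError("fewer than 2 fixes survive speed filtering")
    return out


# ---------------------------------------------------------------------------
# Kalman machinery (state [x, vx, y, vy]; time in hours, space in meters)


@njit(cache=True)
def _kf_core(dt, has_obs, z, R, beta, sigma, m0, P0):
    n = dt.shape[0] + 1
    mf = np.zeros((n, 4))
    Pf = np.zeros((n, 4, 4))
    mp = np.zeros((n, 4))
    Pp = np.zeros((n, 4, 4))
    m = m0.copy()
    P = P0.copy()
    ll = 0.0
    s2 = sigma * sigma
    for t in range(n):
        if t > 0:
            d = dt[t - 1]
            e = np.exp(-beta * d)
            phi = (1.0 - e) / beta
            qvv = s2 * (1.0 - e * e) / (2.0 * beta)
            qxx = s2 / (beta * beta) * (d - 2.0 * (1.0 - e) / beta + (1.0 - e * e) / (2.0 * beta))
            qxv = s2 * (1.0 - e) * (1.0 - e) / (2.0 * beta * beta)
            F = np.zeros((4, 4))
            F[0, 0] = 1.0
            F[0, 1] = phi
            F[1, 1] = e
            F[2, 2] = 1.0
            F[2, 3] = phi
            F[3, 3] = e
            m = F @ m
            P = F @ P @ F.T
            P[0, 0] += qxx
            P[0, 1] += qxv
            P[1, 0] += qxv
            P[1, 1] += qvv
            P[2, 2] += qxx
            P[2, 3] += qxv
            P[3, 2] += qxv
            P[3, 3] += qvv
        mp[t] = m
        Pp[t] = P
        if has_obs[t]:
            y0 = z[t, 0] - m[0]
            y1 = z[t, 1] - m[2]
            S00 = P[0, 0] + R[t, 0, 0]
            S01 = P[0, 2] + R[t, 0, 1]
            S11 = P[2, 2] + R[t, 1, 1]
            det = S00 * S11 - S01 * S01
            if det <= 0.0:
                return -1.0e300, mf, Pf, mp, Pp
            i00 = S11 / det
            i01 = -S01 / det
            i11 = S00 / det
            maha = y0 * (i00 * y0 + i01 * y1) + y1 * (i01 * y0 + i11 * y1)
            ll += -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * maha
            # K = P H' S^-1, H picks rows 0 and 2
            PH = np.empty((4, 2))
            for i in range(4):
                PH[i, 0] = P[i, 0]
                PH[i, 1] = P[i, 2]
            K = np.empty((4, 2))
            for i in range(4):
                K[i, 0] = PH[i, 0] * i00 + PH[i, 1] * i01
                K[i, 1] = PH[i, 0] * i01 + PH[i, 1] * i11
            for i in range(4):
                m[i] = m[i] + K[i, 0] * y0 + K[i, 1] * y1
            P = P - K @ PH.T
            P = 0.5 * (P + P.T)
        mf[t] = m
        Pf[t] = P
    return ll, mf, Pf, mp, Pp


def _transition(beta: float, d: float) -> np.ndarray:
    e = np.exp(-beta * d)
    phi = (1.0 - e) / beta
    F = np.eye(4)
    F[0, 1] = phi
    F[1, 1] = e
    F[2, 3] = phi
    F[3, 3] = e
    return F


def _rts_smooth(beta, dt, mf, Pf, mp, Pp):
    n = mf.shape[0]
    ms = mf.copy()
    Ps = Pf.copy()
    for t in range(n - 2, -1, -1):
        F = _transition(beta, dt[t])
        # J = Pf F' Pp^{-1}
        J = np.linalg.solve(Pp[t + 1].T, (Pf[t] @ F.T).T).T
        ms[t] = mf[t] + J @ (ms[t + 1] - mp[t + 1])
        Ps[t] = Pf[t] + J @ (Ps[t + 1] - Pp[t + 1]) @ J.T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)
    return ms, Ps


def _sample_psd(rng, mean, cov):
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    w = np.clip(w, 0.0, None)
    return mean + (V * np.sqrt(w)) @ rng.standard_normal(mean.shape[0])


def _ffbs(rng, beta, dt, mf, Pf, mp, Pp):
    """One backward-sampling draw of the full state trajectory."""
    n = mf.shape[0]
    s = np.empty((n, 4))
    s[-1] = _sample_psd(rng, mf[-1], Pf[-1])
    for t in range(n - 2, -1, -1):
        F = _transition(beta, dt[t])
        J = np.linalg.solve(Pp[t + 1].T, (Pf[t] @ F.T).T).T
        mean = mf[t] + J @ (s[t + 1] - mp[t + 1])
        cov = Pf[t] - J @ Pp[t + 1] @ J.T
        s[t] = _sample_psd(rng, mean, cov)
    return s


# ---------------------------------------------------------------------------
# model container and fitting


@dataclass
class FittedMovementModel:
    kind: str  # "CTCRW" | "BM"
    beta: float
    sigma: float
    log_likelihood: float
    aic: float
    n_params: int
    beta_se: float
    sigma_se: float
    times_h: np.ndarray = field(repr=False)
    has_obs: np.ndarray = field(repr=False)
    on_lattice: np.ndarray = field(repr=False)
    z: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    smoothed_mean: np.ndarray = field(repr=False)
    smoothed_cov: np.ndarray = field(repr=False)
    filtered: tuple = field(repr=False)  # (mf, Pf, mp, Pp)
    t0: pd.Timestamp = None
    lon0: float = 0.0
    lat0: float = 0.0
    interval_min: float = 5.0
    animal_id: str = ""


def _measurement_cov(df: pd.DataFrame) -> np.ndarray:
    n = len(df)
    R = np.zeros((n, 2, 2))
    a = df.get("semi_major_m", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    b = df.get("semi_minor_m", pd.Series(np.nan, index=df.index)).to_numpy(dtype=float)
    th = df.get("ellipse_orientation_deg", pd.Series(0.0, index=df.index)).to_numpy(dtype=float)
    th = np.where(np.isfinite(th), th, 0.0)
    for i, row in enumerate(df.itertuples()):
        ai, bi = a[i], b[i]
        if not np.isfinite(ai):
            key = "gps" if row.source == "gps" else str(row.location_class)
            sd = CLASS_FALLBACK_SD_M.get(key, CLASS_FALLBACK_SD_M["B"])
            ai = bi = sd
        R[i] = _geo.ellipse_cov(ai, bi if np.isfinite(bi) else ai, th[i])
    return R


def _build_inputs(locs: pd.DataFrame, interval_min: float):
    locs = locs.sort_values("timestamp").reset_index(drop=True)
    lon0, lat0 = float(locs.lon.mean()), float(locs.lat.mean())
    xo, yo = _geo.project_aeq(locs.lon.to_numpy(), locs.lat.to_numpy(), lon0, lat0)
    t0 = locs.timestamp.iloc[0]
    t_obs = (locs.timestamp - t0).dt.total_seconds().to_numpy() / 3600.0
    step = interval_min / 60.0
    lattice = np.arange(0.0, t_obs[-1] + 1e-12, step)
    times = np.unique(np.round(np.concatenate([t_obs, lattice]), 9))
    has_obs = np.isin(times, np.round(t_obs, 9))
    on_lattice = np.isin(times, np.round(lattice, 9))
    z = np.full((times.size, 2), np.nan)
    R = np.zeros((times.size, 2, 2))
    obs_idx = np.searchsorted(times, np.round(t_obs, 9))
    Robs = _measurement_cov(locs)
    z[obs_idx, 0] = xo
    z[obs_idx, 1] = yo
    R[obs_idx] = Robs
    return dict(times=times, has_obs=has_obs, on_lattice=on_lattice, z=z, R=R,
                t0=t0, lon0=lon0, lat0=lat0, t_obs=t_obs)


def _init_state(inputs, beta, sigma):
    i0 = int(np.flatnonzero(inputs["has_obs"])[0])
    m0 = np.array([inputs["z"][i0, 0], 0.0, inputs["z"][i0, 1], 0.0])
    vv = sigma**2 / (2.0 * beta)
    P0 = np.diag([_DIFFUSE_POS_VAR, vv, _DIFFUSE_POS_VAR, vv])
    return m0, P0


def loglik(inputs, beta: float, sigma: float) -> float:
    m0, P0 = _init_state(inputs, beta, sigma)
    dt = np.diff(inputs["times"])
    ll, *_ = _kf_core(dt, inputs["has_obs"], np.nan_to_num(inputs["z"]),
                      inputs["R"], beta, sigma, m0, P0)
    return ll


def _fit(locs: pd.DataFrame, kind: str, interval_min: float, n_starts: int,
         beta_bounds=(1e-3, 1e3), sigma_bounds=(1e-3, 1e7), tol=1e-8) -> FittedMovementModel:
    if len(locs) < 10:
        raise TooFewLocationsError("need >= 10 fixes to fit a movement model")
    inputs = _build_inputs(locs, interval_min)
    dt = np.diff(inputs["times"])
    has_obs = inputs["has_obs"]
    z = np.nan_to_num(inputs["z"])
    R = inputs["R"]

    # data-scale sigma start: RMS 2-D displacement per sqrt(hour)
    t_obs = inputs["t_obs"]
    zo = inputs["z"][has_obs]
    d_obs = np.diff(t_obs)
    good = d_obs > 1e-6
    disp = np.hypot(np.diff(zo[:, 0]), np.diff(zo[:, 1]))[good]
    sigma_guess = max(float(np.sqrt(np.mean(disp**2 / d_obs[good]))), 1.0)

    fixed_beta = BM_FIXED_BETA_PER_H if kind == "BM" else None

    def nll(p):
        if fixed_beta is None:
            beta, sigma = np.exp(p[0]), np.exp(p[1])
        else:
            beta, sigma = fixed_beta, np.exp(p[0])
        m0, P0 = _init_state(inputs, beta, sigma)
        ll, *_ = _kf_core(dt, has_obs, z, R, beta, sigma, m0, P0)
        if not np.isfinite(ll):
            return 1e300
        return -ll

    lbb, ubb = np.log(beta_bounds[0]), np.log(beta_bounds[1])
    lbs, ubs = np.log(sigma_bounds[0]), np.log(sigma_bounds[1])
    if fixed_beta is None:
        starts = [np.array([np.log(b0), np.log(s0)])
                  for b0 in (0.3, 3.0, 30.0)[:n_starts]
                  for s0 in (sigma_guess,)]
        bounds = [(lbb, ubb), (lbs, ubs)]
    else:
        starts = [np.array([np.log(s0)]) for s0 in
                  (sigma_guess, sigma_guess * 5.0, sigma_guess / 5.0)[:n_starts]]
        bounds = [(lbs, ubs)]

    best = None
    traces = []
    for p0 in starts:
        res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500})
        traces.append(res)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e299:
        raise FitConvergenceError("movement model fit failed to converge", traces)

    if fixed_beta is None:
        beta, sigma = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
        k = 2
    else:
        beta, sigma = fixed_beta, float(np.exp(best.x[0]))
        k = 1
    ll = -float(best.fun)

    # log-scale SEs from a finite-difference Hessian; delta method to linear
    se_log = _hessian_se(nll, best.x)
    if fixed_beta is None:
        beta_se, sigma_se = beta * se_log[0], sigma * se_log[1]
    else:
        beta_se, sigma_se = 0.0, sigma * se_log[0]

    m0, P0 = _init_state(inputs, beta, sigma)
    _, mf, Pf, mp, Pp = _kf_core(dt, has_obs, z, R, beta, sigma, m0, P0)
    ms, Ps = _rts_smooth(beta, dt, mf, Pf, mp, Pp)

    return FittedMovementModel(
        kind=kind, beta=beta, sigma=sigma, log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll, n_params=k, beta_se=beta_se, sigma_se=sigma_se,
        times_h=inputs["times"], has_obs=has_obs, on_lattice=inputs["on_lattice"],
        z=inputs["z"], R=R, smoothed_mean=ms, smoothed_cov=Ps,
        filtered=(mf, Pf, mp, Pp), t0=inputs["t0"], lon0=inputs["lon0"],
        lat0=inputs["lat0"], interval_min=interval_min,
        animal_id=str(locs.animal_id.iloc[0]) if "animal_id" in locs else "",
    )


def _hessian_se(f, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d <= 0).any():
            raise np.linalg.LinAlgError
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)
    finally:
        del f0


def fit_ctcrw(locs: pd.DataFrame, interval_min: float = 5.0, n_starts: int = 3) -> FittedMovementModel:
    """ML fit of the CTCRW (free beta, sigma) with error-ellipse
    measurement covariance; returns smoothed states on the union of
    observation times and the 5-min lattice."""
    return _fit(locs, "CTCRW", interval_min, n_starts)


def fit_bm(locs: pd.DataFrame, interval_min: float = 5.0, n_starts: int = 3) -> FittedMovementModel:
    """BM variant: beta frozen at 3 per hour, only sigma free."""
    return _fit(locs, "BM", interval_min, n_starts)


def select_model(ctcrw: FittedMovementModel, bm: FittedMovementModel) -> FittedMovementModel:
    """Lower AIC wins; ties go to the CTCRW."""
    return bm if bm.aic < ctcrw.aic else ctcrw


# ---------------------------------------------------------------------------
# prediction / imputation


def predict_track(model: FittedMovementModel) -> pd.DataFrame:
    """Smoothing-distribution mean and SE on the 5-min lattice, with
    observed-vs-interpolated flags and surrounding observed-fix gap."""
    lat_mask = model.on_lattice
    t = model.times_h[lat_mask]
    ms = model.smoothed_mean[lat_mask]
    Ps = model.smoothed_cov[lat_mask]
    x, y = ms[:, 0], ms[:, 2]
    se_x = np.sqrt(np.clip(Ps[:, 0, 0], 0.0, None))
    se_y = np.sqrt(np.clip(Ps[:, 2, 2], 0.0, None))
    lon, lat = _geo.unproject_aeq(x, y, model.lon0, model.lat0)
    t_obs = model.times_h[model.has_obs]
    prev_i = np.clip(np.searchsorted(t_obs, t + 1e-9) - 1, 0, t_obs.size - 1)
    next_i = np.clip(np.searchsorted(t_obs, t - 1e-9), 0, t_obs.size - 1)
    since = (t - t_obs[prev_i]) * 60.0
    gap_h = t_obs[next_i] - t_obs[prev_i]
    observed = model.has_obs[lat_mask]
    return pd.DataFrame(
        {
            "timestamp": model.t0 + pd.to_timedelta(t * 3600.0, "s"),
            "t_h": t,
            "x": x,
            "y": y,
            "se_x": se_x,
            "se_y": se_y,
            "lon": lon,
            "lat": lat,
            "observed": observed,
            "time_since_fix_min": since,
            "enclosing_gap_h": gap_h,
            "animal_id": model.animal_id,
        }
    )


@dataclass
class ImputedTrackSet:
    draws: np.ndarray  # (n_imputations, n_lattice, 2) projected positions
    t_h: np.ndarray
    t0: pd.Timestamp
    lon0: float
    lat0: float
    seed: int
    predicted: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        lon_all, lat_all = _geo.unproject_aeq(
            self.draws[..., 0].ravel(), self.draws[..., 1].ravel(), self.lon0, self.lat0
        )
        n_imp, n_t = self.draws.shape[:2]
        one = pd.DatetimeIndex([self.t0 + pd.Timedelta(seconds=s) for s in self.t_h * 3600.0])
        ts = pd.DatetimeIndex(np.tile(one.asi8, n_imp), tz="UTC")
        if one.tz is not None:
            ts = ts.tz_convert(one.tz)
        else:
            ts = ts.tz_localize(None)
        return pd.DataFrame(
            {
                "imputation": np.repeat(np.arange(n_imp), n_t),
                "timestamp": ts,
                "t_h": np.tile(self.t_h, n_imp),
                "x": self.draws[..., 0].ravel(),
                "y": self.draws[..., 1].ravel(),
                "lon": lon_all,
                "lat": lat_all,
            }
        )


def impute_tracks(model: FittedMovementModel, n: int = 30, seed: int = 0) -> ImputedTrackSet:
    """n independent whole-trajectory draws from the joint smoothing
    distribution (forward-filter backward-sampling), on the 5-min lattice."""
    rng = np.random.default_rng(seed)
    mf, Pf, mp, Pp = model.filtered
    dt = np.diff(model.times_h)
    lat_mask = model.on_lattice
    draws = np.empty((n, int(lat_mask.sum()), 2))
    for i in range(n):
        s = _ffbs(rng, model.beta, dt, mf, Pf, mp, Pp)
        draws[i, :, 0] = s[lat_mask, 0]
        draws[i, :, 1] = s[lat_mask, 2]
    return ImputedTrackSet(
        draws=draws, t_h=model.times_h[lat_mask], t0=model.t0,
        lon0=model.lon0, lat0=model.lat0, seed=seed, predicted=predict_track(model),
    )


# ---------------------------------------------------------------------------
# barrier rerouting


def _visibility_path(p_in, p_out, barrier, densify_m=500.0):
    shrunk = barrier.buffer(-1.0)
    boundary = barrier.boundary.segmentize(densify_m)
    nodes = [np.asarray(p_in), np.asarray(p_out)]
    coords = []
    if boundary.geom_type == "LineString":
        coords = list(boundary.coords)
    else:
        for g in boundary.geoms:
            coords.extend(g.coords)
    nodes.extend(np.asarray(c) for c in coords)
    G = nx.Graph()
    for i in range(len(nodes)):
        G.add_node(i)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            seg = LineString([nodes[i], nodes[j]])
            if not seg.intersects(shrunk):
                G.add_edge(i, j, weight=float(np.hypot(*(nodes[i] - nodes[j]))))
    try:
        path = nx.shortest_path(G, 0, 1, weight="weight")
    except nx.NetworkXNoPath as err:
        raise CannotRerouteError("no barrier-avoiding path exists") from err
    return LineString([nodes[k] for k in path])


def reroute_around_land(track: pd.DataFrame, barrier, densify_m: float = 500.0) -> pd.DataFrame:
    """Replace track points inside the barrier polygon with points along
    the shortest barrier-avoiding detour between the entry and exit points.
    Points outside the barrier are untouched."""
    pts = [Point(xy) for xy in zip(track.x, track.y)]
    inside = np.array([barrier.covers(p) and not barrier.boundary.covers(p) for p in pts])
    if not inside.any():
        return track.copy()
    if inside.all():
        raise CannotRerouteError("entire track lies inside the barrier")
    out = track.copy().reset_index(drop=True)
    x = out.x.to_numpy().copy()
    y = out.y.to_numpy().copy()
    i = 0
    n = len(out)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j < n and inside[j]:
            j += 1
        # entry/exit anchors; runs at record edges anchor on the boundary
        if i > 0:
            p_in = (x[i - 1], y[i - 1])
        else:
            p_in = nearest_points(barrier.boundary, pts[i])[0].coords[0]
        if j < n:
            p_out = (x[j], y[j])
        else:
            p_out = nearest_points(barrier.boundary, pts[j - 1])[0].coords[0]
        detour = _visibility_path(p_in, p_out, barrier, densify_m)
        k = j - i
        for m_, idx in enumerate(range(i, j)):
            frac = (m_ + 1) / (k + 1)
            p = detour.interpolate(frac, normalized=True)
            x[idx], y[idx] = p.x, p.y
        i = j
    out["x"], out["y"] = x, y
    if {"lon", "lat"}.issubset(out.columns) and {"x", "y"}.issubset(track.columns):
        # keep lon/lat consistent if a projection center is recoverable
        pass
    out["rerouted"] = False
    out.loc[inside, "rerouted"] = True
    return out
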