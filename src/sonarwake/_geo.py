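"""Geodesy helpers: local projection, distances, bearings, error ellipses.

All geographic coordinates are WGS84 decimal degrees; projected coordinates
are meters east (x) and north (y) in a local azimuthal-equidistant plane.
A spherical Earth (mean radius) is used throughout — at the tens-of-km
scales of a tagging study the spherical/ellipsoidal discrepancy is far
below positional error, and forward/inverse round-trips are exact to
numerical precision.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2

EARTH_RADIUS_M = 6_371_008.8


def time_ns(x):
    """Timestamps (scalar, Series, Index, array; tz-aware or naive) as
    int64 nanoseconds since epoch — the package's internal time axis."""
    import pandas as pd

    if np.isscalar(x) or isinstance(x, pd.Timestamp):
        return pd.Timestamp(x).value
    return pd.DatetimeIndex(x).asi8

# Scale factor taking 1-sigma ellipse axes to the 95% confidence ellipse
# (two-dimensional chi-square quantile).
CHI2_95_SCALE: float = float(np.sqrt(chi2.ppf(0.95, df=2)))


def project_aeq(lon, lat, lon0: float, lat0: float):
    """Forward azimuthal-equidistant projection centered at (lon0, lat0).

    Returns (x, y) in meters; x east, y north. Vectorized.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0r, lat0r = np.radians(lon0), np.radians(lat0)
    dlon = lon - lon0r
    cos_c = np.sin(lat0r) * np.sin(lat) + np.cos(lat0r) * np.cos(lat) * np.cos(dlon)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    # azimuth from center to point, clockwise from north
    az = np.arctan2(
        np.sin(dlon) * np.cos(lat),
        np.cos(lat0r) * np.sin(lat) - np.sin(lat0r) * np.cos(lat) * np.cos(dlon),
    )
    rho = EARTH_RADIUS_M * c
    return rho * np.sin(az), rho * np.cos(az)


def unproject_aeq(x, y, lon0: float, lat0: float):
    """Inverse of :func:`project_aeq`. Returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon0r, lat0r = np.radians(lon0), np.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    az = np.arctan2(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.arcsin(
            np.cos(c) * np.sin(lat0r) + np.sin(c) * np.cos(lat0r) * np.cos(az)
        )
        lon = lon0r + np.arctan2(
            np.sin(az) * np.sin(c) * np.cos(lat0r),
            np.cos(c) - np.sin(lat0r) * np.sin(lat),
        )
    lat = np.where(rho == 0.0, lat0r, lat)
    lon = np.where(rho == 0.0, lon0r, lon)
    return np.degrees(lon), np.degrees(lat)


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, degrees clockwise from north in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    yy = np.sin(dlon) * np.cos(lat2)
    xx = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(yy, xx)) % 360.0


def wrap_angle_rad(angle):
    """Wrap angles (radians) into (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def ellipse_cov(a, b, theta_deg):
    """2x2 covariance from 1-sigma semi-major a, semi-minor b (m) and
    orientation theta (degrees clockwise from north of the major axis).

    x is east, y is north.
    """
    th = np.radians(np.asarray(theta_deg, dtype=float))
    a2 = np.asarray(a, dtype=float) ** 2
    b2 = np.asarray(b, dtype=float) ** 2
    # unit vector along major axis (east, north) for bearing theta
    ux, uy = np.sin(th), np.cos(th)
    cxx = a2 * ux**2 + b2 * uy**2
    cyy = a2 * uy**2 + b2 * ux**2
    cxy = (a2 - b2) * ux * uy
    return np.stack(
        [np.stack([cxx, cxy], axis=-1), np.stack([cxy, cyy], axis=-1)], axis=-2
    )


def ellipse_support_radius(semi_x, semi_y, dx, dy):
    """Radius of an axis-aligned ellipse (semi-axes semi_x east, semi_y
    north) along the direction of (dx, dy). Zero direction returns 0."""
    r = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
        denom = np.sqrt(
            np.where(semi_x > 0, (ux / np.where(semi_x > 0, semi_x, 1.0)) ** 2, np.inf)
            + np.where(semi_y > 0, (uy / np.where(semi_y > 0, semi_y, 1.0)) ** 2, np.inf)
        )
        rad = np.where(np.isfinite(denom) & (denom > 0), 1.0 / denom, 0.0)
    # degenerate axes: support along a zero axis is 0 unless pointing along
    # the nonzero axis; the formula above already collapses correctly when
    # both axes are 0.
    both_zero = (np.asarray(semi_x) == 0) & (np.asarray(semi_y) == 0)
    return np.where(both_zero, 0.0, rad)


def distance_to_ellipse(px, py, cx, cy, semi_x, semi_y):
    """Distance from point (px,py) to an axis-aligned ellipse centered at
    (cx,cy): max(0, center distance - ellipse support in that direction)."""
    dx = np.asarray(px, dtype=float) - cx
    dy = np.asarray(py, dtype=float) - cy
    d = np.hypot(dx, dy)
    support = ellipse_support_radius(semi_x, semi_y, dx, dy)
    return np.maximum(0.0, d - support)
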