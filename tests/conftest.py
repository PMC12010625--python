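import numpy as np
import pandas as pd
import pytest

from sonarwake import _geo
from sonarwake.synthetic import SimConfig

CENTER = (-159.9, 22.1)


def make_ctcrw_locations(
    seed: int,
    beta: float = 0.5,
    sigma: float | None = None,
    n: int = 300,
    dt_min: float = 10.0,
    noise_sd: float = 150.0,
    mean_step_m: float = 1000.0,
):
    """Fixes drawn from the exact integrated-OU discretization: the
    independent generative twin of the fitted state-space model.

    Returns (locations DataFrame, true beta, true sigma).
    """
    from sonarwake.synthetic import sigma_for_mean_step

    rng = np.random.default_rng(seed)
    if sigma is None:
        sigma = sigma_for_mean_step(beta, dt_min / 60.0, mean_step_m)
    dt = rng.uniform(0.5 * dt_min, 1.5 * dt_min, n - 1) / 60.0  # hours
    pos = np.zeros((n, 2))
    vel = rng.normal(0.0, sigma / np.sqrt(2.0 * beta), 2)
    for i in range(1, n):
        d = dt[i - 1]
        e = np.exp(-beta * d)
        q_vv = sigma**2 * (1 - e * e) / (2 * beta)
        q_xx = sigma**2 / beta**2 * (d - 2 * (1 - e) / beta + (1 - e * e) / (2 * beta))
        q_xv = sigma**2 * (1 - e) ** 2 / (2 * beta**2)
        chol = np.linalg.cholesky(np.array([[q_xx, q_xv], [q_xv, q_vv]]) + 1e-12 * np.eye(2))
        for ax in range(2):
            eps = chol @ rng.standard_normal(2)
            pos[i, ax] = pos[i - 1, ax] + vel[ax] * (1 - e) / beta + eps[0]
            vel[ax] = e * vel[ax] + eps[1]
    obs = pos + rng.normal(0.0, noise_sd, (n, 2))
    t_h = np.concatenate([[0.0], np.cumsum(dt)])
    lon, lat = _geo.unproject_aeq(obs[:, 0], obs[:, 1], *CENTER)
    df = pd.DataFrame(
        {
            "timestamp": pd.Timestamp("2021-08-11 12:00:00-10:00")
            + pd.to_timedelta(t_h * 3600.0, "s"),
            "lon": lon,
            "lat": lat,
            "source": "argos",
            "location_class": "1",
            "semi_major_m": noise_sd,
            "semi_minor_m": noise_sd,
            "ellipse_orientation_deg": 0.0,
            "gps_residual": np.nan,
            "gps_time_error_s": np.nan,
            "gps_satellites": -1,
            "animal_id": "SIM",
        }
    )
    return df, beta, sigma


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, duration_h=48.0)


@pytest.fixture(scope="session")
def clean_config():
    """No behavior-log gaps, tight GVP timing — exact round-trip conditions."""
    return SimConfig(
        seed=12,
        duration_h=96.0,
        gap_fraction=0.0,
        gvp_onset_delay=(5.8, 1e-9, 5.8, 5.8),
        gvp_cessation_lead=(12.7, 1e-9, 12.7, 12.7),
    )
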