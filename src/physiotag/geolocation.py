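"""Light-based geolocation with SST-matched state-space refinement.

The pipeline estimates one position per day from an archival tag's light
record using the template-fit idea -- longitude from the time of local noon,
latitude from day length -- and then refines the noisy raw estimates in a
state-space smoother that also matches tag-measured sea-surface temperature
(mean external temperature above a 5 m depth cutoff) against a gridded SST
field.  The smoother is an unscented Kalman filter (the SST observation is a
nonlinear function of position) followed by a Rauch-Tung-Striebel backward
pass; the single process-noise parameter (km/sqrt(day)) can be fixed or
estimated by maximising the filter likelihood.

Around the equinoxes the day length barely varies with latitude, so template
latitudes carry almost no information; they are flagged invalid and their
observation standard deviation is inflated so that latitude is carried by
the SST match and the random-walk prior instead.

A brute-force discrete grid filter (:func:`grid_filter_oracle`) implements
the same observation model as an HMM forward-backward pass over a lat/lon
grid, for validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .simulate import SSTField
from .series import TagSeries
from .solar import solar_position

logger = logging.getLogger(__name__)

_KM_PER_DEG = 111.19492664455873

__all__ = [
    "GeoConfig",
    "RawGeoEstimate",
    "Track",
    "detect_twilights",
    "template_fit_position",
    "light_positions",
    "tag_sst_daily",
    "refine_track",
    "grid_filter_oracle",
]


@dataclass
class GeoConfig:
    """Tunable geolocation parameters.

    Observation standard deviations are typical archival-tag magnitudes:
    0.5 deg longitude, 1.0 deg latitude (inflated to 20 deg inside the
    equinox window), 0.3 degC for the SST match.  ``sun_altitude_deg`` is
    the solar elevation the twilight detector's threshold corresponds to;
    ``declination_min_deg`` is the half-width (in declination) of the
    equinox window in which template latitudes are flagged invalid.
    """

    obs_sd_lon: float = 0.5
    obs_sd_lat: float = 1.0
    obs_sd_lat_equinox: float = 20.0
    obs_sd_sst: float = 0.3
    declination_min_deg: float = 3.0
    sun_altitude_deg: float = -6.0
    light_threshold: float = 0.3
    smooth_window_min: float = 10.0
    process_sigma_km: float | None = None  # None -> maximum-likelihood search
    sigma_bounds_km: tuple[float, float] = (10.0, 300.0)
    divergence_nsigma: float = 6.0
    divergence_days: int = 3


@dataclass(frozen=True)
class RawGeoEstimate:
    """One day's template-fit position estimate from light alone."""

    date: pd.Timestamp
    dawn_utc: pd.Timestamp
    dusk_utc: pd.Timestamp
    noon_utc: pd.Timestamp
    lon_light: float
    lat_light: float
    lat_valid: bool
    obs_sd_lon: float
    obs_sd_lat: float


@dataclass
class Track:
    """Smoothed daily positions with posterior uncertainty."""

    data: pd.DataFrame  # date, lat, lon, sd_lat, sd_lon
    log_likelihood: float = math.nan
    process_sigma_km: float = math.nan
    ll_history: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def _wrap_deg(x):
    """Map angle differences / longitudes to (-180, 180]."""
    w = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.ndim(x) == 0 else w


# ---------------------------------------------------------------------------
# Twilights and the template fit
# ---------------------------------------------------------------------------


def detect_twilights(
    series: TagSeries,
    light_threshold: float = 0.3,
    smooth_window_min: float = 10.0,
    min_night_min: float = 60.0,
) -> pd.DataFrame:
    """Detect dawn/dusk threshold crossings on the smoothed log-light curve.

    The log-light series is smoothed with a centred rolling *median* (robust
    to brief dive-induced attenuation spikes); each maximal run of samples
    above the threshold is one candidate daylight period, dated by its
    midpoint.  A run only counts as a day when it is bracketed by at least
    ``min_night_min`` of darkness on both sides (so fragments created by
    deep dives or by the ends of the record are rejected) and lasts between
    4 and 20 hours.  Days without a usable pair are logged as warnings,
    never raised.

    Returns a DataFrame with columns ``date``, ``dawn_utc``, ``dusk_utc``.
    """
    light = series.data["light"]
    dt_s = series.sampling_s
    window = max(int(round(smooth_window_min * 60.0 / dt_s)), 1)
    smoothed = (
        np.log(light.clip(lower=1e-9))
        .rolling(window, center=True, min_periods=1)
        .median()
    )
    above = (smoothed > np.log(light_threshold)).to_numpy()
    idx = series.data.index
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))  # last above sample of each run
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)

    min_gap = int(round(min_night_min * 60.0 / dt_s))
    rows = []
    for k, (s, e) in enumerate(zip(starts, ends)):
        prev_end = ends[k - 1] if k > 0 else None
        next_start = starts[k + 1] if k + 1 < len(starts) else None
        night_before = (s - prev_end) if prev_end is not None else s
        night_after = (next_start - e) if next_start is not None else len(above) - 1 - e
        if s == 0 or e == len(above) - 1:
            continue  # truncated by the record
        if night_before < min_gap or night_after < min_gap:
            continue  # dive fragment, not a day
        dawn, dusk = idx[s], idx[e]
        length_h = (dusk - dawn).total_seconds() / 3600.0
        if not 4.0 <= length_h <= 20.0:
            continue
        mid = dawn + (dusk - dawn) / 2
        rows.append({"date": mid.normalize(), "dawn_utc": dawn, "dusk_utc": dusk})
    out = pd.DataFrame(rows, columns=["date", "dawn_utc", "dusk_utc"])
    found = set(out["date"]) if len(out) else set()
    for day in pd.date_range(idx[0].normalize(), idx[-1].normalize(), freq="D")[
        : series.n_days
    ]:
        if day not in found:
            logger.warning("no usable twilight pair on %s", day.date())
    return out


def template_fit_position(
    dawn_utc,
    dusk_utc,
    config: GeoConfig | None = None,
) -> RawGeoEstimate:
    """Template fit: longitude from local noon, latitude from day length.

    Noon is the dawn/dusk midpoint; longitude follows from
    ``15 deg/h * (12 h - (noon_utc + equation_of_time))``.  Latitude solves
    the sunrise equation at the calibrated twilight sun altitude
    (``config.sun_altitude_deg``).  Inside the equinox window
    (|declination| < ``declination_min_deg``) or when no latitude satisfies
    the observed day length, ``lat_valid`` is False and the latitude
    standard deviation is inflated -- never an exception.
    """
    cfg = config or GeoConfig()
    dawn = pd.Timestamp(dawn_utc)
    dusk = pd.Timestamp(dusk_utc)
    if not dawn < dusk:
        raise ValueError("dawn must precede dusk")
    noon = dawn + (dusk - dawn) / 2
    decl_deg, eot_min = solar_position(noon)
    noon_h = (noon - noon.normalize()).total_seconds() / 3600.0
    lon = _wrap_deg(15.0 * (12.0 - (noon_h + eot_min / 60.0)))

    day_length_h = (dusk - dawn).total_seconds() / 3600.0
    half_angle = np.radians(day_length_h * 15.0 / 2.0)
    decl = np.radians(decl_deg)
    h0 = np.radians(cfg.sun_altitude_deg)
    # solve sin(h0) = sin(lat) sin(decl) + cos(lat) cos(decl) cos(H) for lat
    a, b, c = np.sin(decl), np.cos(decl) * np.cos(half_angle), np.sin(h0)
    r = np.hypot(a, b)
    lat = np.nan
    valid = abs(decl_deg) >= cfg.declination_min_deg
    if r < abs(c):
        valid = False
    else:
        psi = np.arctan2(b, a)
        base = [np.arcsin(c / r) - psi, np.pi - np.arcsin(c / r) - psi]
        cands = [np.degrees(x) + 360.0 * k for x in base for k in (-1, 0, 1)]
        cands = [x for x in cands if -70.0 <= x <= 70.0]
        if not cands:
            valid = False
        else:
            lat = float(min(cands, key=abs))
    return RawGeoEstimate(
        date=noon.normalize(),
        dawn_utc=dawn,
        dusk_utc=dusk,
        noon_utc=noon,
        lon_light=float(lon),
        lat_light=float(lat),
        lat_valid=bool(valid),
        obs_sd_lon=cfg.obs_sd_lon,
        obs_sd_lat=cfg.obs_sd_lat if valid else cfg.obs_sd_lat_equinox,
    )


def light_positions(series: TagSeries, config: GeoConfig | None = None) -> pd.DataFrame:
    """Twilight detection + template fit for every usable day of a series."""
    cfg = config or GeoConfig()
    tw = detect_twilights(series, cfg.light_threshold, cfg.smooth_window_min)
    rows = [
        vars(template_fit_position(r.dawn_utc, r.dusk_utc, cfg)) for r in tw.itertuples()
    ]
    cols = [
        "date", "dawn_utc", "dusk_utc", "noon_utc",
        "lon_light", "lat_light", "lat_valid", "obs_sd_lon", "obs_sd_lat",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.drop_duplicates(subset="date", keep="first").reset_index(drop=True)


def tag_sst_daily(series: TagSeries, depth_cutoff_m: float = 5.0) -> pd.DataFrame:
    """Daily tag-side SST: mean external temperature at depth <= cutoff.

    Days with no qualifying shallow sample are omitted.  Returns columns
    ``date``, ``sst_c``, ``n_samples``.
    """
    if depth_cutoff_m <= 0:
        raise ValueError("depth cutoff must be positive")
    shallow = series.data[series.data["depth_m"] <= depth_cutoff_m]
    if shallow.empty:
        return pd.DataFrame(columns=["date", "sst_c", "n_samples"])
    grp = shallow.groupby(shallow.index.normalize())["temp_external_c"]
    out = grp.agg(sst_c="mean", n_samples="size").reset_index(names="date")
    return out


# ---------------------------------------------------------------------------
# UKF + RTS smoother
# ---------------------------------------------------------------------------


def _build_observations(raw, daily_sst, use_sst):
    """Merge light and SST observations into {date: [(kind, value, sd), ...]}."""
    obs: dict[pd.Timestamp, list] = {}
    if raw is not None and len(raw):
        for r in raw.itertuples():
            day = pd.Timestamp(r.date)
            comps = obs.setdefault(day, [])
            if np.isfinite(r.lon_light):
                comps.append(("lon", float(r.lon_light), float(r.obs_sd_lon)))
            if np.isfinite(r.lat_light):
                comps.append(("lat", float(r.lat_light), float(r.obs_sd_lat)))
    if use_sst and daily_sst is not None and len(daily_sst):
        sd_col = "obs_sd_sst" if "obs_sd_sst" in daily_sst.columns else None
        for r in daily_sst.itertuples():
            if np.isfinite(r.sst_c):
                sd = getattr(r, "obs_sd_sst") if sd_col else None
                obs.setdefault(pd.Timestamp(r.date), []).append(("sst", float(r.sst_c), sd))
    return dict(sorted(obs.items()))


def _sigma_points(x, P):
    n = 2
    lam = 1.0  # Julier symmetric set: alpha=1, kappa=1
    try:
        s = np.linalg.cholesky((n + lam) * P)
    except np.linalg.LinAlgError:
        s = np.linalg.cholesky((n + lam) * (P + 1e-8 * np.eye(n)))
    pts = [x, x + s[:, 0], x + s[:, 1], x - s[:, 0], x - s[:, 1]]
    wm = np.array([lam / (n + lam)] + [1.0 / (2 * (n + lam))] * 4)
    return np.array(pts), wm


def _ukf_filter(days, obs, sigma_km, sst_field, cfg, x0, P0):
    """One forward pass; returns (loglik, per-day filter/prediction moments)."""
    x = x0.copy()
    P = P0.copy()
    ll = 0.0
    filtered, predicted = [], []
    streak = 0
    prev_day = None
    for day in days:
        dt = 1.0 if prev_day is None else max((day - prev_day).days, 1)
        if prev_day is not None:
            q_lat = (sigma_km / _KM_PER_DEG) ** 2 * dt
            q_lon = (sigma_km / (_KM_PER_DEG * max(np.cos(np.radians(x[0])), 0.2))) ** 2 * dt
            P = P + np.diag([q_lat, q_lon])
        x_pred, P_pred = x.copy(), P.copy()

        comps = obs[day]
        if comps:
            chi, wm = _sigma_points(x, P)
            m = len(comps)
            Z = np.zeros((len(chi), m))
            z = np.zeros(m)
            R = np.zeros(m)
            sst_vals = None
            if any(k == "sst" for k, _, _ in comps):
                sst_vals = sst_field.value_at(day, chi[:, 0], chi[:, 1])
            for ci, (kind, value, sd) in enumerate(comps):
                z[ci] = value
                R[ci] = (sd if sd is not None else cfg.obs_sd_sst) ** 2
                if kind == "lat":
                    Z[:, ci] = chi[:, 0]
                elif kind == "lon":
                    Z[:, ci] = chi[:, 1]
                else:
                    Z[:, ci] = sst_vals
            zhat = wm @ Z
            dZ = Z - zhat
            lon_idx = [ci for ci, (k, _, _) in enumerate(comps) if k == "lon"]
            S = (dZ * wm[:, None]).T @ dZ + np.diag(R)
            C = ((chi - x) * wm[:, None]).T @ dZ
            innov = z - zhat
            for ci in lon_idx:
                innov[ci] = _wrap_deg(innov[ci])
            Sinv = np.linalg.inv(S)
            K = C @ Sinv
            x = x + K @ innov
            x[1] = _wrap_deg(x[1])
            P = P - K @ S @ K.T
            P = 0.5 * (P + P.T)
            maha2 = float(innov @ Sinv @ innov)
            ll += -0.5 * (m * np.log(2 * np.pi) + np.log(np.linalg.det(S)) + maha2)
            norm = np.abs(innov) / np.sqrt(np.diag(S))
            if norm.max() > cfg.divergence_nsigma:
                streak += 1
                if streak > cfg.divergence_days:
                    logger.warning("filter divergence on %s; re-initialising", day.date())
                    for kind, value, _ in comps:
                        if kind == "lat":
                            x[0] = value
                        elif kind == "lon":
                            x[1] = value
                    P = P0.copy()
                    streak = 0
            else:
                streak = 0
        filtered.append((x.copy(), P.copy()))
        predicted.append((x_pred, P_pred))
        prev_day = day
    return ll, filtered, predicted


def _rts_smooth(filtered, predicted):
    n = len(filtered)
    xs = [None] * n
    Ps = [None] * n
    xs[-1], Ps[-1] = filtered[-1]
    for t in range(n - 2, -1, -1):
        xf, Pf = filtered[t]
        xp, Pp = predicted[t + 1]
        G = Pf @ np.linalg.inv(Pp)
        dx = xs[t + 1] - xp
        dx[1] = _wrap_deg(dx[1])
        xs[t] = xf + G @ dx
        Ps[t] = Pf + G @ (Ps[t + 1] - Pp) @ G.T
    return xs, Ps


def _golden_max(f, lo, hi, tol=2.0):
    """Golden-section maximiser; returns (argmax, best-so-far history)."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc >= fd else (d, fd)
    history = [best_f]
    while hi - lo > tol:
        if fc >= fd:
            hi, d, fd = d, c, fc
            c = hi - invphi * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d, fd
            d = lo + invphi * (hi - lo)
            fd = f(d)
        x, fx = (c, fc) if fc >= fd else (d, fd)
        if fx > best_f:
            best_x, best_f = x, fx
        history.append(best_f)
    return best_x, history


def refine_track(
    raw_estimates: pd.DataFrame,
    daily_sst: pd.DataFrame | None,
    sst_field: SSTField | None,
    config: GeoConfig | None = None,
    release: tuple[float, float] | None = None,
    use_sst: bool = True,
) -> Track:
    """Fuse template-fit positions and the SST match in a UKF + RTS smoother.

    ``raw_estimates`` is the output of :func:`light_positions` (columns
    ``date``, ``lon_light``, ``lat_light``, ``obs_sd_lon``, ``obs_sd_lat``);
    ``daily_sst`` the output of :func:`tag_sst_daily`.  When
    ``config.process_sigma_km`` is None the process noise is estimated by a
    golden-section maximisation of the filter log-likelihood over
    ``config.sigma_bounds_km``.  ``release``, when known, anchors the
    initial state.
    """
    cfg = config or GeoConfig()
    if use_sst and sst_field is None:
        use_sst = False
    obs = _build_observations(raw_estimates, daily_sst, use_sst)
    days = list(obs.keys())
    if sum(len(v) for v in obs.values()) == 0:
        raise ValueError("no valid observations to filter")
    if len(days) < 3:
        raise ValueError("need at least 3 days with observations")

    if release is not None:
        x0 = np.array([release[0], release[1]], dtype=float)
    else:
        first = obs[days[0]]
        lat0 = next((v for k, v, _ in first if k == "lat"), np.nan)
        if not np.isfinite(lat0):
            lats = [
                v
                for comps in obs.values()
                for k, v, sd in comps
                if k == "lat" and sd is not None and sd <= cfg.obs_sd_lat
            ]
            lat0 = float(np.median(lats)) if lats else 30.0
        lon0 = next((v for k, v, _ in first if k == "lon"), 140.0)
        x0 = np.array([lat0, lon0], dtype=float)
    P0 = np.diag([2.0**2, 2.0**2])

    def loglik(sig):
        ll, _, _ = _ukf_filter(days, obs, sig, sst_field, cfg, x0, P0)
        return ll

    history = []
    if cfg.process_sigma_km is None:
        sigma, history = _golden_max(loglik, *cfg.sigma_bounds_km)
    else:
        sigma = cfg.process_sigma_km
    ll, filtered, predicted = _ukf_filter(days, obs, sigma, sst_field, cfg, x0, P0)
    history.append(ll) if not history else None
    xs, Ps = _rts_smooth(filtered, predicted)

    data = pd.DataFrame(
        {
            "date": days,
            "lat": [x[0] for x in xs],
            "lon": [x[1] for x in xs],
            "sd_lat": [math.sqrt(max(p[0, 0], 0.0)) for p in Ps],
            "sd_lon": [math.sqrt(max(p[1, 1], 0.0)) for p in Ps],
            "sd_lat_filter": [math.sqrt(max(p[0, 0], 0.0)) for _, p in filtered],
            "sd_lon_filter": [math.sqrt(max(p[1, 1], 0.0)) for _, p in filtered],
        }
    )
    return Track(data=data, log_likelihood=ll, process_sigma_km=float(sigma), ll_history=history)


# ---------------------------------------------------------------------------
# Brute-force grid filter (validation oracle)
# ---------------------------------------------------------------------------


def grid_filter_oracle(
    raw_estimates: pd.DataFrame,
    daily_sst: pd.DataFrame | None,
    sst_field: SSTField | None,
    grid_resolution_deg: float = 0.5,
    config: GeoConfig | None = None,
    process_sigma_km: float = 60.0,
    release: tuple[float, float] | None = None,
    extent: tuple[float, float, float, float] | None = None,
    use_sst: bool = True,
) -> Track:
    """Discrete HMM forward-backward smoother over a lat/lon grid.

    Uses the same per-day observation likelihoods as :func:`refine_track`
    and a Gaussian random-walk transition kernel (applied as a separable
    blur).  Posterior mean and sd per day.  Intended as a brute-force
    validation oracle, not for production use.
    """
    cfg = config or GeoConfig()
    if use_sst and sst_field is None:
        use_sst = False
    obs = _build_observations(raw_estimates, daily_sst, use_sst)
    days = list(obs.keys())
    if not days:
        raise ValueError("no days to filter")

    if extent is None:
        lats = [v for c in obs.values() for k, v, sd in c if k == "lat" and sd and sd <= cfg.obs_sd_lat]
        lons = [v for c in obs.values() for k, v, _ in c if k == "lon"]
        if release is not None:
            lats.append(release[0])
            lons.append(release[1])
        if not lats or not lons:
            raise ValueError("cannot infer a grid extent; pass one explicitly")
        extent = (min(lats) - 6, max(lats) + 6, min(lons) - 6, max(lons) + 6)
    g_lat = np.arange(extent[0], extent[1] + grid_resolution_deg / 2, grid_resolution_deg)
    g_lon = np.arange(extent[2], extent[3] + grid_resolution_deg / 2, grid_resolution_deg)
    LAT, LON = np.meshgrid(g_lat, g_lon, indexing="ij")
    mid_lat = float(np.mean(g_lat))

    def likelihood(day):
        logl = np.zeros(LAT.shape)
        for kind, value, sd in obs[day]:
            if kind == "lat":
                logl += -0.5 * ((LAT - value) / sd) ** 2
            elif kind == "lon":
                logl += -0.5 * (_wrap_deg(LON - value) / sd) ** 2
            else:
                s = sd if sd is not None else cfg.obs_sd_sst
                vals = sst_field.value_at(day, LAT.ravel(), LON.ravel()).reshape(LAT.shape)
                logl += -0.5 * ((vals - value) / s) ** 2
        logl -= logl.max()
        return np.exp(logl)

    def blur(p, dt):
        s_lat = process_sigma_km * math.sqrt(dt) / _KM_PER_DEG / grid_resolution_deg
        s_lon = s_lat / max(math.cos(math.radians(mid_lat)), 0.2)
        return gaussian_filter(p, sigma=(s_lat, s_lon), mode="constant")

    Ls = [likelihood(d) for d in days]
    dts = [1.0] + [max((days[i] - days[i - 1]).days, 1) for i in range(1, len(days))]

    if release is not None:
        prior = np.zeros(LAT.shape)
        prior[
            int(np.argmin(np.abs(g_lat - release[0]))),
            int(np.argmin(np.abs(g_lon - release[1]))),
        ] = 1.0
    else:
        prior = np.ones(LAT.shape)
    alphas = []
    a = prior * Ls[0]
    if a.sum() == 0:
        a = prior.copy()
    a /= a.sum()
    alphas.append(a)
    for i in range(1, len(days)):
        a = blur(alphas[-1], dts[i]) * Ls[i]
        tot = a.sum()
        a = a / tot if tot > 0 else np.ones_like(a) / a.size
        alphas.append(a)

    betas = [None] * len(days)
    b = np.ones(LAT.shape)
    betas[-1] = b
    for i in range(len(days) - 2, -1, -1):
        b = blur(Ls[i + 1] * betas[i + 1], dts[i + 1])
        m = b.max()
        betas[i] = b / m if m > 0 else np.ones_like(b)

    rows = []
    for day, a, b in zip(days, alphas, betas):
        p = a * b
        p /= p.sum()
        mean_lat = float((p * LAT).sum())
        mean_lon = float((p * LON).sum())
        rows.append(
            {
                "date": day,
                "lat": mean_lat,
                "lon": mean_lon,
                "sd_lat": float(np.sqrt((p * (LAT - mean_lat) ** 2).sum())),
                "sd_lon": float(np.sqrt((p * (LON - mean_lon) ** 2).sum())),
            }
        )
    return Track(data=pd.DataFrame(rows), process_sigma_km=process_sigma_km)
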