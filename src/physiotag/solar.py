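"""Solar geometry used by the light-based geolocation template fit.

Declination and the equation of time are computed with the Spencer
truncated-Fourier series (the NOAA solar-calculator approximation), which is
accurate to roughly 0.2 degrees in declination and about a minute in the
equation of time -- far below the noise of a tag light sensor.  All inputs
are UTC; local apparent solar time is reconstructed from longitude only
(15 degrees per hour), never from civil time zones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "solar_position",
    "solar_declination_deg",
    "equation_of_time_min",
    "solar_elevation_deg",
    "day_length_hours",
    "day_length_from_declination",
    "equinox_instant",
]


def _as_index(when) -> pd.DatetimeIndex:
    arr = np.asarray(when)
    if arr.ndim == 0:
        arr = arr[None]
    return pd.DatetimeIndex(pd.to_datetime(arr))


def _fractional_year_rad(times: pd.DatetimeIndex) -> np.ndarray:
    doy = times.dayofyear.to_numpy(dtype=float)
    hours = (times - times.normalize()).total_seconds() / 3600.0
    return 2.0 * np.pi / 365.0 * (doy - 1.0 + (np.asarray(hours) - 12.0) / 24.0)


def solar_position(when):
    """Return ``(declination_deg, equation_of_time_min)`` for UTC time(s).

    Scalars in, scalars out; array-likes in, arrays out.  Declination is
    bounded by the obliquity (|delta| <= 23.45 deg); the equation of time
    stays within [-17, +17] minutes over the year.
    """
    times = _as_index(when)
    g = _fractional_year_rad(times)
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl_deg = np.degrees(decl)
    if np.ndim(when) == 0 and not isinstance(when, (list, tuple, np.ndarray, pd.Index)):
        return float(decl_deg[0]), float(eot[0])
    return decl_deg, eot


def solar_declination_deg(when):
    """Solar declination (degrees north) at UTC time(s) ``when``."""
    return solar_position(when)[0]


def equation_of_time_min(when):
    """Equation of time (apparent minus mean solar time, minutes)."""
    return solar_position(when)[1]


def solar_elevation_deg(when, lat_deg, lon_deg):
    """Solar elevation angle above the horizon, degrees.

    ``when`` is UTC; ``lat_deg``/``lon_deg`` may be scalars or arrays
    broadcastable against ``when``.  No atmospheric refraction is applied.
    """
    times = _as_index(when)
    decl, eot = solar_position(times.to_numpy())
    utc_min = np.asarray((times - times.normalize()).total_seconds()) / 60.0
    true_solar_min = utc_min + eot + 4.0 * np.asarray(lon_deg, dtype=float)
    hour_angle = np.radians(true_solar_min / 4.0 - 180.0)
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    d = np.radians(decl)
    sin_el = np.sin(lat) * np.sin(d) + np.cos(lat) * np.cos(d) * np.cos(hour_angle)
    el = np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    if el.ndim == 0 or (el.size == 1 and np.ndim(when) == 0):
        return float(np.ravel(el)[0])
    return el


def day_length_from_declination(
    lat_deg: float, declination_deg: float, sun_altitude_deg: float = 0.0
) -> float:
    """Day length (hours) from the sunrise equation at a given declination.

    Symmetric under ``(lat, decl) -> (-lat, -decl)``.  Polar day returns
    24.0 and polar night 0.0 rather than raising.
    """
    decl = np.radians(declination_deg)
    lat = np.radians(lat_deg)
    h0 = np.radians(sun_altitude_deg)
    cos_h = (np.sin(h0) - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    if cos_h <= -1.0:
        return 24.0
    if cos_h >= 1.0:
        return 0.0
    return float(2.0 * np.degrees(np.arccos(cos_h)) / 15.0)


def day_length_hours(lat_deg: float, when, sun_altitude_deg: float = 0.0) -> float:
    """Astronomical day length (hours) at a latitude and UTC instant.

    ``sun_altitude_deg`` is the solar elevation defining 'day' (0 for the
    geometric horizon, -6 for civil twilight).
    """
    return day_length_from_declination(
        lat_deg, solar_declination_deg(when), sun_altitude_deg
    )


def equinox_instant(year: int, month: int = 3) -> pd.Timestamp:
    """UTC instant in ``month`` (3 or 9) of ``year`` when declination crosses zero."""
    if month not in (3, 9):
        raise ValueError("equinoxes occur in March (3) or September (9)")
    lo = pd.Timestamp(year=year, month=month, day=10)
    hi = pd.Timestamp(year=year, month=month, day=30)

    def f(offset_days: float) -> float:
        return solar_declination_deg(lo + pd.Timedelta(days=float(offset_days)))

    root = brentq(f, 0.0, (hi - lo).days)
    return lo + pd.Timedelta(days=float(root))
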