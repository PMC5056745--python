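"""Independent solar-position oracle for cross-checking event times.

Deliberately a different algorithm from the package's closed-form
hour-angle route: Meeus-style low-accuracy ecliptic coordinates of the sun
(mean longitude + equation of centre, no equation-of-time shortcut),
converted to altitude via the Greenwich sidereal time, with the crossing
time located numerically by bracketed root-finding on the altitude curve.
"""

import numpy as np
import pandas as pd
from scipy.optimize import brentq


def _julian_day(t_utc: pd.Timestamp) -> float:
    return t_utc.to_julian_date()


def sun_altitude_deg(t_utc: pd.Timestamp, lat_deg: float, lon_deg: float) -> float:
    """Geometric solar altitude (degrees) at a UTC instant."""
    n = _julian_day(t_utc) - 2451545.0
    L = np.deg2rad((280.460 + 0.9856474 * n) % 360.0)        # mean longitude
    g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)        # mean anomaly
    lam = L + np.deg2rad(1.915) * np.sin(g) + np.deg2rad(0.020) * np.sin(2 * g)
    eps = np.deg2rad(23.439 - 0.0000004 * n)
    delta = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    gmst_deg = (280.46061837 + 360.98564736629 * n) % 360.0
    H = np.deg2rad(gmst_deg + lon_deg) - ra
    phi = np.deg2rad(lat_deg)
    sin_alt = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(H)
    return float(np.rad2deg(np.arcsin(np.clip(sin_alt, -1, 1))))


def crossing_times_local(lat_deg, lon_deg, date, altitude_deg, tz_hours=8.0):
    """(rise, set) local clock times where the sun crosses ``altitude_deg``.

    Scans the local day at 10-minute resolution and refines each sign change
    of altitude - threshold with brentq.  Returns None for a missing crossing.
    """
    day0 = pd.Timestamp(date).normalize() - pd.Timedelta(hours=tz_hours)  # UTC
    f = lambda mins: sun_altitude_deg(day0 + pd.Timedelta(minutes=mins),
                                      lat_deg, lon_deg) - altitude_deg
    grid = np.arange(0, 24 * 60 + 1, 10.0)
    vals = np.array([f(m) for m in grid])
    rise = sett = None
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va < 0 <= vb:
            rise = brentq(f, a, b, xtol=1e-3)
        elif va >= 0 > vb:
            sett = brentq(f, a, b, xtol=1e-3)
    to_local = lambda m: (day0 + pd.Timedelta(minutes=m)
                          + pd.Timedelta(hours=tz_hours)) if m is not None else None
    return to_local(rise), to_local(sett)
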