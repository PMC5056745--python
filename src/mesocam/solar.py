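"""Solar geometry, diel-period classification, and the sun-time transform.

Sunrise/sunset and astronomical-twilight times are computed with the standard
low-precision solar-position geometry (solar declination + equation of time +
hour angle)::

    cos H = (sin h0 - sin phi sin delta) / (cos phi cos delta)

which is accurate to about a minute at mid-latitudes — far below the
resolution of camera-trap timestamps.  Three short fixed-point iterations
refine the declination/equation-of-time at the event hour itself.

Clock times are local standard time (default UTC+8 for Southwest China, no
daylight saving).  Two altitude thresholds matter:

* ``-0.833`` degrees: geometric sunrise/sunset (refraction + solar radius);
* ``-18`` degrees: astronomical twilight, bounding the crepuscular periods.

The *sun-time* transform removes seasonal photoperiod variation by rescaling
each day so sunrise maps to 06:00 and sunset to 18:00; daylight hours are
stretched linearly between those anchors and night hours between 18:00 and
(next-day) 06:00.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mesocam.errors import MesocamError, SolarEventMissing

logger = logging.getLogger(__name__)

SUNRISE_ALTITUDE_DEG = -0.833
ASTRO_TWILIGHT_DEG = -18.0
DEFAULT_TZ_HOURS = 8.0

PERIODS = ("crepuscular", "diurnal", "nocturnal")


def _decl_eqtime(gamma: np.ndarray):
    """Solar declination (rad) and equation of time (min) from fractional year."""
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma) - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma) - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    return decl, eqtime


def _event_utc_minutes(latitude, longitude, doy, sun_altitude_deg, rising):
    """UTC minutes past midnight of the altitude crossing; NaN when absent.

    Vectorized over ``doy``/``latitude``/``longitude``.  ``rising`` selects the
    morning (True) or evening (False) crossing.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    h0 = np.deg2rad(sun_altitude_deg)
    lon = np.asarray(longitude, dtype=float)
    doy = np.asarray(doy, dtype=float)
    # start at local solar noon, then refine at the event hour
    utc_hour = 12.0 - lon / 15.0
    out = np.full(np.broadcast(lat, lon, doy).shape, np.nan)
    for _ in range(3):
        gamma = 2 * np.pi / 365.0 * (doy - 1 + (utc_hour - 12.0) / 24.0)
        decl, eqtime = _decl_eqtime(gamma)
        cos_h = (np.sin(h0) - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
        with np.errstate(invalid="ignore"):
            ha = np.rad2deg(np.arccos(np.clip(cos_h, -1.0, 1.0)))
        valid = np.abs(cos_h) <= 1.0
        signed = ha if rising else -ha
        minutes = 720.0 - 4.0 * (lon + signed) - eqtime
        out = np.where(valid, minutes, np.nan)
        utc_hour = np.where(valid, minutes / 60.0, utc_hour)
    return out


def solar_event_times(latitude: float, longitude: float, date,
                      sun_altitude_deg: float = SUNRISE_ALTITUDE_DEG,
                      tz_hours: float = DEFAULT_TZ_HOURS):
    """Local clock times of the rising and setting crossings of an altitude.

    Raises :class:`SolarEventMissing` when the sun never crosses
    ``sun_altitude_deg`` on ``date`` (polar day/night at high latitudes).
    """
    date = pd.Timestamp(date).normalize()
    doy = date.dayofyear
    rise = _event_utc_minutes(latitude, longitude, doy, sun_altitude_deg, True)
    sett = _event_utc_minutes(latitude, longitude, doy, sun_altitude_deg, False)
    if np.isnan(rise) or np.isnan(sett):
        raise SolarEventMissing(
            f"sun does not cross {sun_altitude_deg} deg at lat {latitude} on {date.date()}"
        )
    off = tz_hours * 60.0
    return (date + pd.Timedelta(minutes=float(rise) + off),
            date + pd.Timedelta(minutes=float(sett) + off))


@dataclass(frozen=True)
class DielSchedule:
    """The four diel anchors for one station-date (local clock time).

    ``dawn_start`` and ``dusk_end`` are the astronomical-twilight crossings
    (sun at -18 deg); ``sunrise``/``sunset`` at -0.833 deg.  The four periods
    partition the 24-h day: crepuscular = [dawn_start, sunrise) +
    [sunset, dusk_end); diurnal = [sunrise, sunset); nocturnal = remainder.
    """
    date: pd.Timestamp
    dawn_start: pd.Timestamp
    sunrise: pd.Timestamp
    sunset: pd.Timestamp
    dusk_end: pd.Timestamp
    station_id: str | None = None


def diel_schedule(latitude: float, longitude: float, date,
                  tz_hours: float = DEFAULT_TZ_HOURS,
                  twilight_deg: float = ASTRO_TWILIGHT_DEG,
                  horizon_deg: float = SUNRISE_ALTITUDE_DEG,
                  station_id: str | None = None) -> DielSchedule:
    """Compute the :class:`DielSchedule` for one station-date."""
    sunrise, sunset = solar_event_times(latitude, longitude, date, horizon_deg, tz_hours)
    dawn, dusk = solar_event_times(latitude, longitude, date, twilight_deg, tz_hours)
    return DielSchedule(pd.Timestamp(date).normalize(), dawn, sunrise, sunset, dusk,
                        station_id)


def classify_diel_period(t, schedule: DielSchedule) -> str:
    """Classify a clock time as crepuscular, diurnal, or nocturnal."""
    t = pd.Timestamp(t)
    s = schedule
    if s.sunrise <= t < s.sunset:
        return "diurnal"
    if s.dawn_start <= t < s.sunrise or s.sunset <= t < s.dusk_end:
        return "crepuscular"
    return "nocturnal"


def to_sun_time(t, schedule: DielSchedule,
                next_schedule: DielSchedule | None = None,
                prev_schedule: DielSchedule | None = None) -> float:
    """Transform a clock time to the relative sun-time hour in [0, 24).

    Sunrise maps to 06:00 and sunset to 18:00 exactly.  Daytime is stretched
    linearly between them; night-time linearly between 18:00 and next-day
    06:00 using the bracketing sunset and sunrise.  ``next_schedule`` is
    required for times after sunset, ``prev_schedule`` for times before
    sunrise (the previous night's tail).
    """
    t = pd.Timestamp(t)
    s = schedule
    if s.sunrise <= t < s.sunset:
        frac = (t - s.sunrise) / (s.sunset - s.sunrise)
        return 6.0 + 12.0 * float(frac)
    if t >= s.sunset:
        if next_schedule is None:
            raise MesocamError("next-day schedule required for post-sunset times")
        night = next_schedule.sunrise - s.sunset
        if night <= pd.Timedelta(0):
            raise MesocamError("zero-length night interval")
        frac = (t - s.sunset) / night
    else:  # before sunrise: previous night
        if prev_schedule is None:
            raise MesocamError("previous-day schedule required for pre-sunrise times")
        night = s.sunrise - prev_schedule.sunset
        if night <= pd.Timedelta(0):
            raise MesocamError("zero-length night interval")
        frac = (t - prev_schedule.sunset) / night
    return (18.0 + 12.0 * float(frac)) % 24.0


def from_sun_time(sun_hour: float, schedule: DielSchedule,
                  next_schedule: DielSchedule) -> pd.Timestamp:
    """Inverse sun-time map onto the cycle [sunrise, next sunrise).

    Sun-hours in [6, 18) land in this date's daylight; the rest land in the
    night interval [sunset, next sunrise).
    """
    s = float(sun_hour) % 24.0
    if 6.0 <= s < 18.0:
        return schedule.sunrise + (s - 6.0) / 12.0 * (schedule.sunset - schedule.sunrise)
    night_frac = ((s - 18.0) % 24.0) / 12.0
    return schedule.sunset + night_frac * (next_schedule.sunrise - schedule.sunset)


def schedules_for_dates(latitude: float, longitude: float, dates,
                        tz_hours: float = DEFAULT_TZ_HOURS) -> dict:
    """Map each date to its :class:`DielSchedule` (one solar fix per date)."""
    return {pd.Timestamp(d).normalize(): diel_schedule(latitude, longitude, d, tz_hours)
            for d in pd.DatetimeIndex(dates).normalize().unique()}


def sun_times_for_events(events: pd.DataFrame, deployments: pd.DataFrame,
                         tz_hours: float = DEFAULT_TZ_HOURS) -> pd.DataFrame:
    """Attach sun-time hours and diel periods to an event table.

    Uses each event's station coordinates (first matching deployment row).
    Returns a copy of ``events`` with ``sun_hour`` (float, [0, 24)) and
    ``period`` columns.
    """
    coords = (deployments.groupby("station_id")[["latitude", "longitude"]]
              .first().to_dict("index"))
    sun_hours = np.empty(len(events))
    periods = np.empty(len(events), dtype=object)
    cache: dict = {}

    def sched(lat, lon, day):
        key = (round(lat, 5), round(lon, 5), day)
        if key not in cache:
            cache[key] = diel_schedule(lat, lon, day, tz_hours)
        return cache[key]

    for k, ev in enumerate(events.itertuples(index=False)):
        c = coords[ev.station_id]
        t = pd.Timestamp(ev.event_time)
        day = t.normalize()
        s = sched(c["latitude"], c["longitude"], day)
        nxt = sched(c["latitude"], c["longitude"], day + pd.Timedelta(days=1))
        prv = sched(c["latitude"], c["longitude"], day - pd.Timedelta(days=1))
        sun_hours[k] = to_sun_time(t, s, nxt, prv)
        periods[k] = classify_diel_period(t, s)
    out = events.copy()
    out["sun_hour"] = sun_hours
    out["period"] = periods
    return out


@dataclass(frozen=True)
class AvailabilityVector:
    """Proportional availability of the three diel periods (sums to 1)."""
    crepuscular: float
    diurnal: float
    nocturnal: float

    def as_array(self) -> np.ndarray:
        return np.array([self.crepuscular, self.diurnal, self.nocturnal])

    def __post_init__(self):
        total = self.crepuscular + self.diurnal + self.nocturnal
        if not np.isclose(total, 1.0, atol=1e-9):
            raise MesocamError(f"availability must sum to 1, got {total}")


def _overlap_hours(a0, a1, b0, b1) -> float:
    lo, hi = max(a0, b0), min(a1, b1)
    return max((hi - lo) / pd.Timedelta(hours=1), 0.0)


def period_availability(deployments: pd.DataFrame,
                        tz_hours: float = DEFAULT_TZ_HOURS,
                        months=None) -> AvailabilityVector:
    """Diel-period availability summed over all active station-dates.

    For each deployment, each calendar date's active interval (clipped to the
    deployment's start/end) is intersected with that date's crepuscular,
    diurnal, and nocturnal windows; the three duration sums are normalized to
    proportions.  ``months`` optionally restricts to station-dates in those
    calendar months (e.g. the warm season Mar-Nov).
    """
    totals = np.zeros(3)  # crepuscular, diurnal, nocturnal
    cache: dict = {}
    for dep in deployments.itertuples(index=False):
        lat, lon = float(dep.latitude), float(dep.longitude)
        t0, t1 = pd.Timestamp(dep.start), pd.Timestamp(dep.end)
        for day in pd.date_range(t0.normalize(), (t1 - pd.Timedelta(nanoseconds=1)).normalize()):
            if months is not None and day.month not in months:
                continue
            key = (round(lat, 3), round(lon, 3), day)
            if key not in cache:
                cache[key] = diel_schedule(lat, lon, day, tz_hours)
            s = cache[key]
            a0, a1 = max(t0, day), min(t1, day + pd.Timedelta(days=1))
            crep = (_overlap_hours(a0, a1, s.dawn_start, s.sunrise)
                    + _overlap_hours(a0, a1, s.sunset, s.dusk_end))
            diur = _overlap_hours(a0, a1, s.sunrise, s.sunset)
            active = (a1 - a0) / pd.Timedelta(hours=1)
            totals += [crep, diur, active - crep - diur]
    if totals.sum() <= 0:
        raise MesocamError("no active station-dates; availability undefined")
    p = totals / totals.sum()
    return AvailabilityVector(*p)
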