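"""Solar and lunar ephemeris utilities for classifying camera-trap detections.

Night-time activity analysis needs two astronomical quantities per detection:
whether the timestamp falls between dusk and dawn, and the illuminated fraction
of the lunar disc. Both are computed from standard low-precision algorithms —
the NOAA solar-position equations for sun altitude and twilight times, and
simplified ecliptic lunar/solar longitudes for the moon phase. Accuracy is
about ±2 minutes for twilight times and ±0.02 for the lunar fraction, which is
ample for day/night labelling and a [0, 1] illumination covariate.

Dawn and dusk default to civil twilight (sun altitude −6°), the convention of
the suncalc family of tools; pass ``twilight_deg=-0.833`` for sunrise/sunset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta, timezone

__all__ = ["SunTimes", "sun_times", "is_night", "lunar_fraction"]

#: Default sun altitude (degrees) defining dawn/dusk: civil twilight.
CIVIL_TWILIGHT_DEG = -6.0

#: Study-area default timezone offset (East Africa Time).
DEFAULT_TZ_OFFSET_HOURS = 3.0

_MAX_LATITUDE = 66.0


@dataclass(frozen=True)
class SunTimes:
    """Dawn and dusk instants (UTC) for one local calendar date."""

    date: date
    dawn: datetime
    dusk: datetime
    latitude: float
    longitude: float
    twilight_deg: float = CIVIL_TWILIGHT_DEG


def _to_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


def _fractional_year(t: datetime) -> float:
    """NOAA fractional year gamma in radians."""
    doy = t.timetuple().tm_yday
    leap = 366 if t.year % 4 == 0 and (t.year % 100 != 0 or t.year % 400 == 0) else 365
    return 2.0 * math.pi / leap * (doy - 1 + (t.hour - 12) / 24.0)


def _equation_of_time_min(gamma: float) -> float:
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )


def _solar_declination_rad(gamma: float) -> float:
    return (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )


def sun_times(
    day: date,
    lat: float,
    lon: float,
    twilight_deg: float = CIVIL_TWILIGHT_DEG,
) -> SunTimes:
    """Dawn and dusk (UTC) for a calendar date at planar coordinates.

    Parameters
    ----------
    day
        Calendar date (interpreted as the local day at ``lon``).
    lat, lon
        Geographic coordinates in degrees; east and north positive.
    twilight_deg
        Sun altitude defining dawn/dusk. −6° (civil twilight) by default.

    Raises
    ------
    ValueError
        For polar latitudes (|lat| ≥ 66°), where twilight may not occur.
    """
    if abs(lat) >= _MAX_LATITUDE:
        raise ValueError(
            f"latitude {lat} is polar (|lat| >= {_MAX_LATITUDE}); "
            "twilight times are not defined year-round there"
        )
    noon_guess = datetime.combine(day, time(12), tzinfo=timezone.utc)
    gamma = _fractional_year(noon_guess)
    eqtime = _equation_of_time_min(gamma)
    decl = _solar_declination_rad(gamma)

    lat_r = math.radians(lat)
    h0 = math.radians(twilight_deg)
    cos_ha = (math.sin(h0) - math.sin(lat_r) * math.sin(decl)) / (
        math.cos(lat_r) * math.cos(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha_min = math.degrees(math.acos(cos_ha)) * 4.0  # hour angle in minutes

    solar_noon_min = 720.0 - 4.0 * lon - eqtime  # minutes after UTC midnight
    midnight = datetime.combine(day, time(0), tzinfo=timezone.utc)
    dawn = midnight + timedelta(minutes=solar_noon_min - ha_min)
    dusk = midnight + timedelta(minutes=solar_noon_min + ha_min)
    return SunTimes(day, dawn, dusk, lat, lon, twilight_deg)


def is_night(
    timestamp: datetime,
    lat: float,
    lon: float,
    twilight_deg: float = CIVIL_TWILIGHT_DEG,
    timezone_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> bool:
    """True iff the instant is after dusk or before dawn of its local day.

    The boundary instants themselves (exactly dawn, exactly dusk) count as
    day: night is strictly after dusk and strictly before dawn.
    """
    t = _to_utc(timestamp)
    local_day = (t + timedelta(hours=timezone_offset_hours)).date()
    st = sun_times(local_day, lat, lon, twilight_deg)
    return t < st.dawn or t > st.dusk


_J2000 = datetime(2000, 1, 1, 12, tzinfo=timezone.utc)


def _days_since_j2000(t: datetime) -> float:
    return (_to_utc(t) - _J2000).total_seconds() / 86400.0


def _sun_ecliptic(d: float) -> tuple[float, float]:
    """Sun geocentric ecliptic longitude (rad) and distance (km)."""
    m = math.radians((357.5291 + 0.98560028 * d) % 360.0)
    c = (
        1.9148 * math.sin(m)
        + 0.02 * math.sin(2 * m)
        + 0.0003 * math.sin(3 * m)
    )
    # 282.9372 = argument of perihelion (102.9372 deg) + 180 deg
    lon = math.radians((math.degrees(m) + c + 282.9372) % 360.0)
    dist = 149598000.0 * (1.000001018 * (1 - 0.0167**2)) / (1 + 0.0167 * math.cos(m))
    return lon, dist


def _moon_ecliptic(d: float) -> tuple[float, float, float]:
    """Moon ecliptic longitude, latitude (rad) and distance (km).

    Truncated lunar theory: evection, variation and the annual equation are
    folded into the three largest longitude terms, which keeps the phase
    angle good to ~1°.
    """
    L = math.radians((218.316 + 13.176396 * d) % 360.0)  # mean longitude
    M = math.radians((134.963 + 13.064993 * d) % 360.0)  # mean anomaly
    F = math.radians((93.272 + 13.229350 * d) % 360.0)  # argument of latitude
    D = math.radians((297.850 + 12.190749 * d) % 360.0)  # mean elongation

    lon = L + math.radians(
        6.289 * math.sin(M)
        - 1.274 * math.sin(M - 2 * D)
        + 0.658 * math.sin(2 * D)
        - 0.186 * math.sin(math.radians((357.5291 + 0.98560028 * d) % 360.0))
    )
    lat = math.radians(5.128 * math.sin(F))
    dist = 385001.0 - 20905.0 * math.cos(M)
    return lon, lat, dist


def lunar_fraction(timestamp: datetime) -> float:
    """Illuminated fraction of the lunar disc in [0, 1].

    Uses the phase angle between sun and moon as seen from Earth:
    ``fraction = (1 + cos(phase_angle)) / 2``. Accuracy about ±0.02.

    Raises
    ------
    ValueError
        For timestamps outside 1900–2100, where the truncated series degrade.
    """
    t = _to_utc(timestamp)
    if not (1900 <= t.year <= 2100):
        raise ValueError(f"timestamp year {t.year} outside supported range 1900-2100")
    d = _days_since_j2000(t)
    slon, sdist = _sun_ecliptic(d)
    mlon, mlat, mdist = _moon_ecliptic(d)

    # geocentric elongation of the moon from the sun
    phi = math.acos(
        min(1.0, max(-1.0, math.cos(mlat) * math.cos(mlon - slon)))
    )
    # phase angle (selenocentric sun-earth angle)
    inc = math.atan2(sdist * math.sin(phi), mdist - sdist * math.cos(phi))
    return (1.0 + math.cos(inc)) / 2.0
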