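"""Solar position (NOAA algorithm) and the dataset's fixed-offset clock.

The deposited product timestamps are US Central Standard Time held fixed at
UTC-6 year-round (no daylight saving), so a single tzinfo constant is used
throughout instead of a zoneinfo lookup.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

__all__ = ["CST", "solar_zenith_deg", "solar_position"]

#: US Central Standard Time, fixed UTC-6 (no DST).
CST = timezone(timedelta(hours=-6), name="CST")


def _julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = (
        dt_utc.day
        + (dt_utc.hour + dt_utc.minute / 60.0 + dt_utc.second / 3600.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def solar_position(when: datetime, latitude: float, longitude: float) -> tuple[float, float]:
    """Solar zenith and azimuth (degrees) via the NOAA low-accuracy ephemeris.

    ``when`` must be timezone-aware; ``longitude`` positive east.  Accuracy is
    a few hundredths of a degree, ample for daytime masks and diurnal scaling.
    """
    if when.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    dt_utc = when.astimezone(timezone.utc)
    jd = _julian_day(dt_utc)
    t = (jd - 2451545.0) / 36525.0  # Julian centuries from J2000

    # geometric mean longitude / anomaly (deg)
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = math.radians(m)
    # equation of center, sun true longitude
    c = (
        math.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    # obliquity (corrected)
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(math.radians(omega))

    # declination
    decl = math.degrees(
        math.asin(math.sin(math.radians(eps)) * math.sin(math.radians(app_long)))
    )

    # equation of time (minutes)
    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mr)
        + 4 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )

    minutes_utc = dt_utc.hour * 60.0 + dt_utc.minute + dt_utc.second / 60.0
    true_solar_min = (minutes_utc + eot + 4.0 * longitude) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0
    if hour_angle < -180.0:
        hour_angle += 360.0

    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    ha_r = math.radians(hour_angle)
    cos_zen = math.sin(lat_r) * math.sin(decl_r) + math.cos(lat_r) * math.cos(decl_r) * math.cos(ha_r)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zenith = math.degrees(math.acos(cos_zen))

    # azimuth, clockwise from north
    denom = math.cos(lat_r) * math.sin(math.radians(zenith))
    if abs(denom) > 1e-12:
        cos_az = (math.sin(lat_r) * cos_zen - math.sin(decl_r)) / denom
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.degrees(math.acos(cos_az))
        azimuth = (az + 180.0) % 360.0 if hour_angle > 0 else (180.0 - az) % 360.0
    else:
        azimuth = 0.0
    return zenith, azimuth


def solar_zenith_deg(when: datetime, latitude: float, longitude: float) -> float:
    """Solar zenith angle in degrees (0 = overhead, >= 90 = sun below horizon)."""
    return solar_position(when, latitude, longitude)[0]
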