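"""Geographic primitives: DMS parsing, flat-earth distances, sound speed.

Distances between nearby points (recorder arrays span at most a few km) are
computed with the equirectangular ("flat-earth") approximation: longitude
differences are scaled by the cosine of the mean latitude, latitude
differences map directly to arc length, and Pythagoras does the rest on a
sphere of mean radius 6,371,000 m. At sub-5-km separations this agrees with
great-circle distance to well under 0.1%.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "EARTH_RADIUS_M",
    "GeoPoint",
    "EarthModel",
    "DMSParseError",
    "parse_dms",
    "format_dms",
    "parse_coordinate",
    "flat_earth_distance",
    "local_offset_m",
    "offset_point",
    "speed_of_sound",
]

EARTH_RADIUS_M = 6_371_000.0


class DMSParseError(ValueError):
    """A coordinate string could not be interpreted as D°M′S.ss″ H."""


@dataclass(frozen=True)
class EarthModel:
    """Spherical earth with a fixed mean radius in meters."""

    radius_m: float = EARTH_RADIUS_M

    def __post_init__(self) -> None:
        if not self.radius_m > 0:
            raise ValueError(f"earth radius must be positive, got {self.radius_m}")


@dataclass(frozen=True)
class GeoPoint:
    """A position in decimal degrees (lat north-positive, lon east-positive)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


# Degree/minute/second marks appear in ASCII and several Unicode variants
# depending on who typed the coordinate table.
_DEG = "°ºo"
_MIN = "'′´’"
_SEC = "\"″”"
_DMS_RE = re.compile(
    rf"""^\s*
    (?P<deg>\d+(?:\.\d+)?)\s*[{_DEG}]\s*
    (?:(?P<min>\d+(?:\.\d+)?)\s*[{_MIN}]\s*)?
    (?:(?P<sec>\d+(?:\.\d+)?)\s*[{_SEC}]\s*)?
    (?P<hemi>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_dms(text: str) -> float:
    """Parse a degrees-minutes-seconds string like ``35°39′38.12″ N``.

    Returns decimal degrees, negative for S/W hemispheres. Minutes and
    seconds must be < 60.
    """
    m = _DMS_RE.match(text)
    if m is None:
        raise DMSParseError(f"unrecognized DMS coordinate: {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or 0.0)
    if minutes >= 60.0:
        raise DMSParseError(f"minutes field {minutes} >= 60 in {text!r}")
    if seconds >= 60.0:
        raise DMSParseError(f"seconds field {seconds} >= 60 in {text!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    hemi = (m.group("hemi") or "N").upper()
    if hemi in "SW":
        value = -value
    return value


def format_dms(value: float, axis: str = "lat", sec_decimals: int = 2) -> str:
    """Format decimal degrees as ``D°M′S.ss″ H`` (inverse of :func:`parse_dms`)."""
    if axis not in ("lat", "lon"):
        raise ValueError("axis must be 'lat' or 'lon'")
    hemi = ("N", "S") if axis == "lat" else ("E", "W")
    h = hemi[0] if value >= 0 else hemi[1]
    mag = abs(value)
    deg = int(mag)
    rem = (mag - deg) * 60.0
    minutes = int(rem)
    seconds = round((rem - minutes) * 60.0, sec_decimals)
    if seconds >= 60.0:  # carry after rounding
        seconds -= 60.0
        minutes += 1
    if minutes >= 60:
        minutes -= 60
        deg += 1
    return f"{deg}°{minutes}′{seconds:.{sec_decimals}f}″ {h}"


def parse_coordinate(cell: str | float) -> float:
    """Interpret a table cell as either decimal degrees or a DMS string."""
    if isinstance(cell, (int, float)):
        return float(cell)
    text = cell.strip()
    try:
        return float(text)
    except ValueError:
        return parse_dms(text)


def flat_earth_distance(
    p1: GeoPoint, p2: GeoPoint, earth: EarthModel = EarthModel()
) -> float:
    """Equirectangular distance in meters between two nearby points.

    d = R * sqrt(x^2 + y^2) with
    x = dlon_rad * cos(mean latitude), y = dlat_rad.

    Note: the latitude term uses the *difference* of the two latitudes; the
    mean latitude enters only through the cosine scaling of the longitude
    difference.
    """
    x = math.radians(p2.lon - p1.lon) * math.cos(math.radians((p1.lat + p2.lat) / 2.0))
    y = math.radians(p2.lat - p1.lat)
    return earth.radius_m * math.hypot(x, y)


def local_offset_m(
    origin: GeoPoint, p: GeoPoint, earth: EarthModel = EarthModel()
) -> tuple[float, float]:
    """(east, north) displacement in meters of ``p`` relative to ``origin``.

    Uses the origin latitude for the longitude scaling, i.e. a local
    tangent-plane frame anchored at ``origin``; exact inverse of
    :func:`offset_point`.
    """
    east = (
        math.radians(p.lon - origin.lon)
        * math.cos(math.radians(origin.lat))
        * earth.radius_m
    )
    north = math.radians(p.lat - origin.lat) * earth.radius_m
    return east, north


def offset_point(
    origin: GeoPoint, east_m: float, north_m: float, earth: EarthModel = EarthModel()
) -> GeoPoint:
    """Point displaced by (east, north) meters from ``origin``."""
    lat = origin.lat + math.degrees(north_m / earth.radius_m)
    lon = origin.lon + math.degrees(
        east_m / (earth.radius_m * math.cos(math.radians(origin.lat)))
    )
    return GeoPoint(lat, lon)


def speed_of_sound(temp_c: float) -> float:
    """Speed of sound in dry air, m/s, from air temperature in Celsius.

    Linear approximation v = 331.2 + 0.606*T, valid for ordinary surface
    temperatures; anchors at 331.2 m/s (0 C) and ~343 m/s (20 C). An
    explicitly supplied speed elsewhere in the pipeline always takes
    precedence over this model.
    """
    if not (-40.0 <= temp_c <= 50.0):
        raise ValueError(f"temperature {temp_c} C outside plausible band [-40, 50]")
    return 331.2 + 0.606 * temp_c
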