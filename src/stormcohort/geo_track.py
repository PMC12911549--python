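"""Storm best-track handling: parsing, densification, closest approach.

A hurricane best track is the post-season authoritative record of the storm
center's position, typically at 6-hour resolution (HURDAT2).  Exposure windows
are anchored to the *closest approach* of the storm center to each small-area
centroid, so the track is first densified to a fixed sub-hourly step (default
15 minutes) by piecewise-linear interpolation of latitude and longitude
against time, and the minimum great-circle distance over the densified track
is then recorded together with its timestamp.

Longitudes are kept in [-180, 180] with no antimeridian handling (Gulf-of-
Mexico scope); a track whose longitudes span more than 180 degrees is
rejected rather than silently mis-interpolated.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Default local-time offset from UTC for calendar-day alignment (hours).
#: Central Standard Time, the study region's local standard time.
DEFAULT_UTC_OFFSET_HOURS = -6.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Vectorized over numpy arrays; symmetric and nonnegative.  Raises
    :class:`ValidationError` for coordinates outside WGS84 bounds.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(v, dtype=float) for v in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValidationError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValidationError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class ClosestApproach:
    """Minimum storm-center distance for one area and when it occurred."""

    area_id: object
    distance_km: float
    approach_time: pd.Timestamp
    approach_date: dt.date


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    """Check a track table (timestamp, lat, lon) and return it time-sorted-as-given.

    Requires >=2 fixes, strictly increasing timestamps, coordinates in bounds,
    and a longitude span that does not straddle the antimeridian.
    """
    required = {"timestamp", "lat", "lon"}
    if not required.issubset(track.columns):
        raise ValidationError(f"track must have columns {sorted(required)}")
    if len(track) < 2:
        raise ValidationError("track needs at least 2 fixes")
    ts = pd.to_datetime(track["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValidationError("track timestamps must be strictly increasing")
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValidationError("track coordinates out of bounds")
    if lon.max() - lon.min() > 180.0:
        raise ValidationError("track spans the antimeridian; not supported")
    out = track.copy()
    out["timestamp"] = ts
    return out


def read_track(path, fmt: str = "csv") -> pd.DataFrame:
    """Read a storm track.

    ``fmt='csv'`` expects columns (timestamp ISO-8601, lat, lon).
    ``fmt='hurdat2'`` parses the HURDAT2 data-line dialect: date ``YYYYMMDD``,
    time ``HHMM``, latitude ``dd.dN``/``dd.dS``, longitude ``ddd.dW``/``ddd.dE``
    in columns 1, 2, 5, 6 of each comma-separated data row.
    """
    if fmt == "csv":
        df = pd.read_csv(path)
        return validate_track(df)
    if fmt == "hurdat2":
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = [p.strip() for p in line.strip().split(",")]
                if len(parts) < 7 or not parts[0].isdigit():
                    continue  # header line of a storm block
                date, time = parts[0], parts[1]
                ts = pd.Timestamp(
                    f"{date[:4]}-{date[4:6]}-{date[6:8]} {time[:2]}:{time[2:4]}"
                )
                rows.append(
                    {
                        "timestamp": ts,
                        "lat": _parse_hemi(parts[4], "N", "S"),
                        "lon": _parse_hemi(parts[5], "E", "W"),
                    }
                )
        return validate_track(pd.DataFrame(rows))
    raise ValidationError(f"unknown track format {fmt!r}")


def _parse_hemi(token: str, pos: str, neg: str) -> float:
    token = token.strip()
    suffix = token[-1].upper()
    value = float(token[:-1])
    if suffix == pos:
        return value
    if suffix == neg:
        return -value
    raise ValidationError(f"bad hemisphere suffix in {token!r}")


def interpolate_track(track: pd.DataFrame, step_minutes: int = 15) -> pd.DataFrame:
    """Densify a track to a fixed time step by linear interpolation.

    Returns a DataFrame (timestamp, lat, lon) whose grid starts at the first
    fix with floor(span/step)+1 points; when the span divides evenly the final
    grid point coincides with the last source fix, otherwise the last source
    fix is appended so both endpoints are always preserved.  The source step
    is recorded in ``DataFrame.attrs['step_minutes']``.
    """
    track = validate_track(track)
    if step_minutes <= 0:
        raise ValidationError("step_minutes must be positive")
    t = track["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64")
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    step_ns = int(step_minutes) * 60 * 1_000_000_000
    span = t[-1] - t[0]
    n_pts = int(span // step_ns) + 1
    grid = t[0] + step_ns * np.arange(n_pts, dtype="int64")
    if grid[-1] != t[-1]:
        grid = np.append(grid, t[-1])
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(grid),
            "lat": np.interp(grid, t, lat),
            "lon": np.interp(grid, t, lon),
        }
    )
    out.attrs["step_minutes"] = int(step_minutes)
    return out


def closest_approach(
    itrack: pd.DataFrame,
    lat: float,
    lon: float,
    area_id,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> ClosestApproach:
    """Minimum-distance point of a (densified) track to one centroid.

    Ties in distance are broken by the earliest timestamp.  The approach
    *date* is the calendar date of the approach time shifted by
    ``utc_offset_hours`` (daily rain gauges report local days, and the
    exposure window is defined in calendar days).
    """
    if len(itrack) == 0:
        raise ValidationError("empty track")
    d = haversine_km(lat, lon, itrack["lat"].to_numpy(), itrack["lon"].to_numpy())
    i = int(np.argmin(d))  # argmin returns the first (earliest) minimum
    when = pd.Timestamp(itrack["timestamp"].iloc[i])
    local = when + pd.Timedelta(hours=utc_offset_hours)
    return ClosestApproach(
        area_id=area_id,
        distance_km=float(d[i]),
        approach_time=when,
        approach_date=local.date(),
    )


def closest_approach_table(
    itrack: pd.DataFrame,
    areas: pd.DataFrame,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS,
) -> pd.DataFrame:
    """Closest approach for every row of an areas table (area_id, lat, lon)."""
    records = [
        closest_approach(itrack, row.lat, row.lon, row.area_id, utc_offset_hours)
        for row in areas.itertuples()
    ]
    return pd.DataFrame(
        {
            "area_id": [r.area_id for r in records],
            "distance_km": [r.distance_km for r in records],
            "approach_time": [r.approach_time for r in records],
            "approach_date": [r.approach_date for r in records],
        }
    )
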