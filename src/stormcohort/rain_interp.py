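"""Inverse-distance-weighted rainfall interpolation at area centroids.

Daily station precipitation (GHCN-Daily style) is interpolated to each area
centroid as a convex combination of in-radius station values with weights
d^(-power).  Stations with a missing value on a date contribute nothing that
day (GHCN missingness is not zero rain).  If fewer than ``min_stations``
stations fall inside the search radius, the radius doubles until satisfied,
bounded by ``max_radius_km``; a station within 1 m of the centroid short-
circuits to its own value.  Cumulative exposure rain is the sum over the
4-day window anchored at the closest approach: 2 days before through 1 day
after.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError
from .geo_track import haversine_km

#: Default IDW settings, chosen for Gulf-region gauge densities.
IDW_POWER = 2.0
IDW_RADIUS_KM = 150.0
IDW_MIN_STATIONS = 3
IDW_MAX_RADIUS_KM = 600.0

#: A station closer than this to the centroid is used directly.
COLOCATION_KM = 0.001

#: Exposure window in days relative to the approach date (inclusive).
WINDOW_OFFSETS = (-2, 1)


def read_stations(path) -> pd.DataFrame:
    """Station table CSV: station_id, lat, lon. Ids must be unique."""
    df = pd.read_csv(path)
    return validate_stations(df)


def validate_stations(df: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "lat", "lon"}
    if not required.issubset(df.columns):
        raise ValidationError(f"stations must have columns {sorted(required)}")
    if df["station_id"].duplicated().any():
        raise ValidationError("duplicate station ids")
    if np.any(np.abs(df["lat"]) > 90) or np.any(np.abs(df["lon"]) > 180):
        raise ValidationError("station coordinates out of bounds")
    return df


def read_daily_rain(path, ghcn_tenths: bool = False) -> pd.DataFrame:
    """Daily precipitation CSV: station_id, date (ISO-8601), precip_mm.

    With ``ghcn_tenths=True`` values are read in the GHCN-Daily convention of
    tenths of millimetres and divided by 10.  Missing values stay NaN.
    """
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if ghcn_tenths:
        df = df.assign(precip_mm=df["precip_mm"] / 10.0)
    return validate_daily_rain(df)


def validate_daily_rain(df: pd.DataFrame) -> pd.DataFrame:
    required = {"station_id", "date", "precip_mm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"daily rain must have columns {sorted(required)}")
    if df.duplicated(subset=["station_id", "date"]).any():
        raise ValidationError("more than one record per station-date")
    vals = df["precip_mm"].to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValidationError("negative precipitation")
    return df


def idw_estimate(
    centroid,
    date,
    stations: pd.DataFrame,
    daily_rain: pd.DataFrame,
    power: float = IDW_POWER,
    radius_km: float = IDW_RADIUS_KM,
    min_stations: int = IDW_MIN_STATIONS,
    max_radius_km: float = IDW_MAX_RADIUS_KM,
) -> float:
    """IDW precipitation estimate (mm) at ``centroid=(lat, lon)`` for one date."""
    if power <= 0:
        raise ValidationError("IDW power must be positive")
    lat, lon = centroid
    day = daily_rain[daily_rain["date"] == _as_date(date)]
    day = day[day["precip_mm"].notna()]
    if day.empty:
        raise MissingDataError(f"no station reports anywhere on {date}")
    merged = day.merge(stations, on="station_id", how="inner")
    d = haversine_km(lat, lon, merged["lat"].to_numpy(), merged["lon"].to_numpy())
    values = merged["precip_mm"].to_numpy(dtype=float)
    return _idw_from_distances(d, values, power, radius_km, min_stations, max_radius_km)


def _idw_from_distances(d, values, power, radius_km, min_stations, max_radius_km):
    near = d < COLOCATION_KM
    if near.any():
        return float(values[np.argmin(d)])
    radius = float(radius_km)
    while (d <= radius).sum() < min_stations and radius < max_radius_km:
        radius = min(radius * 2.0, max_radius_km)
    inside = d <= radius
    if not inside.any():
        raise MissingDataError(
            f"no reporting station within {max_radius_km:g} km of centroid"
        )
    w = d[inside] ** (-power)
    return float(np.sum(w * values[inside]) / np.sum(w))


def centroid_rain_series(
    areas: pd.DataFrame,
    stations: pd.DataFrame,
    daily_rain: pd.DataFrame,
    dates=None,
    **idw_kwargs,
) -> pd.DataFrame:
    """Estimate daily rain at every area centroid.

    Returns long-format (area_id, date, precip_mm_est).  ``dates`` defaults to
    all dates present in ``daily_rain``.  The station-to-centroid distance
    matrix is computed once; per-date work is a masked weighted sum.
    """
    stations = validate_stations(stations)
    daily_rain = validate_daily_rain(daily_rain)
    if dates is None:
        dates = sorted(daily_rain["date"].unique())
    dates = [_as_date(x) for x in dates]
    power = idw_kwargs.get("power", IDW_POWER)
    radius_km = idw_kwargs.get("radius_km", IDW_RADIUS_KM)
    min_stations = idw_kwargs.get("min_stations", IDW_MIN_STATIONS)
    max_radius_km = idw_kwargs.get("max_radius_km", IDW_MAX_RADIUS_KM)

    sid = stations["station_id"].to_numpy()
    order = {s: i for i, s in enumerate(sid)}
    dist = haversine_km(
        areas["lat"].to_numpy()[:, None],
        areas["lon"].to_numpy()[:, None],
        stations["lat"].to_numpy()[None, :],
        stations["lon"].to_numpy()[None, :],
    )
    by_date = {d: g for d, g in daily_rain.groupby("date")}
    rows = []
    for date in dates:
        g = by_date.get(date)
        if g is not None:
            g = g[g["precip_mm"].notna()]
        if g is None or g.empty:
            raise MissingDataError(f"no station reports anywhere on {date}")
        cols = np.array([order[s] for s in g["station_id"]])
        vals = g["precip_mm"].to_numpy(dtype=float)
        for ai, area_id in enumerate(areas["area_id"]):
            est = _idw_from_distances(
                dist[ai, cols], vals, power, radius_km, min_stations, max_radius_km
            )
            rows.append((area_id, date, est))
    return pd.DataFrame(rows, columns=["area_id", "date", "precip_mm_est"])


def window_rain(series, approach_date, offsets=WINDOW_OFFSETS) -> float:
    """Cumulative rain (mm) over the approach-anchored window.

    ``series`` maps date -> estimated mm (a dict, a pandas Series indexed by
    date, or a long DataFrame with ``date``/``precip_mm_est`` columns for a
    single area).  The window is ``approach_date + offsets[0]`` through
    ``approach_date + offsets[1]`` inclusive; any missing day raises
    :class:`MissingDataError` naming the absent dates.
    """
    if isinstance(series, pd.DataFrame):
        series = series.set_index("date")["precip_mm_est"]
    if isinstance(series, pd.Series):
        series = series.to_dict()
    day0 = _as_date(approach_date)
    wanted = [day0 + dt.timedelta(days=k) for k in range(offsets[0], offsets[1] + 1)]
    missing = [d.isoformat() for d in wanted if d not in series]
    if missing:
        raise MissingDataError(f"window days missing: {', '.join(missing)}")
    return float(sum(series[d] for d in wanted))


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()
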