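"""High-rain exposure classification per small area.

An area is *exposed* when its cumulative centroid rainfall over the 4-day
window (2 days before through 1 day after the storm's closest approach)
strictly exceeds the threshold, default 75 mm (about 3 in).  Exposure is
rain-only: distance to the storm track enters only through the timing of the
window, never as a cap, though an optional maximum-distance cap is available
for users following other conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geo_track, rain_interp
from .errors import ValidationError

#: Rain threshold defining high-rain exposure (mm over the 4-day window).
THRESHOLD_MM = 75.0

MM_PER_INCH = 25.4


def classify_exposure(cumulative_mm: float, threshold_mm: float = THRESHOLD_MM) -> bool:
    """True iff cumulative rain strictly exceeds the threshold."""
    if np.any(np.asarray(cumulative_mm) < 0):
        raise ValidationError("cumulative rain must be nonnegative")
    return bool(np.asarray(cumulative_mm) > threshold_mm) if np.isscalar(cumulative_mm) \
        else np.asarray(cumulative_mm) > threshold_mm


def build_exposure_table(
    areas: pd.DataFrame,
    stations: pd.DataFrame,
    daily_rain: pd.DataFrame,
    track: pd.DataFrame,
    *,
    step_minutes: int = 15,
    threshold_mm: float = THRESHOLD_MM,
    window_offsets=rain_interp.WINDOW_OFFSETS,
    utc_offset_hours: float = geo_track.DEFAULT_UTC_OFFSET_HOURS,
    max_distance_km: float | None = None,
    **idw_kwargs,
) -> pd.DataFrame:
    """Run the full exposure pipeline for every area.

    Interpolates the track, finds each centroid's closest approach, IDW-
    estimates daily rain at the centroid for the window days, accumulates
    the window, and classifies.  Returns one row per area with columns
    (area_id, cumulative_mm, cumulative_in, distance_km, approach_time,
    approach_date, exposed).  Deterministic given inputs and settings.
    """
    itrack = geo_track.interpolate_track(track, step_minutes=step_minutes)
    approaches = geo_track.closest_approach_table(itrack, areas, utc_offset_hours)

    # union of all window days actually needed
    import datetime as dt

    needed = set()
    for d in approaches["approach_date"]:
        for k in range(window_offsets[0], window_offsets[1] + 1):
            needed.add(d + dt.timedelta(days=k))
    series = rain_interp.centroid_rain_series(
        areas, stations, daily_rain, dates=sorted(needed), **idw_kwargs
    )
    by_area = {a: g.set_index("date")["precip_mm_est"] for a, g in series.groupby("area_id")}

    cumulative = []
    for row in approaches.itertuples():
        cumulative.append(
            rain_interp.window_rain(by_area[row.area_id], row.approach_date, window_offsets)
        )
    cumulative = np.asarray(cumulative)
    exposed = cumulative > threshold_mm
    if max_distance_km is not None:
        exposed &= approaches["distance_km"].to_numpy() <= max_distance_km
    out = approaches.copy()
    out.insert(1, "cumulative_mm", cumulative)
    # inches reported at 1 decimal, round-half-even
    out.insert(2, "cumulative_in", np.round(cumulative / MM_PER_INCH, 1))
    out["exposed"] = exposed
    return out


def exposure_rain_summary(exposure_table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of cumulative rain (inches) by exposure status."""
    rows = []
    for flag, g in exposure_table.groupby("exposed"):
        inches = g["cumulative_mm"] / MM_PER_INCH
        q1, med, q3 = inches.quantile([0.25, 0.5, 0.75])
        rows.append(
            {
                "exposed": bool(flag),
                "n_areas": len(g),
                "median_in": med,
                "iqr_low_in": q1,
                "iqr_high_in": q3,
            }
        )
    return pd.DataFrame(rows)
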