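"""Synthetic study generator: storm, station rainfall, areas, cohort, mortality.

Everything downstream of this module is testable without restricted claims
data because the generator produces all four pipeline inputs with the
statistical structure the analysis assumes:

* a smooth storm track crossing the synthetic region (quadratic Bezier
  between the configured endpoints, seeded curvature), 6-hourly fixes;
* station-day rainfall = (background + peak * exp(-d/decay_scale)) * noise,
  where d is the station's distance to the track positions of that local
  calendar day and the noise is mean-one gamma with configured coefficient
  of variation — no storm fixes that day means background only;
* a beneficiary cohort with configured covariate marginals, clustered in
  areas, and an exponential proportional-hazards mortality process with a
  known exposure log-HR and log-normal area frailty, censored at one year.

The generator is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cohort_mod
from . import exposure as exposure_mod
from .config import SimConfig
from .errors import ValidationError
from .geo_track import DEFAULT_UTC_OFFSET_HOURS, haversine_km, validate_track

RACE_LABELS = {"nh_white": "NH-White", "nh_black": "NH-Black",
               "hispanic": "Hispanic", "other": "Other"}
CONDITIONS = ("adrd", "chf", "copd", "dm", "ckd")


def _child_rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_storm(config: SimConfig, seed=None) -> pd.DataFrame:
    """Storm best track: 6-hourly fixes along a seeded quadratic Bezier.

    First and last fixes equal the configured endpoints exactly; the control
    point is the midpoint displaced perpendicular to the chord by a
    N(0, track_curvature_deg^2) draw, giving a smooth, gently curved path.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p0 = np.array([config.track_start_lat, config.track_start_lon])
    p2 = np.array([config.track_end_lat, config.track_end_lon])
    chord = p2 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValidationError("degenerate storm geometry")
    perp = np.array([-chord[1], chord[0]]) / norm
    p1 = (p0 + p2) / 2.0 + rng.normal(0.0, config.track_curvature_deg) * perp

    n_fixes = config.storm_duration_days * 24 // config.fix_interval_hours + 1
    u = np.linspace(0.0, 1.0, n_fixes)
    pts = ((1 - u) ** 2)[:, None] * p0 + (2 * u * (1 - u))[:, None] * p1 + (u**2)[:, None] * p2
    start = pd.Timestamp(config.landfall_date)
    times = start + pd.to_timedelta(
        np.arange(n_fixes) * config.fix_interval_hours, unit="h"
    )
    return validate_track(
        pd.DataFrame({"timestamp": times, "lat": pts[:, 0], "lon": pts[:, 1]})
    )


def generate_areas(config: SimConfig, seed=None) -> pd.DataFrame:
    """Area table: uniform centroids in the region box, rurality by configured probs."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lat = rng.uniform(config.lat_min, config.lat_max, config.n_areas)
    lon = rng.uniform(config.lon_min, config.lon_max, config.n_areas)
    cats = list(config.rurality_probs)
    rurality = rng.choice(cats, size=config.n_areas, p=list(config.rurality_probs.values()))
    return pd.DataFrame(
        {
            "area_id": [f"A{i:04d}" for i in range(config.n_areas)],
            "lat": lat,
            "lon": lon,
            "rurality": rurality,
        }
    )


def generate_stations(config: SimConfig, seed=None) -> pd.DataFrame:
    """Station table: uniform locations in a slightly padded region box."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pad = 0.5
    lat = rng.uniform(config.lat_min - pad, config.lat_max + pad, config.n_stations)
    lon = rng.uniform(config.lon_min - pad, config.lon_max + pad, config.n_stations)
    return pd.DataFrame(
        {
            "station_id": [f"S{i:04d}" for i in range(config.n_stations)],
            "lat": lat,
            "lon": lon,
        }
    )


def rainfall_mean_surface(
    config: SimConfig, track: pd.DataFrame, stations: pd.DataFrame, dates=None
) -> pd.DataFrame:
    """Expected station-day rainfall (mm): background + distance-decayed storm peak.

    The storm term applies only on local calendar days when the track has
    fixes; d is the minimum station-to-fix distance among that day's fixes.
    This closed-form mean is what the noisy generator fluctuates around, and
    what Monte-Carlo checks compare against.
    """
    local = track["timestamp"] + pd.Timedelta(hours=DEFAULT_UTC_OFFSET_HOURS)
    track_days = local.dt.date
    if dates is None:
        first = min(track_days) - dt.timedelta(days=config.rain_days_before)
        last = max(track_days) + dt.timedelta(days=config.rain_days_after)
        dates = [first + dt.timedelta(days=k) for k in range((last - first).days + 1)]
    rows = []
    slat = stations["lat"].to_numpy()
    slon = stations["lon"].to_numpy()
    for date in dates:
        mask = (track_days == date).to_numpy()
        mean = np.full(len(stations), config.background_mm, dtype=float)
        if mask.any():
            d = haversine_km(
                slat[:, None],
                slon[:, None],
                track["lat"].to_numpy()[None, mask],
                track["lon"].to_numpy()[None, mask],
            ).min(axis=1)
            mean = mean + config.peak_mm_per_day * np.exp(-d / config.decay_scale_km)
        for sid, m in zip(stations["station_id"], mean):
            rows.append((sid, date, m))
    return pd.DataFrame(rows, columns=["station_id", "date", "mean_mm"])


def generate_rainfall(
    config: SimConfig, track: pd.DataFrame, stations: pd.DataFrame, seed=None, dates=None
) -> pd.DataFrame:
    """Station-day precipitation records with multiplicative gamma noise.

    Complete by default (no missing values).  With ``noise_cv=0`` the field
    equals the mean surface exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    surface = rainfall_mean_surface(config, track, stations, dates=dates)
    mean = surface["mean_mm"].to_numpy()
    if config.noise_cv > 0:
        shape = 1.0 / config.noise_cv**2
        noise = rng.gamma(shape, 1.0 / shape, size=len(mean))
    else:
        noise = np.ones_like(mean)
    return pd.DataFrame(
        {
            "station_id": surface["station_id"],
            "date": surface["date"],
            "precip_mm": mean * noise,
        }
    )


def baseline_daily_hazard(config: SimConfig) -> float:
    """Constant daily hazard giving the configured one-year mortality at the
    reference profile (mean-age female, no comorbidities, unexposed, frailty 1)."""
    return -np.log(1.0 - config.baseline_annual_mortality) / config.followup_days


def generate_cohort(
    config: SimConfig,
    exposure_table: pd.DataFrame,
    areas: pd.DataFrame,
    seed=None,
):
    """Draw beneficiaries and their survival outcomes.

    Returns ``(beneficiaries, survival)``: the beneficiary table carries the
    covariates plus death/censor dates; the survival table carries follow-up
    time in days and the event indicator, consistent with the dates via the
    cohort module's elapsed-days convention (deaths on the landfall day get
    time 0.5).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_beneficiaries
    area_ids = exposure_table["area_id"].to_numpy()
    area_idx = rng.integers(0, len(area_ids), size=n)
    assigned = area_ids[area_idx]
    exposed = exposure_table["exposed"].to_numpy()[area_idx].astype(bool)

    a = (config.age_min - config.age_mean) / config.age_sd
    b = (config.age_max - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    female = rng.random(n) < config.female_p
    race = rng.choice(
        [RACE_LABELS[k] for k in config.race_probs],
        size=n,
        p=list(config.race_probs.values()),
    )
    dual = rng.random(n) < config.dual_p
    flags = {c: rng.random(n) < config.condition_prevalence[c] for c in CONDITIONS}
    n_flagged = np.sum([flags[c] for c in CONDITIONS], axis=0)
    n_comorbid = n_flagged + rng.poisson(config.extra_comorbidity_mean, size=n)
    relocated = rng.random(n) < config.relocation_p
    rurality = areas.set_index("area_id")["rurality"].reindex(assigned).to_numpy()

    # proportional-hazards event process
    beta_e = np.full(n, config.true_log_hr_exposure)
    for cond, value in config.exposure_log_hr_by_condition.items():
        beta_e = np.where(flags[cond], value, beta_e)
    frailty = rng.normal(0.0, config.frailty_sd, size=len(area_ids))
    eta = (
        beta_e * exposed
        + config.log_hr_age_per_year * (age - config.age_mean)
        + config.log_hr_male * (~female)
        + config.log_hr_dual * dual
        + config.log_hr_per_comorbidity * n_comorbid
        + frailty[area_idx]
    )
    lam = baseline_daily_hazard(config) * np.exp(eta)
    t_cont = rng.exponential(1.0 / lam)
    event = t_cont <= config.followup_days
    death_day = np.floor(t_cont).astype(int)

    landfall = config.landfall_date
    death_date = np.array(
        [
            landfall + dt.timedelta(days=int(d)) if e else None
            for d, e in zip(death_day, event)
        ],
        dtype=object,
    )
    censor_date = landfall + dt.timedelta(days=config.followup_days)

    beneficiaries = pd.DataFrame(
        {
            "beneficiary_id": [f"B{i:07d}" for i in range(n)],
            "area_id": assigned,
            "age": age,
            "sex": np.where(female, "female", "male"),
            "race_ethnicity": race,
            "dual_eligible": dual,
            **{c: flags[c] for c in CONDITIONS},
            "n_comorbidities": n_comorbid,
            "rurality": rurality,
            "relocated": relocated,
            "death_date": death_date,
            "censor_date": censor_date,
        }
    )
    exit_date = [dd if dd is not None else censor_date for dd in death_date]
    time_days = np.array(
        [
            cohort_mod.elapsed_days(d, landfall, followup_days=config.followup_days)
            for d in exit_date
        ]
    )
    survival = pd.DataFrame(
        {
            "beneficiary_id": beneficiaries["beneficiary_id"],
            "time_days": time_days,
            "event": event,
        }
    )
    return beneficiaries, survival


def simulate_inputs(config: SimConfig, seed=None) -> dict:
    """Generate all pipeline inputs (and the exposure table the cohort used).

    Child seeds for the storm, areas, stations, rainfall, and cohort stages
    are spawned from the single master seed, so the whole bundle is a pure
    function of (config, seed).
    """
    master = config.seed if seed is None else seed
    r_storm, r_areas, r_stations, r_rain, r_cohort = _child_rngs(master, 5)
    track = generate_storm(config, seed=r_storm)
    areas = generate_areas(config, seed=r_areas)
    stations = generate_stations(config, seed=r_stations)
    daily_rain = generate_rainfall(config, track, stations, seed=r_rain)
    exposure_table = exposure_mod.build_exposure_table(
        areas, stations, daily_rain, track
    )
    beneficiaries, survival = generate_cohort(
        config, exposure_table, areas, seed=r_cohort
    )
    return {
        "track": track,
        "areas": areas,
        "stations": stations,
        "daily_rain": daily_rain,
        "exposure": exposure_table,
        "beneficiaries": beneficiaries,
        "survival": survival,
    }
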