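"""Configuration dataclasses for simulation and pipeline runs, with YAML I/O."""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError


def _race_probs():
    return {"nh_white": 0.744, "nh_black": 0.093, "hispanic": 0.128, "other": 0.035}


def _condition_prev():
    return {"adrd": 0.125, "chf": 0.172, "copd": 0.139, "dm": 0.308, "ckd": 0.274}


def _rurality_probs():
    return {"metro": 0.778, "micro": 0.119, "rural": 0.103}


@dataclass
class SimConfig:
    """Parameters of the synthetic study: storm, rainfall field, cohort, survival.

    Cohort marginals default to the observed composition of the real
    Gulf-coast Medicare population the pipeline is designed for (age mean
    75.8 y / SD 7.3, 56.3% female, 7.7% dual-eligible, condition prevalences
    ADRD 12.5% ... CKD 27.4%); they emulate that composition, they do not
    reproduce any individual-level data.  The mortality process is
    proportional-hazards by construction: exponential event times with hazard
    lambda0 * exp(beta_E * exposed + beta' x + b_area), b_area log-normal.
    """

    seed: int = 0

    # spatial scope (synthetic Texas/Louisiana-like box)
    n_areas: int = 250
    n_stations: int = 120
    lat_min: float = 27.5
    lat_max: float = 32.5
    lon_min: float = -97.5
    lon_max: float = -91.0

    # storm geometry: smooth track crossing the region south to north
    track_start_lat: float = 24.5
    track_start_lon: float = -94.0
    track_end_lat: float = 33.5
    track_end_lon: float = -96.0
    track_curvature_deg: float = 1.0  # sd of the Bezier control-point offset
    landfall_date: dt.date = dt.date(2017, 8, 25)
    storm_duration_days: int = 7
    fix_interval_hours: int = 6

    # rainfall field
    peak_mm_per_day: float = 130.0
    decay_scale_km: float = 120.0
    background_mm: float = 2.0
    noise_cv: float = 0.5  # coefficient of variation of multiplicative gamma noise
    rain_days_before: int = 3  # calendar padding around the storm period
    rain_days_after: int = 2

    # cohort marginals
    n_beneficiaries: int = 200_000
    age_mean: float = 75.8
    age_sd: float = 7.3
    age_min: float = 65.0
    age_max: float = 105.0
    female_p: float = 0.563
    race_probs: dict = field(default_factory=_race_probs)
    dual_p: float = 0.077
    condition_prevalence: dict = field(default_factory=_condition_prev)
    extra_comorbidity_mean: float = 2.8  # Poisson count on top of the 5 flags
    rurality_probs: dict = field(default_factory=_rurality_probs)
    relocation_p: float = 0.027

    # survival process
    baseline_annual_mortality: float = 0.04
    true_log_hr_exposure: float = math.log(1.05)
    log_hr_age_per_year: float = 0.07
    log_hr_male: float = math.log(1.4)
    log_hr_dual: float = 0.0
    log_hr_per_comorbidity: float = math.log(1.10)
    #: optional per-condition override of the exposure log-HR (test knob for
    #: subgroup-effect recovery); first matching condition in dict order wins.
    exposure_log_hr_by_condition: dict = field(default_factory=dict)
    frailty_sd: float = 0.1
    followup_days: int = 365

    def validate(self) -> "SimConfig":
        for name in ("female_p", "dual_p", "relocation_p", "baseline_annual_mortality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("n_areas", "n_stations", "n_beneficiaries"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.frailty_sd < 0:
            raise ValidationError("frailty_sd must be >= 0")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("race_probs must sum to 1")
        if abs(sum(self.rurality_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("rurality_probs must sum to 1")
        for p in self.condition_prevalence.values():
            if not 0.0 <= p <= 1.0:
                raise ValidationError("condition prevalence outside [0, 1]")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValidationError("degenerate region box")
        if (self.track_start_lat, self.track_start_lon) == (
            self.track_end_lat,
            self.track_end_lon,
        ):
            raise ValidationError("degenerate storm geometry: start equals end")
        if self.storm_duration_days <= 0 or self.fix_interval_hours <= 0:
            raise ValidationError("degenerate storm duration")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline settings (exposure construction + modelling)."""

    threshold_mm: float = 75.0
    window_before_days: int = 2
    window_after_days: int = 1
    step_minutes: int = 15
    utc_offset_hours: float = -6.0
    idw_power: float = 2.0
    idw_radius_km: float = 150.0
    idw_min_stations: int = 3
    idw_max_radius_km: float = 600.0
    ghcn_tenths: bool = False
    include_relocated: bool = False
    seed: int = 0

    @property
    def window_offsets(self):
        return (-self.window_before_days, self.window_after_days)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, dt.date):
        return obj.isoformat()
    return obj


def dump_yaml(config) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=False)


def load_sim_config(path_or_stream) -> SimConfig:
    data = _load(path_or_stream)
    if "landfall_date" in data:
        data["landfall_date"] = dt.date.fromisoformat(str(data["landfall_date"]))
    return SimConfig(**data).validate()


def load_run_config(path_or_stream) -> RunConfig:
    return RunConfig(**_load(path_or_stream))


def _load(path_or_stream) -> dict:
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError("config YAML must be a mapping")
    return data
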