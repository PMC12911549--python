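import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stormcohort import synthetic_data as sd
from stormcohort.config import SimConfig
from stormcohort.errors import ValidationError


def test_storm_track_endpoints_and_fix_count():
    cfg = SimConfig()
    track = sd.generate_storm(cfg, seed=5)
    assert len(track) == 29  # 7 days at 6-h fixes: 28 intervals + 1
    assert track["lat"].iloc[0] == cfg.track_start_lat
    assert track["lon"].iloc[0] == cfg.track_start_lon
    assert track["lat"].iloc[-1] == cfg.track_end_lat
    assert track["lon"].iloc[-1] == cfg.track_end_lon


def test_storm_track_deterministic_given_seed():
    cfg = SimConfig()
    t1 = sd.generate_storm(cfg, seed=5)
    t2 = sd.generate_storm(cfg, seed=5)
    pd.testing.assert_frame_equal(t1, t2)


def test_degenerate_geometry_rejected():
    cfg = SimConfig(track_start_lat=30.0, track_start_lon=-95.0,
                    track_end_lat=30.0, track_end_lon=-95.0)
    with pytest.raises(ValidationError):
        sd.generate_storm(cfg)


def test_zero_noise_rainfall_equals_mean_surface():
    cfg = SimConfig(noise_cv=0.0, n_stations=10)
    track = sd.generate_storm(cfg, seed=1)
    stations = sd.generate_stations(cfg, seed=2)
    rain = sd.generate_rainfall(cfg, track, stations, seed=3)
    surface = sd.rainfall_mean_surface(cfg, track, stations)
    np.testing.assert_allclose(rain["precip_mm"], surface["mean_mm"], rtol=1e-12)


def test_far_station_sees_background_only():
    cfg = SimConfig(noise_cv=0.0)
    track = sd.generate_storm(cfg, seed=1)
    far = pd.DataFrame({"station_id": ["F"], "lat": [29.0], "lon": [-75.0]})
    rain = sd.generate_rainfall(cfg, track, far, seed=1)
    # ~1800 km from the track: storm term is e^(-15) of the peak
    assert rain["precip_mm"].max() == pytest.approx(cfg.background_mm, rel=1e-4)


def test_monte_carlo_station_mean_matches_closed_form():
    """Mean of the noisy field over 500 draws sits within 3 SE of the surface."""
    cfg = SimConfig(n_stations=3)
    track = sd.generate_storm(cfg, seed=1)
    stations = sd.generate_stations(cfg, seed=2)
    surface = sd.rainfall_mean_surface(cfg, track, stations)
    target = surface.iloc[7]
    draws = []
    for s in range(500):
        rain = sd.generate_rainfall(cfg, track, stations, seed=1000 + s)
        match = rain[(rain["station_id"] == target["station_id"]) &
                     (rain["date"] == target["date"])]
        draws.append(match["precip_mm"].iloc[0])
    draws = np.asarray(draws)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - target["mean_mm"]) < 3 * se


def _null_bundle(n, seed, **kw):
    cfg = SimConfig(n_beneficiaries=n, n_areas=50, n_stations=40,
                    true_log_hr_exposure=0.0, frailty_sd=0.0, **kw)
    return cfg, sd.simulate_inputs(cfg, seed=seed)


def test_null_effect_gives_equal_group_mortality():
    cfg, b = _null_bundle(60_000, seed=3, log_hr_age_per_year=0.0,
                          log_hr_male=0.0, log_hr_per_comorbidity=0.0)
    df = b["beneficiaries"].merge(b["survival"], on="beneficiary_id")
    df = df.merge(b["exposure"][["area_id", "exposed"]], on="area_id")
    p1 = df.loc[df["exposed"], "event"].mean()
    p0 = df.loc[~df["exposed"], "event"].mean()
    n1 = df["exposed"].sum()
    se = np.sqrt(p0 * (1 - p0) * (1 / n1 + 1 / (len(df) - n1)))
    assert abs(p1 - p0) < 3 * se


def test_baseline_mortality_calibration():
    """With all covariate effects off, the event fraction matches the
    exponential-CDF target 1 - exp(-lambda0 * 365)."""
    cfg, b = _null_bundle(100_000, seed=4, log_hr_age_per_year=0.0,
                          log_hr_male=0.0, log_hr_per_comorbidity=0.0)
    frac = b["survival"]["event"].mean()
    p = cfg.baseline_annual_mortality
    se = np.sqrt(p * (1 - p) / cfg.n_beneficiaries)
    assert abs(frac - p) < 3 * se


def test_cohort_reproducible_under_seed(small_config):
    b1 = sd.simulate_inputs(small_config, seed=21)
    b2 = sd.simulate_inputs(small_config, seed=21)
    pd.testing.assert_frame_equal(b1["beneficiaries"], b2["beneficiaries"])
    pd.testing.assert_frame_equal(b1["survival"], b2["survival"])


def test_survival_record_invariants(small_bundle):
    surv = small_bundle["survival"]
    assert (surv["time_days"] > 0).all()
    assert (surv["time_days"] <= 365).all()
    assert (surv.loc[~surv["event"], "time_days"] == 365).all()


def test_beneficiary_invariants(small_bundle):
    bene = small_bundle["beneficiaries"]
    assert (bene["age"] >= 65).all()
    flags = bene[list(sd.CONDITIONS)].sum(axis=1)
    assert (bene["n_comorbidities"] >= flags).all()


def test_covariate_marginals_match_config():
    cfg = SimConfig(n_beneficiaries=60_000, n_areas=50, n_stations=40)
    b = sd.simulate_inputs(cfg, seed=9)
    bene = b["beneficiaries"]
    n = len(bene)

    def within_3se(obs_p, p):
        return abs(obs_p - p) < 3 * np.sqrt(p * (1 - p) / n)

    assert within_3se((bene["sex"] == "female").mean(), cfg.female_p)
    assert within_3se(bene["dual_eligible"].mean(), cfg.dual_p)
    assert within_3se(bene["relocated"].mean(), cfg.relocation_p)
    for cond, p in cfg.condition_prevalence.items():
        assert within_3se(bene[cond].mean(), p)
    for key, p in cfg.race_probs.items():
        assert within_3se((bene["race_ethnicity"] == sd.RACE_LABELS[key]).mean(), p)
    # age against the truncated-normal theoretical mean
    a = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    bspec = (cfg.age_max - cfg.age_mean) / cfg.age_sd
    mu = stats.truncnorm.mean(a, bspec, loc=cfg.age_mean, scale=cfg.age_sd)
    se = bene["age"].std() / np.sqrt(n)
    assert abs(bene["age"].mean() - mu) < 3 * se
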