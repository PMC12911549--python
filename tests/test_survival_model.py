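import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from stormcohort import synthetic_data as sd
from stormcohort import survival_model as svm
from stormcohort.cohort import build_cohort
from stormcohort.config import SimConfig
from stormcohort.descriptive_epi import logrank_test
from stormcohort.errors import DegenerateGroupError, ValidationError


def brute_force_breslow(time, event, X):
    """Independent oracle: explicit Breslow partial likelihood, generic optimizer."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T

    def negll(beta):
        ll = 0.0
        for t in np.unique(time[event]):
            at_risk = time >= t
            dead = event & (time == t)
            eta = X @ beta
            ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
        return -ll

    res = optimize.minimize(negll, np.zeros(X.shape[1]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


@pytest.mark.parametrize(
    "time, event, x",
    [
        ([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 0.0, 1.0]),
        ([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 0, 1, 0], [0.0, 1.0, 1.0, 0.0, 1.0]),
        ([1.0, 1.0, 2.0, 3.0], [1, 1, 1, 0], [1.0, 0.0, 1.0, 0.0]),  # tied deaths
    ],
)
def test_small_fixture_matches_brute_force_partial_likelihood(time, event, x):
    fit = svm.fit_cox(time, event, np.asarray(x))
    oracle = brute_force_breslow(time, event, x)
    assert fit.coef[0] == pytest.approx(oracle[0], abs=1e-6)


def test_frailty_off_reduces_to_plain_cox(small_cohort):
    X, names = svm.build_design(small_cohort)
    t = small_cohort["time_days"].to_numpy()
    e = small_cohort["event"].to_numpy()
    plain = svm.fit_cox(t, e, X, names=names)
    frailty0 = svm.fit_cox_frailty(t, e, X, small_cohort["area_id"], names=names, theta=0.0)
    np.testing.assert_allclose(frailty0.coef, plain.coef, atol=1e-12)
    np.testing.assert_allclose(frailty0.se, plain.se, atol=1e-12)


def test_ci_exponentiation_order_preserving(small_cohort):
    fit = svm.fit_adjusted(small_cohort)
    assert (fit.ci_low <= fit.hr).all() and (fit.hr <= fit.ci_high).all()
    assert fit.theta >= 0
    assert fit.converged


def test_duplicating_subjects_shrinks_se_sqrt2():
    rng = np.random.default_rng(4)
    n = 300
    X = rng.normal(size=(n, 2))
    t = rng.exponential(1 / np.exp(X @ [0.4, -0.2]))
    e = t < 1.0
    t = np.minimum(t, 1.0)
    fit = svm.fit_cox(t, e, X)
    fit2 = svm.fit_cox(np.tile(t, 2), np.tile(e, 2), np.tile(X, (2, 1)))
    np.testing.assert_allclose(fit2.coef, fit.coef, atol=1e-7)
    np.testing.assert_allclose(fit.se / fit2.se, np.sqrt(2), rtol=1e-6)


def test_score_test_equals_logrank_untied():
    rng = np.random.default_rng(6)
    t = rng.exponential(50, 80)
    g = rng.integers(0, 2, 80).astype(bool)
    e = t < 70
    stat, p = svm.score_test_two_group(t, e, g)
    lr_stat, lr_p = logrank_test(t[g], e[g], t[~g], e[~g])
    assert stat == pytest.approx(lr_stat, abs=1e-6)
    assert p == pytest.approx(lr_p, abs=1e-6)


def test_collinear_covariates_diagnosed():
    rng = np.random.default_rng(1)
    n = 50
    x = rng.normal(size=n)
    X = np.column_stack([x, 2 * x])
    t = rng.exponential(1.0, n)
    with pytest.raises(ValidationError, match="collinear|singular"):
        svm.fit_cox(t, np.ones(n, bool), X)


def test_no_events_rejected():
    with pytest.raises(DegenerateGroupError):
        svm.fit_cox([1.0, 2.0], [0, 0], [[0.0], [1.0]])


def test_exposure_effect_recovery_moderate_n():
    """Single larger replicate: estimated exposure log-HR within 3 SE of truth."""
    cfg = SimConfig(n_beneficiaries=120_000)
    b = sd.simulate_inputs(cfg, seed=42)
    df = build_cohort(b["beneficiaries"], b["survival"], b["exposure"]).data
    fit = svm.fit_adjusted(df)
    i = fit.names.index("exposed")
    assert abs(fit.coef[i] - cfg.true_log_hr_exposure) < 3 * fit.se[i]
    # adjusted covariates recovered too
    j = fit.names.index("age")
    assert abs(fit.coef[j] - cfg.log_hr_age_per_year) < 3 * fit.se[j]


def test_null_generator_ci_coverage():
    """With beta_E = 0 the 95% CI covers HR 1 in at least ~93% of replicates
    (scaled-down: 40 replicates at n = 20,000)."""
    cfg = SimConfig(n_beneficiaries=20_000, n_areas=60, n_stations=40,
                    true_log_hr_exposure=0.0)
    covered = 0
    reps = 40
    for r in range(reps):
        b = sd.simulate_inputs(cfg, seed=500 + r)
        df = build_cohort(b["beneficiaries"], b["survival"], b["exposure"]).data
        fit = svm.fit_adjusted(df)
        i = fit.names.index("exposed")
        covered += fit.ci_low[i] <= 1.0 <= fit.ci_high[i]
    assert covered / reps >= 0.85


def test_subgroup_table_contains_overall_row(small_cohort):
    tab = svm.subgroup_hrs(
        small_cohort,
        specs=[svm.SubgroupSpec("overall", lambda d: np.ones(len(d), dtype=bool))],
    )
    overall = svm.fit_adjusted(small_cohort)
    i = overall.names.index("exposed")
    row = tab.iloc[0]
    assert row["hr"] == pytest.approx(overall.hr[i], rel=1e-9)
    assert row["events"] == overall.n_events


def test_subgroup_specific_effect_ordering_recovered():
    """Generator with an ADRD-specific exposure HR of 1.5 (others 1.0):
    the fitted ADRD subgroup HR must exceed the non-ADRD fit and bracket 1.5."""
    cfg = SimConfig(
        n_beneficiaries=120_000,
        true_log_hr_exposure=0.0,
        exposure_log_hr_by_condition={"adrd": np.log(1.5)},
    )
    b = sd.simulate_inputs(cfg, seed=77)
    df = build_cohort(b["beneficiaries"], b["survival"], b["exposure"]).data
    specs = [
        svm.SubgroupSpec("adrd", lambda d: d["adrd"].to_numpy(), exclude_condition="adrd"),
        svm.SubgroupSpec("no_adrd", lambda d: ~d["adrd"].to_numpy()),
    ]
    tab = svm.subgroup_hrs(df, specs=specs).set_index("subgroup")
    assert tab.loc["adrd", "hr"] > tab.loc["no_adrd", "hr"]
    assert tab.loc["adrd", "ci_low"] <= 1.5 <= tab.loc["adrd", "ci_high"]
    assert tab.loc["no_adrd", "ci_low"] <= 1.0 <= tab.loc["no_adrd", "ci_high"]


def test_underpopulated_subgroup_skipped_with_reason(small_cohort):
    spec = svm.SubgroupSpec("empty", lambda d: np.zeros(len(d), dtype=bool))
    tab = svm.subgroup_hrs(small_cohort, specs=[spec])
    assert tab.iloc[0]["note"] != ""
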