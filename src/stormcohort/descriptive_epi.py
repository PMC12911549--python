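"""Unadjusted epidemiology: rates, RR, attributable measures, KM, log-rank, Table 1.

Mortality "rates" here are one-year cumulative-incidence proportions (fixed
365-day follow-up), not person-time rates.  The attributable fraction among
the exposed is (RR - 1)/RR, and attributable deaths are the exposed-group
deaths in excess of those expected at the unexposed rate,
n_exposed * (rate_exposed - rate_unexposed) — algebraically AF * deaths_exposed.
Negative values are reported as computed, never floored.

Kaplan-Meier estimation and the log-rank test delegate to lifelines; Table-1
hypothesis tests use scipy (t-test for means, Mann-Whitney for medians,
Pearson chi-squared without continuity correction for proportions),
two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import DegenerateGroupError


@dataclass(frozen=True)
class EpiMeasures:
    deaths_exposed: int
    n_exposed: int
    deaths_unexposed: int
    n_unexposed: int
    rate_exposed: float
    rate_unexposed: float
    relative_risk: float
    attributable_fraction_exposed: float
    attributable_deaths: float


def epi_measures(cohort: pd.DataFrame, mask=None) -> EpiMeasures:
    """Unadjusted 2x2 measures within an optional subgroup mask.

    Requires both exposure groups nonempty and at least one unexposed death
    (otherwise RR is undefined and an explicit error is raised rather than a
    silent infinity).
    """
    df = cohort if mask is None else cohort[np.asarray(mask)]
    exposed = df["exposed"].astype(bool)
    n1, n0 = int(exposed.sum()), int((~exposed).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateGroupError("an exposure group is empty in this subgroup")
    d1 = int(df.loc[exposed, "event"].sum())
    d0 = int(df.loc[~exposed, "event"].sum())
    if d0 == 0:
        raise DegenerateGroupError("zero unexposed deaths: relative risk undefined")
    r1, r0 = d1 / n1, d0 / n0
    rr = r1 / r0
    af = (rr - 1.0) / rr
    return EpiMeasures(
        deaths_exposed=d1,
        n_exposed=n1,
        deaths_unexposed=d0,
        n_unexposed=n0,
        rate_exposed=r1,
        rate_unexposed=r0,
        relative_risk=rr,
        attributable_fraction_exposed=af,
        attributable_deaths=n1 * (r1 - r0),
    )


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival and cumulative incidence on the event-time grid.

    Returns (time, survival, cum_incidence, at_risk); right censoring at the
    follow-up boundary is handled as ordinary censoring.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise DegenerateGroupError("empty input to km_curve")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(),
            "cum_incidence": 1.0 - surv.to_numpy(),
            "at_risk": at_risk.to_numpy(),
        }
    ).reset_index(drop=True)


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank test; returns (chi-square statistic, two-sided p)."""
    event_a = np.asarray(event_a, dtype=bool)
    event_b = np.asarray(event_b, dtype=bool)
    if len(np.asarray(time_a)) == 0 or len(np.asarray(time_b)) == 0:
        raise DegenerateGroupError("empty group in log-rank test")
    if event_a.sum() + event_b.sum() == 0:
        raise DegenerateGroupError("no events: log-rank statistic undefined")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def km_curves_by_exposure(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long-format KM cumulative incidence by exposure group with log-rank p."""
    out = []
    for flag, g in cohort.groupby(cohort["exposed"].astype(bool)):
        curve = km_curve(g["time_days"], g["event"])
        curve.insert(0, "group", "exposed" if flag else "unexposed")
        out.append(curve)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Table 1


def _prop_test(x_counts, y_counts):
    """Pearson chi-squared (no continuity correction) on a k x 2 table."""
    table = np.vstack([x_counts, y_counts])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def table_one(cohort: pd.DataFrame, continuous=("age", "n_comorbidities", "cumulative_mm"),
              categorical=("sex", "race_ethnicity", "dual_eligible", "rurality",
                           "adrd", "chf", "copd", "dm", "ckd")) -> pd.DataFrame:
    """Characteristics by exposure status with the conventional test per type.

    Continuous variables get mean (SD) with a t-test and median (IQR) with a
    Mann-Whitney test; categorical variables get n (%) with a chi-squared
    test.  Constant variables are kept but their test is skipped with a note.
    """
    exposed = cohort["exposed"].astype(bool)
    g1, g0 = cohort[exposed], cohort[~exposed]
    rows = []
    for var in continuous:
        if var not in cohort.columns:
            continue
        x1 = g1[var].dropna().to_numpy(dtype=float)
        x0 = g0[var].dropna().to_numpy(dtype=float)
        if np.ptp(cohort[var].dropna()) == 0:
            rows.append(_t1row(var, "mean (SD)", x1, x0, np.nan, np.nan, "constant; test skipped"))
            continue
        t, p_t = stats.ttest_ind(x1, x0, equal_var=False)
        _, p_u = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        rows.append(_t1row(var, "mean (SD)", x1, x0, float(t), float(p_t), ""))
        rows.append(
            {
                "variable": var,
                "summary": "median (IQR)",
                "overall": _median_iqr(np.concatenate([x1, x0])),
                "exposed": _median_iqr(x1),
                "unexposed": _median_iqr(x0),
                "statistic": np.nan,
                "p": float(p_u),
                "note": "Mann-Whitney",
            }
        )
    for var in categorical:
        if var not in cohort.columns:
            continue
        levels = sorted(cohort[var].dropna().unique(), key=str)
        c1 = np.array([(g1[var] == lv).sum() for lv in levels])
        c0 = np.array([(g0[var] == lv).sum() for lv in levels])
        if len(levels) < 2:
            chi2, p, note = np.nan, np.nan, "constant; test skipped"
        else:
            chi2, p = _prop_test(c1, c0)
            note = "chi-squared"
        for lv, a, b in zip(levels, c1, c0):
            rows.append(
                {
                    "variable": var,
                    "summary": f"n (%) [{lv}]",
                    "overall": _n_pct(a + b, len(cohort)),
                    "exposed": _n_pct(a, len(g1)),
                    "unexposed": _n_pct(b, len(g0)),
                    "statistic": chi2,
                    "p": p,
                    "note": note,
                }
            )
    return pd.DataFrame(rows)


def _t1row(var, kind, x1, x0, stat, p, note):
    both = np.concatenate([x1, x0])
    return {
        "variable": var,
        "summary": kind,
        "overall": f"{both.mean():.2f} ({both.std(ddof=1):.2f})",
        "exposed": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
        "unexposed": f"{x0.mean():.2f} ({x0.std(ddof=1):.2f})",
        "statistic": stat,
        "p": p,
        "note": note or "t-test",
    }


def _median_iqr(x):
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def _n_pct(k, n):
    return f"{k} ({100.0 * k / n:.1f})" if n else "0 (0.0)"


def epi_measures_by_subgroup(cohort: pd.DataFrame, subgroups: dict) -> pd.DataFrame:
    """EpiMeasures per named subgroup mask (subgroup-restricted denominators).

    ``subgroups`` maps name -> boolean mask over cohort rows.  Subgroups where
    the measures are degenerate are reported with a reason instead of numbers.
    """
    rows = []
    for name, mask in subgroups.items():
        try:
            m = epi_measures(cohort, mask)
        except DegenerateGroupError as exc:
            rows.append({"subgroup": name, "note": str(exc)})
            continue
        rows.append(
            {
                "subgroup": name,
                "n_exposed": m.n_exposed,
                "n_unexposed": m.n_unexposed,
                "deaths_exposed": m.deaths_exposed,
                "deaths_unexposed": m.deaths_unexposed,
                "rate_exposed": m.rate_exposed,
                "rate_unexposed": m.rate_unexposed,
                "relative_risk": m.relative_risk,
                "attributable_fraction": m.attributable_fraction_exposed,
                "attributable_deaths": m.attributable_deaths,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
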