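"""Sensitivity analyses: E-values, residual spatial autocorrelation, relocation.

The E-value is the minimum strength of association (risk-ratio scale) an
unmeasured confounder would need with both exposure and outcome to explain
away an observed association: E = RR + sqrt(RR * (RR - 1)), applied to 1/RR
first when the estimate is protective.  With a rare outcome (~4%/year) the
hazard ratio is used directly as the risk ratio; this approximation is
recorded in the output metadata.

Residual spatial structure is assessed with global Moran's I on area-averaged
martingale residuals, under row-standardized k-nearest-neighbour weights
(k = 5) built from centroid great-circle distances, with a seeded
permutation null (999 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGroupError, ValidationError
from .geo_track import haversine_km


@dataclass(frozen=True)
class EValueResult:
    e_point: float
    e_ci: float
    approximation: str = "HR treated as RR (rare outcome)"


def _evalue_from_rr(rr: float) -> float:
    if rr < 1.0:
        rr = 1.0 / rr
    return rr + np.sqrt(rr * (rr - 1.0))


def evalue(hr: float, ci_low: float | None = None, ci_high: float | None = None) -> EValueResult:
    """E-value for an estimate and (optionally) its confidence interval.

    ``e_ci`` uses the CI limit closer to the null and is 1 when the interval
    crosses 1 (no unmeasured confounding needed to reach the null).
    """
    if hr <= 0:
        raise ValidationError("hazard ratio must be positive")
    e_point = _evalue_from_rr(hr)
    if ci_low is None or ci_high is None:
        return EValueResult(e_point=float(e_point), e_ci=float("nan"))
    if not (0 < ci_low <= hr <= ci_high):
        raise ValidationError("require 0 < ci_low <= hr <= ci_high")
    if ci_low <= 1.0 <= ci_high:
        e_ci = 1.0
    else:
        limit = ci_low if hr > 1.0 else ci_high
        e_ci = _evalue_from_rr(limit)
    return EValueResult(e_point=float(e_point), e_ci=float(e_ci))


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    z: float
    p: float
    scheme: str
    n_permutations: int


def knn_weights(lats, lons, k: int = 5) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix on great-circle distance."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(lats)
    if n < 3:
        raise ValidationError("need at least 3 areas for spatial weights")
    k = min(k, n - 1)
    d = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    np.fill_diagonal(d, np.inf)
    W = np.zeros((n, n))
    nbrs = np.argsort(d, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    W[rows, nbrs.ravel()] = 1.0
    return W / W.sum(axis=1, keepdims=True)


def morans_i(
    values,
    weights: np.ndarray | None = None,
    centroids: pd.DataFrame | None = None,
    k: int = 5,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with a two-sided permutation p-value.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Either a weight matrix or a centroid table (lat, lon) must be supplied;
    constant input is a degenerate-input error, never silent NaN.  The
    permutation null shuffles values across areas with a seeded generator,
    so p-values are reproducible; the z-score is against the permutation
    distribution.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("Moran's I needs at least 3 areas")
    if np.ptp(x) == 0:
        raise DegenerateGroupError("constant values: Moran's I undefined")
    if weights is None:
        if centroids is None:
            raise ValidationError("supply weights or centroids")
        weights = knn_weights(centroids["lat"], centroids["lon"], k=k)
        scheme = f"knn{k}_row_standardized"
    else:
        weights = np.asarray(weights, dtype=float)
        scheme = "user_supplied"
    if weights.shape != (n, n):
        raise ValidationError("weight matrix shape mismatch")
    S0 = weights.sum()
    z = x - x.mean()
    denom = float(z @ z)
    I_obs = float(n / S0 * (z @ weights @ z) / denom)

    rng = np.random.default_rng(seed)
    # permuted z'Wz for all permutations at once; denominator is invariant
    perms = np.array([rng.permutation(z) for _ in range(n_permutations)])
    I_perm = n / S0 * np.einsum("pi,ij,pj->p", perms, weights, perms) / denom
    expected = -1.0 / (n - 1)
    sd = float(I_perm.std(ddof=1))
    p = (1.0 + np.sum(np.abs(I_perm - expected) >= abs(I_obs - expected))) / (
        n_permutations + 1.0
    )
    return MoranResult(
        I=I_obs,
        expected=expected,
        z=(I_obs - expected) / sd if sd > 0 else np.inf,
        p=float(p),
        scheme=scheme,
        n_permutations=n_permutations,
    )


def residuals_by_area(fit, cohort: pd.DataFrame) -> pd.Series:
    """Area-averaged martingale residuals (event minus expected events).

    Requires a converged fit carrying per-subject expected-event counts in
    the cohort's row order.
    """
    if not fit.converged:
        raise ValidationError("refusing residuals from a non-converged fit")
    if fit.expected_events is None or len(fit.expected_events) != len(cohort):
        raise ValidationError("fit does not match cohort rows")
    resid = fit.event.astype(float) - fit.expected_events
    return pd.Series(resid, index=cohort["area_id"].to_numpy()).groupby(level=0).mean()


def relocation_sensitivity(
    beneficiaries: pd.DataFrame,
    survival: pd.DataFrame,
    exposure_table: pd.DataFrame,
    specs=None,
    theta=None,
) -> pd.DataFrame:
    """Side-by-side subgroup HRs excluding vs including relocated beneficiaries."""
    from . import cohort as cohort_mod
    from . import survival_model

    out = []
    for include, label in ((False, "primary"), (True, "with_relocated")):
        cohort = cohort_mod.build_cohort(
            beneficiaries, survival, exposure_table, include_relocated=include
        )
        tab = survival_model.subgroup_hrs(cohort.data, specs=specs, theta=theta)
        tab = tab.rename(
            columns={c: f"{c}_{label}" for c in tab.columns if c != "subgroup"}
        )
        out.append(tab)
    return out[0].merge(out[1], on="subgroup", how="outer")
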