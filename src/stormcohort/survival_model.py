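"""Cox proportional hazards with gamma shared frailty at the area level.

The adjusted association between high-rain exposure and one-year mortality is
estimated by a Cox model with a multiplicative area-level random effect
(shared frailty).  Frailties are gamma with mean 1 and variance theta, and the
model is fit by the classical penalized/EM scheme:

* inner loop — Newton maximization of the Breslow-ties partial likelihood
  with the current log-frailties as offsets (tolerance 1e-8);
* E-step — cluster-level posterior gamma moments
  E[w_j] = (1/theta + D_j) / (1/theta + A_j), with D_j the cluster's events
  and A_j its accumulated expected events under the current fit;
* M-step — the one-dimensional score equation for 1/theta solved by Brent's
  method, a monotone ascent on the marginal (Klein) likelihood;

iterated to an outer tolerance of 1e-6 on theta (cap 100 outer iterations).
With theta fixed at 0 the fit reduces exactly to ordinary Cox partial
likelihood.  Confidence intervals are Wald on the log scale (z = 1.96), with
standard errors from the observed information of the final inner fit
(frailties held at their posterior means — standard for shared-frailty
software and accurate for small theta).

Covariates follow the study model: exposure, age (continuous), sex,
race/ethnicity, comorbidity count, and rurality.  Race-defined subgroup
models drop the race covariate; condition-defined subgroups exclude the
defining condition's flag from the comorbidity-count covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConvergenceError, DegenerateGroupError, ValidationError

Z_95 = 1.959963984540054

CONDITIONS = ("adrd", "chf", "copd", "dm", "ckd")


# ---------------------------------------------------------------------------
# partial-likelihood machinery (Breslow ties)


class _CoxData:
    """Time-sorted views and tie-group indexing reused across Newton steps."""

    def __init__(self, time, event, X):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        if np.any(time <= 0):
            raise ValidationError("event/censoring times must be positive")
        order = np.argsort(-time, kind="stable")  # descending: prefix = risk set
        self.order = order
        self.time = time[order]
        self.event = event[order]
        self.X = X[order]
        self.n, self.p = self.X.shape
        # tie groups over distinct times (descending)
        change = np.empty(self.n, dtype=bool)
        change[0] = True
        change[1:] = self.time[1:] != self.time[:-1]
        self.starts = np.flatnonzero(change)
        self.G = len(self.starts)
        self.ends = np.append(self.starts[1:], self.n)
        self.d_g = np.add.reduceat(self.event.astype(float), self.starts)
        ev = self.event[:, None] * self.X
        self.sum_x_events = np.add.reduceat(ev, self.starts, axis=0)

    def stats_at(self, eta):
        """Risk-set sums S, A, B per tie group and event eta sums."""
        w = np.exp(eta)
        S_g = np.add.reduceat(w, self.starts)
        A_g = np.add.reduceat(w[:, None] * self.X, self.starts, axis=0)
        B_g = np.empty((self.G, self.p, self.p))
        for g in range(self.G):
            sl = slice(self.starts[g], self.ends[g])
            Xg = self.X[sl]
            B_g[g] = Xg.T @ (Xg * w[sl, None])
        S = np.cumsum(S_g)
        A = np.cumsum(A_g, axis=0)
        B = np.cumsum(B_g, axis=0)
        eta_ev = np.add.reduceat(self.event * eta, self.starts)
        return w, S, A, B, eta_ev

    def loglik_grad_hess(self, beta, offset):
        eta = self.X @ beta + offset
        _, S, A, B, eta_ev = self.stats_at(eta)
        d = self.d_g
        ll = float(np.sum(eta_ev) - np.sum(d * np.log(S)))
        abar = A / S[:, None]
        grad = self.sum_x_events.sum(axis=0) - (d[:, None] * abar).sum(axis=0)
        H = np.zeros((self.p, self.p))
        for g in np.flatnonzero(d):
            H -= d[g] * (B[g] / S[g] - np.outer(abar[g], abar[g]))
        return ll, grad, H, S

    def breslow_cumhaz(self, S):
        """Breslow baseline cumulative hazard evaluated at each subject's exit.

        Returned in the same (descending-time) order as the sorted arrays.
        """
        h0_g = np.where(S > 0, self.d_g / S, 0.0)
        # groups are in descending time; cumulative hazard at group g is the
        # sum of h0 over groups with time <= t_g, i.e. a suffix sum
        cum_g = np.cumsum(h0_g[::-1])[::-1]
        group_of = np.repeat(np.arange(self.G), self.ends - self.starts)
        return cum_g[group_of]


def _newton_cox(data: _CoxData, offset, beta0=None, tol=1e-8, max_iter=60):
    beta = np.zeros(data.p) if beta0 is None else np.array(beta0, dtype=float)
    ll, grad, H, S = data.loglik_grad_hess(beta, offset)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "singular information matrix: collinear covariates or separation"
            ) from exc
        new_beta = beta + step
        new_ll, new_grad, new_H, new_S = data.loglik_grad_hess(new_beta, offset)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step /= 2.0
            halvings += 1
            if halvings > 30:
                raise ConvergenceError("Newton step-halving failed", trace={"ll": ll})
            new_beta = beta + step
            new_ll, new_grad, new_H, new_S = data.loglik_grad_hess(new_beta, offset)
        delta = new_ll - ll
        beta, ll, grad, H, S = new_beta, new_ll, new_grad, new_H, new_S
        if abs(delta) < tol:
            return beta, ll, grad, H, S, it
    raise ConvergenceError(
        f"Cox Newton did not converge in {max_iter} iterations",
        trace={"loglik": ll, "grad_max": float(np.max(np.abs(grad)))},
    )


def breslow_partial_loglik(beta, time, event, X, offset=None):
    """Breslow-ties log partial likelihood at ``beta`` (no fitting)."""
    data = _CoxData(time, event, X)
    off = np.zeros(data.n) if offset is None else np.asarray(offset, float)[data.order]
    ll, _, _, _ = data.loglik_grad_hess(np.atleast_1d(np.asarray(beta, float)), off)
    return ll


# ---------------------------------------------------------------------------
# fit containers and entry points


@dataclass
class CoxFit:
    """Fitted Cox model, optionally with gamma shared frailty."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    theta: float
    loglik: float
    iterations: int
    converged: bool
    n: int
    n_events: int
    n_clusters: int = 1
    frailty: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    # per-subject pieces in original row order, for residuals
    expected_events: np.ndarray | None = field(default=None, repr=False)
    event: np.ndarray | None = field(default=None, repr=False)

    @property
    def hr(self):
        return np.exp(self.coef)

    @property
    def ci_low(self):
        with np.errstate(over="ignore"):
            return np.exp(self.coef - Z_95 * self.se)

    @property
    def ci_high(self):
        # an unstable subgroup can have a huge SE; an infinite limit is honest
        with np.errstate(over="ignore"):
            return np.exp(self.coef + Z_95 * self.se)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def fit_cox(time, event, X, names=None, offset=None, beta0=None, tol=1e-8) -> CoxFit:
    """Ordinary Cox partial-likelihood fit (Breslow ties), no frailty."""
    data = _CoxData(time, event, X)
    if data.event.sum() == 0:
        raise DegenerateGroupError("no events: partial likelihood undefined")
    off = np.zeros(data.n) if offset is None else np.asarray(offset, float)[data.order]
    beta, ll, grad, H, S, it = _newton_cox(data, off, beta0=beta0, tol=tol)
    se = np.sqrt(np.diag(np.linalg.inv(-H)))
    cumhaz = data.breslow_cumhaz(S)
    expected = cumhaz * np.exp(data.X @ beta + off)
    inv = np.empty(data.n, dtype=int)
    inv[data.order] = np.arange(data.n)
    return CoxFit(
        names=list(names) if names is not None else [f"x{i}" for i in range(data.p)],
        coef=beta,
        se=se,
        theta=0.0,
        loglik=ll,
        iterations=it,
        converged=True,
        n=data.n,
        n_events=int(data.event.sum()),
        expected_events=expected[inv],
        event=data.event[inv],
    )


def _marginal_loglik(nu, D, A, S, data, eta_events):
    """Klein's marginal log-likelihood (gamma frailty integrated out, profile h0).

    ``eta_events`` is the frailty-free linear predictor summed over events.
    The nu = inf limit is the full Breslow log-likelihood without frailty.
    """
    ev_groups = data.d_g > 0
    h0 = data.d_g[ev_groups] / S[ev_groups]
    ll_cox = float(np.sum(data.d_g[ev_groups] * np.log(h0))) + eta_events
    if not np.isfinite(nu):
        return ll_cox - float(np.sum(A))
    gam = np.sum(
        special.gammaln(nu + D)
        - special.gammaln(nu)
        + nu * np.log(nu)
        - (nu + D) * np.log(nu + A)
    )
    return ll_cox + float(gam)


def _penalized_variance(data, cl_sorted, m, beta, w, theta):
    """Variance of beta from the full (beta, log-frailty) penalized Hessian.

    Holding frailties fixed understates the variance of cluster-level
    covariates; the joint penalized information (gamma penalty contributing
    w_j / theta on the diagonal of the frailty block) restores it.  Returns
    the beta block of the inverse information via its Schur complement.
    """
    eta = data.X @ beta + np.log(w)[cl_sorted]
    ew = np.exp(eta)
    group_of = np.repeat(np.arange(data.G), data.ends - data.starts)
    flat = group_of * m + cl_sorted
    Sgj = np.bincount(flat, weights=ew, minlength=data.G * m).reshape(data.G, m)
    Agj = np.empty((data.G, m, data.p))
    for k in range(data.p):
        Agj[:, :, k] = np.bincount(
            flat, weights=ew * data.X[:, k], minlength=data.G * m
        ).reshape(data.G, m)
    Sgj = np.cumsum(Sgj, axis=0)
    Agj = np.cumsum(Agj, axis=0)
    S = Sgj.sum(axis=1)
    abar = Agj.sum(axis=1) / S[:, None]
    d = data.d_g
    P = Sgj / S[:, None]

    I_bb = np.diag(d @ P) - (P.T * d) @ P + np.diag(w / theta)
    I_bB = np.einsum("g,gmp->mp", d / S, Agj) - np.einsum("g,gp,gm->mp", d, abar, P)
    _, _, H_BB, _ = data.loglik_grad_hess(beta, np.log(w)[cl_sorted])
    I_BB = -H_BB
    schur = I_BB - I_bB.T @ np.linalg.solve(I_bb, I_bB)
    return np.linalg.inv(schur)


def fit_cox_frailty(
    time,
    event,
    X,
    cluster,
    names=None,
    theta=None,
    theta_max=2.0,
    outer_tol=1e-6,
    inner_tol=1e-8,
    max_em=500,
) -> CoxFit:
    """Gamma shared-frailty Cox fit: profile likelihood in theta, EM inside.

    For each candidate variance theta the inner EM alternates a Newton fit of
    the offset partial likelihood with the gamma E-step until the Klein
    marginal likelihood stabilizes; the outer loop maximizes that profile
    over theta by bounded Brent search to ``outer_tol``, warm-starting
    coefficients and frailties between evaluations.  ``theta=None`` estimates
    the variance; ``theta=0`` forces the ordinary Cox path; a positive
    ``theta`` holds it fixed.  Raises :class:`ConvergenceError` (carrying the
    evaluation trace) if the inner EM exhausts its cap.
    """
    cluster = np.asarray(cluster)
    labels, cl_idx = np.unique(cluster, return_inverse=True)
    m = len(labels)
    if m < 2 and theta != 0.0:
        raise ValidationError("frailty model needs >= 2 clusters")
    if theta == 0.0:
        fit = fit_cox(time, event, X, names=names)
        fit.n_clusters = m
        fit.cluster_labels = labels
        fit.frailty = np.ones(m)
        return fit

    data = _CoxData(time, event, X)
    if data.event.sum() == 0:
        raise DegenerateGroupError("no events")
    cl_sorted = cl_idx[data.order]
    D = np.bincount(cl_sorted, weights=data.event.astype(float), minlength=m)

    state = {"beta": None, "w": np.ones(m), "iters": 0}
    trace = []

    def em_profile(theta_val):
        """Marginal log-likelihood profiled at a fixed frailty variance."""
        nu = np.inf if theta_val < 1e-12 else 1.0 / theta_val
        beta, w = state["beta"], state["w"].copy()
        if not np.isfinite(nu):
            w = np.ones(m)
        ll_old = -np.inf
        for _ in range(max_em):
            off = np.log(w)[cl_sorted]
            beta, _, _, H, S, _ = _newton_cox(data, off, beta0=beta, tol=inner_tol)
            cumhaz = data.breslow_cumhaz(S)
            risk = np.exp(data.X @ beta)  # frailty-free relative hazard
            A = np.bincount(cl_sorted, weights=cumhaz * risk, minlength=m)
            if np.isfinite(nu):
                w = (nu + D) / (nu + A)  # posterior mean frailty
            eta_events = float(np.sum(data.event * (data.X @ beta)))
            ll = _marginal_loglik(nu, D, A, S, data, eta_events)
            state["iters"] += 1
            if abs(ll - ll_old) < 1e-10 * (1.0 + abs(ll)):
                break
            ll_old = ll
        else:
            raise ConvergenceError(
                f"frailty EM did not stabilize within {max_em} iterations "
                f"at theta={theta_val:g}",
                trace=trace,
            )
        state["beta"], state["w"] = beta, w
        trace.append((theta_val, ll))
        return ll, (beta, H, S, cumhaz, risk, w)

    if theta is not None:
        theta_hat = float(theta)
        ll, aux = em_profile(theta_hat)
    else:
        res = optimize.minimize_scalar(
            lambda th: -em_profile(th)[0],
            bounds=(0.0, theta_max),
            method="bounded",
            options={"xatol": outer_tol},
        )
        theta_hat = float(res.x)
        ll, aux = em_profile(theta_hat)
        ll0, aux0 = em_profile(0.0)  # boundary check: variance may collapse
        if ll0 >= ll:
            theta_hat, ll, aux = 0.0, ll0, aux0
    beta, H, S, cumhaz, risk, w = aux

    if theta_hat > 0:
        var_beta = _penalized_variance(data, cl_sorted, m, beta, w, theta_hat)
        se = np.sqrt(np.diag(var_beta))
    else:
        se = np.sqrt(np.diag(np.linalg.inv(-H)))
    expected = cumhaz * risk * w[cl_sorted]
    inv = np.empty(data.n, dtype=int)
    inv[data.order] = np.arange(data.n)
    return CoxFit(
        names=list(names) if names is not None else [f"x{i}" for i in range(data.p)],
        coef=beta,
        se=se,
        theta=theta_hat,
        loglik=float(ll),
        iterations=state["iters"],
        converged=True,
        n=data.n,
        n_events=int(data.event.sum()),
        n_clusters=m,
        frailty=w,
        cluster_labels=labels,
        expected_events=expected[inv],
        event=data.event[inv],
    )


def score_test_two_group(time, event, group):
    """Cox partial-likelihood score test at beta=0 for a binary covariate.

    With untied event times this equals the log-rank chi-square exactly.
    Returns (statistic, two-sided p).
    """
    X = np.asarray(group, dtype=float).reshape(-1, 1)
    data = _CoxData(time, event, X)
    if data.event.sum() == 0:
        raise DegenerateGroupError("no events")
    _, grad, H, _ = data.loglik_grad_hess(np.zeros(1), np.zeros(data.n))
    info = -H[0, 0]
    if info <= 0:
        raise DegenerateGroupError("degenerate score-test information")
    stat = float(grad[0] ** 2 / info)
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# cohort-level interface


def build_design(
    df: pd.DataFrame, drop_race: bool = False, exclude_condition: str | None = None
):
    """Design matrix for the study's adjusted model.

    Columns: exposure, age (centered at the sample mean), male sex, race
    dummies (reference NH-White; omitted when ``drop_race``), comorbidity
    count (minus the defining condition's flag when ``exclude_condition``),
    rurality dummies (reference metro).  Constant columns (e.g. a rurality
    level absent from a small subgroup) are dropped and not reported.
    """
    cols = {}
    cols["exposed"] = df["exposed"].astype(float).to_numpy()
    age = df["age"].to_numpy(dtype=float)
    cols["age"] = age - age.mean()
    cols["male"] = (df["sex"] == "male").to_numpy(dtype=float)
    if not drop_race:
        for level, name in (
            ("NH-Black", "race_nh_black"),
            ("Hispanic", "race_hispanic"),
            ("Other", "race_other"),
        ):
            cols[name] = (df["race_ethnicity"] == level).to_numpy(dtype=float)
    count = df["n_comorbidities"].to_numpy(dtype=float)
    if exclude_condition is not None:
        count = count - df[exclude_condition].astype(float).to_numpy()
    cols["n_comorbidities"] = count
    for level, name in (("micro", "rurality_micro"), ("rural", "rurality_rural")):
        cols[name] = (df["rurality"] == level).to_numpy(dtype=float)
    names = [k for k, v in cols.items() if k == "exposed" or np.ptp(v) > 0]
    X = np.column_stack([cols[k] for k in names])
    return X, names


def fit_adjusted(
    df: pd.DataFrame,
    cluster_col: str = "area_id",
    drop_race: bool = False,
    exclude_condition: str | None = None,
    theta=None,
) -> CoxFit:
    """Adjusted frailty Cox fit on an analytic-cohort DataFrame."""
    X, names = build_design(df, drop_race=drop_race, exclude_condition=exclude_condition)
    return fit_cox_frailty(
        df["time_days"].to_numpy(dtype=float),
        df["event"].to_numpy(dtype=bool),
        X,
        df[cluster_col].to_numpy(),
        names=names,
        theta=theta,
    )


@dataclass(frozen=True)
class SubgroupSpec:
    """A named cohort stratum and its model adjustments."""

    name: str
    predicate: object  # callable DataFrame -> boolean mask
    drop_race: bool = False
    exclude_condition: str | None = None


def default_subgroups():
    """Overall plus the study's vulnerable strata.

    Condition subgroups keep the full covariate set but the defining flag is
    excluded from the comorbidity count; race subgroups drop race.
    """
    specs = [SubgroupSpec("overall", lambda d: np.ones(len(d), dtype=bool))]
    for cond in CONDITIONS:
        specs.append(
            SubgroupSpec(cond, (lambda c: lambda d: d[c].astype(bool).to_numpy())(cond),
                         exclude_condition=cond)
        )
    specs += [
        SubgroupSpec("aged_85_plus", lambda d: (d["age"] >= 85).to_numpy()),
        SubgroupSpec("dual_eligible", lambda d: d["dual_eligible"].astype(bool).to_numpy()),
        SubgroupSpec(
            "nh_black", lambda d: (d["race_ethnicity"] == "NH-Black").to_numpy(),
            drop_race=True,
        ),
        SubgroupSpec(
            "hispanic", lambda d: (d["race_ethnicity"] == "Hispanic").to_numpy(),
            drop_race=True,
        ),
    ]
    return specs


def subgroup_hrs(df: pd.DataFrame, specs=None, theta=None) -> pd.DataFrame:
    """Exposure HR table across subgroups (overall model shape).

    Under-populated or degenerate subgroups are reported with a skip reason
    rather than aborting the whole table.
    """
    if specs is None:
        specs = default_subgroups()
    rows = []
    for spec in specs:
        mask = np.asarray(spec.predicate(df), dtype=bool)
        sub = df[mask]
        note = ""
        if sub.empty or sub["event"].sum() < 1:
            note = "no events"
        elif sub["area_id"].nunique() < 2:
            note = "fewer than 2 clusters"
        elif sub["exposed"].astype(bool).nunique() < 2:
            note = "single exposure group"
        if note:
            rows.append({"subgroup": spec.name, "n": len(sub), "note": note})
            continue
        try:
            fit = fit_adjusted(
                sub,
                drop_race=spec.drop_race,
                exclude_condition=spec.exclude_condition,
                theta=theta,
            )
        except (ConvergenceError, ValidationError, DegenerateGroupError) as exc:
            rows.append({"subgroup": spec.name, "n": len(sub), "note": str(exc)})
            continue
        i = fit.names.index("exposed")
        rows.append(
            {
                "subgroup": spec.name,
                "n": fit.n,
                "events": fit.n_events,
                "hr": fit.hr[i],
                "ci_low": fit.ci_low[i],
                "ci_high": fit.ci_high[i],
                "theta": fit.theta,
                "converged": fit.converged,
                "note": "",
            }
        )
    return pd.DataFrame(rows)
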