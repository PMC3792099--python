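"""Semi-parametric regression on counting-process data.

A Cox model over delayed-entry risk sets is the workhorse for the pooled
treatment comparison: transplant subjects enter the risk set at their
transplant date with ``tx_state = 1``, non-transplant subjects span
``(0, t_end]`` with ``tx_state = 0``, all on the time-since-diagnosis
scale.  The single fitted coefficient is the "average" hazard ratio --
informative only under proportional hazards, which is exactly what the
time-varying machinery and the proportional-hazards test here interrogate.

Implementation notes: Breslow tie handling (the natural choice for
counting-process input), Newton-Raphson with step-halving to gradient
max-norm below ``tol``, baseline cumulative hazard by the Breslow
estimator at the covariate reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .stepfun import StepFunction

__all__ = [
    "CoxPH",
    "PHTestResult",
    "TimeVaryingEffect",
    "fit_cox",
    "fit_treatment_comparison",
    "fit_time_varying_effect",
    "test_proportional_hazards",
    "split_at_cutpoints",
]


class ConvergenceError(RuntimeError):
    pass


def _build_stratum(rows: pd.DataFrame, X: np.ndarray):
    entry = rows["entry"].to_numpy(dtype=float)
    exit_ = rows["exit"].to_numpy(dtype=float)
    status = rows["status"].to_numpy(dtype=int)
    if np.any(entry >= exit_):
        raise ValueError("need entry < exit for every at-risk interval")
    et = np.unique(exit_[status == 1])
    d = np.zeros(et.size)
    ev_idx = status == 1
    ev_pos = np.searchsorted(et, exit_[ev_idx])
    np.add.at(d, ev_pos, 1.0)
    s = np.zeros((et.size, X.shape[1]))
    np.add.at(s, ev_pos, X[ev_idx])
    lo = np.searchsorted(et, entry, side="right")
    hi = np.searchsorted(et, exit_, side="right")
    return {"X": X, "et": et, "d": d, "s": s, "lo": lo, "hi": hi,
            "ev_idx": np.flatnonzero(ev_idx), "ev_pos": ev_pos,
            "entry": entry, "exit": exit_, "status": status}


def _accumulate(st, beta):
    """S0, S1, S2 over the stratum's event-time grid at coefficient beta."""
    X, lo, hi = st["X"], st["lo"], st["hi"]
    m = st["et"].size
    p = X.shape[1]
    eta = X @ beta
    eta = eta - eta.max() if eta.size else eta  # guard overflow; cancels in ratios
    w = np.exp(eta)
    s0 = np.zeros(m + 1)
    np.add.at(s0, lo, w)
    np.add.at(s0, hi, -w)
    s0 = np.cumsum(s0)[:m]
    wX = w[:, None] * X
    s1 = np.zeros((m + 1, p))
    np.add.at(s1, lo, wX)
    np.add.at(s1, hi, -wX)
    s1 = np.cumsum(s1, axis=0)[:m]
    outer = wX[:, :, None] * X[:, None, :]
    s2 = np.zeros((m + 1, p, p))
    np.add.at(s2, lo, outer)
    np.add.at(s2, hi, -outer)
    s2 = np.cumsum(s2, axis=0)[:m]
    return s0, s1, s2, eta


def _loglik_parts(strata, beta):
    ll = 0.0
    p = len(beta)
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for st in strata:
        if st["et"].size == 0:
            continue
        s0, s1, s2, eta = _accumulate(st, beta)
        if np.any(s0 <= 0):
            raise ValueError("empty risk set at an event time (left-truncation gap)")
        d, s = st["d"], st["s"]
        ev = st["ev_idx"]
        ll += float(eta[ev].sum() - d @ np.log(s0))
        xbar = s1 / s0[:, None]
        grad += (s - d[:, None] * xbar).sum(axis=0)
        v = s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
        info += np.einsum("j,jkl->kl", d, v)
    return ll, grad, info


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model for delayed-entry counting processes.

    Parameters
    ----------
    covariates : list of str
        Column names used as regressors.  Rows with missing values in any
        of them are dropped (complete-case; the count is recorded).
    strata : str, optional
        Column defining separate baseline hazards (e.g. the transition id).
    tol : float
        Convergence tolerance on the max-norm of the score vector.
    """

    def __init__(self, covariates=None, strata=None, tol=1e-8, max_iter=50,
                 ci_level=0.95, ties="breslow"):
        self.covariates = covariates
        self.strata = strata
        self.tol = tol
        self.max_iter = max_iter
        self.ci_level = ci_level
        self.ties = ties

    # -- likelihood machinery -------------------------------------------------

    def _prepare(self, rows: pd.DataFrame):
        if not self.covariates:
            raise ValueError("covariates must be a non-empty list of columns")
        if self.ties != "breslow":
            raise ValueError("only Breslow tie handling is implemented")
        cols = list(self.covariates)
        use = rows.dropna(subset=cols)
        self.n_dropped_ = len(rows) - len(use)
        if len(use) == 0:
            raise ValueError("no complete-case rows left")
        for c in cols:
            if use[c].nunique() <= 1:
                raise ValueError(f"unidentifiable: covariate {c!r} is constant "
                                 "in the analysis set")
        groups = [use] if self.strata is None else [
            g for _, g in use.groupby(self.strata, sort=True)]
        strata = []
        for g in groups:
            X = g[cols].to_numpy(dtype=float)
            strata.append(_build_stratum(g, X))
        n_events = int(sum(st["d"].sum() for st in strata))
        if n_events < 1:
            raise ValueError("no events in the analysis set")
        return strata, cols, len(use), n_events

    def fit(self, rows: pd.DataFrame):
        strata, cols, n, n_events = self._prepare(rows)
        p = len(cols)
        beta = np.zeros(p)
        ll, grad, info = _loglik_parts(strata, beta)
        self.loglik_null_ = ll
        for _ in range(self.max_iter):
            if np.max(np.abs(grad)) < self.tol:
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as err:
                raise ConvergenceError(f"singular information matrix: {err}")
            # step-halving keeps the partial likelihood monotone; the slack
            # scales with |loglik| so noise-floor changes near the optimum
            # cannot shrink the Newton step to nothing
            slack = 1e-10 * (abs(ll) + 1.0)
            for half in range(40):
                cand = beta + step / (2 ** half)
                ll_new, grad_new, info_new = _loglik_parts(strata, cand)
                if ll_new >= ll - slack:
                    break
            else:
                raise ConvergenceError(
                    "step-halving failed to increase the partial likelihood "
                    f"(loglik {ll:.6g}, |grad| {np.max(np.abs(grad)):.3g})")
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            if np.max(np.abs(beta)) > 40:
                raise ConvergenceError(
                    "monotone partial likelihood (no finite optimum); a "
                    "covariate perfectly separates events, "
                    f"beta={dict(zip(cols, np.round(beta, 2)))}")
        if np.max(np.abs(grad)) >= max(self.tol, 1e-6):
            raise ConvergenceError(
                f"Newton did not converge in {self.max_iter} iterations "
                f"(|grad| = {np.max(np.abs(grad)):.3g})")
        if np.max(np.abs(beta)) > 15:
            # the score can vanish numerically while beta drifts to infinity
            raise ConvergenceError(
                "monotone partial likelihood (no finite optimum); a covariate "
                "perfectly separates events over the risk sets, "
                f"beta={dict(zip(cols, np.round(beta, 2)))}")

        cov = np.linalg.inv(info)
        cov = (cov + cov.T) / 2.0
        self.coef_ = pd.Series(beta, index=cols, name="coef")
        self.cov_ = pd.DataFrame(cov, index=cols, columns=cols)
        self.loglik_ = ll
        self.n_, self.n_events_ = n, n_events
        self._strata_data = strata
        self._beta = beta

        se = np.sqrt(np.diag(cov))
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        wald = beta / se
        self.summary_ = pd.DataFrame({
            "coef": beta, "se": se, "hr": np.exp(beta),
            "hr_lo": np.exp(beta - z * se), "hr_hi": np.exp(beta + z * se),
            "z": wald, "p": 2 * stats.norm.sf(np.abs(wald)),
        }, index=cols)

        self.baseline_cumhaz_ = self._baseline(strata, beta)
        return self

    def _baseline(self, strata, beta):
        curves = []
        for st in strata:
            if st["et"].size == 0:
                curves.append(None)
                continue
            s0 = _accumulate(st, beta)[0]
            # undo the overflow guard so the baseline refers to covariate zero
            c = float((st["X"] @ beta).max()) if st["X"].size else 0.0
            s0 = s0 * math.exp(c)
            inc = st["d"] / s0
            curves.append(StepFunction(
                knots=st["et"], values=np.cumsum(inc),
                variance=np.cumsum(st["d"] / s0 ** 2),
                kind="cumhaz", ci_level=self.ci_level,
                meta={"events": int(st["d"].sum())}))
        return curves[0] if self.strata is None else curves

    # -- quantities for PH diagnostics ---------------------------------------

    def schoenfeld_residuals(self):
        """Per-event (unscaled) Schoenfeld residuals and event times."""
        times, resid = [], []
        for st in self._strata_data:
            if st["et"].size == 0:
                continue
            s0, s1, _, _ = _accumulate(st, self._beta)
            xbar = s1 / s0[:, None]
            ev, pos = st["ev_idx"], st["ev_pos"]
            resid.append(st["X"][ev] - xbar[pos])
            times.append(st["exit"][ev])
        times = np.concatenate(times)
        resid = np.vstack(resid)
        order = np.argsort(times, kind="stable")
        return times[order], resid[order]

    def partial_loglik(self, beta) -> float:
        """Breslow partial log-likelihood at an arbitrary coefficient vector."""
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        return _loglik_parts(self._strata_data, beta)[0]


def fit_cox(rows: pd.DataFrame, covariates, strata=None, **kwargs) -> CoxPH:
    return CoxPH(covariates=list(covariates), strata=strata, **kwargs).fit(rows)


# -- proportional-hazards test ------------------------------------------------

@dataclass
class PHTestResult:
    """Score test for time-constant hazard ratios (scaled Schoenfeld
    residuals regressed on a monotone time transform)."""

    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    transform: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _km_transform(fit: CoxPH, times: np.ndarray) -> np.ndarray:
    """Left-continuous all-cause KM of the fitted sample at the event times."""
    from .nonparametric import KaplanMeierEstimator

    frames = []
    for st in fit._strata_data:
        frames.append(pd.DataFrame(
            {"entry": st["entry"], "exit": st["exit"], "status": st["status"]}))
    km = KaplanMeierEstimator().fit(pd.concat(frames, ignore_index=True))
    return np.asarray(km.survival_(times - 1e-9), dtype=float)


def test_proportional_hazards(fit: CoxPH, transform: str = "km") -> PHTestResult:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Under proportional hazards the residuals are uncorrelated with any time
    transform g(t); the score statistic per covariate and globally is
    chi-squared.  Default transform: left-continuous Kaplan-Meier of the
    event times, which is robust to heavy censoring.
    """
    if fit.n_events_ < 2:
        raise ValueError("proportional-hazards test needs >= 2 events")
    times, resid = fit.schoenfeld_residuals()
    m = resid.shape[0]
    if transform == "km":
        g = _km_transform(fit, times)
    elif transform == "rank":
        g = stats.rankdata(times, method="average")
    elif transform == "log":
        g = np.log(times)
    elif transform == "identity":
        g = times.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")
    gc = g - g.mean()
    ssg = float(gc @ gc)
    if ssg <= 0:
        raise ValueError("degenerate time transform (all event times equal)")
    V = fit.cov_.to_numpy()
    z = resid.T @ gc
    vz = V @ z
    global_stat = float(m * z @ vz / ssg)
    p = len(fit.coef_)
    rows = []
    for k, name in enumerate(fit.coef_.index):
        stat_k = m * vz[k] ** 2 / (V[k, k] * ssg)
        rows.append({"covariate": name, "chisq": stat_k, "df": 1,
                     "p": float(stats.chi2.sf(stat_k, 1))})
    return PHTestResult(
        statistic=global_stat, df=p,
        p_value=float(stats.chi2.sf(global_stat, p)),
        table=pd.DataFrame(rows).set_index("covariate"),
        transform=transform,
    )


# -- treatment comparison and time-varying effects ----------------------------

def fit_treatment_comparison(non_tx: pd.DataFrame, tx: pd.DataFrame,
                             adjust=(), **kwargs) -> CoxPH:
    """The pooled 'average hazard ratio' Cox model on the diagnosis scale.

    Transplant subjects enter the risk set at their transplant date with
    ``tx_state = 1``; non-transplant subjects are at risk from diagnosis
    with ``tx_state = 0``.  The single ``tx_state`` coefficient averages
    over follow-up time and is misleading whenever the hazard ratio varies
    -- which the PH test and :func:`fit_time_varying_effect` check.
    """
    from .events import assemble_multistate_dataset

    data = assemble_multistate_dataset(non_tx, tx, clock="forward")
    rows = data.comparison_rows
    return fit_cox(rows, ["tx_state", *adjust], **kwargs)


def split_at_cutpoints(rows: pd.DataFrame, cutpoints) -> pd.DataFrame:
    """Episode-split at-risk intervals at the given times (days).

    Each row is divided at every cutpoint it straddles; the event indicator
    moves to the final piece.  Adds an ``interval`` column indexing the
    partition (0 = before the first cutpoint).
    """
    cuts = sorted(float(c) for c in cutpoints)
    out = []
    for c_lo, c_hi, k in zip([0.0, *cuts], [*cuts, math.inf],
                             range(len(cuts) + 1)):
        seg = rows[(rows["entry"] < np.minimum(rows["exit"], c_hi))
                   & (rows["exit"] > c_lo)].copy()
        if len(seg) == 0:
            continue
        new_entry = np.maximum(seg["entry"].to_numpy(float), c_lo)
        new_exit = np.minimum(seg["exit"].to_numpy(float), c_hi)
        seg["status"] = np.where(seg["exit"] <= c_hi, seg["status"], 0)
        seg["entry"], seg["exit"] = new_entry, new_exit
        seg["interval"] = k
        out.append(seg)
    return pd.concat(out, ignore_index=True)


@dataclass
class TimeVaryingEffect:
    """Piecewise log hazard ratios plus a smoothed log-HR(t) curve."""

    cutpoints: tuple
    coef_table: pd.DataFrame       # one row per interval
    cov: pd.DataFrame
    smooth: pd.DataFrame           # time_days, loghr, lo, hi
    piecewise_fit: CoxPH
    overall_fit: CoxPH
    extra: dict = field(default_factory=dict)


def _local_linear(x, y, grid, bandwidth):
    """Gaussian-kernel local-linear regression with pointwise variance."""
    est = np.empty(grid.size)
    se = np.empty(grid.size)
    fitted = np.empty(x.size)
    # first pass at the data points to estimate the residual variance
    for i, x0 in enumerate(x):
        w = np.exp(-0.5 * ((x - x0) / bandwidth) ** 2)
        fitted[i] = _wls_at(x, y, w, x0)[0]
    dof = max(x.size - 2.0, 1.0)
    sigma2 = float(np.sum((y - fitted) ** 2)) / dof
    for i, x0 in enumerate(grid):
        w = np.exp(-0.5 * ((x - x0) / bandwidth) ** 2)
        a0, l = _wls_at(x, y, w, x0, return_weights=True)
        est[i] = a0
        se[i] = math.sqrt(sigma2 * float(l @ l))
    return est, se


def _wls_at(x, y, w, x0, return_weights=False):
    xc = x - x0
    s0, s1, s2 = w.sum(), (w * xc).sum(), (w * xc * xc).sum()
    denom = s0 * s2 - s1 * s1
    if denom <= 1e-300:
        l = w / max(s0, 1e-300)
    else:
        l = w * (s2 - xc * s1) / denom
    a0 = float(l @ y)
    return (a0, l) if return_weights else (a0,)


def fit_time_varying_effect(
    rows: pd.DataFrame,
    cutpoints=(91.0, 365.0),
    treatment: str = "tx_state",
    adjust=(),
    smooth_points: int = 80,
    bandwidth_frac: float = 0.4,
    ci_level: float = 0.95,
    **kwargs,
) -> TimeVaryingEffect:
    """Interval-specific treatment coefficients in a single Cox model.

    At-risk intervals are episode-split at the cutpoints (default 3 months
    and 1 year) and one treatment coefficient is fitted per interval; a
    smooth log-HR(t) curve with pointwise CI is obtained by local-linear
    kernel smoothing of the scaled Schoenfeld residuals on log time.
    """
    overall = fit_cox(rows, [treatment, *adjust], **kwargs)

    cuts = tuple(sorted(float(c) for c in cutpoints))
    if not cuts:
        table = pd.DataFrame({
            "interval": ["(0, inf)"],
            "lo_days": [0.0], "hi_days": [math.inf],
            "coef": [overall.coef_[treatment]],
            "se": [overall.summary_.loc[treatment, "se"]],
            "hr": [overall.summary_.loc[treatment, "hr"]],
        })
        piecewise = overall
        cov = overall.cov_
    else:
        split = split_at_cutpoints(rows, cuts)
        edges = [0.0, *cuts, math.inf]
        names = []
        for k in range(len(edges) - 1):
            ev_k = split[(split["interval"] == k) & (split["status"] == 1)]
            for grp in (0, 1):
                if (ev_k[treatment] == grp).sum() == 0:
                    raise ValueError(
                        f"interval ({edges[k]:g}, {edges[k + 1]:g}] days has no "
                        f"event in the {treatment}={grp} group")
            name = f"{treatment}_{k}"
            split[name] = split[treatment] * (split["interval"] == k)
            names.append(name)
        piecewise = fit_cox(split, [*names, *adjust], **kwargs)
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        table = pd.DataFrame({
            "interval": [f"({edges[k]:g}, {edges[k + 1]:g}]"
                         for k in range(len(names))],
            "lo_days": edges[:-1], "hi_days": edges[1:],
            "coef": piecewise.coef_[names].to_numpy(),
            "se": piecewise.summary_.loc[names, "se"].to_numpy(),
            "hr": piecewise.summary_.loc[names, "hr"].to_numpy(),
        })
        table["hr_lo"] = np.exp(table["coef"] - z * table["se"])
        table["hr_hi"] = np.exp(table["coef"] + z * table["se"])
        cov = piecewise.cov_

    # smoothed beta(t): scaled Schoenfeld residuals of the overall fit
    times, resid = overall.schoenfeld_residuals()
    m = resid.shape[0]
    k_tx = list(overall.coef_.index).index(treatment)
    rstar = overall.coef_[treatment] + m * (resid @ overall.cov_.to_numpy())[:, k_tx]
    logt = np.log(times)
    grid = np.linspace(logt.min(), logt.max(), smooth_points)
    bw = bandwidth_frac * (logt.max() - logt.min()) or 1.0
    est, se = _local_linear(logt, rstar, grid, bw)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    smooth = pd.DataFrame({
        "time_days": np.exp(grid), "loghr": est,
        "lo": est - z * se, "hi": est + z * se,
    })
    return TimeVaryingEffect(
        cutpoints=cuts, coef_table=table, cov=cov, smooth=smooth,
        piecewise_fit=piecewise, overall_fit=overall,
    )
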