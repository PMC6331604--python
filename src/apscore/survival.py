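"""Kaplan-Meier, log-rank with Mantel-Haenszel HR, and Cox regression.

Implemented from explicit formulas (not delegated) so every quantity the
evaluation layer reports — chi2, p, O/E, MH hazard ratio, Cox beta/SE — is
auditable.  Ties use the standard conventions: censored observations at an
event time are at risk through the event; Cox uses the Efron correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SurvivalError(ValueError):
    pass


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct event times, ascending
    surv: np.ndarray         # S(t) step values at event_times
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median_survival: float   # NaN if S never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    hr: float  # Mantel-Haenszel, group1 vs group2
    o1: float
    e1: float
    o2: float
    e2: float
    v: float


@dataclass
class CoxResult:
    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int
    message: str = ""

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "hr": self.hr,
                "se": self.se,
                "wald_p": self.wald_p,
            }
        )


def _validate_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise SurvivalError("empty survival input")
    if t.shape != e.shape:
        raise SurvivalError("times and events must align")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise SurvivalError("times must be finite and >= 0")
    if not np.all(np.isin(e, (0, 1))):
        raise SurvivalError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator over distinct event times."""
    t, e = _validate_surv(times, events)
    event_times = np.unique(t[e == 1])
    surv = np.empty(event_times.size)
    n_at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, tk in enumerate(event_times):
        nk = int(np.sum(t >= tk))  # censored at tk still at risk through the event
        dk = int(np.sum((t == tk) & (e == 1)))
        s *= 1.0 - dk / nk
        surv[i] = s
        n_at_risk[i] = nk
        n_events[i] = dk
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KMCurve(event_times, surv, n_at_risk, n_events, median)


def logrank_test(times1, events1, times2, events2) -> LogRankResult:
    """Two-group log-rank test with the Mantel-Haenszel hazard ratio.

    At each distinct event time k: e1_k = n1_k d_k / n_k and
    v_k = d_k (n1_k/n_k)(1 - n1_k/n_k)(n_k - d_k)/(n_k - 1); the variance
    contribution is skipped when n_k = 1.
    """
    t1, e1 = _validate_surv(times1, events1)
    t2, e2 = _validate_surv(times2, events2)
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.ones_like(t1), np.zeros_like(t2)])
    if e.sum() == 0:
        raise SurvivalError("no events in either group")
    o1 = exp1 = o2 = exp2 = var = 0.0
    for tk in np.unique(t[e == 1]):
        at_risk = t >= tk
        nk = at_risk.sum()
        n1k = (at_risk & (g == 1)).sum()
        dk = ((t == tk) & (e == 1)).sum()
        d1k = ((t == tk) & (e == 1) & (g == 1)).sum()
        o1 += d1k
        o2 += dk - d1k
        exp1 += dk * n1k / nk
        exp2 += dk * (nk - n1k) / nk
        if nk > 1:
            var += dk * (n1k / nk) * (1 - n1k / nk) * (nk - dk) / (nk - 1)
    if var == 0:
        raise SurvivalError("zero log-rank variance; groups cannot be compared")
    chi2 = (o1 - exp1) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    if o1 > 0 and o2 > 0 and exp1 > 0 and exp2 > 0:
        hr = (o1 / exp1) / (o2 / exp2)
    elif o1 == 0 and o2 > 0:
        hr = 0.0
    else:
        hr = float("inf")
    return LogRankResult(float(chi2), p, float(hr), float(o1), float(exp1),
                         float(o2), float(exp2), float(var))


def _cox_loglik_grad_hess(beta, t, e, X):
    """Efron-tie partial log-likelihood with analytic gradient and Hessian."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for tk in np.unique(t[e == 1]):
        risk = t >= tk
        dead = (t == tk) & (e == 1)
        d = int(dead.sum())
        wr = w[risk]
        Xr = X[risk]
        wd = w[dead]
        Xd = X[dead]
        s0 = wr.sum()
        s1 = Xr.T @ wr
        s2 = (Xr * wr[:, None]).T @ Xr
        d0 = wd.sum()
        d1 = Xd.T @ wd
        d2 = (Xd * wd[:, None]).T @ Xd
        ll += eta[dead].sum()
        grad += Xd.sum(axis=0)
        for l in range(d):
            f = l / d
            a0 = s0 - f * d0
            a1 = s1 - f * d1
            a2 = s2 - f * d2
            ll -= np.log(a0)
            grad -= a1 / a0
            hess -= a2 / a0 - np.outer(a1, a1) / a0**2
    return ll, grad, hess


def cox_fit(
    clinical_or_times,
    covariates: pd.DataFrame | np.ndarray,
    events=None,
    names: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson with Efron ties.

    Call either ``cox_fit(times, X, events)`` with arrays, or
    ``cox_fit(clinical_df, X)`` where ``clinical_df`` has ``os_days``/``event``
    columns and ``X`` is a DataFrame of numeric/0-1 covariates.
    """
    if isinstance(clinical_or_times, pd.DataFrame):
        df = clinical_or_times
        t = df["os_days"].to_numpy(float)
        e = df["event"].to_numpy(int)
    else:
        if events is None:
            raise SurvivalError("events required when passing raw times")
        t = np.asarray(clinical_or_times, dtype=float)
        e = np.asarray(events, dtype=int)
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    t, e = _validate_surv(t, e)
    if e.sum() == 0:
        raise SurvivalError("no events; Cox model undefined")
    if X.shape[0] != t.size:
        raise SurvivalError("covariate rows must match observations")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        raise SurvivalError(f"constant covariate(s): {[names[i] for i in np.nonzero(const)[0]]}")
    # center for numerical stability; beta unchanged
    Xc = X - X.mean(axis=0)

    beta = np.zeros(X.shape[1])
    converged = False
    message = ""
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, t, e, Xc)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # step-halving to keep the likelihood increasing
        new_beta = beta + step
        new_ll = _cox_loglik_grad_hess(new_beta, t, e, Xc)[0]
        halves = 0
        while new_ll < ll and halves < 10:
            step /= 2
            new_beta = beta + step
            new_ll = _cox_loglik_grad_hess(new_beta, t, e, Xc)[0]
            halves += 1
        beta = new_beta
        if np.max(np.abs(beta)) > 50:
            message = "monotone likelihood (possible perfect separation)"
            break
    else:
        message = "maximum iterations reached"
    ll, grad, hess = _cox_loglik_grad_hess(beta, t, e, Xc)
    if converged and np.max(np.abs(grad)) >= tol:
        converged = False
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    # a huge coefficient with an even larger SE is the signature of a
    # monotone likelihood: the score equation has no finite root
    runaway = (np.abs(beta) > 10) & (se > 100)
    if runaway.any():
        converged = False
        message = message or "monotone likelihood (possible perfect separation)"
    z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(z))
    return CoxResult(list(names), beta, se, wald_p, float(ll), converged, it, message)


def dichotomize_by_median(values) -> np.ndarray:
    """Labels 'high' (> median) / 'low' (<= median; ties low)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SurvivalError("need >= 2 values to dichotomize")
    if np.ptp(x) == 0:
        raise SurvivalError("all values identical; no median split")
    med = np.median(x)
    return np.where(x > med, "high", "low")
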