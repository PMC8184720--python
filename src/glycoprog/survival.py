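"""Core survival machinery.

Cox proportional-hazards fitting maximizes the Efron-tie-corrected partial
likelihood with a vectorized Newton-Raphson solver; the per-gene screening
stage runs tens of thousands of univariate fits, so the solver is written
directly on top of numpy suffix sums rather than a per-fit model object.
Wald inference is reported because the downstream meta-analysis consumes
(log HR, SE) pairs.

Kaplan-Meier curves and the two-group log-rank test delegate to lifelines.
The time-dependent AUC is the cumulative/dynamic (Heagerty-type) estimator:
cases are subjects with an observed event by the horizon, controls are
subjects still at risk after it, and cases are weighted by inverse
probability of censoring from a Kaplan-Meier estimate of the censoring
distribution evaluated at the left limit of the event time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration budget."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a Cox proportional-hazards fit (one entry per covariate)."""

    names: tuple[str, ...]
    log_hr: np.ndarray
    se_log_hr: np.ndarray
    n_samples: int
    n_events: int
    loglik: float

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def wald_z(self) -> np.ndarray:
        return self.log_hr / self.se_log_hr

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.names,
                "log_hr": self.log_hr,
                "se_log_hr": self.se_log_hr,
                "hr": self.hr,
                "wald_p": self.wald_p,
                "n": self.n_samples,
                "n_events": self.n_events,
            }
        )


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: steps at event times only."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def _as_covariate_matrix(covariates, names):
    if isinstance(covariates, pd.DataFrame):
        if names is None:
            names = tuple(str(c) for c in covariates.columns)
        covariates = covariates.to_numpy(dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(covariates.shape[1]))
    return covariates, tuple(names)


def _efron_quantities(beta, X, groups):
    """Log-likelihood, gradient and Hessian of the Efron partial likelihood.

    ``groups`` holds, per unique event time: the start index of its risk set
    in the time-ascending ordering, the row indices of the deaths, and the
    tie count d.  All risk-set sums are suffix sums in that ordering.
    """
    starts, death_idx, d, deaths_flat, l_over_d, l_mask = groups
    n, k = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums over the risk sets (time-ascending order)
    S_suf = np.cumsum(w[::-1])[::-1]
    U_suf = np.cumsum(wx[::-1], axis=0)[::-1]
    M_suf = np.cumsum(wxx[::-1], axis=0)[::-1]

    S_R = S_suf[starts]
    U_R = U_suf[starts]
    M_R = M_suf[starts]

    m = len(starts)
    S_D = np.zeros(m)
    U_D = np.zeros((m, k))
    M_D = np.zeros((m, k, k))
    np.add.at(S_D, death_idx[:, 0], w[death_idx[:, 1]])
    np.add.at(U_D, death_idx[:, 0], wx[death_idx[:, 1]])
    np.add.at(M_D, death_idx[:, 0], wxx[death_idx[:, 1]])

    # Efron correction: for the l-th of d tied deaths the denominator is
    # S_R - (l/d) S_D, l = 0..d-1; l_over_d is an (m, L) matrix with mask.
    phi = S_R[:, None] - l_over_d * S_D[:, None]          # (m, L)
    psi = U_R[:, None, :] - l_over_d[:, :, None] * U_D[:, None, :]   # (m, L, k)
    chi = M_R[:, None, :, :] - l_over_d[:, :, None, None] * M_D[:, None, :, :]

    loglik = float(eta[deaths_flat].sum() - np.log(phi[l_mask]).sum())
    ratio = psi[l_mask] / phi[l_mask][:, None]            # (n_terms, k)
    grad = X[deaths_flat].sum(axis=0) - ratio.sum(axis=0)
    hess = -(
        (chi[l_mask] / phi[l_mask][:, None, None]).sum(axis=0)
        - np.einsum("li,lj->ij", ratio, ratio)
    )
    return loglik, grad, hess


def _tie_groups(times, events):
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq, first = np.unique(t_sorted, return_index=True)
    starts, death_pairs, d = [], [], []
    g = 0
    for u, s in zip(uniq, first):
        stop = np.searchsorted(t_sorted, u, side="right")
        deaths = np.arange(s, stop)[e_sorted[s:stop] == 1]
        if len(deaths) == 0:
            continue
        starts.append(s)
        d.append(len(deaths))
        death_pairs.extend((g, i) for i in deaths)
        g += 1
    starts = np.asarray(starts, dtype=int)
    d = np.asarray(d, dtype=int)
    death_idx = np.asarray(death_pairs, dtype=int).reshape(-1, 2)
    deaths_flat = death_idx[:, 1]
    L = int(d.max())
    l_grid = np.arange(L)[None, :]
    l_mask = l_grid < d[:, None]
    l_over_d = np.where(l_mask, l_grid / d[:, None], 0.0)
    return order, (starts, death_idx, d, deaths_flat, l_over_d, l_mask)


def fit_cox(covariates, os_time, os_event, names=None, max_iter: int = 100, tol: float = 1e-9) -> CoxFit:
    """Fit a Cox proportional-hazards model (1..k covariates, Efron ties).

    Parameters
    ----------
    covariates : array-like (n,) or (n, k) or DataFrame
        Covariate values; a DataFrame contributes its column names.
    os_time, os_event : array-like
        Follow-up times (> 0) and event indicators (1 = death observed).
    """
    X, names = _as_covariate_matrix(covariates, names)
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    n, k = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("covariates, os_time and os_event must have equal length")
    if np.isnan(X).any() or np.isnan(t).any():
        raise ValueError("missing values are not allowed in a Cox fit")
    n_events = int(e.sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    for j in range(k):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate {names[j]!r} has no variation")

    order, groups = _tie_groups(t, e)
    Xs = X[order]

    beta = np.zeros(k)
    loglik, grad, hess = _efron_quantities(beta, Xs, groups)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular Hessian at beta={beta}") from err
        step = -step
        # step-halving line search on the partial likelihood
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            new_ll, new_g, new_h = _efron_quantities(candidate, Xs, groups)
            if new_ll >= loglik - 1e-12:
                break
            factor /= 2.0
        delta = factor * np.max(np.abs(step))
        beta, loglik, grad, hess = candidate, new_ll, new_g, new_h
        if np.max(np.abs(beta)) > 30.0:
            raise ConvergenceError(
                "partial likelihood appears monotone (separated groups): "
                f"|log HR| diverged past {np.max(np.abs(beta)):.1f}"
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last |step| = {delta:.3g}, loglik = {loglik:.6g})"
        )

    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    if not np.all(se > 0):
        raise ConvergenceError("non-positive standard error: information matrix not positive definite")
    return CoxFit(
        names=names,
        log_hr=beta,
        se_log_hr=se,
        n_samples=n,
        n_events=n_events,
        loglik=loglik,
    )


def _product_limit(times: np.ndarray, died: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with steps at 'died' times only."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    d_sorted = died[order]
    uniq = np.unique(t_sorted[d_sorted == 1])
    surv = []
    at_risk = []
    s = 1.0
    for u in uniq:
        n_risk = int(np.sum(t_sorted >= u))
        n_d = int(np.sum((t_sorted == u) & (d_sorted == 1)))
        s *= 1.0 - n_d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return SurvivalCurve(
        event_times=np.asarray(uniq, dtype=float),
        survival_prob=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
    )


def km_estimate(os_time, os_event) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function.

    Censored times shape the risk sets but do not create steps; with no
    events the curve is identically 1 (empty step arrays).
    """
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    if len(t) < 1:
        raise ValueError("km_estimate requires at least one sample")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.unique(t[e == 1])
    if len(event_times) == 0:
        return SurvivalCurve(np.array([]), np.array([]), np.array([], dtype=int))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([int(np.sum(t >= u)) for u in event_times])
    return SurvivalCurve(event_times=event_times, survival_prob=surv, at_risk=at_risk)


def logrank_test(os_time, os_event, group_labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p) with 1 df."""
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    g = np.asarray(group_labels)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"logrank_test requires exactly 2 groups, got {len(levels)}")
    mask = g == levels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("one group is empty")
    res = _lifelines_logrank(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


def censoring_survival(os_time, os_event) -> SurvivalCurve:
    """Kaplan-Meier estimate of the censoring distribution G(t) = P(C > t)."""
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    return _product_limit(t, 1 - e)


def time_dependent_auc(score, os_time, os_event, horizon_t: float) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW case weights.

    Cases: observed event at T <= t.  Controls: observed time > t (still at
    risk).  Case i is weighted by 1 / G(T_i-), the Kaplan-Meier censoring
    survival just before the event.  Tied scores receive half credit.  With
    no censoring before t, every weight is 1 and the value reduces to the
    ordinary AUC of the event-by-t indicator.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(os_time, dtype=float)
    e = np.asarray(os_event, dtype=int)
    if horizon_t <= 0:
        raise ValueError("horizon_t must be positive")
    cases = (t <= horizon_t) & (e == 1)
    controls = t > horizon_t
    if not cases.any():
        raise ValueError(f"no cases (events by t={horizon_t})")
    if not controls.any():
        raise ValueError(f"no controls (subjects at risk after t={horizon_t})")

    G = censoring_survival(t, e)
    # left limit: G just before each case's event time
    w = np.array([1.0 / _left_limit(G, ti) for ti in t[cases]])

    s_case = s[cases]
    s_ctrl = s[controls]
    # weighted concordance of case/control score pairs, half credit for ties
    greater = (s_case[:, None] > s_ctrl[None, :]).sum(axis=1)
    ties = (s_case[:, None] == s_ctrl[None, :]).sum(axis=1)
    num = float(np.sum(w * (greater + 0.5 * ties)))
    den = float(np.sum(w) * len(s_ctrl))
    return num / den


def _left_limit(curve: SurvivalCurve, t: float) -> float:
    """S(t-): value of the step function strictly before t."""
    idx = np.searchsorted(curve.event_times, t, side="left") - 1
    return 1.0 if idx < 0 else float(curve.survival_prob[idx])
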