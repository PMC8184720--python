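"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly from the defining formulas (explicit
loops, grid searches, enumerations) and never calls the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def cox_partial_loglik_binary(b: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Partial log-likelihood for a single covariate, distinct event times."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = time >= time[i]
        ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
    return ll


def grid_max_log_hr(x, time, event, lo=-5.0, hi=5.0) -> float:
    """Coarse-to-fine grid maximization of the partial likelihood."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    grid = np.arange(lo, hi + 1e-12, 0.01)
    vals = [cox_partial_loglik_binary(b, x, time, event) for b in grid]
    best = grid[int(np.argmax(vals))]
    fine = np.arange(best - 0.02, best + 0.02 + 1e-12, 1e-5)
    vals = [cox_partial_loglik_binary(b, x, time, event) for b in fine]
    return float(fine[int(np.argmax(vals))])


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = running_min
    return q


def logrank_chi2_by_risk_sets(time, event, group) -> float:
    """Two-group log-rank statistic as observed-minus-expected over risk sets."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    assert len(levels) == 2
    g1 = group == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1].tolist())):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def km_product_limit(time, event):
    """Hand product-limit curve: (event_times, survival)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    times, surv = [], []
    for t in sorted(set(time[event == 1].tolist())):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        times.append(t)
        surv.append(s)
    return np.array(times), np.array(surv)


def censoring_km_left(time, event, t_query) -> float:
    """G(t-): censoring-distribution KM evaluated just before t_query."""
    time = np.asarray(time, float)
    cens = 1 - np.asarray(event, int)
    g = 1.0
    for t in sorted(set(time[cens == 1].tolist())):
        if t >= t_query:
            break
        n = (time >= t).sum()
        d = ((time == t) & (cens == 1)).sum()
        g *= 1 - d / n
    return g


def ipcw_auc_pairs(score, time, event, horizon) -> float:
    """Brute-force IPCW weighted-pair cumulative/dynamic AUC."""
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    num = 0.0
    den = 0.0
    for i in range(len(time)):
        if not (time[i] <= horizon and event[i] == 1):
            continue
        w = 1.0 / censoring_km_left(time, event, time[i])
        for j in range(len(time)):
            if time[j] <= horizon:
                continue
            den += w
            if score[i] > score[j]:
                num += w
            elif score[i] == score[j]:
                num += 0.5 * w
    return num / den


def ssgsea_running_sum(expr_column, gene_ids, member_set, alpha) -> float:
    """Brute-force single-sample enrichment: explicit ECDF running sum.

    Average ascending ranks for ties; walk genes in decreasing rank order
    (gene id breaks ties); accumulate weighted in-set ECDF minus out-of-set
    ECDF.
    """
    expr_column = np.asarray(expr_column, float)
    n = len(expr_column)
    # average ascending ranks
    ranks = np.empty(n)
    for i in range(n):
        less = np.sum(expr_column < expr_column[i])
        eq = np.sum(expr_column == expr_column[i])
        ranks[i] = less + (eq + 1) / 2.0
    order = sorted(range(n), key=lambda i: (-ranks[i], gene_ids[i]))
    in_set = [gene_ids[i] in member_set for i in order]
    w = [ranks[i] ** alpha if gene_ids[i] in member_set else 0.0 for i in order]
    total_w = sum(w)
    n_out = sum(1 for m in in_set if not m)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for k in range(n):
        cum_in += w[k] / total_w
        cum_out += (0 if in_set[k] else 1) / n_out
        es += cum_in - cum_out
    return es


def mann_whitney_u(a, b) -> float:
    """U statistic of group a by direct pair counting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


def logistic_normal_auc(intercept: float, slope: float, tau: float, n_grid: int = 40001) -> float:
    """AUC of eta ~ N(0, tau^2) as a score for Bernoulli(logistic(a + b eta)).

    Dense-grid numeric integration of P(eta_pos > eta_neg).
    """
    grid = np.linspace(-8 * tau, 8 * tau, n_grid)
    dx = grid[1] - grid[0]
    phi = np.exp(-0.5 * (grid / tau) ** 2)
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * grid)))
    f1 = phi * p
    f0 = phi * (1 - p)
    f1 /= f1.sum() * dx
    f0 /= f0.sum() * dx
    F0 = np.cumsum(f0) * dx
    return float(np.sum(f1 * (F0 - 0.5 * f0 * dx)) * dx)
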