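"""Weighted estimators for the three effect measures.

All estimators consume counting-process analysis rows — one
``(start, stop]`` interval per subject with an event indicator at ``stop``,
the exposure ``group`` (0/1), and a non-negative analysis ``weight`` — and
target marginal contrasts: the outcome models contain the exposure term only,
with confounding handled entirely through the weights.

* risk ratio: complement of the weighted Kaplan-Meier (product-limit)
  survival estimator in each group, at a fixed horizon;
* hazard ratio: weighted Cox partial likelihood (Breslow ties), maximized by
  Newton-Raphson on the scalar exposure coefficient, robust sandwich SE;
* incidence rate ratio: weighted Poisson regression of events on exposure
  with a log person-time offset, fitted by generic IRLS (the two-parameter
  closed form exists and is used to validate the IRLS, not to replace it).

Risk sets are open on the left: a row is at risk at time u iff
``start < u <= stop``, so a subject late-entering at ``t - 0.001`` is at risk
at its own event time ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EstimateResult",
    "EstimatorError",
    "NonFiniteMLEError",
    "weighted_km_risk",
    "rr_at",
    "fit_weighted_cox",
    "fit_weighted_poisson",
    "robust_sandwich",
]


class EstimatorError(ValueError):
    """The estimator is undefined on these inputs."""


class NonFiniteMLEError(EstimatorError):
    """Monotone likelihood: the maximizer is not finite."""


@dataclass
class EstimateResult:
    """A fitted effect estimate on the log scale."""

    estimand: str                      # "RR" | "HR" | "IRR"
    log_estimate: float
    se: float | None = None
    variance_method: str = "none"      # "robust" | "bootstrap" | "model" | "meta" | "none"
    horizon: float | None = None       # RR only
    n_members: int = 0
    n_events: dict = field(default_factory=dict)   # {"unweighted": int, "weighted": float}
    fit: object = field(default=None, repr=False)

    @property
    def estimate(self) -> float:
        return float(np.exp(self.log_estimate))


def _as_arrays(rows: pd.DataFrame):
    start = rows["start"].to_numpy(dtype=float)
    stop = rows["stop"].to_numpy(dtype=float)
    event = rows["event"].to_numpy(dtype=float)
    w = rows["weight"].to_numpy(dtype=float)
    if (stop <= start).any():
        raise EstimatorError("analysis rows must satisfy stop > start")
    if (w < 0).any():
        raise EstimatorError("analysis weights must be >= 0")
    return start, stop, event, w


def _riskset_weight_fn(start: np.ndarray, stop: np.ndarray, w: np.ndarray):
    """Return f(u) = total weight at risk at each time in u (start < u <= stop),
    vectorized over sorted or unsorted u, in O(n log n)."""
    s_stop = np.sort(stop)
    o = np.argsort(start)
    s_start = start[o]
    cw_stop = np.concatenate([[0.0], np.cumsum(w[np.argsort(stop)])])
    cw_start = np.concatenate([[0.0], np.cumsum(w[o])])
    tot = cw_stop[-1]

    def at(u: np.ndarray) -> np.ndarray:
        ge_stop = tot - cw_stop[np.searchsorted(s_stop, u, side="left")]
        ge_start = tot - cw_start[np.searchsorted(s_start, u, side="left")]
        return ge_stop - ge_start

    return at


def _event_table(stop, event, w, xvals=None):
    """Distinct event times with weighted event totals (and x-weighted totals)."""
    mask = event > 0
    times = stop[mask]
    order = np.argsort(times)
    times = times[order]
    u, idx = np.unique(times, return_index=True)
    seg = np.searchsorted(times, u, side="left")
    d_w = np.add.reduceat(w[mask][order], seg) if len(u) else np.empty(0)
    if xvals is None:
        return u, d_w
    dx_w = np.add.reduceat((w * xvals)[mask][order], seg) if len(u) else np.empty(0)
    return u, d_w, dx_w


# ---------------------------------------------------------------------------
# Kaplan-Meier complement

def _km_risk(start, stop, event, w, t: float) -> float:
    u, d_w = _event_table(stop, event, w)
    keep = u <= t
    u, d_w = u[keep], d_w[keep]
    if len(u) == 0:
        return 0.0
    n_w = _riskset_weight_fn(start, stop, w)(u)
    if (n_w <= 0).any():
        bad = u[n_w <= 0][0]
        raise EstimatorError(f"product-limit estimator undefined: no weight at risk at event time {bad}")
    surv = float(np.prod(1.0 - d_w / n_w))
    return 1.0 - surv


def weighted_km_risk(rows: pd.DataFrame, t: float) -> float:
    """Weighted cumulative risk by ``t`` for one exposure group:
    ``1 - prod over event times u <= t of (1 - d_w(u) / n_w(u))`` with
    weighted event mass ``d_w`` and weighted number-at-risk ``n_w``
    (late entry supported).  Invariant to rescaling all weights."""
    if len(rows) == 0:
        raise EstimatorError("empty analysis rows")
    if t <= 0:
        raise EstimatorError("horizon must be > 0")
    return _km_risk(*_as_arrays(rows), t)


def rr_at(rows_exposed: pd.DataFrame, rows_unexposed: pd.DataFrame, t: float) -> EstimateResult:
    """Risk ratio at horizon ``t``: exposed over unexposed KM-complement risks.

    The SE is not computed here; the design-aware nonparametric bootstrap
    supplies it (see :mod:`cohortsampling.variance`)."""
    risk1 = weighted_km_risk(rows_exposed, t)
    risk0 = weighted_km_risk(rows_unexposed, t)
    if risk1 == 0.0 or risk0 == 0.0:
        raise EstimatorError(f"risk is zero at t={t} in one group; log RR undefined")
    n_ev = int(rows_exposed["event"].sum() + rows_unexposed["event"].sum())
    w_ev = float((rows_exposed["event"] * rows_exposed["weight"]).sum()
                 + (rows_unexposed["event"] * rows_unexposed["weight"]).sum())
    return EstimateResult(
        estimand="RR", log_estimate=float(np.log(risk1 / risk0)), se=None,
        variance_method="none", horizon=float(t),
        n_members=len(rows_exposed) + len(rows_unexposed),
        n_events={"unweighted": n_ev, "weighted": w_ev},
    )


# ---------------------------------------------------------------------------
# Weighted Cox partial likelihood (single binary covariate, Breslow ties)

@dataclass
class CoxFit:
    beta: float
    loglik: float
    information: float
    score: float
    converged: bool
    n_iter: int
    # ingredients for the sandwich
    event_times: np.ndarray = field(repr=False, default=None)
    d_w: np.ndarray = field(repr=False, default=None)
    w0_at: np.ndarray = field(repr=False, default=None)   # unexposed riskset weight at u
    w1_at: np.ndarray = field(repr=False, default=None)   # exposed riskset weight at u
    start: np.ndarray = field(repr=False, default=None)
    stop: np.ndarray = field(repr=False, default=None)
    event: np.ndarray = field(repr=False, default=None)
    x: np.ndarray = field(repr=False, default=None)
    w: np.ndarray = field(repr=False, default=None)

    @property
    def model_variance(self) -> float:
        return 1.0 / self.information


_COX_MAX_ABS_BETA = 50.0


def _cox_newton(start, stop, event, x, w, tol: float = 1e-9, max_iter: int = 50) -> CoxFit:
    xv = np.unique(x)
    if not np.all(np.isin(xv, [0.0, 1.0])):
        raise EstimatorError("exposure group must be coded 0/1")
    u, d_w, dx_w = _event_table(stop, event, w, xvals=x)
    if len(u) == 0:
        raise EstimatorError("no events; hazard ratio undefined")
    g1 = x == 1.0
    w1_at = _riskset_weight_fn(start[g1], stop[g1], w[g1])(u) if g1.any() else np.zeros_like(u)
    g0 = ~g1
    w0_at = _riskset_weight_fn(start[g0], stop[g0], w[g0])(u) if g0.any() else np.zeros_like(u)
    sum_dx = float(dx_w.sum())

    # monotone-likelihood pre-check: the partial-likelihood score at beta ->
    # -inf is sum_dx - sum(d_w where only exposed are at risk); at +inf it is
    # sum_dx - sum(d_w where any exposed is at risk); a finite maximizer
    # needs the score to change sign between the limits
    lo = float(d_w[w0_at <= 0].sum())
    hi = float(d_w[w1_at > 0].sum())
    if not lo < sum_dx < hi:
        raise NonFiniteMLEError("non-finite MLE: all events ordered within one group")

    def loglik_score_info(beta: float):
        eb = np.exp(beta)
        s0 = w0_at + eb * w1_at
        p = eb * w1_at / s0
        ll = beta * sum_dx - float(d_w @ np.log(s0))
        score = sum_dx - float(d_w @ p)
        info = float(d_w @ (p * (1.0 - p)))
        return ll, score, info

    beta = 0.0
    ll, score, info = loglik_score_info(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if info <= 0:
            raise NonFiniteMLEError("non-finite MLE: zero partial-likelihood information")
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = loglik_score_info(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = loglik_score_info(new_beta)
            halvings += 1
        if abs(new_beta) > _COX_MAX_ABS_BETA:
            raise NonFiniteMLEError("non-finite MLE: all events ordered within one group")
        delta_ll = abs(new_ll - ll)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if delta_ll <= tol * max(abs(ll), 1e-12):
            converged = True
            break
    return CoxFit(beta=beta, loglik=ll, information=info, score=score, converged=converged,
                  n_iter=it, event_times=u, d_w=d_w, w0_at=w0_at, w1_at=w1_at,
                  start=start, stop=stop, event=event, x=x, w=w)


def _cox_score_residuals(fit: CoxFit) -> np.ndarray:
    """Per-row weighted score residuals at the MLE (martingale form)."""
    eb = np.exp(fit.beta)
    s0 = fit.w0_at + eb * fit.w1_at
    m = eb * fit.w1_at / s0           # weighted mean covariate in the risk set
    dlam = fit.d_w / s0               # Breslow hazard increments
    cum_a = np.concatenate([[0.0], np.cumsum(dlam)])
    cum_b = np.concatenate([[0.0], np.cumsum(m * dlam)])
    u = fit.event_times

    def prefix(arr, t):
        return arr[np.searchsorted(u, t, side="right")]

    a_int = prefix(cum_a, fit.stop) - prefix(cum_a, fit.start)
    b_int = prefix(cum_b, fit.stop) - prefix(cum_b, fit.start)
    idx = np.searchsorted(u, fit.stop)
    idx = np.clip(idx, 0, len(u) - 1)
    m_at_event = m[idx]
    term_event = fit.event * (fit.x - m_at_event)
    term_comp = np.exp(fit.beta * fit.x) * (fit.x * a_int - b_int)
    return fit.w * (term_event - term_comp)


def fit_weighted_cox(rows: pd.DataFrame, variance: str = "robust") -> EstimateResult:
    """Weighted Cox partial-likelihood estimate of the log hazard ratio.

    Breslow handling of ties; counting-process risk sets (late entry
    supported); Newton-Raphson with step halving, converged when the relative
    log-likelihood change is below 1e-9 (max 50 iterations).  ``variance``:
    "robust" (sandwich, subjects as clusters), "model" (inverse information),
    or "none".
    """
    start, stop, event, w = _as_arrays(rows)
    x = rows["group"].to_numpy(dtype=float)
    fit = _cox_newton(start, stop, event, x, w)
    se = None
    if variance == "robust":
        var = robust_sandwich(fit, cluster_ids=rows["id"].to_numpy())
        se = float(np.sqrt(var))
    elif variance == "model":
        se = float(np.sqrt(fit.model_variance))
    elif variance != "none":
        raise ValueError(f"unknown variance method {variance!r}")
    return EstimateResult(
        estimand="HR", log_estimate=float(fit.beta), se=se,
        variance_method=variance, n_members=rows["id"].nunique(),
        n_events={"unweighted": int(event.sum()), "weighted": float((event * w).sum())},
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Weighted Poisson regression with person-time offset

@dataclass
class PoissonFit:
    beta: np.ndarray
    cov_model: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    design: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    mu: np.ndarray = field(repr=False, default=None)
    w: np.ndarray = field(repr=False, default=None)


def _poisson_irls(design, y, offset, w, tol: float = 1e-8, max_iter: int = 100) -> PoissonFit:
    sw_y = float(w @ y)
    sw_pt = float(w @ np.exp(offset))
    beta = np.zeros(design.shape[1])
    beta[0] = np.log(sw_y / sw_pt) if sw_y > 0 else -10.0
    eta = design @ beta + offset
    mu = np.exp(eta)
    ll = float(w @ (y * eta - mu))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = design.T @ (w * (y - mu))
        hess = design.T @ (design * (w * mu)[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimatorError("singular information matrix in Poisson IRLS") from exc
        new_beta = beta + step
        new_eta = design @ new_beta + offset
        new_mu = np.exp(new_eta)
        new_ll = float(w @ (y * new_eta - new_mu))
        halvings = 0
        while not np.isfinite(new_ll) or (new_ll < ll and halvings < 30):
            step /= 2.0
            new_beta = beta + step
            new_eta = design @ new_beta + offset
            new_mu = np.exp(new_eta)
            new_ll = float(w @ (y * new_eta - new_mu))
            halvings += 1
        delta_ll = abs(new_ll - ll)
        beta, eta, mu, ll = new_beta, new_eta, new_mu, new_ll
        if delta_ll <= tol * max(abs(ll), 1e-12):
            converged = True
            break
    hess = design.T @ (design * (w * mu)[:, None])
    cov_model = np.linalg.inv(hess)
    return PoissonFit(beta=beta, cov_model=cov_model, loglik=ll, converged=converged,
                      n_iter=it, design=design, y=y, mu=mu, w=w)


def fit_weighted_poisson(rows: pd.DataFrame, variance: str = "robust") -> EstimateResult:
    """Weighted Poisson regression of events on exposure with a
    log(person-time) offset; person-time is ``stop - start`` per row.

    The coefficient on exposure is the log incidence rate ratio.  ``variance``:
    "robust" (sandwich, subjects as clusters), "model", or "none".  Robust
    Poisson SEs can behave poorly under case-cohort sampling; the bootstrap
    alternative lives in :mod:`cohortsampling.variance`.
    """
    start, stop, event, w = _as_arrays(rows)
    x = rows["group"].to_numpy(dtype=float)
    pt = stop - start
    for g in (0.0, 1.0):
        mask = x == g
        if float(w[mask] @ pt[mask]) <= 0:
            raise EstimatorError(f"zero weighted person-time in group {int(g)}")
        if float(w[mask] @ event[mask]) <= 0:
            raise EstimatorError(f"zero weighted events in group {int(g)}; log IRR undefined")
    design = np.column_stack([np.ones_like(x), x])
    fit = _poisson_irls(design, event, np.log(pt), w)
    se = None
    if variance == "robust":
        cov = robust_sandwich(fit, cluster_ids=rows["id"].to_numpy())
        se = float(np.sqrt(cov[1, 1]))
    elif variance == "model":
        se = float(np.sqrt(fit.cov_model[1, 1]))
    elif variance != "none":
        raise ValueError(f"unknown variance method {variance!r}")
    return EstimateResult(
        estimand="IRR", log_estimate=float(fit.beta[1]), se=se,
        variance_method=variance, n_members=rows["id"].nunique(),
        n_events={"unweighted": int(event.sum()), "weighted": float((event * w).sum())},
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Robust sandwich variance

def _cluster_sum(scores: np.ndarray, cluster_ids) -> np.ndarray:
    if cluster_ids is None:
        return scores
    _, codes = np.unique(np.asarray(cluster_ids), return_inverse=True)
    if scores.ndim == 1:
        return np.bincount(codes, weights=scores)
    return np.column_stack(
        [np.bincount(codes, weights=scores[:, j]) for j in range(scores.shape[1])]
    )


def robust_sandwich(fit, cluster_ids=None):
    """Cluster-robust sandwich covariance ``A^{-1} B A^{-1}``.

    ``A`` is the weighted observed information at the MLE and ``B`` the sum
    over clusters of outer products of summed weighted score contributions
    (score residuals for the Cox fit).  Each subject is one cluster; with no
    ``cluster_ids`` every row is its own cluster (identical to singleton
    clusters of unrelated rows).

    Returns a scalar variance for :class:`CoxFit` and a covariance matrix for
    :class:`PoissonFit`.
    """
    if isinstance(fit, CoxFit):
        resid = _cox_score_residuals(fit)
        u = _cluster_sum(resid, cluster_ids)
        b = float(u @ u)
        if fit.information <= 0:
            raise EstimatorError("singular information in sandwich")
        return b / fit.information ** 2
    if isinstance(fit, PoissonFit):
        scores = fit.design * (fit.w * (fit.y - fit.mu))[:, None]
        s = _cluster_sum(scores, cluster_ids)
        b = s.T @ s
        return fit.cov_model @ b @ fit.cov_model
    raise TypeError(f"unsupported fit type {type(fit).__name__}")
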