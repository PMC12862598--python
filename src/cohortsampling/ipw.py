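"""Stabilized inverse-probability-of-treatment weights under sampling designs.

The exposure (propensity) model is a logistic regression of exposure on
sex, a cubic B-spline in age with 2 interior knots, race/ethnicity, state,
and enrollment period, maximized by iteratively reweighted least squares.
Under a sampling design, the model is weighted by the inverse sampling
probability ``1/pi`` so it estimates the full-cohort propensity; in
case-cohort designs every subject appears once (non-subcohort cases carry
design weight 1), so fitting on the members *is* fitting on unique
individuals.

The stabilized weight for a subject with exposure ``a`` and covariates ``L``
is ``P(A=a) / P(A=a|L)`` with the numerator the sampling-weighted marginal
prevalence, and the analysis weight composes it with the design:
``analysis_weight = ipw / pi``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import qr
from scipy.special import expit

from .cohort import CategoryLevels

__all__ = [
    "SplineSpec",
    "PropensityModel",
    "LogisticFit",
    "SeparationError",
    "AliasingError",
    "age_spline_basis",
    "default_age_knots",
    "exposure_design_matrix",
    "fit_weighted_logistic",
    "fit_exposure_model",
    "stabilized_ipw",
    "weight_diagnostics",
]

logger = logging.getLogger(__name__)

WEIGHT_SET_COLUMNS = ("id", "ipw", "sampling_prob", "analysis_weight")


class SeparationError(ValueError):
    """Perfect separation: fitted exposure probabilities degenerate.

    Consider coarsening sparse covariate levels."""


class AliasingError(ValueError):
    """The design matrix is rank deficient; the message names aliased terms."""


@dataclass(frozen=True)
class SplineSpec:
    """Cubic B-spline basis definition for the age term."""

    knots: tuple[float, float]          # interior knots, strictly increasing
    boundary: tuple[float, float]       # (min, max) of the modeled age range

    def __post_init__(self):
        lo, hi = self.boundary
        if not all(lo < k < hi for k in self.knots):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if len(self.knots) >= 2 and not np.all(np.diff(self.knots) > 0):
            raise ValueError("interior knots must be strictly increasing")


def default_age_knots(age: np.ndarray, weights: np.ndarray | None = None) -> SplineSpec:
    """Interior knots at the 33.3rd and 66.7th (weighted) percentiles of age,
    boundary knots at the observed min/max."""
    age = np.asarray(age, dtype=float)
    if weights is None:
        k1, k2 = np.percentile(age, [100 / 3, 200 / 3])
    else:
        order = np.argsort(age)
        cw = np.cumsum(np.asarray(weights, dtype=float)[order])
        cw /= cw[-1]
        k1, k2 = np.interp([1 / 3, 2 / 3], cw, age[order])
    return SplineSpec(knots=(float(k1), float(k2)), boundary=(float(age.min()), float(age.max())))


def age_spline_basis(age, spec: SplineSpec) -> np.ndarray:
    """Evaluate the cubic B-spline basis (2 interior knots → 6 columns).

    The columns form a partition of unity and are C² at the knots.  Ages
    outside the boundary-knot range are clamped to the boundary with a logged
    warning (the basis is extrapolation-free).
    """
    age = np.asarray(age, dtype=float)
    lo, hi = spec.boundary
    outside = (age < lo) | (age > hi)
    if outside.any():
        logger.warning("clamping %d age value(s) outside [%g, %g] to the boundary",
                       int(outside.sum()), lo, hi)
        age = np.clip(age, lo, hi)
    t = np.concatenate([[lo] * 4, list(spec.knots), [hi] * 4])
    return BSpline.design_matrix(age, t, k=3, extrapolate=False).toarray()


def exposure_design_matrix(
    cohort: pd.DataFrame,
    levels: CategoryLevels | None = None,
    spline: SplineSpec | None = None,
    sample_weights: np.ndarray | None = None,
):
    """Build (X, term_names, spline_spec) for the exposure model.

    Columns: intercept; sex (male); age spline (first basis column dropped —
    redundant with the intercept by partition of unity); race, state, period
    dummies with the first level as reference.
    """
    levels = levels or CategoryLevels()
    n = len(cohort)
    age = cohort["age"].to_numpy(dtype=float)
    if spline is None:
        spline = default_age_knots(age, sample_weights)
    basis = age_spline_basis(age, spline)[:, 1:]

    cols = [np.ones(n), (cohort["sex"].to_numpy() == levels.sex[1]).astype(float)]
    names = ["intercept", f"sex[{levels.sex[1]}]"]
    for j in range(basis.shape[1]):
        cols.append(basis[:, j])
        names.append(f"age_spline[{j + 1}]")
    for col, lev in (("race", levels.race), ("state", levels.state), ("period", levels.period)):
        vals = cohort[col].to_numpy()
        for level in lev[1:]:
            cols.append((vals == level).astype(float))
            names.append(f"{col}[{level}]")
    return np.column_stack(cols), names, spline


@dataclass
class PropensityModel:
    """A fitted (sampling-weighted) logistic exposure model."""

    coefficients: np.ndarray
    term_names: list[str]
    spline: SplineSpec
    levels: CategoryLevels
    converged: bool
    n_iter: int
    grad_norm: float
    weighted_prevalence: float     # 1/pi-weighted marginal P(A=1)

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        x, _, _ = exposure_design_matrix(cohort, self.levels, self.spline)
        return expit(x @ self.coefficients)


def _diagnose_aliasing(x: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


@dataclass
class LogisticFit:
    """A weighted logistic fit on an explicit design matrix."""

    beta: np.ndarray
    fitted: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float


def fit_weighted_logistic(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximize the weighted binomial log-likelihood by IRLS (Newton with
    step halving); converged when the relative log-likelihood change drops
    below ``tol``.  Raises :class:`AliasingError` on rank deficiency (naming
    the aliased columns) and :class:`SeparationError` when the fitted
    probabilities degenerate with diverging coefficients."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    names = names or [f"x{j}" for j in range(x.shape[1])]

    p_bar = float(w @ y / w.sum())
    beta = np.zeros(x.shape[1])
    if 0.0 < p_bar < 1.0 and np.all(x[:, 0] == 1.0):
        beta[0] = np.log(p_bar / (1.0 - p_bar))
    mu = expit(x @ beta)

    def loglik(mu_):
        m = np.clip(mu_, 1e-300, 1 - 1e-16)
        return float(w @ (y * np.log(m) + (1 - y) * np.log1p(-m)))

    ll = loglik(mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = x.T @ (w * (y - mu))
        wt = w * mu * (1 - mu)
        hess = x.T @ (x * wt[:, None])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            aliased = _diagnose_aliasing(x * np.sqrt(w)[:, None], names)
            raise AliasingError(
                f"rank-deficient design; aliased term(s): {', '.join(aliased) or 'unknown'}"
            ) from None
        new_beta = beta + step
        new_mu = expit(x @ new_beta)
        new_ll = loglik(new_mu)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_mu = expit(x @ new_beta)
            new_ll = loglik(new_mu)
            halvings += 1
        delta_ll = abs(new_ll - ll)
        beta, mu, ll = new_beta, new_mu, new_ll
        if delta_ll <= tol * max(abs(ll), 1e-12):
            converged = True
            break

    saturated = (mu < 1e-10) | (mu > 1 - 1e-10)
    if saturated.any() and np.abs(beta).max() > 30:
        raise SeparationError(
            "perfect separation in the logistic model; consider coarsening covariates"
        )
    grad_norm = float(np.abs(x.T @ (w * (y - mu))).max())
    return LogisticFit(beta=beta, fitted=mu, loglik=ll, converged=converged,
                       n_iter=it, grad_norm=grad_norm)


def fit_exposure_model(
    cohort: pd.DataFrame,
    sampling_probs: np.ndarray | None = None,
    levels: CategoryLevels | None = None,
    spline: SplineSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> PropensityModel:
    """Fit the ``1/pi``-weighted logistic exposure model on
    sex + spline(age) + race + state + period (see
    :func:`exposure_design_matrix`) via :func:`fit_weighted_logistic`."""
    levels = levels or CategoryLevels()
    a = cohort["exposure"].to_numpy(dtype=float)
    if a.min() == a.max():
        raise ValueError("both exposure groups must be present")
    if sampling_probs is None:
        w = np.ones(len(cohort))
    else:
        pi = np.asarray(sampling_probs, dtype=float)
        if (pi <= 0).any() or (pi > 1).any():
            raise ValueError("sampling probabilities must be in (0, 1]")
        w = 1.0 / pi

    x, names, spline = exposure_design_matrix(cohort, levels, spline, sample_weights=w)
    fit = fit_weighted_logistic(x, a, w, names=names, tol=tol, max_iter=max_iter)
    return PropensityModel(
        coefficients=fit.beta, term_names=names, spline=spline, levels=levels,
        converged=fit.converged, n_iter=fit.n_iter, grad_norm=fit.grad_norm,
        weighted_prevalence=float(w @ a / w.sum()),
    )


def stabilized_ipw(
    cohort: pd.DataFrame,
    model: PropensityModel,
    sampling_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weight set with columns ``(id, ipw, sampling_prob, analysis_weight)``.

    ``ipw = P(A=a) / P(A=a|L)`` with the sampling-weighted marginal
    prevalence in the numerator and the model's fitted value in the
    denominator; ``analysis_weight = ipw / sampling_prob`` exactly.
    """
    if not model.converged:
        raise ValueError("exposure model did not converge; refusing to build weights")
    a = cohort["exposure"].to_numpy(dtype=float)
    phat = model.predict_proba(cohort)
    if ((phat == 0.0) & (a == 1.0)).any() or ((phat == 1.0) & (a == 0.0)).any():
        raise ValueError("fitted exposure probability of 0/1 for an observed subject")
    p_num = np.where(a == 1.0, model.weighted_prevalence, 1.0 - model.weighted_prevalence)
    p_den = np.where(a == 1.0, phat, 1.0 - phat)
    ipw = p_num / p_den
    pi = np.ones(len(cohort)) if sampling_probs is None else np.asarray(sampling_probs, float)
    ws = pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "ipw": ipw,
        "sampling_prob": pi,
        "analysis_weight": ipw / pi,
    })
    if not np.isfinite(ws["analysis_weight"]).all() or (ws["analysis_weight"] <= 0).any():
        raise ValueError("non-finite or non-positive analysis weight")
    return ws


def weight_diagnostics(weights: pd.DataFrame, exposure: np.ndarray) -> dict:
    """Mean/SD/min/max of ipw and analysis weight by exposure group."""
    out = {}
    for g in (0, 1):
        mask = np.asarray(exposure) == g
        for col in ("ipw", "analysis_weight"):
            v = weights.loc[mask, col]
            out[f"{col}_group{g}"] = {
                "mean": float(v.mean()), "sd": float(v.std()),
                "min": float(v.min()), "max": float(v.max()),
            }
    return out
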