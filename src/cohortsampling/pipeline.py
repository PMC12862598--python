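"""End-to-end analysis pipelines: design draw → weighting → estimation.

A :class:`DesignSpec` names one of the four designs with its parameter
(``f`` for subcohort/case-cohort, ``k`` for divide).  :func:`run_pipeline`
executes the whole chain on a cohort — drawing the design with a seed,
fitting the sampling-weighted exposure model on the members, composing
stabilized IPW with the inverse sampling probability, building
counting-process rows, and running the requested estimator.  Divide designs
estimate per subsample and recombine by fixed-effects inverse-variance
meta-analysis; the risk ratio, which has no analytic SE, gets its per-
subsample SE from an inner bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import designs as dz
from .estimators import EstimateResult, fit_weighted_cox, fit_weighted_poisson, rr_at
from .ipw import fit_exposure_model, stabilized_ipw

__all__ = ["DesignSpec", "estimate_on_design", "run_pipeline", "pipeline_estimator"]


@dataclass(frozen=True)
class DesignSpec:
    """One analysis design: kind in {full, divide, subcohort, casecohort}."""

    kind: str
    f: float | None = None
    k: int | None = None

    def __post_init__(self):
        if self.kind not in ("full", "divide", "subcohort", "casecohort"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind in ("subcohort", "casecohort") and self.f is None:
            raise ValueError(f"{self.kind} requires a sampling fraction f")
        if self.kind == "divide" and self.k is None:
            raise ValueError("divide requires a partition count k")

    @property
    def label(self) -> str:
        if self.kind == "full":
            return "Full data"
        if self.kind == "divide":
            return f"Divide ({self.k} samples)"
        name = "Subcohort" if self.kind == "subcohort" else "Case-cohort"
        return f"{name} ({self.f:.0%})"


def draw_design(cohort: pd.DataFrame, spec: DesignSpec, seed: int | None = None):
    """Draw the design sample(s) for a spec; a list for divide, else one."""
    if spec.kind == "full":
        return dz.full_design(cohort)
    if spec.kind == "subcohort":
        return dz.draw_subcohort(cohort, spec.f, seed)
    if spec.kind == "casecohort":
        return dz.draw_case_cohort(cohort, spec.f, seed)
    return dz.partition_divide(cohort, spec.k, seed)


def estimate_on_design(
    cohort: pd.DataFrame,
    design: dz.DesignSample,
    estimand: str,
    horizon: float | None = 5.0,
    variance: str = "robust",
) -> EstimateResult:
    """Weight and estimate on one drawn design sample.

    The exposure model is weighted by the inverse sampling probability and
    fitted on the design members (one record per person); the outcome model
    carries ``ipw / pi`` and contains the exposure term only.
    """
    members = design.members(cohort)
    model = fit_exposure_model(members, sampling_probs=design.sampling_prob)
    weights = stabilized_ipw(members, model, sampling_probs=design.sampling_prob)
    rows = dz.build_analysis_rows(cohort, design, weights, estimand=estimand)
    if estimand == "RR":
        return rr_at(rows[rows["group"] == 1], rows[rows["group"] == 0], horizon)
    if estimand == "HR":
        return fit_weighted_cox(rows, variance=variance)
    if estimand == "IRR":
        return fit_weighted_poisson(rows, variance=variance)
    raise ValueError(f"unknown estimand {estimand!r}")


def run_pipeline(
    cohort: pd.DataFrame,
    spec: DesignSpec,
    estimand: str,
    horizon: float | None = 5.0,
    seed: int | None = None,
    variance: str = "robust",
    inner_b: int = 50,
) -> EstimateResult:
    """Run the full design → IPW → estimator chain; deterministic given seed.

    For divide designs the K subsample estimates are recombined by
    inverse-variance meta-analysis using robust SEs (HR, IRR) or inner-
    bootstrap SEs drawn within each subsample (RR, ``inner_b`` replicates,
    the before-split rule).
    """
    from .variance import BootstrapSpec, bootstrap_se, meta_combine  # cycle guard

    drawn = draw_design(cohort, spec, seed)
    if spec.kind != "divide":
        return estimate_on_design(cohort, drawn, estimand, horizon, variance=variance)

    estimates, ses = [], []
    n_members = 0
    n_events = 0
    for j, sample in enumerate(drawn):
        sub = sample.members(cohort)
        full_sub = dz.full_design(sub)
        if estimand == "RR":
            res = estimate_on_design(sub, full_sub, "RR", horizon)
            if inner_b < 2:
                raise ValueError("divide + RR needs an inner bootstrap (inner_b >= 2)")
            inner_seed = int(np.random.SeedSequence(
                entropy=0 if seed is None else seed, spawn_key=(j,)
            ).generate_state(1)[0] % 2**31)
            boot = bootstrap_se(
                sub,
                pipeline_estimator(DesignSpec("full"), "RR", horizon),
                BootstrapSpec(b=inner_b, seed=inner_seed),
            )
            se = boot.se
        else:
            res = estimate_on_design(sub, full_sub, estimand, horizon, variance="robust")
            se = res.se
        estimates.append(res.log_estimate)
        ses.append(se)
        n_members += res.n_members
        n_events += res.n_events.get("unweighted", 0)
    meta = meta_combine(estimates, ses)
    return EstimateResult(
        estimand=estimand, log_estimate=meta.combined_log_estimate, se=meta.combined_se,
        variance_method="meta", horizon=horizon if estimand == "RR" else None,
        n_members=n_members, n_events={"unweighted": n_events},
        fit=meta,
    )


def pipeline_estimator(spec: DesignSpec, estimand: str, horizon: float | None = 5.0,
                       inner_b: int = 50):
    """A ``(cohort, seed) -> log estimate`` callable for the bootstrap."""

    def run(cohort: pd.DataFrame, seed: int) -> float:
        return run_pipeline(cohort, spec, estimand, horizon, seed=seed,
                            variance="none", inner_b=inner_b).log_estimate

    return run
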