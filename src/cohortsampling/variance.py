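"""Design-aware nonparametric bootstrap and inverse-variance recombination.

The bootstrap resamples *subjects* (n-of-n with replacement) and re-runs the
entire analysis pipeline in every replicate — design draw with a replicate-
specific seed, exposure-model refit, weight composition, estimation — so the
sampling process itself is reflected in the SE:

* ``from_full`` (full, subcohort, case-cohort): replicates resample the full
  cohort before the design is drawn;
* ``before_split`` (divide): the partition is drawn once; replicates resample
  within each subsample, giving per-subsample SEs that feed the fixed-effects
  inverse-variance meta-analysis.

Resampled duplicates receive fresh ids so each copy is an independent
cluster.  Per-replicate seeds are spawned from the spec seed, so results are
bitwise reproducible and independent of worker count and replicate order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

__all__ = [
    "BootstrapSpec",
    "BootstrapResult",
    "MetaResult",
    "meta_combine",
    "bootstrap_se",
    "bootstrap_before_split",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSpec:
    """Nonparametric bootstrap settings.

    ``b`` defaults to 500 resamples (a practical minimum for stable SD-based
    SEs); ``failure_policy`` is the tolerated fraction of failed replicates.
    """

    b: int = 500
    seed: int = 0
    stage: str = "from_full"            # or "before_split"
    failure_policy: float = 0.05
    n_jobs: int = 1

    def __post_init__(self):
        if self.b < 2:
            raise ValueError("b must be >= 2")
        if self.stage not in ("from_full", "before_split"):
            raise ValueError(f"unknown bootstrap stage {self.stage!r}")


@dataclass
class BootstrapResult:
    se: float
    ci_percentile: tuple[float, float]
    estimates: np.ndarray = field(repr=False)
    n_failed: int = 0

    def wald_ci(self, point: float, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return point - z * self.se, point + z * self.se


@dataclass
class MetaResult:
    """Fixed-effects inverse-variance combination of K estimates."""

    combined_log_estimate: float
    combined_se: float
    per_sample: list[tuple[float, float]]


def meta_combine(estimates, ses) -> MetaResult:
    """Fixed-effects inverse-variance meta-analysis: weights ``1/se^2``,
    combined estimate ``sum(v*b)/sum(v)``, combined SE ``sum(v)^(-1/2)``.
    Exactly invariant to permutation of the inputs."""
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 1 or len(b) != len(s):
        raise ValueError("need K >= 1 estimates with matching SEs")
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("all SEs must be finite and > 0")
    v = 1.0 / s**2
    combined = float((v * b).sum() / v.sum())
    combined_se = float(v.sum() ** -0.5)
    return MetaResult(combined, combined_se, list(zip(b.tolist(), s.tolist())))


def _replicate_seed(seed: int, b_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(b_idx,))


def _one_replicate(cohort: pd.DataFrame, estimator, seed: int, b_idx: int) -> float:
    ss = _replicate_seed(seed, b_idx)
    rng = np.random.default_rng(ss)
    n = len(cohort)
    idx = rng.integers(0, n, size=n)
    resampled = cohort.iloc[idx].reset_index(drop=True)
    resampled = resampled.assign(id=np.arange(n).astype(str))  # fresh cluster ids
    est_seed = int(ss.generate_state(1)[0] % 2**31)
    try:
        return float(estimator(resampled, est_seed))
    except Exception as exc:  # noqa: BLE001 — estimator failures are policy-counted
        logger.warning("bootstrap replicate %d failed: %s", b_idx, exc)
        return np.nan


def bootstrap_se(cohort: pd.DataFrame, estimator, spec: BootstrapSpec) -> BootstrapResult:
    """SE of a pipeline estimator by the nonparametric bootstrap.

    ``estimator`` is a ``(cohort, seed) -> log estimate`` callable (see
    :func:`cohortsampling.pipeline.pipeline_estimator`); every replicate
    re-runs it end to end, design draw and IPW refit included.  Returns the
    SD (denominator ``b - 1``) of the replicate estimates and the 2.5/97.5
    percentile interval.  Deterministic given ``spec.seed`` regardless of
    input row order or ``n_jobs``.
    """
    cohort = cohort.sort_values("id", kind="stable").reset_index(drop=True)
    if spec.n_jobs == 1:
        estimates = [_one_replicate(cohort, estimator, spec.seed, b) for b in range(spec.b)]
    else:
        estimates = Parallel(n_jobs=spec.n_jobs)(
            delayed(_one_replicate)(cohort, estimator, spec.seed, b) for b in range(spec.b)
        )
    estimates = np.asarray(estimates, dtype=float)
    failed = int(np.isnan(estimates).sum())
    if failed > spec.failure_policy * spec.b:
        raise RuntimeError(
            f"{failed}/{spec.b} bootstrap replicates failed (policy {spec.failure_policy:.0%})"
        )
    if failed:
        logger.warning("excluded %d failed bootstrap replicate(s)", failed)
    valid = estimates[~np.isnan(estimates)]
    se = float(np.std(valid, ddof=1))
    lo, hi = np.percentile(valid, [2.5, 97.5])
    return BootstrapResult(se=se, ci_percentile=(float(lo), float(hi)),
                           estimates=estimates, n_failed=failed)


def bootstrap_before_split(
    cohort: pd.DataFrame,
    k: int,
    estimator,
    spec: BootstrapSpec,
    partition_seed: int | None = None,
) -> tuple[MetaResult, list[BootstrapResult]]:
    """Divide-design bootstrap: partition once, bootstrap within each
    subsample (the before-split rule), recombine by meta-analysis.

    ``estimator`` runs a full-style pipeline on one subsample.  The point
    estimates come from the original (un-resampled) subsamples; the per-
    subsample bootstrap SEs supply the meta-analysis weights.
    """
    from .designs import partition_divide

    samples = partition_divide(cohort, k, partition_seed if partition_seed is not None
                               else spec.seed)
    points, ses, boots = [], [], []
    for j, sample in enumerate(samples):
        sub = sample.members(cohort)
        sub_seed = int(_replicate_seed(spec.seed, j).generate_state(1)[0] % 2**31)
        points.append(float(estimator(sub, sub_seed)))
        sub_spec = BootstrapSpec(b=spec.b, seed=sub_seed, stage="from_full",
                                 failure_policy=spec.failure_policy, n_jobs=spec.n_jobs)
        boot = bootstrap_se(sub, estimator, sub_spec)
        ses.append(boot.se)
        boots.append(boot)
    return meta_combine(points, ses), boots
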