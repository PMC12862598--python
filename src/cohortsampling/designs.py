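"""The four analysis designs and their counting-process representations.

* ``full``: everyone, sampling probability 1.
* ``divide``: a uniformly random partition into K near-equal subsamples,
  each analyzed as a full-style design and later recombined by
  inverse-variance meta-analysis.
* ``subcohort``: exposure-stratified sampling — all exposed subjects
  (pi = 1) plus a simple random sample without replacement of a fraction
  ``f`` of the unexposed (pi = f).
* ``casecohort``: the subcohort plus every case not already sampled,
  included with selection weight 1 (pi = 1) and flagged
  ``nonsubcohort_case``.

Non-subcohort cases enter the analysis late, at ``LATE_ENTRY_OFFSET`` before
their event time, so they contribute 0.001 person-years and their own event:
the single counting-process encoding ``(max(0, time - 0.001), time]`` serves
the risk, hazard, and rate estimands alike (the Poisson estimator consumes
``stop - start`` as person-time).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "LATE_ENTRY_OFFSET",
    "DEFAULT_FRACTIONS",
    "DEFAULT_K",
    "DesignSample",
    "full_design",
    "partition_divide",
    "draw_subcohort",
    "draw_case_cohort",
    "build_analysis_rows",
]

logger = logging.getLogger(__name__)

#: Person-years contributed by non-subcohort cases (and the late-entry offset).
LATE_ENTRY_OFFSET = 0.001
DEFAULT_FRACTIONS = (0.10, 0.25)
DEFAULT_K = (10, 20, 50)

ESTIMANDS = ("RR", "HR", "IRR")


@dataclass
class DesignSample:
    """A sampled analysis set with per-member sampling probabilities.

    Members are kept in original cohort order.  ``nonsubcohort_case`` implies
    ``event == 1`` and ``in_subcohort == False``.
    """

    design: str                       # full | divide | subcohort | casecohort
    member_ids: np.ndarray
    sampling_prob: np.ndarray
    in_subcohort: np.ndarray
    nonsubcohort_case: np.ndarray
    f: float | None = None
    k: int | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.member_ids)

    def members(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Member rows of ``cohort`` in design order."""
        pos = pd.Index(cohort["id"]).get_indexer(self.member_ids)
        if (pos < 0).any():
            raise ValueError("design member id missing from cohort")
        return cohort.iloc[pos].reset_index(drop=True)

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("member_ids", "sampling_prob", "in_subcohort", "nonsubcohort_case"):
            d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "DesignSample":
        d = json.loads(text)
        d["member_ids"] = np.asarray(d["member_ids"], dtype=str)
        d["sampling_prob"] = np.asarray(d["sampling_prob"], dtype=float)
        d["in_subcohort"] = np.asarray(d["in_subcohort"], dtype=bool)
        d["nonsubcohort_case"] = np.asarray(d["nonsubcohort_case"], dtype=bool)
        return cls(**d)


def _make(design, ids, pi, in_sub, nsc, **kw) -> DesignSample:
    return DesignSample(design=design, member_ids=np.asarray(ids),
                        sampling_prob=np.asarray(pi, dtype=float),
                        in_subcohort=np.asarray(in_sub, dtype=bool),
                        nonsubcohort_case=np.asarray(nsc, dtype=bool), **kw)


def full_design(cohort: pd.DataFrame) -> DesignSample:
    """Everyone, with sampling probability 1."""
    n = len(cohort)
    return _make("full", cohort["id"].to_numpy(), np.ones(n),
                 np.ones(n, dtype=bool), np.zeros(n, dtype=bool))


def partition_divide(cohort: pd.DataFrame, k: int, seed: int | None = None) -> list[DesignSample]:
    """Uniformly random partition into ``k`` subsamples of near-equal size
    (sizes differ by at most 1): random permutation, then contiguous blocks.
    Each subsample is a full-style design restricted to its members."""
    n = len(cohort)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    ids = cohort["id"].to_numpy()
    samples = []
    offset = 0
    for j, size in enumerate(sizes):
        pos = np.sort(perm[offset: offset + size])
        offset += size
        m = len(pos)
        samples.append(_make("divide", ids[pos], np.ones(m), np.ones(m, dtype=bool),
                             np.zeros(m, dtype=bool), k=k, seed=seed))
    return samples


def _stratified_positions(cohort: pd.DataFrame, f: float, rng: np.random.Generator):
    exposure = cohort["exposure"].to_numpy()
    pos_exposed = np.flatnonzero(exposure == 1)
    pos_unexposed = np.flatnonzero(exposure == 0)
    if len(pos_exposed) == 0 or len(pos_unexposed) == 0:
        raise ValueError("both exposure groups must be present")
    m = int(round(f * len(pos_unexposed)))
    if m == 0:
        raise ValueError(f"f={f} samples zero unexposed subjects")
    sampled = rng.choice(pos_unexposed, size=m, replace=False)
    return pos_exposed, sampled


def draw_subcohort(cohort: pd.DataFrame, f: float, seed: int | None = None) -> DesignSample:
    """Exposure-stratified subcohort: all exposed (pi = 1) plus an exact-size
    SRSWOR of ``round(f * N_unexposed)`` unexposed subjects (pi = f)."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pos_exposed, sampled = _stratified_positions(cohort, f, rng)
    pos = np.sort(np.concatenate([pos_exposed, sampled]))
    exposure = cohort["exposure"].to_numpy()[pos]
    pi = np.where(exposure == 1, 1.0, f)
    m = len(pos)
    return _make("subcohort", cohort["id"].to_numpy()[pos], pi,
                 np.ones(m, dtype=bool), np.zeros(m, dtype=bool), f=f, seed=seed)


def draw_case_cohort(cohort: pd.DataFrame, f: float, seed: int | None = None) -> DesignSample:
    """The subcohort (same seed, same ``f``) augmented with every case not
    already sampled, flagged ``nonsubcohort_case`` with selection weight 1.
    All exposed subjects are in the subcohort, so non-subcohort cases are
    unexposed cases by construction.

    Because every case reaches the analysis set with certainty (through the
    subcohort or through the augmentation), the inclusion probability of a
    case is 1: pi = f applies only to sampled unexposed *non-cases*.  This
    keeps the weighted event mass unbiased — a case's event always carries
    design weight 1, never 1/f.
    """
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pos_exposed, sampled = _stratified_positions(cohort, f, rng)
    sub_pos = np.concatenate([pos_exposed, sampled])
    event = cohort["event"].to_numpy()
    case_pos = np.flatnonzero(event == 1)
    extra = np.setdiff1d(case_pos, sub_pos)
    pos = np.sort(np.concatenate([sub_pos, extra]))
    in_sub = np.isin(pos, sub_pos)
    exposure = cohort["exposure"].to_numpy()[pos]
    pi = np.where((exposure == 0) & (event[pos] == 0), f, 1.0)
    return _make("casecohort", cohort["id"].to_numpy()[pos], pi, in_sub, ~in_sub, f=f, seed=seed)


def build_analysis_rows(
    cohort: pd.DataFrame,
    design: DesignSample,
    weights: pd.DataFrame,
    estimand: str = "HR",
) -> pd.DataFrame:
    """Counting-process rows ``(id, start, stop, event, group, weight)``.

    Ordinary members contribute ``(0, time]`` with their composed analysis
    weight.  Non-subcohort cases late-enter at ``time - 0.001`` (clamped to 0
    with a logged warning when ``time <= 0.001``), contributing exactly 0.001
    person-years and their event at weight ``ipw * 1``; the same encoding
    serves all three estimands.
    """
    if estimand not in ESTIMANDS:
        raise ValueError(f"estimand must be one of {ESTIMANDS}")
    members = design.members(cohort)
    ws = weights.set_index("id")
    if set(ws.index) != set(members["id"]):
        raise ValueError("weight set must cover exactly the design members")
    ws = ws.loc[members["id"]]

    time = members["time"].to_numpy(dtype=float)
    start = np.zeros(len(members))
    nsc = design.nonsubcohort_case
    if nsc.any():
        start[nsc] = time[nsc] - LATE_ENTRY_OFFSET
        clamped = nsc & (start < 0)
        if clamped.any():
            logger.warning("clamped late entry to 0 for %d non-subcohort case(s) with "
                           "follow-up <= %g", int(clamped.sum()), LATE_ENTRY_OFFSET)
            start[clamped] = 0.0
    return pd.DataFrame({
        "id": members["id"].to_numpy(),
        "start": start,
        "stop": time,
        "event": members["event"].to_numpy(dtype=np.int64),
        "group": members["exposure"].to_numpy(dtype=np.int64),
        "weight": ws["analysis_weight"].to_numpy(dtype=float),
    })
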