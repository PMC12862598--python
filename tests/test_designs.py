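"""Design construction: partitions, stratified subcohorts, case-cohort
augmentation, and the counting-process conventions for non-subcohort cases."""

import numpy as np
import pandas as pd
import pytest

from cohortsampling import (
    LATE_ENTRY_OFFSET,
    DesignSample,
    build_analysis_rows,
    draw_case_cohort,
    draw_subcohort,
    full_design,
    partition_divide,
    validate_cohort,
)


@pytest.fixture
def toy(toy_cohort):
    return validate_cohort(toy_cohort)


def unit_weights(design):
    return pd.DataFrame({
        "id": design.member_ids,
        "ipw": np.ones(len(design)),
        "sampling_prob": design.sampling_prob,
        "analysis_weight": 1.0 / design.sampling_prob,
    })


class TestPartition:
    def test_k1_is_the_full_cohort(self, toy):
        (sample,) = partition_divide(toy, 1, seed=0)
        assert list(sample.member_ids) == list(toy["id"])
        assert (sample.sampling_prob == 1).all()

    def test_exact_division(self, desk_cohort):
        cohort = desk_cohort.iloc[:100]
        samples = partition_divide(cohort, 10, seed=1)
        assert [len(s) for s in samples] == [10] * 10

    def test_near_equal_sizes_and_conservation(self, desk_cohort):
        cohort = desk_cohort.iloc[:101]
        samples = partition_divide(cohort, 10, seed=1)
        assert sorted(len(s) for s in samples) == [10] * 9 + [11]
        union = np.concatenate([s.member_ids for s in samples])
        assert len(union) == 101
        assert len(np.unique(union)) == 101

    def test_k_bounds(self, toy):
        with pytest.raises(ValueError):
            partition_divide(toy, len(toy) + 1, seed=0)

    def test_deterministic_given_seed(self, toy):
        a = partition_divide(toy, 5, seed=9)
        b = partition_divide(toy, 5, seed=9)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.member_ids, s2.member_ids)


class TestSubcohort:
    def test_f1_includes_everyone_at_probability_one(self, toy):
        sample = draw_subcohort(toy, 1.0, seed=0)
        assert list(sample.member_ids) == list(toy["id"])
        assert (sample.sampling_prob == 1.0).all()

    def test_exact_unexposed_sample_size(self, desk_cohort):
        cohort = pd.concat([
            desk_cohort[desk_cohort["exposure"] == 1].iloc[:50],
            desk_cohort[desk_cohort["exposure"] == 0].iloc[:1000],
        ]).reset_index(drop=True)
        sample = draw_subcohort(cohort, 0.25, seed=4)
        members = sample.members(cohort)
        assert (members["exposure"] == 0).sum() == 250
        assert (members["exposure"] == 1).sum() == 50
        np.testing.assert_array_equal(
            sample.sampling_prob, np.where(members["exposure"] == 1, 1.0, 0.25)
        )

    def test_inclusion_probability_is_f(self, toy):
        """SRSWOR oracle: each unexposed subject's inclusion frequency over
        2000 seeds is binomial(f); all 20 frequencies within 3 SEs of 0.25
        (threshold widened for the 20 simultaneous comparisons)."""
        f, reps = 0.25, 2000
        counts = {i: 0 for i in toy.index[toy["exposure"] == 0]}
        unexposed_ids = set(toy.loc[toy["exposure"] == 0, "id"])
        for s in range(reps):
            chosen = set(draw_subcohort(toy, f, seed=s).member_ids) & unexposed_ids
            for i in toy.index[toy["exposure"] == 0]:
                counts[i] += toy.loc[i, "id"] in chosen
        se = np.sqrt(f * (1 - f) / reps)
        freqs = np.array([c / reps for c in counts.values()])
        assert np.abs(freqs - f).max() < 3.5 * se

    def test_horvitz_thompson_conservation(self, toy):
        """With exact-size SRSWOR, sum(1/pi) = n_exposed + round(f*N0)/f for
        every seed: exactly n when f*N0 is integral, and within the rounding
        bound 0.5/f of n otherwise."""
        totals = np.asarray([
            float((1.0 / draw_subcohort(toy, 0.25, seed=s).sampling_prob).sum())
            for s in range(50)
        ])
        np.testing.assert_allclose(totals, len(toy), atol=1e-12)  # 0.25 * 20 integral
        total_odd = float((1.0 / draw_subcohort(toy, 0.23, seed=0).sampling_prob).sum())
        assert abs(total_odd - len(toy)) <= 0.5 / 0.23

    def test_empty_unexposed_stratum_rejected(self, toy):
        with pytest.raises(ValueError, match="zero unexposed"):
            draw_subcohort(toy, 0.01, seed=0)


class TestCaseCohort:
    def test_all_cases_retained(self, desk_cohort):
        cohort = desk_cohort.iloc[:5000]
        sample = draw_case_cohort(cohort, 0.1, seed=2)
        members = sample.members(cohort)
        assert members["event"].sum() == cohort["event"].sum()

    def test_f1_identical_to_subcohort(self, toy):
        cc = draw_case_cohort(toy, 1.0, seed=7)
        sub = draw_subcohort(toy, 1.0, seed=7)
        np.testing.assert_array_equal(cc.member_ids, sub.member_ids)
        assert not cc.nonsubcohort_case.any()

    def test_superset_of_subcohort_same_seed(self, toy):
        cc = draw_case_cohort(toy, 0.25, seed=3)
        sub = draw_subcohort(toy, 0.25, seed=3)
        assert set(sub.member_ids) <= set(cc.member_ids)

    def test_nonsubcohort_case_count_by_enumeration(self, toy):
        """Toy cohort: 5 exposed (2 cases), 20 unexposed (4 cases).  For any
        seed, the non-subcohort cases are exactly the unexposed cases the
        subcohort draw missed."""
        for seed in range(25):
            sub = draw_subcohort(toy, 0.25, seed=seed)
            cc = draw_case_cohort(toy, 0.25, seed=seed)
            unexposed_cases = set(toy.loc[(toy.exposure == 0) & (toy.event == 1), "id"])
            caught = unexposed_cases & set(sub.member_ids)
            assert cc.nonsubcohort_case.sum() == 4 - len(caught)
        # at least one seed catches exactly 1 unexposed case -> 3 augmented
        counts = set()
        for seed in range(25):
            counts.add(int(draw_case_cohort(toy, 0.25, seed=seed).nonsubcohort_case.sum()))
        assert 3 in counts

    def test_case_probability_is_one(self, toy):
        """All cases (exposed or not, subcohort or not) carry pi = 1; only
        sampled unexposed non-cases carry pi = f."""
        cc = draw_case_cohort(toy, 0.25, seed=1)
        members = cc.members(toy)
        is_case = members["event"].to_numpy() == 1
        exposed = members["exposure"].to_numpy() == 1
        np.testing.assert_array_equal(
            cc.sampling_prob, np.where(is_case | exposed, 1.0, 0.25)
        )
        assert (members.loc[cc.nonsubcohort_case, "event"] == 1).all()
        assert not (cc.nonsubcohort_case & cc.in_subcohort).any()

    def test_json_roundtrip(self, toy):
        cc = draw_case_cohort(toy, 0.25, seed=1)
        back = DesignSample.from_json(cc.to_json())
        np.testing.assert_array_equal(back.member_ids, cc.member_ids)
        np.testing.assert_array_equal(back.sampling_prob, cc.sampling_prob)
        assert back.f == cc.f and back.seed == cc.seed


class TestAnalysisRows:
    def test_full_design_rows(self, toy):
        design = full_design(toy)
        rows = build_analysis_rows(toy, design, unit_weights(design), "HR")
        assert (rows["start"] == 0).all()
        np.testing.assert_array_equal(rows["stop"].to_numpy(), toy["time"].to_numpy())
        np.testing.assert_array_equal(rows["event"].to_numpy(), toy["event"].to_numpy())
        np.testing.assert_array_equal(rows["weight"].to_numpy(), np.ones(len(toy)))

    @pytest.mark.parametrize("estimand", ["RR", "HR", "IRR"])
    def test_nonsubcohort_case_late_entry(self, toy, estimand):
        """A non-subcohort case with event time 3.0 contributes the interval
        (2.999, 3.0]: late entry 0.001 before the event for HR/RR, and
        exactly 0.001 person-years (stop - start) for IRR."""
        toy = toy.copy()
        toy.loc[(toy.exposure == 0) & (toy.event == 1), "time"] = 3.0
        for seed in range(20):
            cc = draw_case_cohort(toy, 0.25, seed=seed)
            if cc.nonsubcohort_case.any():
                break
        rows = build_analysis_rows(toy, cc, unit_weights(cc), estimand)
        nsc = rows.loc[cc.nonsubcohort_case]
        np.testing.assert_allclose(nsc["start"], 3.0 - LATE_ENTRY_OFFSET)
        np.testing.assert_allclose(nsc["stop"], 3.0)
        np.testing.assert_allclose(nsc["stop"] - nsc["start"], LATE_ENTRY_OFFSET)
        assert (nsc["event"] == 1).all()

    def test_short_follow_up_clamped(self, toy, caplog):
        import logging
        toy = toy.copy()
        toy.loc[(toy.exposure == 0) & (toy.event == 1), "time"] = LATE_ENTRY_OFFSET / 2
        for seed in range(20):
            cc = draw_case_cohort(toy, 0.25, seed=seed)
            if cc.nonsubcohort_case.any():
                break
        with caplog.at_level(logging.WARNING, logger="cohortsampling.designs"):
            rows = build_analysis_rows(toy, cc, unit_weights(cc), "HR")
        assert "clamped" in caplog.text
        nsc = rows.loc[cc.nonsubcohort_case]
        assert (nsc["start"] == 0.0).all()
        assert (nsc["stop"] > nsc["start"]).all()

    def test_weight_set_must_match_members(self, toy):
        design = draw_subcohort(toy, 0.25, seed=0)
        weights = unit_weights(full_design(toy))
        with pytest.raises(ValueError, match="exactly the design members"):
            build_analysis_rows(toy, design, weights, "HR")
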