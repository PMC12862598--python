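"""Weighted KM / Cox / Poisson estimators against hand calculations,
brute-force likelihood oracles, and independent library implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cohortsampling import (
    EstimatorError,
    NonFiniteMLEError,
    fit_weighted_cox,
    fit_weighted_poisson,
    robust_sandwich,
    rr_at,
    weighted_km_risk,
)

from conftest import make_rows


# hand fixture: events at 1 and 3, censored at 2 and 5
# Risk(3) = 1 - (1 - 1/4)(1 - 1/2) = 0.625
KM_FIXTURE = make_rows([0, 0, 0, 0], [1, 2, 3, 5], [1, 0, 1, 0], [1] * 4, [1.0] * 4)
# one event at 1, rest censored: Risk(3) = 1/4
KM_FIXTURE_LOW = make_rows([0, 0, 0, 0], [1, 2, 4, 5], [1, 0, 0, 0], [0] * 4, [1.0] * 4)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        assert weighted_km_risk(KM_FIXTURE, 3.0) == pytest.approx(0.625, abs=1e-15)
        assert weighted_km_risk(KM_FIXTURE_LOW, 3.0) == pytest.approx(0.25, abs=1e-15)

    def test_no_events_before_horizon(self):
        assert weighted_km_risk(KM_FIXTURE, 0.5) == 0.0

    def test_weight_scale_invariance(self):
        scaled = KM_FIXTURE.assign(weight=KM_FIXTURE["weight"] * 7.0)
        assert weighted_km_risk(scaled, 3.0) == weighted_km_risk(KM_FIXTURE, 3.0)

    def test_equals_empirical_proportion_without_censoring(self):
        """No censoring, no late entry, unit weights: KM risk at t is exactly
        the proportion of events by t."""
        rng = np.random.default_rng(0)
        times = rng.exponential(2.0, 300)
        rows = make_rows(np.zeros(300), times, np.ones(300), np.zeros(300), np.ones(300))
        for t in (0.5, 1.0, 3.0):
            assert weighted_km_risk(rows, t) == pytest.approx((times <= t).mean(), abs=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        n = 200
        start = np.where(rng.random(n) < 0.3, rng.uniform(0, 1, n), 0.0)
        stop = start + rng.exponential(1.5, n)
        rows = make_rows(start, stop, rng.integers(0, 2, n), np.zeros(n),
                         rng.uniform(0.1, 5, n))
        risks = [weighted_km_risk(rows, t) for t in np.linspace(0.1, 8, 25)]
        assert all(0.0 <= r <= 1.0 for r in risks)
        assert np.all(np.diff(risks) >= -1e-15)

    def test_matches_lifelines_weighted_with_late_entry(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        n = 250
        start = np.where(rng.random(n) < 0.4, rng.uniform(0, 0.8, n), 0.0)
        stop = start + rng.exponential(2.0, n)
        event = rng.integers(0, 2, n)
        w = rng.uniform(0.5, 3.0, n)
        rows = make_rows(start, stop, event, np.zeros(n), w)
        kmf = KaplanMeierFitter()
        with pytest.warns(Warning):
            kmf.fit(stop, event_observed=event, entry=start, weights=w)
        for t in (1.0, 2.5, 4.0):
            theirs = 1 - float(kmf.survival_function_at_times(t).iloc[0])
            assert weighted_km_risk(rows, t) == pytest.approx(theirs, abs=1e-10)


class TestRiskRatio:
    def test_identical_groups_give_null(self):
        res = rr_at(KM_FIXTURE, KM_FIXTURE.assign(group=0), 3.0)
        assert res.log_estimate == 0.0
        assert res.variance_method == "none"

    def test_hand_fixture_ratio(self):
        res = rr_at(KM_FIXTURE, KM_FIXTURE_LOW, 3.0)
        assert res.log_estimate == pytest.approx(np.log(2.5), abs=1e-12)
        assert res.horizon == 3.0

    def test_zero_risk_group_is_an_error(self):
        late = make_rows([0, 0], [4.0, 5.0], [1, 0], [1, 1], [1.0, 1.0])
        with pytest.raises(EstimatorError, match="log RR undefined|risk is zero"):
            rr_at(late, KM_FIXTURE_LOW, 3.0)


# 6-subject Cox fixture: exposed events at 1 and 4 plus a censoring at 5;
# unexposed events at 2 and 3 plus a censoring at 5
COX_FIXTURE = make_rows(
    [0] * 6, [1, 4, 5, 2, 3, 5], [1, 1, 0, 1, 1, 0], [1, 1, 1, 0, 0, 0], [1.0] * 6
)


def brute_force_cox_beta():
    """Maximize the hand-written Breslow partial likelihood on a grid /
    golden section, independent of the Newton implementation."""
    def neg_log_pl(beta):
        e = np.exp(beta)
        terms = [
            beta - np.log(3 * e + 3),   # exposed event at t=1
            -np.log(2 * e + 3),         # unexposed event at t=2
            -np.log(2 * e + 2),         # unexposed event at t=3
            beta - np.log(2 * e + 1),   # exposed event at t=4
        ]
        return -sum(terms)

    res = minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestCox:
    def test_matches_brute_force_partial_likelihood(self):
        res = fit_weighted_cox(COX_FIXTURE, variance="none")
        assert res.log_estimate == pytest.approx(brute_force_cox_beta(), abs=1e-4)
        assert res.fit.converged

    def test_row_duplication_with_half_weights(self):
        doubled = pd.concat([COX_FIXTURE, COX_FIXTURE], ignore_index=True)
        doubled["weight"] = 0.5
        res1 = fit_weighted_cox(COX_FIXTURE, variance="none")
        res2 = fit_weighted_cox(doubled, variance="none")
        assert res2.log_estimate == pytest.approx(res1.log_estimate, abs=1e-12)

    def test_weight_scale_invariance(self):
        scaled = COX_FIXTURE.assign(weight=3.7)
        res1 = fit_weighted_cox(COX_FIXTURE, variance="none")
        res2 = fit_weighted_cox(scaled, variance="none")
        assert res2.log_estimate == pytest.approx(res1.log_estimate, abs=1e-12)

    def test_null_under_permuted_labels(self):
        """With exposure labels permuted at random, estimates center on 0."""
        rng = np.random.default_rng(12)
        n = 500
        stop = rng.exponential(2.0, n)
        event = (rng.random(n) < 0.6).astype(int)
        half = np.arange(n) < n // 2
        betas = []
        for _ in range(20):
            rows = make_rows(np.zeros(n), stop, event, rng.permutation(half).astype(int),
                             np.ones(n))
            betas.append(fit_weighted_cox(rows, variance="none").log_estimate)
        mean = np.mean(betas)
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(mean) < 4 * mc_se + 0.02

    def test_monotone_likelihood_raises(self):
        rows = make_rows([0] * 4, [1, 2, 3, 4], [1, 1, 0, 0], [1, 1, 0, 0], [1.0] * 4)
        with pytest.raises(NonFiniteMLEError):
            fit_weighted_cox(rows, variance="none")

    def test_matches_lifelines_weighted_entry_robust(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(7)
        n = 400
        start = np.where(rng.random(n) < 0.3, rng.uniform(0, 0.5, n), 0.0)
        stop = np.minimum(start + rng.exponential(2.0, n), 5.0)
        event = ((stop < 5.0) & (rng.random(n) < 0.7)).astype(int)
        rows = make_rows(start, stop, event, rng.integers(0, 2, n),
                         rng.uniform(0.5, 3.0, n))
        res = fit_weighted_cox(rows)
        df = rows.rename(columns={"stop": "T", "event": "E"})
        cph = CoxPHFitter()
        cph.fit(df[["start", "T", "E", "group", "weight"]], duration_col="T",
                event_col="E", entry_col="start", weights_col="weight", robust=True)
        assert res.log_estimate == pytest.approx(cph.params_["group"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["group"], rel=1e-2)

    def test_score_residuals_sum_to_score(self):
        from cohortsampling.estimators import _cox_score_residuals
        res = fit_weighted_cox(COX_FIXTURE, variance="none")
        assert _cox_score_residuals(res.fit).sum() == pytest.approx(res.fit.score, abs=1e-10)


def poisson_fixture():
    """Exposed: 10 events / 100 person-years; unexposed: 5 / 100."""
    exposed = make_rows(np.zeros(20), np.full(20, 5.0), [1] * 10 + [0] * 10,
                        np.ones(20), np.ones(20), ids=[f"e{i}" for i in range(20)])
    unexposed = make_rows(np.zeros(20), np.full(20, 5.0), [1] * 5 + [0] * 15,
                          np.zeros(20), np.ones(20), ids=[f"u{i}" for i in range(20)])
    return pd.concat([exposed, unexposed], ignore_index=True)


class TestPoisson:
    def test_crude_rate_ratio_closed_form(self):
        res = fit_weighted_poisson(poisson_fixture(), variance="model")
        assert res.log_estimate == pytest.approx(np.log(2.0), abs=1e-8)
        # two-group Poisson model SE: sqrt(1/d1 + 1/d0)
        assert res.se == pytest.approx(np.sqrt(1 / 10 + 1 / 5), abs=1e-8)

    def test_offset_linearity(self):
        rows = poisson_fixture()
        doubled = rows.copy()
        doubled.loc[doubled["group"] == 1, "stop"] *= 2
        res1 = fit_weighted_poisson(rows, variance="none")
        res2 = fit_weighted_poisson(doubled, variance="none")
        assert res2.log_estimate == pytest.approx(res1.log_estimate - np.log(2), abs=1e-8)

    def test_irls_matches_weighted_closed_form(self):
        """Weights 2 on half the unexposed rows: IRLS equals the weighted
        crude rate ratio log[(sum w d / sum w pt)_1 / (sum w d / sum w pt)_0]."""
        rows = poisson_fixture()
        unexp = rows.index[rows["group"] == 0]
        rows.loc[unexp[:10], "weight"] = 2.0
        res = fit_weighted_poisson(rows, variance="none")
        w = rows["weight"].to_numpy()
        d = rows["event"].to_numpy()
        pt = (rows["stop"] - rows["start"]).to_numpy()
        g = rows["group"].to_numpy()
        expected = np.log((w[g == 1] @ d[g == 1]) / (w[g == 1] @ pt[g == 1])) - np.log(
            (w[g == 0] @ d[g == 0]) / (w[g == 0] @ pt[g == 0]))
        assert res.log_estimate == pytest.approx(expected, abs=1e-10)

    def test_zero_events_in_group_is_an_error(self):
        rows = poisson_fixture()
        rows.loc[rows["group"] == 1, "event"] = 0
        with pytest.raises(EstimatorError, match="zero weighted events"):
            fit_weighted_poisson(rows)

    def test_matches_statsmodels_var_weights(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        n = 300
        rows = make_rows(np.zeros(n), rng.uniform(0.5, 5, n),
                         rng.integers(0, 2, n), rng.integers(0, 2, n),
                         rng.uniform(0.5, 3, n))
        res = fit_weighted_poisson(rows, variance="robust")
        pt = (rows["stop"] - rows["start"]).to_numpy()
        x = sm.add_constant(rows["group"].to_numpy(float))
        glm = sm.GLM(rows["event"].to_numpy(float), x, family=sm.families.Poisson(),
                     offset=np.log(pt), var_weights=rows["weight"].to_numpy())
        assert res.log_estimate == pytest.approx(glm.fit().params[1], abs=1e-8)
        # HC0 with var_weights is the same singleton-cluster sandwich
        assert res.se == pytest.approx(glm.fit(cov_type="HC0").bse[1], abs=1e-8)


class TestSandwich:
    def test_singleton_clusters_equal_no_clusters(self):
        res = fit_weighted_poisson(poisson_fixture(), variance="none")
        cov_rows = robust_sandwich(res.fit, cluster_ids=None)
        cov_singleton = robust_sandwich(res.fit, cluster_ids=np.arange(40))
        np.testing.assert_allclose(cov_rows, cov_singleton, atol=1e-14)

    def test_cox_cluster_aggregation_changes_variance(self):
        """Grouping two rows of the same subject into one cluster must change
        B (scores sum within cluster) relative to splitting them."""
        rows = pd.concat([COX_FIXTURE, COX_FIXTURE], ignore_index=True)
        rows["weight"] = 0.5
        res = fit_weighted_cox(rows, variance="none")
        v_split = robust_sandwich(res.fit, cluster_ids=np.arange(12))
        v_merged = robust_sandwich(res.fit, cluster_ids=np.arange(12) % 6)
        assert v_merged == pytest.approx(2 * v_split, rel=1e-10)
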