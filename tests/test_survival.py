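"""Kaplan-Meier, log-rank, Cox and contingency estimators against
independent oracles (hand computation, lifelines, closed forms)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from failtiming.survival import (BackwardEliminatedCox, CoxPHModel,
                                 backward_eliminate, contingency_test,
                                 cox_fit, derive_endpoints, km_estimate,
                                 logrank_test, survival_at)

# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_worked_example(self):
        # hand product-limit: S(4) = (5/6)(4/5)(2/3) = 4/9
        curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        assert survival_at(curve, 4) == pytest.approx(4 / 9)
        assert survival_at(curve, 3.5) == pytest.approx(2 / 3)
        assert survival_at(curve, 0) == 1.0
        # beyond the last event the step function stays at its last value
        assert survival_at(curve, 100) == pytest.approx(survival_at(curve, 6))

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        assert survival_at(curve, 10) == 1.0

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=40))
    def test_no_censoring_equals_empirical_survival(self, times):
        curve = km_estimate(times, np.ones(len(times)))
        t = np.asarray(times)
        for q in [0.0, np.median(t), max(t)]:
            assert survival_at(curve, q) == pytest.approx(np.mean(t > q))

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(0)
        curve = km_estimate(rng.exponential(5, 200), rng.random(200) < 0.6)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank


def _logrank_by_hand(t1, e1, t2, e2):
    """Exhaustive O-E / hypergeometric-variance computation."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2]).astype(bool)
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    U = V = 0.0
    for tau in sorted(set(t[e])):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = (e & (t == tau)).sum()
        d1 = (e & (t == tau) & (g == 0)).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t, e = [1, 3, 5, 7.0], [1, 0, 1, 1]
        res = logrank_test((t, e), (t, e))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computation_oracle(self):
        t1, e1 = [2, 4, 4, 6, 9.0], [1, 1, 0, 1, 0]
        t2, e2 = [1, 4, 5, 8, 8.0], [1, 1, 1, 0, 1]
        res = logrank_test((t1, e1), (t2, e2))
        assert res.chi_square == pytest.approx(
            _logrank_by_hand(np.array(t1), np.array(e1),
                             np.array(t2), np.array(e2)), rel=1e-12)
        # observed minus expected sums to zero over groups
        assert (res.observed - res.expected).sum() == pytest.approx(0, abs=1e-9)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(7)
        for k in (2, 3):
            n = 150
            g = rng.integers(0, k, n)
            t = np.round(rng.exponential(12 * np.exp(0.3 * g)), 1) + 0.1
            e = rng.random(n) < 0.7
            mine = logrank_test(*[(t[g == j], e[g == j]) for j in range(k)])
            ref = multivariate_logrank_test(t, g, e)
            assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.8
        g = rng.integers(0, 2, 80)
        a = logrank_test((t[g == 0], e[g == 0]), (t[g == 1], e[g == 1]))
        b = logrank_test((t[g == 1], e[g == 1]), (t[g == 0], e[g == 0]))
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_zero_events_convention(self):
        res = logrank_test(([1, 2.0], [0, 0]), ([3, 4.0], [0, 0]))
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_power_under_strong_effect(self):
        """log-HR 1 with 500 per arm is detected essentially always."""
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(20.0, 500)
            t2 = rng.exponential(20.0 / np.e, 500)
            c1, c2 = rng.uniform(10, 60, 500), rng.uniform(10, 60, 500)
            res = logrank_test((np.minimum(t1, c1), t1 <= c1),
                               (np.minimum(t2, c2), t2 <= c2))
            rejections += res.p_value < 0.05
        assert rejections / n_seeds > 0.99

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(([1, 2], [1, 1]))

    def test_equals_cox_score_test_without_ties(self):
        rng = np.random.default_rng(12)
        n = 70
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10 * np.exp(0.5 * g))
        e = rng.random(n) < 0.8
        chi2, _ = CoxPHModel().score_test(g, t, e)
        lr = logrank_test((t[g == 0], e[g == 0]), (t[g == 1], e[g == 1]))
        assert chi2 == pytest.approx(lr.chi_square, abs=1e-6)


# ---------------------------------------------------------------------------
# Cox proportional hazards


class TestCox:
    def test_matches_reference_implementation(self):
        """Efron-ties fits agree with lifelines on random small datasets."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(40, 120))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            t = np.round(rng.exponential(10 * np.exp(0.4 * X[:, 0])), 1) + 0.1
            e = rng.random(n) < 0.75
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
            df["T"], df["E"] = t, e
            ref = CoxPHFitter().fit(df, "T", "E")
            mine = cox_fit(df[[f"x{i}" for i in range(p)]], t, e)
            assert np.max(np.abs(mine.coef - ref.params_.values)) < 1e-4
            assert np.max(np.abs(mine.se - ref.standard_errors_.values)) < 1e-4

    def test_breslow_matches_sksurv(self):
        from sksurv.linear_model import CoxPHSurvivalAnalysis
        from sksurv.util import Surv
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 2))
        t = np.round(rng.exponential(10 * np.exp(0.5 * X[:, 0]))) + 1
        e = rng.random(120) < 0.8
        mine = cox_fit(X, t, e, ties="breslow")
        ref = CoxPHSurvivalAnalysis(tol=1e-12).fit(X, Surv.from_arrays(e, t))
        assert np.max(np.abs(mine.coef - ref.coef_)) < 1e-6

    def test_result_invariants(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        t = rng.exponential(10 * np.exp(0.3 * X[:, 0]))
        e = rng.random(200) < 0.7
        model = CoxPHModel().fit(X, t, e)
        fit = model.result_
        assert np.allclose(fit.hazard_ratio, np.exp(fit.coef))
        assert np.all(fit.ci_lower <= fit.hazard_ratio)
        assert np.all(fit.hazard_ratio <= fit.ci_upper)
        # damped Newton: the negative log partial likelihood never increases
        assert np.all(np.diff(model.nll_path_) <= 1e-10)
        assert model.converged_

    def test_null_covariate_calibration(self):
        """An independent covariate stays near zero with a null P value."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            n = 2000
            x = rng.normal(size=n)
            t = rng.exponential(20.0, n)
            c = rng.uniform(10, 60, n)
            fit = cox_fit(x, np.minimum(t, c), t <= c)
            ok += (abs(fit.coef[0]) < 0.1) and (fit.p_value[0] > 0.05)
        assert ok >= 90

    def test_no_event_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], [0, 0, 0, 0, 0])


class TestBackwardElimination:
    @staticmethod
    def _make(seed, n=1200, loghr=1.0, n_noise=3):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"true": rng.integers(0, 2, n).astype(float)})
        for i in range(n_noise):
            X[f"noise{i}"] = rng.integers(0, 2, n).astype(float)
        lam = 0.01 * np.exp(loghr * X["true"].to_numpy())
        t = rng.exponential(1 / lam)
        c = rng.uniform(30, 90, n)
        return X, np.minimum(t, c), t <= c

    def test_true_effect_retained_noise_dropped(self):
        X, t, e = self._make(seed=2)
        est = BackwardEliminatedCox().fit(X, t, e)
        assert "true" in est.retained_
        dropped = {name for name, _ in est.elimination_trace_}
        assert dropped.isdisjoint(est.retained_)

    def test_screened_out_candidate_gives_empty_fit(self):
        # frozen seed where the univariable noise covariate has P ~ 0.9
        rng = np.random.default_rng(77)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(20, n)
        e = rng.random(n) < 0.8
        uni = cox_fit(x, t, e)
        assert uni.p_value[0] > 0.10  # guards the fixture itself
        fit = backward_eliminate(pd.DataFrame({"x": x}), t, e)
        assert fit.names == []
        assert fit.elimination_trace[0][0] == "x"

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            backward_eliminate(pd.DataFrame(), [1, 2], [1, 1])


# ---------------------------------------------------------------------------
# contingency tests


class TestContingency:
    def test_balanced_table_is_null(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "chi-square"

    def test_sparse_2x2_uses_fisher_with_enumerated_p(self):
        res = contingency_test([[3, 1], [1, 3]])
        assert res.method == "fisher"
        # exhaustive hypergeometric enumeration of tables at least as extreme
        p_exact = sum(stats.hypergeom.pmf(k, 8, 4, 4)
                      for k in range(5)
                      if stats.hypergeom.pmf(k, 8, 4, 4)
                      <= stats.hypergeom.pmf(3, 8, 4, 4) + 1e-12)
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_matches_textbook_formula(self):
        tab = np.array([[20, 30, 25], [25, 24, 31]])
        res = contingency_test(tab)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        chi2 = ((tab - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 2), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[0, 0], [5, 3]])


# ---------------------------------------------------------------------------
# endpoint derivation


def _record(pid="P1", tl=60.0, el=0, td=60.0, ed=0, to=60.0, dead=0):
    return {"patient_id": pid, "t_locoregional": tl, "locoregional_event": el,
            "t_distant": td, "distant_event": ed,
            "t_death_or_lastcontact": to, "death": dead}


class TestDeriveEndpoints:
    def test_postfailure_clock(self):
        df = pd.DataFrame([_record(tl=10, el=1, td=25, to=25, dead=1)])
        ep = derive_endpoints(df)
        assert ep.loc[0, "pf_lrf_time"] == pytest.approx(15)
        assert ep.loc[0, "pf_lrf_event"] == 1
        assert np.isnan(ep.loc[0, "pf_df_time"])  # no distant failure

    def test_event_free_patient_censored_everywhere(self):
        ep = derive_endpoints(pd.DataFrame([_record()]))
        for name in ("os", "ffs", "lrffs", "dffs"):
            assert ep.loc[0, f"{name}_time"] == 60
            assert ep.loc[0, f"{name}_event"] == 0

    def test_ffs_is_first_event(self, cohort10k, endpoints10k):
        ep = endpoints10k
        for name in ("lrffs", "dffs", "os"):
            assert (ep["ffs_time"] <= ep[f"{name}_time"] + 1e-9).all()

    def test_failure_fraction_matches_generator_oracle(self, cohort10k,
                                                       endpoints10k):
        from failtiming.cohort import expected_event_fractions
        params, _ = cohort10k
        exp = expected_event_fractions(params)["locoregional"]
        obs = endpoints10k["lrffs_event"].mean()
        se = np.sqrt(exp * (1 - exp) / len(endpoints10k))
        assert abs(obs - exp) < 4 * se

    def test_invalid_record_lists_offender(self):
        df = pd.DataFrame([_record(), _record(pid="P2", tl=-1)])
        with pytest.raises(ValueError, match="P2"):
            derive_endpoints(df)

    def test_failure_after_death_rejected(self):
        df = pd.DataFrame([_record(pid="P9", tl=80, el=1, to=50, dead=1)])
        with pytest.raises(ValueError, match="P9"):
            derive_endpoints(df)
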