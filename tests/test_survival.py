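"""Kaplan-Meier, log-rank, the Cox partial-likelihood fit, and the
univariate-screen -> multivariate procedure."""

import numpy as np
import pandas as pd
import pytest

from immunoprox import (
    SurvivalRecord,
    administrative_censor,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    screen_then_model,
)
from immunoprox.survival import FitError, ZeroEventsError, cox_loglik


def _simulate_cox(rng, n, beta, lam0=0.05, cmax=80.0, binary=True):
    x = (
        rng.binomial(1, 0.5, n).astype(float)
        if binary
        else rng.normal(0, 1, n)
    )
    t_event = rng.exponential(1.0 / (lam0 * np.exp(beta * x)))
    cens = rng.uniform(0, cmax, n)
    return x, np.minimum(t_event, cens), (t_event <= cens).astype(int)


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        curve = km_estimate((np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1])))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])
        assert curve.evaluate(0.5) == 1.0
        assert curve.evaluate(2.5) == pytest.approx(1 / 3)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate((np.array([5.0, 7.0, 9.0]), np.array([0, 0, 0])))
        assert curve.event_times.size == 0
        assert curve.evaluate(100.0) == 1.0

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(10.0, 200)
        curve = km_estimate((t, np.ones(200, dtype=int)))
        for q in (2.0, 5.0, 10.0, 20.0):
            assert curve.evaluate(q) == pytest.approx(np.mean(t > q))

    def test_subject_order_invariance(self, rng):
        t = rng.exponential(10.0, 50)
        e = rng.binomial(1, 0.7, 50)
        a = km_estimate((t, e))
        perm = rng.permutation(50)
        b = km_estimate((t[perm], e[perm]))
        np.testing.assert_allclose(a.survival, b.survival)

    def test_late_censored_subject_enters_all_risk_sets(self):
        """A subject censored after the last event adds no event time but sits
        in every risk set; hand product-limit values confirm both effects."""
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        b = km_estimate((np.append(t, 10.0), np.append(e, 0)))
        np.testing.assert_array_equal(b.event_times, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(b.at_risk, [4, 3, 2])
        np.testing.assert_allclose(b.survival, [3 / 4, 1 / 2, 1 / 4])
        # beyond the censoring time the curve stays flat at the last value
        assert b.evaluate(50.0) == pytest.approx(1 / 4)
        # the exact censoring time is irrelevant once past the last event
        c = km_estimate((np.append(t, 99.0), np.append(e, 0)))
        np.testing.assert_allclose(c.survival, b.survival)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate((np.array([0.0, 1.0]), np.array([1, 1])))
        with pytest.raises(ValueError):
            SurvivalRecord("p", -1.0, 1)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        res = logrank_test((t, e), (t.copy(), e.copy()))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        """Alternating tie-free event times, computed by explicit O/E/V
        tabulation with the hypergeometric variance."""
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 1])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 1, 1])

        # oracle: walk the pooled event times
        times = np.concatenate([ta, tb])
        group = np.array([0, 0, 0, 1, 1, 1])
        order = np.argsort(times)
        o = e_exp = v = 0.0
        for i, idx in enumerate(order):
            n_at_risk = len(times) - i
            n_a = np.sum(times[group == 0] >= times[idx])
            frac = n_a / n_at_risk
            o += group[idx] == 0
            e_exp += frac
            v += frac * (1 - frac)
        expected = (o - e_exp) ** 2 / v

        res = logrank_test((ta, ea), (tb, eb))
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_symmetric_in_group_labels(self, rng):
        xa = rng.exponential(10, 30)
        xb = rng.exponential(15, 25)
        ea = rng.binomial(1, 0.8, 30)
        eb = rng.binomial(1, 0.8, 25)
        r1 = logrank_test((xa, ea), (xb, eb))
        r2 = logrank_test((xb, eb), (xa, ea))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_invariant_under_monotone_time_transform(self, rng):
        xa = rng.exponential(10, 30)
        xb = rng.exponential(15, 25)
        ea = rng.binomial(1, 0.8, 30)
        eb = rng.binomial(1, 0.8, 25)
        r1 = logrank_test((xa, ea), (xb, eb))
        r2 = logrank_test((np.log1p(xa), ea), (np.log1p(xb), eb))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_zero_events_signalled(self):
        t = np.array([1.0, 2.0])
        with pytest.raises(ZeroEventsError):
            logrank_test((t, np.zeros(2, int)), (t, np.zeros(2, int)))


class TestCoxFit:
    def test_null_binary_covariate_gives_hr_one(self):
        # two groups with literally identical survival experience
        t = np.tile(np.array([2.0, 4.0, 6.0, 8.0, 10.0]), 2)
        e = np.tile(np.array([1, 1, 0, 1, 0]), 2)
        x = np.repeat([0.0, 1.0], 5)
        fit = cox_fit(x[:, None], (t, e))
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_loglik_at_estimate_matches_grid_search(self):
        """Small tie-free fixture: beta-hat maximises the partial likelihood,
        cross-checked against a dense grid scan."""
        t = np.array([1.0, 2.5, 3.0, 4.5, 6.0, 7.5, 9.0])
        e = np.array([1, 1, 0, 1, 1, 0, 1])
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, -0.2])
        fit = cox_fit(x[:, None], (t, e))
        grid = np.linspace(fit.beta[0] - 2, fit.beta[0] + 2, 4001)
        lls = [cox_loglik(x, (t, e), b) for b in grid]
        assert fit.loglik >= max(lls) - 1e-4
        assert abs(grid[int(np.argmax(lls))] - fit.beta[0]) < 2e-3

    def test_likelihood_at_estimate_exceeds_null(self, rng):
        x, t, e = _simulate_cox(rng, 120, 0.8)
        fit = cox_fit(x[:, None], (t, e))
        assert fit.loglik >= fit.loglik_null

    def test_matches_lifelines_efron(self, rng):
        """Independent implementation cross-check, heavy ties included."""
        x, t, e = _simulate_cox(rng, 200, 0.7)
        t = np.ceil(t)  # induce ties
        fit = cox_fit(x[:, None], (t, e), ties="efron", names=["x"])

        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_parameter_recovery(self, rng):
        x, t, e = _simulate_cox(rng, 500, 0.7, binary=False)
        fit = cox_fit(x[:, None], (t, e))
        assert fit.beta[0] == pytest.approx(0.7, abs=0.15)

    def test_score_test_equals_logrank_on_tie_free_data(self, rng):
        x, t, e = _simulate_cox(rng, 80, 0.5)
        stat, _ = cox_score_test(x[:, None], (t, e), ties="breslow")
        hi = x == 1
        lr = logrank_test((t[hi], e[hi]), (t[~hi], e[~hi]))
        assert stat == pytest.approx(lr.statistic, abs=1e-6)

    def test_efron_equals_breslow_without_ties(self, rng):
        x, t, e = _simulate_cox(rng, 60, 0.5, binary=False)
        a = cox_fit(x[:, None], (t, e), ties="efron")
        b = cox_fit(x[:, None], (t, e), ties="breslow")
        assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-7)

    def test_constant_covariate_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        with pytest.raises(FitError, match="constant"):
            cox_fit(np.ones((3, 1)), (t, e))

    def test_more_covariates_than_events_rejected(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 0])
        X = np.array([[1.0, 2.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(FitError, match="events"):
            cox_fit(X, (t, e))

    def test_separation_flagged(self):
        # perfect split: all group-1 events precede every group-0 event
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(x[:, None], (t, e))
        assert "monotone_likelihood" in fit.flags


class TestScreenThenModel:
    def test_strong_variable_selected_nulls_mostly_rejected(self, rng):
        n = 400
        z = rng.normal(0, 1, n)
        t_event = rng.exponential(1.0 / (0.05 * np.exp(1.0 * (z > 0))))
        cens = rng.uniform(0, 60, n)
        t = np.minimum(t_event, cens)
        e = (t_event <= cens).astype(int)
        design = pd.DataFrame({"strong": (z > 0).astype(float)})
        for j in range(9):
            design[f"null{j}"] = rng.binomial(1, 0.5, n).astype(float)
        res = screen_then_model(design, (t, e))
        assert "strong" in res.selected
        assert len([v for v in res.selected if v.startswith("null")]) <= 2
        assert res.multivariate is not None
        assert "strong" in res.multivariate.names

    def test_alpha_zero_selects_nothing(self, rng):
        x, t, e = _simulate_cox(rng, 100, 1.0)
        res = screen_then_model(pd.DataFrame({"x": x}), (t, e), alpha=0.0)
        assert res.selected == []
        assert res.multivariate is None
        assert res.notes

    def test_identical_copies_flag_collinearity(self, rng):
        x, t, e = _simulate_cox(rng, 150, 1.0)
        design = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        res = screen_then_model(design, (t, e))
        assert any("collinear" in n for n in res.notes)
        assert res.multivariate is not None
        assert len(res.multivariate.names) == 1

    def test_logrank_p_reported_for_binary_candidates(self, rng):
        x, t, e = _simulate_cox(rng, 120, 0.8)
        res = screen_then_model(pd.DataFrame({"x": x}), (t, e))
        assert "p_logrank" in res.univariate.columns
        assert np.isfinite(res.univariate["p_logrank"]).all()


class TestAdministrativeCensoring:
    def test_five_year_rfs_rule(self):
        t = np.array([12.0, 60.0, 80.0])
        e = np.array([1, 1, 1])
        tc, ec = administrative_censor(t, e, horizon=60.0)
        np.testing.assert_array_equal(tc, [12.0, 60.0, 60.0])
        np.testing.assert_array_equal(ec, [1, 1, 0])
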