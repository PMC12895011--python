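"""Survival stack against hand tables, brute-force pair enumeration, and lifelines."""

import numpy as np
import pytest
from lifelines import CoxPHFitter
import pandas as pd

import histomil as hm
from histomil import (
    SurvivalData,
    censor_at,
    compare_correlated_cindex,
    concordance_index,
    cox_univariable,
    cumulative_recurrence,
    logrank_test,
    threshold_continuous_predictions,
)


def brute_force_cindex(time, event, pred):
    """O(n^2) pair enumeration with the declared pair rule."""
    credit = comparable = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                comparable += 1
                if pred[i] > pred[j]:
                    credit += 1
                elif pred[i] == pred[j]:
                    credit += 0.5
    return credit / comparable


def random_survival(rng, n, with_pred_ties=False):
    time = np.round(rng.exponential(5, size=n), 1)
    event = rng.random(n) < 0.7
    pred = np.round(rng.normal(size=n), 1) if with_pred_ties else rng.normal(size=n)
    return SurvivalData(time, event, pred)


class TestCensoring:
    def test_event_after_horizon_censored(self):
        d = censor_at(SurvivalData([12.0], [True], [1.0]))
        assert d.time[0] == 10.0 and not d.event[0]

    def test_event_at_horizon_kept(self):
        d = censor_at(SurvivalData([10.0], [True], [1.0]))
        assert d.time[0] == 10.0 and d.event[0]

    def test_early_censoring_untouched(self):
        d = censor_at(SurvivalData([3.0], [False], [1.0]))
        assert d.time[0] == 3.0 and not d.event[0]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalData([-1.0], [True], [0.0])


class TestConcordance:
    def test_perfect_ordering(self):
        d = SurvivalData([1, 2, 3], [1, 1, 1], [3, 2, 1])
        assert concordance_index(d) == 1.0

    def test_predictor_tie_half_credit(self):
        d = SurvivalData([1, 2, 3], [1, 1, 1], [3, 3, 1])
        assert concordance_index(d) == pytest.approx(2.5 / 3)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(SurvivalData([1, 2], [0, 1], [1, 2]))  # only the later time has an event

    def test_brute_force_agreement_with_censoring(self, rng):
        for _ in range(200):
            d = random_survival(rng, int(rng.integers(5, 31)), with_pred_ties=True)
            if not d.event.any():
                continue
            try:
                c = concordance_index(d)
            except ValueError:
                continue
            assert c == pytest.approx(brute_force_cindex(d.time, d.event, d.predictor), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        d = random_survival(rng, 25)
        d2 = SurvivalData(d.time, d.event, np.exp(d.predictor))
        assert concordance_index(d) == pytest.approx(concordance_index(d2))

    def test_complement_identity_without_ties(self, rng):
        d = random_survival(rng, 25)
        d2 = SurvivalData(d.time, d.event, -d.predictor)
        assert concordance_index(d) + concordance_index(d2) == pytest.approx(1.0)


class TestCorrelatedCindex:
    def test_identical_predictors_give_p_one(self, rng):
        d = random_survival(rng, 30)
        res = compare_correlated_cindex(d, d)
        assert res.effect == 0.0 and res.p_value == 1.0

    def test_mismatched_outcomes_rejected(self, rng):
        a = random_survival(rng, 20)
        b = random_survival(rng, 20)
        with pytest.raises(ValueError):
            compare_correlated_cindex(a, b)

    def test_bootstrap_oracle_agreement(self, rng):
        """Jackknife variance of dC vs a 2000-resample paired bootstrap."""
        for trial in range(3):
            time = rng.exponential(5, size=60)
            event = rng.random(60) < 0.7
            pa, pb = rng.normal(size=60), rng.normal(size=60)
            da = SurvivalData(time, event, pa)
            db = SurvivalData(time, event, pb)
            res = compare_correlated_cindex(da, db)
            deltas = []
            for _ in range(2000):
                idx = rng.integers(0, 60, size=60)
                try:
                    ca = brute_np_cindex(time[idx], event[idx], pa[idx])
                    cb = brute_np_cindex(time[idx], event[idx], pb[idx])
                except ZeroDivisionError:
                    continue
                deltas.append(ca - cb)
            boot_sd = np.std(deltas, ddof=1)
            jack_sd = abs(res.effect - 0) / abs(res.statistic) if res.statistic != 0 else np.nan
            assert jack_sd == pytest.approx(boot_sd, rel=0.35)
            from scipy import stats as ss
            p_boot = 2 * ss.norm.sf(abs(res.effect) / boot_sd)
            assert res.p_value == pytest.approx(p_boot, abs=0.1)


def brute_np_cindex(time, event, pred):
    comp = (time[:, None] < time[None, :]) & event[:, None]
    n = comp.sum()
    if n == 0:
        raise ZeroDivisionError
    credit = comp * ((pred[:, None] > pred[None, :]) + 0.5 * (pred[:, None] == pred[None, :]))
    return credit.sum() / n


class TestCox:
    def test_grid_search_oracle(self):
        """Newton solution vs dense grid maximisation of the hand-written
        Breslow partial log-likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1], dtype=bool)
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def loglik(beta):
            ll = 0.0
            for i in range(4):
                risk = time >= time[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-5, 5, 200_001)
        beta_grid = grid[np.argmax([loglik(b) for b in grid])]
        fit = cox_univariable(SurvivalData(time, event, x))
        assert fit.coef == pytest.approx(beta_grid, abs=1e-4)
        assert fit.converged

    def test_lifelines_cross_check(self, rng):
        # untied continuous times: Breslow and Efron coincide
        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(scale=np.exp(-0.5 * x))
        event = rng.random(n) < 0.8
        fit = cox_univariable(SurvivalData(time, event, x))
        df = pd.DataFrame({"T": time, "E": event, "x": x})
        ll = CoxPHFitter().fit(df, "T", "E")
        assert fit.coef == pytest.approx(ll.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(ll.standard_errors_["x"], abs=1e-4)

    def test_negation_antisymmetry(self, rng):
        d = random_survival(rng, 40)
        f1 = cox_univariable(d)
        f2 = cox_univariable(SurvivalData(d.time, d.event, -d.predictor))
        assert f1.coef == pytest.approx(-f2.coef, abs=1e-6)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            cox_univariable(SurvivalData([1, 2, 3], [1, 1, 0], [2, 2, 2]))

    def test_monotone_likelihood_flagged(self):
        # predictor perfectly separates early events from late censoring
        fit = cox_univariable(SurvivalData([1, 2, 9, 10], [1, 1, 0, 0], [10.0, 9.0, 0.1, 0.0]))
        assert not fit.converged
        assert "monotone" in fit.note or "convergence" in fit.note

    def test_summary_mentions_hazard_ratio(self, rng):
        fit = cox_univariable(random_survival(rng, 40))
        assert "HR" in fit.summary()


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        res = logrank_test(SurvivalData(time, event, np.zeros(8)), groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_oe_table(self):
        """Group A events at t=1,2; group B events at t=3,4: O, E and V
        accumulated by hand over the four event times."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1], dtype=bool)
        groups = np.array(["A", "A", "B", "B"])
        o_a = e_a = v = 0.0
        for t in sorted(time):
            at_risk = time >= t
            n_a = (at_risk & (groups == "A")).sum()
            n_tot = at_risk.sum()
            d = ((time == t) & event).sum()
            o_a += ((time == t) & event & (groups == "A")).sum()
            e_a += d * n_a / n_tot
            if n_tot > 1:
                v += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
        chi2_hand = (o_a - e_a) ** 2 / v
        res = logrank_test(SurvivalData(time, event, np.zeros(4)), groups)
        assert res.statistic == pytest.approx(chi2_hand, rel=1e-6)

    def test_label_swap_invariance(self, rng):
        d = random_survival(rng, 30)
        groups = np.where(rng.random(30) < 0.5, "x", "y")
        if len(set(groups)) < 2:
            groups[0], groups[1] = "x", "y"
        r1 = logrank_test(d, groups)
        swapped = np.where(groups == "x", "y", "x")
        r2 = logrank_test(d, swapped)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_single_group_rejected(self, rng):
        d = random_survival(rng, 10)
        with pytest.raises(ValueError):
            logrank_test(d, np.repeat("a", 10))


class TestCumulativeRecurrence:
    def test_no_events_flat_zero(self):
        d = SurvivalData([1, 2, 3], [0, 0, 0], [0, 0, 0])
        curves = cumulative_recurrence(d, np.repeat("g", 3))
        _, ci = curves["g"]
        assert np.all(ci == 0.0)

    def test_single_event_jump(self):
        d = SurvivalData([1, 2, 3, 4], [1, 0, 0, 0], [0] * 4)
        times, ci = cumulative_recurrence(d, np.repeat("g", 4))["g"]
        assert ci[times == 1.0][0] == pytest.approx(1 / 4)  # no censoring before the event

    def test_hand_product_limit_table(self):
        # 5 subjects: events at 1 and 3, censored at 2, events at 4, censored at 5
        d = SurvivalData([1, 2, 3, 4, 5], [1, 0, 1, 1, 0], [0] * 5)
        times, ci = cumulative_recurrence(d, np.repeat("g", 5))["g"]
        surv_hand = {1: 4 / 5, 3: 4 / 5 * 2 / 3, 4: 4 / 5 * 2 / 3 * 1 / 2}
        for t, s in surv_hand.items():
            assert 1 - ci[times == float(t)][0] == pytest.approx(s)


class TestThresholding:
    def test_assay_cutoff(self):
        out = threshold_continuous_predictions([52.94118, 52.94117, 10.0, 80.0])
        np.testing.assert_array_equal(out, [1, 0, 0, 1])

    def test_single_group_warns(self):
        with pytest.warns(UserWarning, match="single group"):
            threshold_continuous_predictions([1.0, 2.0])
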