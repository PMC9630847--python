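"""Cox estimation, hazard-weighted scoring, cut-point and log-rank."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triadnet.ptpscore_survival import (
    HazardEstimate,
    NoEventsError,
    SurvivalTable,
    cox_univariate,
    km_logrank,
    logrank_chisq,
    optimal_cutpoint,
    ptp_score,
    select_significant,
)


def _sim_survival(rng, x, beta, censor=0.0, h0=0.05):
    lam = h0 * np.exp(beta * x)
    T = rng.exponential(1.0 / lam)
    if censor > 0:
        C = rng.exponential(1.0 / (censor / (1 - censor) * lam.mean()), x.size)
        return SurvivalTable(
            tuple(map(str, range(x.size))), np.minimum(T, C), (T <= C).astype(int)
        )
    return SurvivalTable(tuple(map(str, range(x.size))), T, np.ones(x.size, int))


class TestCoxUnivariate:
    def test_matches_lifelines_on_untied_data(self, rng):
        from lifelines import CoxPHFitter

        x = rng.standard_normal(150)
        table = _sim_survival(rng, x, 0.6)
        mine = cox_univariate(x, table, ties="efron")
        df = pd.DataFrame({"t": table.time, "e": table.event, "x": x})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert mine.coef == pytest.approx(ll.params_.iloc[0], abs=1e-4)
        assert mine.se == pytest.approx(ll.standard_errors_.iloc[0], rel=1e-3)
        # Breslow equals Efron when no event times are tied
        breslow = cox_univariate(x, table, ties="breslow")
        assert breslow.coef == pytest.approx(mine.coef, abs=1e-9)

    def test_tied_event_times_breslow_vs_lifelines_efron_close(self, rng):
        from lifelines import CoxPHFitter

        x = rng.standard_normal(120)
        table = _sim_survival(rng, x, 0.7)
        rounded = SurvivalTable(
            table.samples, np.ceil(table.time * 2) / 2, table.event
        )
        mine = cox_univariate(x, rounded, ties="efron")
        df = pd.DataFrame({"t": rounded.time, "e": rounded.event, "x": x})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert mine.coef == pytest.approx(ll.params_.iloc[0], abs=1e-4)

    def test_planted_hr_recovery(self):
        hrs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(500)
            table = _sim_survival(rng, x, math.log(2), censor=0.2)
            hrs.append(cox_univariate(x, table).hr)
        assert 1.8 <= np.median(hrs) <= 2.2

    def test_no_events_raises(self):
        table = SurvivalTable(("a", "b", "c"), np.ones(3), np.zeros(3, int))
        with pytest.raises(NoEventsError):
            cox_univariate(np.arange(3.0), table)

    def test_constant_covariate_flagged(self):
        table = SurvivalTable(
            tuple("abcd"), np.array([1.0, 2, 3, 4]), np.ones(4, int)
        )
        est = cox_univariate(np.ones(4), table)
        assert not est.ok and np.isnan(est.hr)


class TestSelectSignificant:
    def test_threshold(self):
        ests = [
            HazardEstimate("g1", 2.0, 0.7, 0.1, 0.01, 50),
            HazardEstimate("g2", 1.1, 0.1, 0.1, 0.2, 50),
        ]
        assert select_significant(ests) == ["g1"]

    def test_empty_roster_warns(self):
        ests = [HazardEstimate("g1", 1.0, 0.0, 0.1, 0.5, 50)]
        with pytest.warns(UserWarning):
            assert select_significant(ests) == []

    def test_mixture_recall_and_precision(self):
        # 50% of genes carry a real effect at beta = log 2
        rng = np.random.default_rng(5)
        true_genes, ests = set(), []
        for i in range(40):
            x = rng.standard_normal(300)
            beta = math.log(2) if i % 2 == 0 else 0.0
            if beta:
                true_genes.add(f"g{i}")
            table = _sim_survival(rng, x, beta)
            ests.append(
                cox_univariate(x, table, gene=f"g{i}")
            )
        roster = set(select_significant(ests))
        recall = len(roster & true_genes) / len(true_genes)
        precision = len(roster & true_genes) / len(roster)
        assert recall >= 0.9
        assert precision >= 0.7


class TestPTPScore:
    def _z(self, values, genes, samples):
        return pd.DataFrame(values, index=genes, columns=samples)

    def test_hand_example(self):
        # HR 2.0 and 0.5, z-expression +1 and -1 -> (2.0 - 0.5) / 2 = 0.75
        z = self._z([[1.0, -1.0], [-1.0, 1.0]], ["g1", "g2"], ["s1", "s2"])
        result = ptp_score(z, {"g1": 2.0, "g2": 0.5})
        assert result.scores["s1"] == pytest.approx((2.0 * 1 + 0.5 * -1) / 2)
        assert result.scores["s1"] == pytest.approx(0.75)

    def test_zero_expression_zero_score(self):
        z = self._z([[1.0, -1.0, 0.0]], ["g"], ["a", "b", "c"])
        # relax: column c has z 0 -> score 0
        result = ptp_score(z, {"g": 3.0})
        assert result.scores["c"] == 0.0

    def test_single_gene_reduction(self, rng):
        e = rng.standard_normal(40)
        e = (e - e.mean()) / e.std(ddof=1)
        z = self._z([e], ["g"], [f"s{i}" for i in range(40)])
        hr = 1.7
        result = ptp_score(z, {"g": hr})
        np.testing.assert_allclose(result.scores.to_numpy(), e * hr)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity_in_expression(self, seed, c):
        r = np.random.default_rng(seed)
        vals = r.standard_normal((3, 25))
        vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
            axis=1, ddof=1, keepdims=True
        )
        z = pd.DataFrame(vals, index=list("abc"), columns=range(25))
        weights = {"a": 1.5, "b": 0.5, "c": 2.5}
        base = ptp_score(z, weights).scores
        # scaling all z-values by c scales every score by c (checked on the
        # raw linear form; the scaled matrix itself is no longer unit-sd)
        manual = (vals * np.array([[1.5], [0.5], [2.5]])).mean(axis=0)
        np.testing.assert_allclose(base.to_numpy(), manual)
        np.testing.assert_allclose(c * base.to_numpy(), (c * vals * np.array([[1.5], [0.5], [2.5]])).mean(axis=0))

    def test_unnormalized_input_rejected(self):
        z = self._z([[5.0, 7.0, 9.0]], ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="z-normalized"):
            ptp_score(z, {"g": 2.0})

    def test_empty_roster_rejected(self):
        z = pd.DataFrame(np.empty((0, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="roster"):
            ptp_score(z, {})


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        # both groups observe exactly the same death times
        time = np.array([1.0, 2, 3, 4, 5, 6] * 2)
        event = np.ones(12, int)
        group = np.array([0] * 6 + [1] * 6)
        chi, p = logrank_chisq(time, event, group == 1)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_six_sample_table(self):
        # groups A: deaths at 1, 3, 5; B: deaths at 2, 4, 6 (no censoring).
        # Mantel-Haenszel by hand: O-E = -23/30, V = 1091/900,
        # chi-square = (23/30)^2 / (1091/900) = 529/1091.
        time = np.array([1.0, 3, 5, 2, 4, 6])
        event = np.ones(6, int)
        group = np.array([False, False, False, True, True, True])
        chi, _ = logrank_chisq(time, event, group)
        assert chi == pytest.approx(float(Fraction(529, 1091)), abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        x = rng.standard_normal(100)
        table = _sim_survival(rng, x, 0.8, censor=0.2)
        mask = x > 0
        chi, p = logrank_chisq(table.time, table.event, mask)
        ref = logrank_test(
            table.time[mask],
            table.time[~mask],
            table.event[mask],
            table.event[~mask],
        )
        assert chi == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_km_logrank_returns_curves(self, rng):
        x = rng.standard_normal(60)
        table = _sim_survival(rng, x, 1.0)
        res = km_logrank((x > 0).astype(int), table)
        assert set(res.km_curves) == {"0", "1"}
        for curve in res.km_curves.values():
            assert (curve.iloc[-1] <= curve.iloc[0]).all()


class TestOptimalCutpoint:
    def test_planted_threshold_recovered(self):
        found = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            score = rng.standard_normal(400)
            lam = 0.05 * 3.0 ** (score > 0)
            T = rng.exponential(1.0 / lam)
            table = SurvivalTable(tuple(map(str, range(400))), T, np.ones(400, int))
            found.append(optimal_cutpoint(score, table).cutpoint)
        inside = np.mean([abs(c) <= 0.2 for c in found])
        assert inside >= 0.8

    def test_minprop_half_forces_median(self, rng):
        score = rng.standard_normal(100)
        table = _sim_survival(rng, score, 1.0)
        cut = optimal_cutpoint(score, table, minprop=0.5)
        assert cut.n_low == cut.n_high == 50
        assert cut.cutpoint == pytest.approx(np.sort(score)[49])

    def test_invariant_under_monotone_transform(self, rng):
        score = rng.standard_normal(120)
        table = _sim_survival(rng, score, 1.0)
        a = optimal_cutpoint(score, table)
        b = optimal_cutpoint(np.exp(score), table)
        assert b.chi_sq == pytest.approx(a.chi_sq)
        assert b.cutpoint == pytest.approx(np.exp(a.cutpoint))

    def test_null_survival_still_returns_value(self, rng):
        score = rng.standard_normal(80)
        table = _sim_survival(rng, np.zeros(80), 0.0)
        cut = optimal_cutpoint(score, table)
        assert np.isfinite(cut.cutpoint)

    def test_constant_scores_rejected(self, rng):
        table = _sim_survival(rng, np.zeros(10), 0.0)
        with pytest.raises(ValueError):
            optimal_cutpoint(np.ones(10), table)
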