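"""Unit tests for contingency scores, reliability, ROC and stress areas."""

import numpy as np
import pytest

import cropcsi as cc
from cropcsi.errors import DegenerateSeriesError
from cropcsi.verification import ContingencyTable


class TestEts:
    def test_perfect_forecast_scores_one(self):
        assert cc.ets(ContingencyTable(j=8, k=0, l=0, m=22)) == pytest.approx(1.0)

    def test_symmetric_no_skill_table(self):
        # j_r = (10*10)/20 = 5 -> ETS = 0
        assert cc.ets(ContingencyTable(5, 5, 5, 5)) == pytest.approx(0.0)

    def test_hand_evaluated_table(self):
        # j_r = (3*3)/10 = 0.9 -> (2 - 0.9) / (4 - 0.9)
        assert cc.ets(ContingencyTable(2, 1, 1, 6)) == pytest.approx(1.1 / 3.1)

    def test_all_correct_negatives_undefined(self):
        assert np.isnan(cc.ets(ContingencyTable(0, 0, 0, 30)))

    def test_invariant_under_cell_scaling(self):
        t1 = ContingencyTable(3, 2, 4, 21)
        t5 = ContingencyTable(15, 10, 20, 105)
        assert cc.ets(t1) == pytest.approx(cc.ets(t5), abs=1e-12)


class TestContingency:
    def test_counting_with_geq_rule(self):
        t = cc.contingency_from_probs(np.array([0.6, 0.5]), np.array([1, 1]),
                                      member_fraction=0.6)
        assert (t.j, t.k, t.l, t.m) == (1, 0, 1, 0)

    def test_zero_fraction_forecasts_every_year(self):
        t = cc.contingency_from_probs(np.linspace(0, 1, 30),
                                      np.zeros(30, bool), member_fraction=0.0)
        assert t.l == 0 and t.m == 0

    def test_matches_year_by_year_tally(self, rng):
        probs = rng.integers(0, 11, 30) / 10
        outcomes = rng.random(30) < 0.25
        t = cc.contingency_from_probs(probs, outcomes, 0.6)
        j = k = l = m = 0
        for p, o in zip(probs, outcomes):
            fe = p >= 0.6
            j += fe and o
            k += fe and not o
            l += (not fe) and o
            m += (not fe) and not o
        assert (t.j, t.k, t.l, t.m) == (j, k, l, m)


class TestEventProbabilities:
    def test_member_counting(self):
        member_csi = np.array([[-2.0], [-1.5], [-1.2], [-1.1], [-1.05],
                               [-1.01], [0.5], [1.0], [2.0], [3.0]])
        probs, _ = cc.event_probabilities(member_csi, np.array([0.0]), -1.0)
        assert probs[0] == pytest.approx(0.6)

    def test_no_members_below(self):
        probs, _ = cc.event_probabilities(np.ones((10, 4)), np.zeros(4), -1.0)
        assert np.all(probs == 0)

    def test_quartile_base_rate_over_30_years(self, rng):
        csi = rng.standard_normal(30)
        thr = cc.event_threshold(csi, 0.25)
        assert int(np.sum(csi < thr)) in (7, 8)


class TestReliability:
    def test_calibrated_ensemble_slope_near_one(self, rng):
        probs = rng.integers(0, 11, size=5000) / 10.0
        outcomes = rng.random(5000) < probs
        rel = cc.reliability_diagram(probs, outcomes, n_boot=200,
                                     rng=np.random.default_rng(5))
        assert 0.9 <= rel.slope <= 1.1
        assert rel.slope_ci[0] <= rel.slope <= rel.slope_ci[1]

    def test_constant_climatological_forecast_single_bin(self):
        probs = np.full(200, 0.25)
        outcomes = np.arange(200) % 4 == 0
        rel = cc.reliability_diagram(probs, outcomes, n_boot=10,
                                     rng=np.random.default_rng(0))
        assert (rel.bin_weight > 0).sum() == 1
        assert np.isnan(rel.slope)

    def test_never_observed_event_zero_frequency(self, rng):
        probs = rng.random(300)
        rel = cc.reliability_diagram(probs, np.zeros(300, bool), n_boot=10,
                                     rng=np.random.default_rng(0))
        assert np.nanmax(rel.bin_freq) == 0.0


class TestRoc:
    def test_perfect_discrimination(self):
        outcomes = np.arange(100) < 25
        probs = np.where(outcomes, 0.9, 0.1)
        roc = cc.roc_and_rocss(probs, outcomes)
        assert roc.area == pytest.approx(1.0)
        assert roc.rocss == pytest.approx(1.0)

    def test_no_skill_near_zero(self, rng):
        probs = rng.integers(0, 11, 1000) / 10.0
        outcomes = rng.random(1000) < 0.3
        roc = cc.roc_and_rocss(probs, outcomes)
        assert abs(roc.rocss) < 0.1

    def test_label_reversal_negates_rocss(self, rng):
        probs = rng.integers(0, 11, 200) / 10.0
        outcomes = rng.random(200) < np.clip(probs, 0.05, 0.95)
        fwd = cc.roc_and_rocss(probs, outcomes)
        rev = cc.roc_and_rocss(probs, ~outcomes)
        assert rev.rocss == pytest.approx(-fwd.rocss, abs=1e-12)

    def test_sweep_points_monotone(self, rng):
        probs = rng.integers(0, 11, 500) / 10.0
        outcomes = rng.random(500) < np.clip(probs, 0.1, 0.9)
        roc = cc.roc_and_rocss(probs, outcomes)
        # thresholds descend, so hit/false-alarm rates must not decrease
        assert np.all(np.diff(roc.hit_rate) >= -1e-12)
        assert np.all(np.diff(roc.false_alarm_rate) >= -1e-12)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateSeriesError):
            cc.roc_and_rocss(rng.random(50), np.ones(50, bool))


class TestCorrelationSkill:
    def test_identity_and_antiphase(self, rng):
        x = rng.standard_normal(30)
        r, p, sig = cc.correlation_skill(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = cc.correlation_skill(x, -x)
        assert r == pytest.approx(-1.0)

    def test_null_rejection_rate(self):
        # independent series: significance claimed ~5% of the time
        hits = 0
        for seed in range(1000):
            r = np.random.default_rng(seed)
            _, _, sig = cc.correlation_skill(r.standard_normal(30),
                                             r.standard_normal(30))
            hits += sig
        assert 0.02 <= hits / 1000 <= 0.08


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self, rng):
        lo, hi = cc.bootstrap_ci(np.ones((50, 1)), lambda s: 1.0, n_reps=100,
                                 rng=rng)
        assert lo == hi == 1.0

    def test_same_seed_identical_interval(self, rng):
        data = np.random.default_rng(3).standard_normal((100, 1))
        i1 = cc.bootstrap_ci(data, lambda s: s.mean(), n_reps=200,
                             rng=np.random.default_rng(9))
        i2 = cc.bootstrap_ci(data, lambda s: s.mean(), n_reps=200,
                             rng=np.random.default_rng(9))
        assert i1 == i2

    def test_clt_width_for_sample_mean(self):
        from scipy import stats

        widths = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            data = r.standard_normal((100, 1))
            lo, hi = cc.bootstrap_ci(data, lambda s: s.mean(), n_reps=400, rng=r)
            widths.append(hi - lo)
        expected = 2 * stats.norm.ppf(0.875) / np.sqrt(100)
        assert np.mean(widths) == pytest.approx(expected, rel=0.2)


class TestStressArea:
    def test_all_combined(self):
        frac = cc.classify_stress_area(np.full((3, 5), -2.0), np.full((3, 5), 2.0),
                                       np.array([1.0, 2.0, 3.0]))
        assert np.all(frac["combined"] == 1.0)
        assert np.all(frac["drought_only"] == 0.0)

    def test_no_stress(self):
        frac = cc.classify_stress_area(np.zeros((2, 4)), np.zeros((2, 4)),
                                       np.ones(2))
        assert frac.to_numpy().sum() == 0.0

    def test_three_country_hand_tally(self):
        spei = np.array([[-2.0], [-1.5], [0.5]])
        hdd = np.array([[0.0], [2.0], [1.5]])
        areas = np.array([1.0, 2.0, 3.0])
        frac = cc.classify_stress_area(spei, hdd, areas)
        assert frac["drought_only"][0] == pytest.approx(1 / 6)
        assert frac["combined"][0] == pytest.approx(2 / 6)
        assert frac["heat_only"][0] == pytest.approx(3 / 6)

    def test_fractions_bounded_and_exclusive(self, rng):
        spei = rng.standard_normal((5, 40)) * 1.5
        hdd = rng.standard_normal((5, 40)) * 1.5
        frac = cc.classify_stress_area(spei, hdd, rng.random(5) + 0.1)
        vals = frac.to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(vals.sum(axis=1) <= 1 + 1e-12)
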