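import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from radsel.errors import DegenerateRegionError, ParameterError
from radsel.survival import (
    SurvivalData,
    altman_correct,
    feature_survival_analysis,
    km_curve,
    km_logrank,
    optimal_cutoff,
)

from .oracles import altman_minimal_p


class TestKMCurve:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40)
        curve = km_curve(t, np.ones(40))
        for tt, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > tt), abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        if e.sum() == 0:
            e[0] = 1
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(tt).iloc[0]), abs=1e-10
            )

    def test_nonincreasing_within_unit_interval(self):
        rng = np.random.default_rng(2)
        curve = km_curve(rng.exponential(5, 30), rng.integers(0, 2, 30))
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([3.0, 5, 8, 3, 5, 8])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = km_logrank(SurvivalData(t, e, group=g))
        assert res.hazard_ratio == pytest.approx(1.0)
        assert res.p_logrank_raw == pytest.approx(1.0)

    def test_hand_worked_six_patient_table(self):
        # group 0 dies at 1, 3, 5; group 1 dies at 2, 4, 6 (no censoring).
        # Walking the risk table: E0 = 1/2 + 2/5 + 1/2 + 1/3 + 1/2 = 67/30,
        # V = 1/4 + 6/25 + 1/4 + 2/9 + 1/4 = 1.21222...,
        # chi2 = (3 - 67/30)^2 / V, HR(group1 vs group0) = (3/E1)/(3/E0) = 67/113.
        t = np.array([1.0, 3, 5, 2, 4, 6])
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        res = km_logrank(SurvivalData(t, e, group=g))
        e0 = 67.0 / 30.0
        v = 0.25 + 6.0 / 25.0 + 0.25 + 2.0 / 9.0 + 0.25
        chi2 = (3.0 - e0) ** 2 / v
        assert res.expected[0] == pytest.approx(e0, abs=1e-12)
        assert res.chi_square == pytest.approx(chi2, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(67.0 / 113.0, abs=1e-12)
        from scipy.stats import chi2 as chi2_dist

        assert res.p_logrank_raw == pytest.approx(chi2_dist.sf(chi2, 1), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_lifelines(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        g = rng.integers(0, 2, 60)
        if e.sum() < 2 or np.unique(g).size < 2:
            pytest.skip("degenerate draw")
        res = km_logrank(SurvivalData(t, e, group=g))
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.p_logrank_raw == pytest.approx(ref.p_value, abs=1e-10)

    def test_group_relabel_reciprocal_hr(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 50)
        e = np.ones(50, dtype=int)
        g = rng.integers(0, 2, 50)
        r1 = km_logrank(SurvivalData(t, e, group=g))
        r2 = km_logrank(SurvivalData(t, e, group=1 - g))
        assert r1.hazard_ratio == pytest.approx(1.0 / r2.hazard_ratio)
        assert r1.p_logrank_raw == pytest.approx(r2.p_logrank_raw, abs=1e-12)

    def test_later_group_has_protective_hr_and_ordered_curves(self):
        t = np.array([1.0, 2, 3, 4, 11, 12, 13, 14])
        e = np.ones(8, dtype=int)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = km_logrank(SurvivalData(t, e, group=g))
        assert res.hazard_ratio < 1.0
        low, high = res.km_curves
        # at every event time the later group's survival dominates
        assert all(
            high.survival[high.times <= tt].min(initial=1.0) >= s - 1e-12
            for tt, s in zip(low.times, low.survival)
        )

    def test_zero_event_group_flags_hr_undefined(self):
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.array([1, 1, 1, 0, 0, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = km_logrank(SurvivalData(t, e, group=g))
        assert math.isnan(res.hazard_ratio)
        assert 0 <= res.p_logrank_raw <= 1


class TestOptimalCutoff:
    def test_separable_case(self):
        values = np.array([1.0, 2, 9, 10] * 3)
        surv = SurvivalData(
            time=np.ones(12),
            event=np.array([0, 0, 1, 1] * 3),
        )
        c = optimal_cutoff(values, surv)
        assert 2.0 < c < 9.0

    def test_tied_j_takes_lower_cutoff(self):
        values = np.array([1.0, 2.0, 3.0, 4.0] * 3)
        surv = SurvivalData(
            time=np.ones(12), event=np.array([0, 0, 1, 1] * 3)
        )
        # cutoffs 2.5 and any same-J competitor: lower one must win
        c = optimal_cutoff(values, surv)
        highs = values > c
        j_at = lambda cc: abs(
            np.mean((values > cc)[surv.event == 1])
            - np.mean((values > cc)[surv.event == 0])
        )
        assert all(j_at(c) >= j_at(cc) - 1e-12 for cc in [1.5, 2.5, 3.5])
        ties = [cc for cc in [1.5, 2.5, 3.5] if j_at(cc) == pytest.approx(j_at(c))]
        assert c == min(ties)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=30)
        surv = SurvivalData(rng.exponential(10, 30), rng.integers(0, 2, 30))
        if surv.event.sum() in (0, 30):
            pytest.skip("degenerate draw")
        c = optimal_cutoff(values, surv)
        uniq = np.sort(np.unique(values))
        mids = (uniq[:-1] + uniq[1:]) / 2
        lo = max(1, math.ceil(0.1 * 30))
        pos, neg = surv.event == 1, surv.event == 0
        best, best_j = None, -1
        for cc in mids:
            high = values > cc
            if not lo <= high.sum() <= 30 - lo:
                continue
            j = abs(np.mean(high[pos]) - np.mean(high[neg]))
            if j > best_j + 1e-12:
                best, best_j = cc, j
        assert c == pytest.approx(best)

    def test_constant_feature_is_error(self):
        surv = SurvivalData(np.ones(10), np.ones(10))
        with pytest.raises(DegenerateRegionError):
            optimal_cutoff(np.full(10, 3.0), surv)


class TestAltman:
    def test_at_validity_bound_returns_one(self):
        assert altman_correct(0.1) == 1.0

    def test_inflation_on_grid(self):
        grid = np.linspace(1e-6, 0.0999, 1000)
        for p in grid:
            assert altman_correct(float(p)) >= p

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.05, 0.09])
    def test_matches_independent_transcription(self, p):
        assert altman_correct(p) == pytest.approx(
            min(altman_minimal_p(p), 1.0), rel=1e-10
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            altman_correct(0.0)
        with pytest.raises(ParameterError):
            altman_correct(0.01, eps=0.7)


class TestOptimalCutoffCalibration:
    def test_altman_restores_type_one_error(self):
        # null: exponential survival with no group effect; scanning cutoffs
        # makes the raw minimal log-rank P anti-conservative, the corrected
        # P must keep type-I error near or below nominal
        rng = np.random.default_rng(9)
        n_sims = 300
        raw_hits = corrected_hits = 0
        for _ in range(n_sims):
            values = rng.normal(size=65)
            surv = SurvivalData(rng.exponential(23, 65), np.ones(65, dtype=int))
            cutoffs = np.unique(values)
            mids = (cutoffs[:-1] + cutoffs[1:]) / 2
            keep = [c for c in mids if 7 <= np.sum(values > c) <= 58]
            p_min = min(
                km_logrank(
                    SurvivalData(surv.time, surv.event,
                                 group=(values > c).astype(int))
                ).p_logrank_raw
                for c in keep[:: max(1, len(keep) // 20)]
            )
            raw_hits += p_min < 0.05
            corrected = altman_correct(p_min) if p_min < 0.1 else 1.0
            corrected_hits += corrected < 0.05
        assert raw_hits / n_sims > 0.10  # selection inflates the raw P
        assert corrected_hits / n_sims <= 0.10


class TestFeatureSurvivalAnalysis:
    def test_pipeline_composes(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=65)
        t_event = rng.exponential(23 / np.exp(0.8 * (values > 0)), 65)
        censor = rng.uniform(0, 60, 65)
        surv = SurvivalData(
            np.minimum(t_event, censor), (t_event <= censor).astype(int)
        )
        res = feature_survival_analysis(values, surv)
        assert res.p_altman >= res.p_logrank_raw
        assert res.hazard_ratio > 0
        assert not math.isnan(res.cutoff)
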