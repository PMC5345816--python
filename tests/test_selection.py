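import numpy as np
import pytest

from radsel.errors import DegenerateOutcomeError, ParameterError
from radsel.io import FeatureTable
from radsel.reference import PREDICTIVE_IMPORTANCE, PROGNOSTIC_IMPORTANCE
from radsel.selection import (
    ImportanceRanking,
    RFConfig,
    hfs_select,
    rank_importance,
    subset_search,
    threshold_select,
)
from radsel.synthetic import CohortSpec, make_cohort

FAST = RFConfig(trees=100, trees_search=50, seed=0)


def _planted_table(seed: int, n_noise: int = 27, n: int = 65) -> FeatureTable:
    """One feature equal to the label (plus tiny jitter), rest pure noise."""
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < 0.63).astype(float)
    signal = labels + 0.01 * rng.normal(size=n)
    values = np.column_stack([signal] + [rng.normal(size=n) for _ in range(n_noise)])
    return FeatureTable(
        patient_ids=[f"P{k}" for k in range(n)],
        feature_names=["signal"] + [f"noise{k}" for k in range(n_noise)],
        values=values,
        response=labels,
    )


class TestRankImportance:
    def test_planted_signal_ranks_first(self):
        wins = 0
        for seed in range(20):
            t = _planted_table(seed)
            r = rank_importance(t, t.response, RFConfig(trees=100, seed=seed))
            wins += r.entries[0][0] == "signal"
        assert wins >= 19

    def test_deterministic_for_fixed_seed(self):
        t = _planted_table(1)
        r1 = rank_importance(t, t.response, FAST)
        r2 = rank_importance(t, t.response, FAST)
        assert r1.entries == r2.entries

    def test_duplicated_informative_features_beat_noise(self):
        rng = np.random.default_rng(5)
        n = 65
        labels = (rng.random(n) < 0.5).astype(float)
        sig = labels + 0.3 * rng.normal(size=n)
        values = np.column_stack(
            [sig, sig + 1e-9 * rng.normal(size=n)]
            + [rng.normal(size=n) for _ in range(10)]
        )
        t = FeatureTable(
            [f"P{k}" for k in range(n)],
            ["dup1", "dup2"] + [f"noise{k}" for k in range(10)],
            values, response=labels,
        )
        r = rank_importance(t, labels, RFConfig(trees=200, seed=5))
        ci = r.coefficients
        assert ci["dup1"] + ci["dup2"] > max(
            v for k, v in ci.items() if k.startswith("noise")
        )

    def test_single_class_labels_rejected(self):
        t = _planted_table(0)
        with pytest.raises(DegenerateOutcomeError):
            rank_importance(t, np.ones(t.n_patients), FAST)


class TestThresholdRule:
    def test_published_predictive_coefficients_all_retained(self):
        ranking = ImportanceRanking(entries=list(PREDICTIVE_IMPORTANCE))
        assert len(threshold_select(ranking)) == 9

    def test_published_prognostic_coefficients_all_retained(self):
        ranking = ImportanceRanking(entries=list(PROGNOSTIC_IMPORTANCE))
        assert len(threshold_select(ranking)) == 8

    def test_strictly_below_fraction_dropped(self):
        ranking = ImportanceRanking(entries=[("a", 1.0), ("b", 0.05)])
        assert threshold_select(ranking) == ["a"]

    def test_equal_coefficients_all_retained(self):
        ranking = ImportanceRanking(entries=[("a", 0.2), ("b", 0.2), ("c", 0.2)])
        assert threshold_select(ranking) == ["a", "b", "c"]


class TestSubsetSearch:
    def test_perfect_feature_found_alone(self):
        t = _planted_table(2, n_noise=2)
        res = subset_search(t, t.response, ["signal", "noise0", "noise1"], FAST)
        assert res.subset == ["signal"]
        assert res.oob_error <= 0.05

    def test_single_candidate_single_log_entry(self):
        t = _planted_table(3, n_noise=1)
        res = subset_search(t, t.response, ["signal"], FAST)
        assert res.subset == ["signal"]
        assert len(res.search_log) == 1

    def test_nine_candidates_enumerate_511_subsets(self):
        t = _planted_table(4, n_noise=8)
        cfg = RFConfig(trees=20, trees_search=20, seed=4)
        res = subset_search(t, t.response, list(t.feature_names), cfg)
        assert len(res.search_log) == 511

    def test_reported_error_is_log_minimum(self):
        t = _planted_table(5, n_noise=4)
        res = subset_search(t, t.response, list(t.feature_names), FAST)
        assert res.oob_error == min(e for _, e in res.search_log)

    def test_error_not_above_full_candidate_set(self):
        t = _planted_table(6, n_noise=4)
        cand = list(t.feature_names)
        res = subset_search(t, t.response, cand, FAST)
        full = next(e for s, e in res.search_log if len(s) == len(cand))
        assert res.oob_error <= full

    def test_deterministic_for_fixed_seed(self):
        t = _planted_table(7, n_noise=3)
        a = subset_search(t, t.response, list(t.feature_names), FAST)
        b = subset_search(t, t.response, list(t.feature_names), FAST)
        assert a.subset == b.subset and a.search_log == b.search_log

    def test_empty_candidates_rejected(self):
        t = _planted_table(8, n_noise=1)
        with pytest.raises(ParameterError):
            subset_search(t, t.response, [], FAST)

    def test_beyond_limit_uses_nested_importance_chain(self):
        t = _planted_table(9, n_noise=11)
        cfg = RFConfig(trees=50, trees_search=30, seed=9, exhaustive_limit=5)
        ci = {name: 1.0 / (k + 1) for k, name in enumerate(t.feature_names)}
        res = subset_search(t, t.response, list(t.feature_names), cfg, ci=ci)
        assert len(res.search_log) == len(t.feature_names)  # one per chain step
        sizes = [len(s) for s, _ in res.search_log]
        assert sizes == sorted(sizes, reverse=True)


class TestHFS:
    def test_perfect_feature_selected_first(self):
        t = _planted_table(10, n_noise=5)
        res = hfs_select(t, t.response, list(t.feature_names), FAST)
        assert res.subset[0] == "signal"
        assert res.method == "hfs_svm"

    def test_all_noise_terminates_small_and_deterministic(self):
        rng = np.random.default_rng(11)
        n = 40
        labels = (rng.random(n) < 0.5).astype(float)
        t = FeatureTable(
            [f"P{k}" for k in range(n)],
            [f"noise{k}" for k in range(6)],
            rng.normal(size=(n, 6)),
            response=labels,
        )
        a = hfs_select(t, labels, list(t.feature_names), FAST)
        b = hfs_select(t, labels, list(t.feature_names), FAST)
        assert a.subset == b.subset
        assert len(a.subset) <= 3

    def test_greedy_path_follows_logged_rule(self):
        # every logged step at size k+1 must extend the chosen size-k prefix,
        # and the chosen extension maximizes accuracy among its size peers
        t = _planted_table(12, n_noise=4)
        res = hfs_select(t, t.response, list(t.feature_names), FAST)
        by_size: dict[int, list] = {}
        for subset, err in res.search_log:
            by_size.setdefault(len(subset), []).append((subset, err))
        prefix = ()
        for size in sorted(by_size):
            entries = by_size[size]
            assert all(s[:-1] == prefix for s, _ in entries)
            best_err = min(e for _, e in entries)
            chosen = tuple(res.subset[:size])
            if size <= len(res.subset):
                chosen_err = next(e for s, e in entries if s == chosen)
                assert chosen_err == best_err
                prefix = chosen


class TestPlantedRecovery:
    def test_two_informative_features_recovered(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(
                n_patients=65, n_features=28, blocks=(),
                informative=(("f001", 1.5), ("f002", 1.5)), seed=seed,
            )
            t = make_cohort(spec)
            cfg = RFConfig(trees=200, seed=seed)
            r = rank_importance(t, t.response, cfg)
            kept = threshold_select(r)
            res = subset_search(t, t.response, kept, cfg, ci=r.coefficients)
            hits += {"f001", "f002"} <= set(res.subset)
        assert hits >= 8
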