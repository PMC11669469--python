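import numpy as np
import pytest
from sklearn.base import clone

from equity_audit import scenarios
from equity_audit.matching import (
    EffectEstimate,
    MatchSpec,
    ModerationEffect,
    NearestNeighborMatcher,
    match_nearest,
    matching_covariates,
    moderation_effect,
    moderation_table,
)
from equity_audit.synthetic_data import generate_cohort


def brute_force_pairs(targets, pool, metric="hamming"):
    """Independent oracle: exhaustive all-pairs scan, lowest-index ties."""
    out = []
    for i, t in enumerate(targets):
        best_j, best_d = 0, np.inf
        for j, p in enumerate(pool):
            d = np.abs(t - p).sum() if metric == "hamming" else np.sqrt(((t - p) ** 2).sum())
            if d < best_d - 1e-12:
                best_j, best_d = j, d
        out.append((i, best_j, best_d))
    return out


class TestMatchNearest:
    def test_exact_duplicate_is_chosen_at_distance_zero(self):
        pool = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]])
        res = match_nearest([[0, 1, 1]], pool)
        assert res.pool_index[0] == 1
        assert res.distance[0] == 0.0

    def test_equidistant_ties_break_to_lowest_index(self):
        pool = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        res = match_nearest([[0.0, 0.0]], pool)
        assert res.pool_index[0] == 0

    def test_empty_pool_and_length_mismatch_are_errors(self):
        with pytest.raises(ValueError, match="empty"):
            match_nearest([[1.0]], np.empty((0, 1)))
        with pytest.raises(ValueError, match="mismatch"):
            match_nearest([[1.0, 0.0]], [[1.0]])

    @pytest.mark.parametrize("metric", ["hamming", "euclidean"])
    def test_agrees_with_exhaustive_scan(self, metric, rng):
        for _ in range(30):
            n_t, n_p = rng.integers(1, 20), rng.integers(1, 50)
            d = rng.integers(1, 8)
            targets = rng.integers(0, 2, (n_t, d)).astype(float)
            pool = rng.integers(0, 2, (n_p, d)).astype(float)
            res = match_nearest(targets, pool, metric=metric)
            expected = brute_force_pairs(targets, pool, metric)
            for (ti, pi, dist), (ei, ej, ed) in zip(res.pairs, expected):
                assert (ti, pi) == (ei, ej)
                assert dist == pytest.approx(ed, abs=1e-9)

    def test_self_match_excluded_for_duplicated_record(self):
        # bootstrap-style data: the target's own record appears in the pool
        targets = np.array([[1.0, 1.0]])
        pool = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 1.0]])
        res = match_nearest(targets, pool, target_ids=["a"], pool_ids=["a", "b", "c"])
        assert res.pool_index[0] == 1  # duplicate of ANOTHER record is allowed
        res2 = match_nearest(targets, pool, target_ids=["a"], pool_ids=["a", "a", "c"])
        assert res2.pool_index[0] == 2

    def test_all_self_matches_is_an_error(self):
        with pytest.raises(ValueError, match="self-match"):
            match_nearest([[1.0]], [[1.0]], target_ids=["a"], pool_ids=["a"])

    def test_multiplicity_counts_pool_reuse(self):
        res = match_nearest([[0.0], [0.0], [1.0]], [[0.0], [1.0]])
        assert res.multiplicity == {0: 2, 1: 1}


class TestCovariates:
    def test_full_mode_excludes_inspected_variable(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=300, seed=1))
        _, names = matching_covariates(cohort, "full", "ethnicity")
        assert not any("ethnicity" in n for n in names)
        assert any("gender" in n for n in names)
        assert any("age_group" in n for n in names)
        assert sum("uptake" in n for n in names) == len(cohort.treatments)

    def test_score_only_mode_is_one_column(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=100, seed=1))
        X, names = matching_covariates(cohort, "initial_score")
        assert X.shape[1] == 1 and names == ["initial_score"]


class TestModerationEffect:
    def test_null_cohort_effect_ci_covers_zero(self):
        cohort = generate_cohort(scenarios.null_effects(n=3000, seed=21))
        est = moderation_effect(cohort, MatchSpec("gender", "Male", mode="full"),
                                n_boot=200, seed=2)
        assert est.ci_low <= 0.0 <= est.ci_high

    def test_harmful_direct_effect_estimates_positive(self):
        cohort = generate_cohort(scenarios.direct_effect(seed=22))
        est = moderation_effect(
            cohort, MatchSpec("ethnicity", "Black or Black British", mode="full"),
            n_boot=50, seed=3)
        assert est.effect > 0.15
        assert est.ci_low > 0.0

    def test_deterministic_given_seed(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=1200, seed=23))
        spec = MatchSpec("gender", "Male", mode="full")
        a = moderation_effect(cohort, spec, n_boot=80, seed=11)
        b = moderation_effect(cohort, spec, n_boot=80, seed=11)
        assert (a.effect, a.ci_low, a.ci_high) == (b.effect, b.ci_low, b.ci_high)

    def test_empty_group_is_suppressed_with_warning(self, make_cohort, caplog):
        import logging

        cohort = make_cohort([{"gender": "Female"}] * 20)
        with caplog.at_level(logging.WARNING, logger="equity_audit"):
            est = moderation_effect(cohort, MatchSpec("gender", "Male"), n_boot=10, seed=0)
        assert est.suppressed and np.isnan(est.effect)
        assert any("suppressed" in r.message for r in caplog.records)

    def test_pairs_bootstrap_mode_runs_and_brackets_point(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=1500, seed=24))
        est = moderation_effect(cohort, MatchSpec("gender", "Male", mode="initial_score"),
                                n_boot=300, seed=4, bootstrap="pairs")
        assert est.ci_low <= est.effect <= est.ci_high

    def test_ate_mode_close_to_att_under_exchangeability(self):
        cohort = generate_cohort(scenarios.direct_effect(seed=25))
        spec = MatchSpec("ethnicity", "Black or Black British", mode="full")
        att = moderation_effect(cohort, spec, n_boot=20, seed=5)
        ate = moderation_effect(cohort, spec, n_boot=20, seed=5, estimand="ate")
        assert ate.effect == pytest.approx(att.effect, abs=0.15)


class TestModerationTable:
    def test_only_observed_levels_and_both_modes_present(self, make_cohort):
        rows = ([{"ethnicity": "White"}] * 30 + [{"ethnicity": "Black or Black British",
                                                  "honos6_followup": "1"}] * 30)
        table = moderation_table(make_cohort(rows), n_boot=20, seed=0)
        eth = {e.level for e in table if e.variable == "ethnicity"}
        assert eth == {"White", "Black or Black British"}
        assert {e.mode for e in table} == {"initial_score", "full"}

    def test_low_count_levels_flagged_suppressed(self, make_cohort):
        rows = [{"gender": "Female"}] * 30 + [{"gender": "Non-binary/other"}] * 3
        table = moderation_table(make_cohort(rows), n_boot=20, seed=0)
        nb = [e for e in table if e.level == "Non-binary/other"]
        assert nb and all(e.suppressed and np.isnan(e.effect) for e in nb)

    def test_reproducible_given_seed(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=900, seed=26))
        import pandas as pd

        from equity_audit.matching import effects_frame

        t1 = moderation_table(cohort, n_boot=30, seed=7, modes=("initial_score",))
        t2 = moderation_table(cohort, n_boot=30, seed=7, modes=("initial_score",))
        pd.testing.assert_frame_equal(effects_frame(t1), effects_frame(t2))


class TestEstimatorClasses:
    def test_matcher_wraps_match_nearest(self, rng):
        pool = rng.integers(0, 2, (40, 5)).astype(float)
        X = rng.integers(0, 2, (10, 5)).astype(float)
        m = NearestNeighborMatcher().fit(pool)
        idx, dist = m.match(X)
        ref = match_nearest(X, pool)
        assert np.array_equal(idx, ref.pool_index)
        assert clone(m).metric == m.metric

    def test_moderation_estimator_exposes_fitted_attributes(self):
        cohort = generate_cohort(scenarios.analysis_cohort(n=800, seed=27))
        est = ModerationEffect(variable="gender", level="Male", mode="initial_score",
                               n_boot=40, random_state=0).fit(cohort)
        assert isinstance(est.estimate_, EffectEstimate)
        assert est.ci_[0] <= est.effect_ <= est.ci_[1]
        assert est.n_group_ + est.n_pool_ == cohort.n
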