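"""Node profiles, event distributions, MANOVA, transition statistics,
correlation, cross-validation, and the regression baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cogstates as cs
from cogstates.som import BMUSequence


def seq(indices, n_nodes=20, **kw):
    idx = np.asarray(indices)
    return BMUSequence(idx, np.arange(len(idx)), n_nodes=n_nodes, **kw)


class TestNodeProfiles:
    def test_profiles_are_group_means(self, trained_on_cohort):
        feats, model, bmus = trained_on_cohort
        profiles = cs.node_profiles(model, feats, bmus)
        assert sum(p.size for p in profiles) == len(feats)
        assert sum(p.size_fraction for p in profiles) == pytest.approx(1.0)
        for p in profiles:
            members = feats.X[bmus.node_indices == p.node]
            if p.size == 0:
                assert p.mean_vector is None
            else:
                assert np.allclose(p.mean_vector, members.mean(axis=0))

    def test_misaligned_inputs_rejected(self, trained_on_cohort):
        feats, model, bmus = trained_on_cohort
        short = cs.FeatureMatrix(feats.X[:5], feats.reference_times[:5])
        with pytest.raises(ValueError):
            cs.node_profiles(model, short, bmus)


class TestEventDistribution:
    def test_no_matching_events_all_zero(self):
        bmus = seq([1, 2, 3])
        events = cs.EventLog(np.array([0]), ["other"])
        with pytest.raises(KeyError):
            cs.event_distribution(bmus, events, "absent")
        d = cs.event_distribution(bmus, events, "other")
        assert d.n_instances + d.n_unmatched == 1

    def test_middle_point_rule(self):
        # windows over epochs (4,5,6) -> reference time 5
        bmus = BMUSequence(np.array([7, 9, 11]), np.array([4, 5, 6]), n_nodes=20)
        events = cs.EventLog(np.array([5]), ["enemy"])
        d = cs.event_distribution(bmus, events, "enemy")
        assert d.counts[9 - 1] == 1
        assert d.counts.sum() == 1

    def test_artifact_gap_counts_unmatched(self):
        bmus = BMUSequence(np.array([3, 4]), np.array([1, 2]), n_nodes=20)
        events = cs.EventLog(np.array([2, 10]), ["e", "e"])
        d = cs.event_distribution(bmus, events, "e")
        assert d.n_instances == 1
        assert d.n_unmatched == 1

    def test_counts_match_exhaustive_matching(self, trained_on_cohort, small_cohort):
        feats, model, _ = trained_on_cohort
        sess = small_cohort.sessions[0]
        fm = cs.featurize_session(sess.metrics)
        bmus = cs.map_sequence(model, fm)
        label = sess.events.labels[0]
        d = cs.event_distribution(bmus, sess.events, label)
        expected = np.zeros(20, dtype=int)
        unmatched = 0
        for t, lab in zip(sess.events.times, sess.events.labels):
            if lab != label:
                continue
            hits = np.flatnonzero(bmus.reference_times == t)
            if len(hits) == 0:
                unmatched += 1
            else:
                expected[bmus.node_indices[hits[0]] - 1] += 1
        assert np.array_equal(d.counts, expected)
        assert d.n_unmatched == unmatched


class TestMANOVA:
    def test_identical_groups_give_unit_lambda(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((10, 4))
        Y = np.vstack([block, block])
        res = cs.manova_oneway(Y, ["a"] * 10 + ["b"] * 10)
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.partial_eta_squared == pytest.approx(0.0, abs=1e-10)

    def test_two_groups_match_hotelling_t2(self):
        """Rao's F for g = 2 equals the Hotelling T² F transform."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((15, 3))
        B = rng.standard_normal((12, 3)) + 0.5
        res = cs.manova_oneway(np.vstack([A, B]), ["a"] * 15 + ["b"] * 12)
        n1, n2, p = 15, 12, 3
        d = A.mean(0) - B.mean(0)
        S = ((A - A.mean(0)).T @ (A - A.mean(0)) + (B - B.mean(0)).T @ (B - B.mean(0))) / (
            n1 + n2 - 2
        )
        T2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
        F = T2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
        assert res.f_statistic == pytest.approx(F, rel=1e-10)
        assert res.df1 == p
        assert res.df2 == n1 + n2 - p - 1
        assert res.partial_eta_squared == pytest.approx(1 - res.wilks_lambda)

    def test_univariate_reduces_to_anova(self):
        rng = np.random.default_rng(2)
        y = [rng.standard_normal(10), rng.standard_normal(12) + 1, rng.standard_normal(8)]
        res = cs.manova_oneway(
            np.concatenate(y)[:, None], ["a"] * 10 + ["b"] * 12 + ["c"] * 8
        )
        F, p = stats.f_oneway(*y)
        assert res.f_statistic == pytest.approx(F, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_observed_power_in_unit_interval(self):
        rng = np.random.default_rng(3)
        Y = np.vstack([rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 1])
        res = cs.manova_oneway(Y, ["a"] * 20 + ["b"] * 20)
        assert 0.0 <= res.observed_power <= 1.0
        assert res.observed_power > 0.9  # large separation, decent n

    def test_singular_scatter_needs_ridge(self):
        # one-hot observations: rows sum to 1, so E is singular
        rng = np.random.default_rng(4)
        Y = np.eye(4)[rng.integers(0, 4, 40)]
        labels = ["a"] * 20 + ["b"] * 20
        with pytest.raises(np.linalg.LinAlgError):
            cs.manova_oneway(Y, labels)
        res = cs.manova_oneway(Y, labels, ridge=1e-6)
        assert res.regularized
        assert 0 < res.wilks_lambda <= 1


class TestTransitionStatistics:
    def test_small_sequence_matrix(self):
        T = cs.transition_matrix(seq([2, 3, 3]))
        assert T[1, 2] == 1 and T[2, 2] == 1
        assert T.sum() == 2

    def test_matrix_total_counts_transitions_per_session(self, trained_on_cohort):
        _, _, bmus = trained_on_cohort
        T = cs.transition_matrix(bmus)
        expected = sum(len(idx) - 1 for _, idx, _ in bmus.per_session() if len(idx))
        assert T.sum() == expected

    def test_matrix_never_bridges_sessions(self):
        bmus = BMUSequence(
            np.array([1, 1, 20, 20]), np.array([0, 1, 0, 1]),
            [("a", "1"), ("b", "1")], np.array([0, 0, 1, 1]), n_nodes=20,
        )
        T = cs.transition_matrix(bmus)
        assert T[0, 0] == 1 and T[19, 19] == 1 and T.sum() == 2

    def test_score_closed_forms(self):
        assert cs.transition_score(np.array([5, 5, 5, 5])).score == 0
        assert cs.transition_score(np.array([1, 20, 1])).score == 38
        assert cs.transition_score(np.array([7])).score == 0

    def test_score_matches_brute_force_formula(self):
        rng = np.random.default_rng(5)
        idx = rng.integers(1, 21, 1000)
        expected = sum(abs(int(idx[j]) - int(idx[j - 1])) for j in range(1, len(idx)))
        assert cs.transition_score(idx).score == expected

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(ValueError):
            cs.transition_score(np.array([0, 5]), n_nodes=20)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 20), min_size=1, max_size=200))
    def test_score_bounds_and_matrix_consistency(self, indices):
        idx = np.array(indices)
        res = cs.transition_score(idx, n_nodes=20)
        t = len(idx)
        assert 0 <= res.score <= (t - 1) * 19 if t > 1 else res.score == 0
        T = cs.transition_matrix(seq(idx))
        dist_weighted = sum(
            T[a, b] * abs(a - b) for a in range(20) for b in range(20)
        )
        assert dist_weighted == res.score

    def test_distance_histogram_partitions_matrix(self, trained_on_cohort):
        _, _, bmus = trained_on_cohort
        T = cs.transition_matrix(bmus)
        hist = cs.distance_histogram(T)
        assert hist.sum() == T.sum()
        single = cs.distance_histogram(cs.transition_matrix(seq([4, 4, 4])))
        assert single[0] == 2 and single[1:].sum() == 0

    def test_local_transitions_dominate_on_sticky_cohort(self, trained_on_cohort):
        """Smooth latent dynamics concentrate transitions at short grid distances."""
        _, _, bmus = trained_on_cohort
        hist = cs.distance_histogram(cs.transition_matrix(bmus))
        assert hist[1] > hist[5]


class TestCorrelation:
    def test_perfect_linear_relation(self):
        scores = [cs.TransitionScoreResult("s", f"t{i}", 10 * i, 50) for i in range(5)]
        perf = [
            cs.PerformanceRecord("s", f"t{i}", "percent_enemy_hits", 2 * (10 * i) / 10 + 1)
            for i in range(5)
        ]
        res = cs.correlate_performance(scores, perf)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_independent_noise_is_small(self):
        rng = np.random.default_rng(6)
        scores = [
            cs.TransitionScoreResult("s", f"t{i}", int(rng.integers(0, 1000)), 50)
            for i in range(1000)
        ]
        perf = [
            cs.PerformanceRecord("s", f"t{i}", "m", float(rng.uniform(0, 100)))
            for i in range(1000)
        ]
        res = cs.correlate_performance(scores, perf)
        assert abs(res.r) < 0.1

    def test_hand_computed_five_pair_table(self):
        """r and p agree with the textbook formulas computed longhand."""
        x = [120.0, 95.0, 180.0, 60.0, 150.0]
        y = [55.0, 40.0, 70.0, 35.0, 72.0]
        n = 5
        mx, my = sum(x) / n, sum(y) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sxx = sum((a - mx) ** 2 for a in x)
        syy = sum((b - my) ** 2 for b in y)
        r_exp = sxy / math.sqrt(sxx * syy)
        t_stat = r_exp * math.sqrt((n - 2) / (1 - r_exp**2))
        p_exp = 2 * stats.t.sf(abs(t_stat), n - 2)
        scores = [cs.TransitionScoreResult("s", f"t{i}", int(v), 10) for i, v in enumerate(x)]
        perf = [cs.PerformanceRecord("s", f"t{i}", "m", v) for i, v in enumerate(y)]
        res = cs.correlate_performance(scores, perf)
        assert res.r == pytest.approx(r_exp, rel=1e-9)
        assert res.p_value == pytest.approx(p_exp, rel=1e-9)
        assert res.n == 5

    def test_degenerate_inputs_rejected(self):
        scores = [cs.TransitionScoreResult("s", f"t{i}", 5, 10) for i in range(4)]
        perf = [cs.PerformanceRecord("s", f"t{i}", "m", 50.0 + i) for i in range(4)]
        with pytest.raises(ValueError):
            cs.correlate_performance(scores, perf)  # zero score variance
        with pytest.raises(ValueError):
            cs.correlate_performance(scores[:2], perf[:2])  # too few pairs


class TestCrossValidation:
    def test_51_subjects_give_paper_fold_sizes(self):
        folds = cs.crossval_split([f"S{i}" for i in range(51)], 10)
        sizes = [len(train) for train, _ in folds]
        assert sizes == [5] * 9 + [6]
        for train, test in folds:
            assert len(train) + len(test) == 51

    def test_training_sets_partition_subjects(self):
        subjects = [f"S{i}" for i in range(23)]
        folds = cs.crossval_split(subjects, 10)
        all_train = [s for train, _ in folds for s in train]
        assert sorted(all_train) == sorted(subjects)
        assert len(set(all_train)) == len(all_train)

    def test_even_split(self):
        folds = cs.crossval_split([f"S{i}" for i in range(20)], 10)
        assert all(len(train) == 2 for train, _ in folds)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            cs.crossval_split(["a", "b"], 10)

    def test_autovalidation_reproduces_non_cv_pipeline(self, small_cohort, trained_on_cohort):
        feats, model, bmus = trained_on_cohort
        av = cs.run_autoval(small_cohort, cs.SOMConfig(n_iterations=60))
        manual = {s.key: s.score for s in cs.transition_scores(bmus)}
        for s in av.scores:
            assert s.score == manual[s.key]

    def test_planted_effect_recovered_under_crossval(self):
        """Person-independent CV still finds a strong planted link."""
        spec = cs.CohortSpec(
            n_subjects=10, sessions_per_subject=2, session_duration_s=120,
            performance_beta=5.0, performance_noise_sd=2.0,  # true r ~ 0.93
            master_seed=11,
        )
        cohort = cs.generate_cohort(spec)
        cv = cs.run_crossval(cohort, cs.SOMConfig(n_iterations=60), n_folds=10)
        assert cv.correlation.r > 0
        assert cv.correlation.p_value < 0.05
        assert cv.correlation.n == len(cohort.sessions)
        # person-independence: no fold trains and tests the same subject
        subjects = sorted({s.metrics.subject_id for s in cohort.sessions})
        for train, (_, test) in zip(cv.fold_train_subjects, cs.crossval_split(subjects, 10)):
            assert not set(train) & set(test)


class TestRegressionBaseline:
    def _features(self, X, n_sessions):
        per = len(X) // n_sessions
        keys = [(f"S{i:02d}", "T00") for i in range(n_sessions)]
        index = np.repeat(np.arange(n_sessions), per)
        return cs.FeatureMatrix(X, np.tile(np.arange(per), n_sessions), keys, index)

    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(7)
        # centering before QR keeps the columns exactly orthogonal and mean-free
        M = rng.standard_normal((40, 9))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        fm = self._features(Q, 40)
        perf = [cs.PerformanceRecord(f"S{i:02d}", "T00", "m", float(50 + 10 * rng.random()))
                for i in range(40)]
        res = cs.regression_baseline(fm, perf)
        for name in cs.FEATURE_NAMES:
            assert res.vif[name] == pytest.approx(1.0, abs=1e-6)
            assert res.tolerance[name] == pytest.approx(1.0 / res.vif[name])

    def test_duplicated_predictor_raises(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 9))
        X[:, 1] = X[:, 0]
        fm = self._features(X, 30)
        perf = [cs.PerformanceRecord(f"S{i:02d}", "T00", "m", float(rng.uniform(0, 100)))
                for i in range(30)]
        with pytest.raises(np.linalg.LinAlgError):
            cs.regression_baseline(fm, perf)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 9))
        fm = self._features(X, 30)
        y = rng.uniform(20, 80, 30)
        perf = [cs.PerformanceRecord(f"S{i:02d}", "T00", "m", float(v))
                for i, v in enumerate(y)]
        res = cs.regression_baseline(fm, perf)
        Xc = np.column_stack([np.ones(30), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        got = [res.coefficients["intercept"]] + [res.coefficients[n] for n in cs.FEATURE_NAMES]
        assert np.allclose(got, beta, atol=1e-9)

    def test_window_replication_unit(self, small_cohort, trained_on_cohort):
        feats, _, _ = trained_on_cohort
        res = cs.regression_baseline(feats, small_cohort.performance)
        assert res.n == len(feats)
        assert 0.0 <= res.r_squared <= 1.0
        assert all(0 < res.tolerance[n] <= 1.0 + 1e-12 for n in cs.FEATURE_NAMES)
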