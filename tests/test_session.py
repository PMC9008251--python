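import numpy as np
import pytest

import synadapt as sa


class TestRunSession:
    def test_frozen_session_leaves_trainset_unchanged(self, clean_features, small_trainset):
        stream = clean_features[0][:30]
        state = sa.run_session(small_trainset, stream, adapt=False)
        assert state.trainset is small_trainset
        assert len(state.history) == 30

    def test_empty_stream(self, small_trainset):
        state = sa.run_session(small_trainset, [], adapt=True)
        assert state.history == []

    def test_reject_everything_equals_frozen(self, clean_features, small_trainset):
        stream = clean_features[0][:40]
        frozen = sa.run_session(small_trainset, stream, adapt=False)
        vetoed = sa.run_session(small_trainset, stream, adapt=True, force_reject=True)
        assert [p for _, p, _, _ in frozen.history] == [p for _, p, _, _ in vetoed.history]
        np.testing.assert_array_equal(vetoed.trainset.samples, small_trainset.samples)

    def test_accuracy_matches_independent_counter(self, clean_features, small_trainset):
        stream = clean_features[0][:50]
        state = sa.run_session(small_trainset, stream, adapt=True)
        manual = sum(1 for _, p, t, _ in state.history if p == t) / len(state.history)
        assert state.accuracy == pytest.approx(manual)

    def test_invariants_preserved_after_adaptation(self, clean_features, small_trainset):
        state = sa.run_session(small_trainset, clean_features[0], adapt=True)
        ts = state.trainset
        assert ts.n_train == small_trainset.n_train
        assert (ts.weights > 0).all() and (ts.weights <= 3).all()
        np.testing.assert_array_equal(
            np.bincount(ts.labels), np.bincount(small_trainset.labels)
        )


class TestCrossvalidate:
    def test_each_user_held_out_once(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        report = sa.crossvalidate(recs, "B", cycles=1, seed=0,
                                  features_per_user=clean_features)
        assert set(report.per_user_accuracy) == {r.user_id for r in recs}
        assert report.step_accuracy.shape[0] == len(recs)

    def test_scheme_c_perfect_on_separable_data(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        report = sa.crossvalidate(recs, "C", cycles=1, seed=0,
                                  features_per_user=clean_features)
        assert report.mean_accuracy == pytest.approx(1.0)

    def test_scheme_b_perfect_without_user_variability(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        report = sa.crossvalidate(recs, "B", cycles=1, seed=0,
                                  features_per_user=clean_features)
        assert report.mean_accuracy == pytest.approx(1.0)

    def test_same_seed_reproduces_report(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        r1 = sa.crossvalidate(recs, "D", cycles=2, seed=9, features_per_user=clean_features)
        r2 = sa.crossvalidate(recs, "D", cycles=2, seed=9, features_per_user=clean_features)
        assert r1.per_user_accuracy == r2.per_user_accuracy
        np.testing.assert_array_equal(r1.step_accuracy, r2.step_accuracy)

    def test_accuracies_are_probabilities(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        report = sa.crossvalidate(recs, "D", cycles=1, seed=3,
                                  features_per_user=clean_features)
        assert (report.step_accuracy >= 0).all() and (report.step_accuracy <= 1).all()
        assert 0 <= report.mean_accuracy <= 1

    def test_missing_gesture_skips_fold_with_warning(self, clean_cohort, clean_features):
        _, recs = clean_cohort
        feats = [list(f) for f in clean_features]
        feats[0] = [f for f in feats[0] if f.label != 2]  # user 0 lacks gesture 2
        with pytest.warns(UserWarning, match="skipped"):
            report = sa.crossvalidate(recs, "B", cycles=1, seed=0, features_per_user=feats)
        assert recs[0].user_id not in report.per_user_accuracy

    def test_unknown_scheme_rejected(self, clean_cohort):
        _, recs = clean_cohort
        with pytest.raises(ValueError):
            sa.crossvalidate(recs, "X")


class TestChannelWeightSummary:
    def test_single_feature_is_its_own_summary(self):
        f = sa.SynergyFeature(np.array([0.0, 0.5, 1.0]), label=2)
        df = sa.channel_weight_summary([f], stage="test")
        np.testing.assert_allclose(df.loc[2, ["ch0", "ch1", "ch2"]].astype(float),
                                   [0.0, 0.5, 1.0])

    def test_generator_ground_truth_channel(self):
        # gesture activating only channel 9 of 16
        patterns = np.full((2, 16), 0.02)
        patterns[0, 9] = 1.0
        patterns[1, 3] = 1.0
        cfg = sa.SynthConfig(users=1, gestures=2, channels=16, repetitions=2,
                             user_gain_sd=0.0, rep_gain_sd=0.0, burst_mod_amp=0.0,
                             bad_rep_rate=0.0, base_patterns=patterns,
                             noise_sd=0.001, master_seed=1)
        rec = sa.generate_cohort(cfg)[0]
        feats = sa.extract_features(rec, seed=0)
        df = sa.channel_weight_summary(feats, stage="existing")
        assert df.columns[1 + 9] == "ch9"
        row = df.loc[1].drop("stage").astype(float)
        assert row.idxmax() == "ch9"

    def test_adapted_trainset_moves_toward_test_user(self):
        # Monte-Carlo property: after adaptation the per-gesture channel
        # summaries of the train set resemble the new user more, on
        # average over cohorts, than the frozen representative set did
        def cos_to_test(summary, test_summary):
            out = []
            for g in test_summary.index:
                a = summary.loc[g].drop("stage").astype(float).to_numpy()
                b = test_summary.loc[g].drop("stage").astype(float).to_numpy()
                out.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))
            return float(np.mean(out))

        diffs = []
        for seed in range(4):
            cfg = sa.SynthConfig(users=4, repetitions=6, drift_rate=0.05,
                                 bad_rep_rate=0.0, master_seed=seed)
            recs = sa.generate_cohort(cfg)
            feats = [sa.extract_features(r, seed=100 + i) for i, r in enumerate(recs)]
            initial = sa.trainset_from_features([f for fs in feats[1:] for f in fs])
            state = sa.run_session(initial, feats[0], adapt=True, new_user="new")
            test_sum = sa.channel_weight_summary(feats[0], stage="test")
            before = cos_to_test(sa.channel_weight_summary(initial, "initial"), test_sum)
            after = cos_to_test(
                sa.channel_weight_summary(state.trainset, "updated"), test_sum
            )
            diffs.append(after - before)
        assert np.mean(diffs) > 0
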