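import numpy as np
import pytest

import synadapt as sa
from synadapt.knn import NeighborTable, neighbor_table, select_k


def make_trainset(samples, labels, weights=None, users=None):
    samples = np.asarray(samples, dtype=float)
    labels = np.asarray(labels, dtype=int)
    templates = {
        int(c): sa.Template(samples[labels == c].mean(axis=0), int(c))
        for c in np.unique(labels)
    }
    return sa.WeightedTrainSet(
        samples,
        labels,
        np.ones(len(labels)) if weights is None else np.asarray(weights, float),
        users or ["u"] * len(labels),
        templates,
    )


def table_from_sorted_labels(labels):
    """A neighbor table whose i-th nearest neighbor has the i-th label."""
    n = len(labels)
    return NeighborTable(np.arange(n), np.arange(1, n + 1, dtype=float))


class TestNeighborTable:
    def test_3_4_5_triangle(self):
        ts = make_trainset([[3.0, 4.0], [10.0, 10.0]], [1, 2])
        t = neighbor_table(np.zeros(2), ts)
        assert t.distances[0] == 25.0

    def test_query_equal_to_row_is_first(self, rng):
        X = rng.random((20, 3))
        ts = make_trainset(X, np.ones(20, dtype=int))
        t = neighbor_table(X[7], ts)
        assert t.order[0] == 7 and t.distances[0] == 0.0

    def test_matches_argsort_oracle(self, rng):
        X = rng.random((200, 5))
        ts = make_trainset(X, rng.integers(1, 4, 200))
        q = rng.random(5)
        t = neighbor_table(q, ts)
        d2 = ((X - q) ** 2).sum(axis=1)
        np.testing.assert_array_equal(t.order, np.argsort(d2, kind="stable"))
        assert (np.diff(t.distances) >= 0).all()

    def test_dimension_mismatch(self):
        ts = make_trainset([[0.0, 0.0]], [1])
        with pytest.raises(ValueError, match="dimension"):
            neighbor_table(np.zeros(3), ts)


class TestSelectK:
    def test_pure_equidistant_shell_picks_kmax(self):
        # all k_max nearest share one class on a shell at distance 1:
        # purity v = 1 for every k, density k/(pi d^2) grows with k
        n = 40
        table = NeighborTable(np.arange(n), np.ones(n))
        trace = select_k(table, np.ones(n, dtype=int), gesture_count=2, k_max=40)
        assert trace.decision_path == "score"
        assert trace.chosen_K == 40

    def test_intersection_halves_pf(self):
        # class 1 leads at k=5 and 10; class 2 overtakes at k=15
        labels = [1, 1, 1, 2, 2] + [1, 1, 1, 2, 2] + [1, 2, 2, 2, 2]
        trace = select_k(table_from_sorted_labels(labels), np.array(labels),
                         gesture_count=2, k_max=15)
        assert trace.decision_path == "intersection"
        assert trace.p_f == 15
        assert trace.chosen_K == 7  # floor(15 / 2)

    def test_small_ratio_sets_k5(self):
        # stable leader, final counts 11 vs 9 -> ratio 1.22 < 2 -> K = 5
        labels = ([1, 1, 1, 2, 2] + [1, 1, 1, 2, 2]
                  + [1, 1, 2, 2, 2] + [1, 1, 1, 2, 2])
        trace = select_k(table_from_sorted_labels(labels), np.array(labels),
                         gesture_count=2, k_max=20)
        counts = np.bincount(labels)
        assert counts[1] == 11 and counts[2] == 9
        assert trace.decision_path == "ratio_small"
        assert trace.chosen_K == 5

    def test_deterministic(self, rng):
        labels = rng.integers(1, 5, 60)
        t = table_from_sorted_labels(labels)
        t1 = select_k(t, labels, 4, k_max=60)
        t2 = select_k(t, labels, 4, k_max=60)
        assert t1.chosen_K == t2.chosen_K and t1.decision_path == t2.decision_path

    def test_k_bounds(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            labels = r.integers(1, 5, 50)
            trace = select_k(table_from_sorted_labels(labels), labels, 4, k_max=50)
            assert 1 <= trace.chosen_K <= 50


class TestClassify:
    def test_unanimous_neighborhood(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        ts = make_trainset(X, [1] * 10 + [2] * 10)
        assert sa.classify(np.zeros(2), ts).label == 1

    def test_weighted_vote_beats_count(self):
        # 3 class-A neighbors with weight 1 vs 2 class-B with weight 2
        X = np.array([[0.1, 0], [0.11, 0], [0.12, 0], [0.2, 0], [0.21, 0]])
        ts = make_trainset(X, [1, 1, 1, 2, 2], weights=[1, 1, 1, 2, 2])
        pred = sa.classify(np.zeros(2), ts, k_step=5, k_max=5)
        assert pred.vote_tally == {1: 3.0, 2: 4.0}
        assert pred.label == 2

    def test_unit_weights_reduce_to_plain_knn(self, rng):
        X = rng.random((100, 4))
        y = rng.integers(1, 5, 100)
        ts = make_trainset(X, y)
        K = 15
        for _ in range(100):
            q = rng.random(4)
            pred = sa.classify(q, ts, k_step=K, k_max=K)  # single-point grid
            # brute-force plain-KNN oracle with the same tie rules
            d2 = ((X - q) ** 2).sum(axis=1)
            idx = np.argsort(d2, kind="stable")[:K]
            tally, dsum = {}, {}
            for i in idx:
                tally[y[i]] = tally.get(y[i], 0) + 1
                dsum[y[i]] = dsum.get(y[i], 0.0) + d2[i]
            expect = min(tally, key=lambda c: (-tally[c], dsum[c], c))
            assert pred.label == expect

    def test_agrees_with_sklearn_on_clear_majorities(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        X = rng.random((120, 3))
        y = rng.integers(1, 4, 120)
        ts = make_trainset(X, y)
        K = 11
        clf = sklearn.KNeighborsClassifier(n_neighbors=K).fit(X, y)
        checked = 0
        for _ in range(100):
            q = rng.random(3)
            d2 = ((X - q) ** 2).sum(axis=1)
            counts = np.bincount(y[np.argsort(d2)[:K]])
            if (counts == counts.max()).sum() > 1:
                continue  # sklearn breaks ties differently; skip exact ties
            assert sa.classify(q, ts, k_step=K, k_max=K).label == clf.predict([q])[0]
            checked += 1
        assert checked > 50


class TestWeightUpdates:
    def test_reinforce_at_zero(self):
        assert sa.reinforce_weight(0.0) == pytest.approx(1.5)

    def test_penalize_at_four(self):
        assert sa.penalize_weight(4.0) == pytest.approx(1.0)

    def test_repeated_reinforcement_bounded_by_three(self):
        q = 1.0
        prev = 0.0
        for _ in range(100):
            q = float(sa.reinforce_weight(q))
            assert prev <= q < 3.0  # monotone up to the fixed point, capped at 3
            prev = q
        assert 2.8 < q < 3.0  # fixed point of 3/(1+e^-q) is ~2.83

    def test_update_targets_only_chosen_neighbors(self, rng):
        X = rng.random((30, 2))
        y = np.array([1] * 15 + [2] * 15)
        ts = make_trainset(X, y)
        pred = sa.classify(X[0], ts, k_step=5, k_max=5)
        before = ts.weights.copy()
        sa.update_weights(ts, pred, qualified_label=pred.label)
        touched = set(pred.neighbor_indices.tolist())
        for i in range(30):
            if i in touched:
                expected = (
                    sa.reinforce_weight(before[i])
                    if y[i] == pred.label
                    else before[i] / 4
                )
                assert ts.weights[i] == pytest.approx(float(expected))
            else:
                assert ts.weights[i] == before[i]

    def test_weights_stay_in_open_interval(self, rng):
        q = np.ones(50)
        for _ in range(10_000 // 50):
            mask = rng.random(50) < 0.5
            q[mask] = sa.reinforce_weight(q[mask])
            q[~mask] = sa.penalize_weight(q[~mask])
            assert (q > 0).all() and (q < 3).all()
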