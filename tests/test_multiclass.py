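import numpy as np
import pytest

from lcnc import (FeatureTable, es_predict, es_schedule, fit_es, fit_ovr,
                  fit_pairwise_pool, fit_system, generate_dataset, max_wins,
                  ovo_predict, ovr_predict, predict_sample, predict_table,
                  small_spec, vote_rank)
from lcnc.model_selection import predict_binary

from conftest import fast_spec


def _scaled(table):
    from lcnc import autoscale_apply, autoscale_fit
    p = autoscale_fit(table.values)
    return FeatureTable(autoscale_apply(table.values, p), table.sample_ids,
                        table.feature_names, table.labels)


@pytest.fixture(scope="module")
def five_class_table():
    return _scaled(generate_dataset(small_spec(
        k=5, n_per_class=8, n_features=5,
        within_class_sd_fraction=0.03, seed=13)))


@pytest.fixture(scope="module")
def five_class_pool(five_class_table):
    return fit_pairwise_pool(five_class_table,
                             fast_spec("plsda", n_splits=8, max_lv=2))


class TestPairwisePool:
    def test_pair_count_k3(self, three_blob_table):
        pool = fit_pairwise_pool(_scaled(three_blob_table),
                                 fast_spec("plsda", n_splits=8, max_lv=2))
        assert len(pool.models) == 3

    def test_pair_count_formula(self, five_class_pool):
        k = len(five_class_pool.classes)
        assert len(five_class_pool.models) == k * (k - 1) // 2 == 10

    def test_unordered_key_retrieval(self, five_class_pool):
        m1 = five_class_pool.model_for(2, 5)
        m2 = five_class_pool.model_for(5, 2)
        assert m1 is m2

    def test_pair_models_trained_on_two_classes_only(self, five_class_pool):
        model, pos, neg = five_class_pool.model_for(1, 2)
        assert (pos, neg) == (1, 2)

    def test_small_class_rejected(self, three_blob_table):
        t = three_blob_table.take_rows([0, 1, 2, 10])  # class 2: 1 sample
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_pairwise_pool(t, fast_spec("plsda"))


class TestOvoPredict:
    def test_subset_of_two_equals_pair_decision(self, five_class_pool,
                                                five_class_table):
        x = five_class_table.values[0]
        res = ovo_predict(five_class_pool, x, [1, 2])
        model, pos, neg = five_class_pool.model_for(1, 2)
        resp, _ = predict_binary(model, x[None, :])
        assert res.winner == (pos if resp[0] >= 0 else neg)

    def test_vote_total_is_pair_count(self, five_class_pool,
                                      five_class_table):
        res = ovo_predict(five_class_pool, five_class_table.values[3])
        assert sum(res.votes.values()) == 10

    def test_subset_restriction_never_consults_outside_models(
            self, five_class_pool, five_class_table):
        import copy
        pruned = copy.copy(five_class_pool)
        subset = [1, 3, 4]
        pruned.models = {k: v for k, v in five_class_pool.models.items()
                         if k <= set(subset)}
        res = ovo_predict(pruned, five_class_table.values[0], subset)
        assert sum(res.votes.values()) == 3

    def test_cyclic_votes_tie_to_lowest_class(self):
        votes = {1: 1, 2: 1, 3: 1}
        assert max_wins([1, 2, 3]) == [1, 2, 3]
        assert vote_rank(votes, 3)[0] == 1

    def test_unknown_class_rejected(self, five_class_pool,
                                    five_class_table):
        with pytest.raises(ValueError, match="unknown"):
            ovo_predict(five_class_pool, five_class_table.values[0], [1, 99])


class TestOvr:
    def test_full_subset_one_model_per_class(self, five_class_table):
        model = fit_ovr(five_class_table, [1, 2, 3, 4, 5],
                        fast_spec("plsda", n_splits=8, max_lv=2))
        assert sorted(model.models) == [1, 2, 3, 4, 5]

    def test_centroid_sample_wins_its_class(self, five_class_table):
        model = fit_ovr(five_class_table, [1, 2, 3],
                        fast_spec("plsda", n_splits=8, max_lv=2))
        x = five_class_table.values[five_class_table.rows_for_class(2)].mean(0)
        responses, winner = ovr_predict(model, x)
        assert winner == 2
        assert sorted(responses) == [1, 2, 3]

    def test_two_class_subset_mirrors_pairwise(self, five_class_table,
                                               five_class_pool):
        model = fit_ovr(five_class_table, [1, 2],
                        fast_spec("plsda", n_splits=8, max_lv=2))
        for row in (0, 10, 20):
            x = five_class_table.values[row]
            _, w_ovr = ovr_predict(model, x)
            w_ovo = ovo_predict(five_class_pool, x, [1, 2]).winner
            assert w_ovr == w_ovo

    def test_missing_class_rejected(self, five_class_table):
        empty = five_class_table.restrict_classes([1, 2])
        with pytest.raises(ValueError, match="no training samples"):
            fit_ovr(empty, [1, 3], fast_spec("plsda"))


class TestSchedule:
    @pytest.mark.parametrize("k, expected", [
        (37, [37, 19, 10]),
        (40, [40, 20, 10]),
        (12, [12]),
        (20, [20, 10]),
    ])
    def test_recursive_halving(self, k, expected):
        s = es_schedule(k)
        assert s.stage_counts == expected
        assert s.n_subclassifiers == 2 * len(expected)

    def test_formula_mode_stops_earlier_for_37(self):
        # round(37/4) = 9 falls below the minimum, so the literal formula
        # yields one stage fewer than recursive halving
        assert es_schedule(37, mode="formula").stage_counts == [37, 19]

    def test_small_min_classes(self):
        assert es_schedule(12, min_classes=3).stage_counts == [12, 6, 3]

    def test_strictly_decreasing_and_bounded(self):
        for k in range(2, 60):
            s = es_schedule(k)
            assert s.stage_counts[0] == k
            assert all(a > b for a, b in zip(s.stage_counts,
                                             s.stage_counts[1:]))
            assert all(c >= 2 for c in s.stage_counts)
            assert all(c >= 10 for c in s.stage_counts[1:])


class TestVoteRank:
    def test_descending_votes(self):
        assert vote_rank({"A": 3, "B": 1, "C": 2}, 2) == ["A", "C"]

    def test_tie_broken_by_response_sum(self):
        votes = {"A": 1, "B": 1, "C": 1}
        sums = {"A": -2.0, "B": 5.0, "C": 1.0}
        assert vote_rank(votes, 3, sums) == ["B", "C", "A"]

    def test_full_ranking_is_permutation(self):
        votes = {1: 2, 2: 2, 3: 0, 4: 1}
        assert sorted(vote_rank(votes, 4)) == [1, 2, 3, 4]

    def test_top_m_bounds(self):
        with pytest.raises(ValueError):
            vote_rank({1: 1, 2: 0}, 3)


class TestMaxWins:
    def test_staged_votes_resolve_without_tie(self):
        # one subclassifier says 35, two say 34, three say 37
        assert max_wins([35, 34, 34, 37, 37, 37]) == [37]

    def test_tie_reported(self):
        assert set(max_wins([1, 2, 1, 2])) == {1, 2}


class TestES:
    def test_separable_prediction_matches_ovo(self, five_class_table):
        spec = fast_spec("plsda", n_splits=8, max_lv=2)
        es = fit_es(five_class_table, spec)
        assert es.schedule.stage_counts == [5]  # below min_classes: 1 stage
        for row in (0, 17, 33):
            x = five_class_table.values[row]
            pred = es_predict(es, x)
            assert pred.predicted_class == \
                ovo_predict(es.pool, x).winner
            assert not pred.tie_broken
            assert set(pred.votes) == {"C1", "C2"}

    def test_winner_among_subclassifier_votes(self, five_class_table):
        es = fit_es(five_class_table, fast_spec("plsda", n_splits=8,
                                                max_lv=2))
        pred = es_predict(es, five_class_table.values[9])
        assert pred.predicted_class in pred.votes.values()

    def test_multistage_vote_structure(self):
        table = _scaled(generate_dataset(small_spec(
            k=12, n_per_class=6, n_features=5,
            within_class_sd_fraction=0.05, seed=21)))
        es = fit_es(table, fast_spec("plsda", n_splits=6, max_lv=2),
                    min_classes=3)
        assert es.schedule.stage_counts == [12, 6, 3]
        pred = es_predict(es, table.values[30])
        assert set(pred.votes) == {f"C{i}" for i in range(1, 7)}
        assert pred.predicted_class == table.labels[30]

    def test_ovr_cache_reused(self, five_class_table):
        es = fit_es(five_class_table, fast_spec("plsda", n_splits=8,
                                                max_lv=2))
        es_predict(es, five_class_table.values[0])
        n_cached = len(es.ovr_cache)
        es_predict(es, five_class_table.values[1])
        # same separable top-3 subset: no new OVR submodel trained
        assert len(es.ovr_cache) == n_cached


class TestSystems:
    @pytest.mark.parametrize("strategy", ["ovr", "ovo", "es"])
    def test_deterministic_predictions(self, strategy):
        table = generate_dataset(small_spec(
            k=4, n_per_class=8, n_features=5,
            within_class_sd_fraction=0.1, seed=5))
        spec = fast_spec("plsda", n_splits=8, max_lv=2, seed=3)
        p1 = predict_table(fit_system(table, strategy, spec), table)
        p2 = predict_table(fit_system(table, strategy, spec), table)
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_object_shape(self, three_blob_table):
        sys_ = fit_system(three_blob_table, "ovo",
                          fast_spec("plsda", n_splits=8, max_lv=2))
        pred = predict_sample(sys_, three_blob_table.values[0])
        assert pred.predicted_class == 1

    def test_unknown_strategy(self, three_blob_table):
        with pytest.raises(ValueError, match="strategy"):
            fit_system(three_blob_table, "ecoc", fast_spec("plsda"))
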