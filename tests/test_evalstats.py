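"""Evaluation statistics: AUC, survival, splits, drug response, correlation, ORA."""

import numpy as np
import pytest
from scipy import stats

import oracles
from conftest import make_study
from exomir.errors import DegenerateStatisticError, InputError
from exomir.evalstats import (
    auc_rank,
    crc_auc,
    drug_response_test,
    expression_split,
    fit_logistic_combined,
    hypergeom_ora,
    km_curve,
    logrank_test,
    spearman_test,
    stage_auc,
)


class TestAUC:
    def test_perfect_separation(self):
        r = auc_rank([10, 11, 1, 2], [True, True, False, False])
        assert r.auc == 1.0

    def test_pair_counting_example(self):
        values = [3, 5, 1, 2, 4]
        labels = [True, True, False, False, False]
        r = auc_rank(values, labels, auto_direction=False)
        assert r.auc == pytest.approx(5 / 6)
        assert r.auc == pytest.approx(oracles.auc_pairs(values, labels))

    def test_constant_scores_give_half(self):
        assert auc_rank([3, 3, 3, 3], [1, 1, 0, 0]).auc == 0.5

    def test_matches_oracle_and_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.integers(0, 6, size=14).astype(float)  # plenty of ties
            l = rng.random(14) < 0.5
            if l.all() or not l.any():
                continue
            a = auc_rank(v, l, auto_direction=False).auc
            assert a == pytest.approx(oracles.auc_pairs(v, l))
            u = stats.mannwhitneyu(v[l], v[~l]).statistic
            assert a == pytest.approx(u / (l.sum() * (~l).sum()))

    def test_monotone_transform_invariance_and_label_swap(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=12)
        l = np.array([True] * 5 + [False] * 7)
        a = auc_rank(v, l, auto_direction=False).auc
        assert auc_rank(np.exp(3 * v), l, auto_direction=False).auc == pytest.approx(a)
        assert auc_rank(v, ~l, auto_direction=False).auc == pytest.approx(1 - a)

    def test_empty_class_rejected(self):
        with pytest.raises(InputError):
            auc_rank([1, 2], [True, True])


class TestStageAUC:
    def _study(self, shift_stage=None, effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        groups = (["healthy"] * 5 + ["I"] * 6 + ["II"] * 6 + ["IIIA"] * 6
                  + ["IIIB"] * 5 + ["IV"] * 6)
        mat = rng.normal(0, 1, size=(1, len(groups)))
        if shift_stage:
            mat[0, [i for i, g in enumerate(groups) if g == shift_stage]] += effect
        return make_study(mat, groups)

    def test_large_stage_shift_approaches_one(self):
        study = self._study("IV", effect=50)
        assert stage_auc(study, "f0", "IV").auc == 1.0

    def test_healthy_samples_excluded(self):
        # shift healthy wildly: one-vs-rest among tumor samples is unaffected
        study = self._study()
        shifted = study.matrix.copy()
        shifted.loc["f0", study.samples_in_group("healthy")] += 100
        study2 = make_study(shifted.to_numpy(),
                            study.sample_sheet["group"].tolist())
        assert stage_auc(study, "f0", "II").auc == \
            pytest.approx(stage_auc(study2, "f0", "II").auc)

    def test_reduces_to_auc_rank_on_relabelled_data(self):
        study = self._study(seed=3)
        samples = [s for s in study.matrix.columns
                   if study.sample_sheet.loc[s, "group"] != "healthy"]
        v = study.matrix.loc["f0", samples].to_numpy()
        l = (study.sample_sheet.loc[samples, "group"] == "IIIA").to_numpy()
        assert stage_auc(study, "f0", "IIIA").auc == auc_rank(v, l).auc

    def test_absent_stage_rejected(self):
        study = make_study(np.zeros((1, 4)), ["healthy", "healthy", "I", "I"])
        with pytest.raises(InputError):
            stage_auc(study, "f0", "IV")


class TestCombinedLogistic:
    def test_jointly_separable_features_reach_auc_one(self):
        mat = np.array([[0, 0, 1, 1, 5, 5, 6, 6],
                        [1, 0, 0, 1, 4, 5, 5, 4]], dtype=float)
        study = make_study(mat, ["healthy"] * 4 + ["I"] * 4)
        _, roc = fit_logistic_combined(study, ["f0", "f1"], case="I")
        assert roc.auc == 1.0

    def test_single_feature_model_equals_rank_auc(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(0, 1, size=(1, 30))
        groups = ["healthy"] * 14 + ["I"] * 16
        mat[0, 14:] += 1.0
        study = make_study(mat, groups)
        _, roc = fit_logistic_combined(study, ["f0"], case="I")
        assert roc.auc == pytest.approx(crc_auc(study, "f0").auc)


class TestSurvival:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_curve([5, 6, 7], [0, 0, 0])
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert curve.survival_at(0.5) == 1.0

    def test_tied_event_times_grouped_as_one_step(self):
        times, events = [1, 1, 2, 3], [1, 1, 1, 0]
        curve = km_curve(times, events)
        hand = oracles.km_hand(times, events)
        assert list(curve.times) == [t for t, _ in hand]
        np.testing.assert_allclose(curve.survival, [s for _, s in hand])

    def test_uncensored_km_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 20)
        curve = km_curve(t, np.ones(20, int))
        for tt, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > tt).mean())

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            km_curve([-1, 2], [1, 1])

    def test_identical_groups_give_zero_chi_square(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        res = logrank_test(t, e, [0, 0, 0, 1, 1, 1])
        assert res.chi_sq == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        t = [1, 3, 5, 2, 4, 6]
        e = [1, 1, 0, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_sq == pytest.approx(oracles.logrank_hand(t, e, g),
                                           rel=1e-9)

    def test_group_label_swap_is_symmetric(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 16)
        e = (rng.random(16) < 0.8).astype(int)
        g = np.array([0] * 8 + [1] * 8)
        assert logrank_test(t, e, g).chi_sq == \
            pytest.approx(logrank_test(t, e, 1 - g).chi_sq)

    def test_one_sided_group_rejected(self):
        with pytest.raises(InputError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestSplitsAndDrug:
    def test_mean_rule_example(self):
        high = expression_split([1, 2, 3, 4], rule="mean")
        assert list(high) == [False, False, True, True]

    def test_mean_and_median_can_differ_under_outliers(self):
        v = [1, 2, 3, 4, 100]
        mean_high = expression_split(v, rule="mean")
        med_high = expression_split(v, rule="median")
        assert list(mean_high) == [x > np.mean(v) for x in v]
        assert list(med_high) == [x > np.median(v) for x in v]
        assert list(mean_high) != list(med_high)

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            expression_split([5, 5, 5])

    def test_identical_ic50_everywhere_gives_null_result(self):
        res = drug_response_test([2.0] * 8, [1, 2, 3, 4, 5, 6, 7, 8])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_welch_closed_form_on_toy_split(self):
        expr = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        ic50 = np.array([2.0, 2.5, 1.8, 2.2, 5.0, 5.5, 4.8, 5.2])
        res = drug_response_test(ic50, expr, rule="median")
        t_hand, df_hand = oracles.welch_hand(ic50[4:], ic50[:4])
        assert res.statistic == pytest.approx(t_hand)
        assert res.df == pytest.approx(df_hand)
        assert res.direction == "high_expression_resistant"

    def test_tiny_split_group_rejected(self):
        with pytest.raises(InputError):
            drug_response_test([1, 2, 3], [1, 2, 3])


class TestSpearmanAndORA:
    def test_monotone_pairs(self):
        assert spearman_test([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman_test([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_tied_data_equals_pearson_on_midranks(self):
        x = [1, 2, 2, 3, 5, 5, 5]
        y = [2, 1, 4, 4, 6, 7, 6]
        rho, _ = spearman_test(x, y)
        r_mid = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(r_mid)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            spearman_test([1, 1, 1], [1, 2, 3])

    def test_enumeration_example_10_choose_3(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2"}
        res = hypergeom_ora(query, {"s": gene_set}, universe)[0]
        assert res.p == pytest.approx(10 / 120)
        assert res.p == pytest.approx(
            oracles.hypergeom_enum(universe, gene_set, query))

    def test_set_equal_to_universe_and_zero_overlap_give_unit_p(self):
        universe = {f"g{i}" for i in range(8)}
        res = hypergeom_ora({"g0", "g1"}, {"all": universe}, universe)[0]
        assert res.p == 1.0
        res2 = hypergeom_ora({"g0"}, {"none": {"g5", "g6"}}, universe)[0]
        assert res2.p == 1.0 and res2.overlap == 0

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            universe = {f"g{i}" for i in range(10)}
            gene_set = set(rng.choice(sorted(universe), 4, replace=False))
            query = set(rng.choice(sorted(universe), 3, replace=False))
            res = hypergeom_ora(query, {"s": gene_set}, universe)[0]
            assert res.p == pytest.approx(
                oracles.hypergeom_enum(universe, gene_set, query))

    def test_query_outside_universe_rejected(self):
        with pytest.raises(InputError):
            hypergeom_ora({"zzz"}, {"s": {"g0"}}, {"g0", "g1"})
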