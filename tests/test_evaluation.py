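import numpy as np
import pytest

from mirhubnet import (
    ExpressionMatrix,
    InputError,
    ParameterError,
    SyntheticConfig,
    crossval_accuracy,
    generate_dual_dataset,
    global_test,
    random_set_correlation_test,
    survival_compare,
)
from mirhubnet.evaluation import CLASSIFIERS, two_group_logrank
from mirhubnet.io import SurvivalTable


def logrank_oracle(time, event, group):
    """Independent spreadsheet-style observed/expected log-rank table."""
    time, event, group = map(np.asarray, (time, event, group))
    obs_minus_exp, var = 0.0, 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 0)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp**2 / var


class TestCrossvalAccuracy:
    def test_perfectly_separating_feature_all_classifiers(self, labeled_matrix):
        for clf in CLASSIFIERS:
            rep = crossval_accuracy(labeled_matrix, ["f0"], clf, seed=0)
            assert rep.accuracy == 1.0, clf

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(1)
        n = 40
        samples = [f"S{i}" for i in range(n)]
        labels = {s: ("a" if i < n // 2 else "b") for i, s in enumerate(samples)}
        m = ExpressionMatrix([f"f{i}" for i in range(20)], samples,
                             rng.standard_normal((20, n)), labels)
        accs = [crossval_accuracy(m, m.feature_ids, "knn", seed=s).accuracy for s in range(4)]
        assert abs(np.mean(accs) - 0.5) < 0.2

    def test_missing_features_named_in_error(self, labeled_matrix):
        with pytest.raises(InputError, match="ghost"):
            crossval_accuracy(labeled_matrix, ["f0", "ghost"], "knn")

    def test_unknown_classifier_rejected(self, labeled_matrix):
        with pytest.raises(ParameterError):
            crossval_accuracy(labeled_matrix, ["f0"], "deep_net")

    def test_deterministic_given_seed(self, labeled_matrix):
        a = crossval_accuracy(labeled_matrix, labeled_matrix.feature_ids, "svm_rbf", seed=5)
        b = crossval_accuracy(labeled_matrix, labeled_matrix.feature_ids, "svm_rbf", seed=5)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)


class TestRandomSetCorrelation:
    def test_degenerate_pool_gives_p_one(self, labeled_matrix):
        ids = labeled_matrix.feature_ids[:4]
        res = random_set_correlation_test(labeled_matrix, ids, ids, n_iter=100, seed=0)
        assert res.empirical_p == 1.0
        assert np.allclose(res.null_means, res.candidate_mean_r)

    def test_identical_features_have_unit_correlation(self):
        row = np.random.default_rng(2).standard_normal(30)
        m = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(30)],
                             np.vstack([row, row.copy()]))
        res = random_set_correlation_test(m, ["a", "b"], ["a", "b"], n_iter=50, seed=0)
        assert res.candidate_mean_r == pytest.approx(1.0, abs=1e-12)

    def test_planted_module_beats_random_pool(self):
        cfg = SyntheticConfig(n_class_a=100, n_class_b=100, n_mirna=60, n_hubs=1,
                              module_size=5, rho=0.9, de_fraction=0.0, seed=3)
        data = generate_dual_dataset(cfg)
        hub = data.truth.hub_ids[0]
        module = [hub] + data.truth.module_members[hub]
        in_module = set(module)
        pool = [f for f in data.mirna.feature_ids if f not in in_module]
        res = random_set_correlation_test(data.mirna, module, pool, n_iter=1000, seed=3)
        assert res.empirical_p <= 0.01

    def test_small_set_rejected(self, labeled_matrix):
        with pytest.raises(ParameterError):
            random_set_correlation_test(labeled_matrix, ["f0"], labeled_matrix.feature_ids)


class TestGlobalTest:
    def test_indicator_feature_reaches_minimal_p(self):
        n = 24
        samples = [f"S{i}" for i in range(n)]
        labels = {s: ("a" if i < n // 2 else "b") for i, s in enumerate(samples)}
        indicator = np.array([0.0] * (n // 2) + [1.0] * (n // 2))
        m = ExpressionMatrix(["ind"], samples, indicator[None, :], labels)
        res = global_test(m, ["ind"], n_perm=1000, seed=0)
        assert res.p_value <= 2.0 / 1001.0

    def test_q_invariant_to_feature_order_and_label_flip(self, labeled_matrix):
        ids = labeled_matrix.feature_ids
        q1 = global_test(labeled_matrix, ids, n_perm=1000, seed=1).Q
        q2 = global_test(labeled_matrix, ids[::-1], n_perm=1000, seed=1).Q
        assert q1 == pytest.approx(q2, abs=1e-12)
        flipped = {s: ("beta" if c == "alpha" else "alpha")
                   for s, c in labeled_matrix.labels.items()}
        m2 = ExpressionMatrix(labeled_matrix.feature_ids, labeled_matrix.sample_ids,
                              labeled_matrix.values, flipped)
        q3 = global_test(m2, ids, n_perm=1000, seed=1).Q
        assert q1 == pytest.approx(q3, abs=1e-12)

    def test_per_feature_table_complete(self, labeled_matrix):
        res = global_test(labeled_matrix, labeled_matrix.feature_ids, n_perm=1000, seed=0)
        assert list(res.per_feature["feature"]) == labeled_matrix.feature_ids
        assert (res.per_feature["contribution"] >= 0).all()

    def test_single_class_rejected(self):
        m = ExpressionMatrix(["f"], ["s1", "s2"], [[1.0, 2.0]], None)
        with pytest.raises(InputError):
            global_test(m, ["f"], n_perm=1000)


class TestSurvival:
    def test_logrank_matches_hand_worked_oracle(self):
        # 6 subjects, times 1..6 alternating groups, no censoring
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        group = np.array([0, 1, 0, 1, 0, 1])
        stat, _ = two_group_logrank(time[group == 0], event[group == 0],
                                    time[group == 1], event[group == 1])
        assert stat == pytest.approx(logrank_oracle(time, event, group), abs=1e-9)

    def test_logrank_oracle_on_censored_data(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(5.0, size=40).round(3)
        event = rng.integers(0, 2, size=40)
        group = rng.integers(0, 2, size=40)
        stat, _ = two_group_logrank(time[group == 0], event[group == 0],
                                    time[group == 1], event[group == 1])
        assert stat == pytest.approx(logrank_oracle(time, event, group), abs=1e-9)

    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        stat, p = two_group_logrank(t, e, t.copy(), e.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        ta, tb = rng.exponential(3, 20), rng.exponential(6, 25)
        ea, eb = np.ones(20, int), np.ones(25, int)
        s1, _ = two_group_logrank(ta, ea, tb, eb)
        s2, _ = two_group_logrank(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_survival_compare_separable_clusters(self):
        cfg = SyntheticConfig(n_class_a=50, n_class_b=50, n_mirna=30, n_hubs=2,
                              module_size=3, de_fraction=0.5, effect_size=3.0,
                              hazard_ratio=4.0, seed=6)
        data = generate_dual_dataset(cfg)
        de = sorted(data.truth.de_ids)
        res = survival_compare(data.mirna, de, data.survival, seed=0)
        assert set(res.groups.values()) == {"basal_like_trend", "luminal_A_trend"}
        assert res.p_value < 0.01
        assert {"time", "survival", "group"} <= set(res.km_curves.columns)

    def test_degenerate_single_cluster_reports_p_one(self, caplog):
        samples = [f"S{i}" for i in range(10)]
        labels = {s: ("a" if i < 5 else "b") for i, s in enumerate(samples)}
        m = ExpressionMatrix(["f0"], samples, np.zeros((1, 10)), labels)
        surv = SurvivalTable(samples, np.arange(1.0, 11.0), np.ones(10, int))
        with caplog.at_level("WARNING"):
            res = survival_compare(m, ["f0"], surv, seed=0)
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0


class TestHubPanelDirectionalAdvantage:
    def test_weak_classifiers_prefer_concentrated_hub_panel(self):
        """With subtype signal concentrated on hub miRNAs, the compact hub
        panel classifies at least as well, on average, as the full
        differential panel for the two weaker classifiers."""
        accs = {"naive_bayes": [[], []], "knn": [[], []]}
        for seed in range(12):
            cfg = SyntheticConfig(n_mirna=100, de_fraction=0.4, effect_size=0.6,
                                  hub_effect_boost=3.0, de_on_hubs=True, seed=seed)
            data = generate_dual_dataset(cfg)
            hubs = data.truth.hub_ids
            de = sorted(data.truth.de_ids)
            for clf in accs:
                accs[clf][0].append(crossval_accuracy(data.mirna, hubs, clf, seed=seed).accuracy)
                accs[clf][1].append(crossval_accuracy(data.mirna, de, clf, seed=seed).accuracy)
        for clf, (hub_acc, de_acc) in accs.items():
            assert np.mean(hub_acc) >= np.mean(de_acc), clf
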