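import numpy as np
import pytest

from texrad.evaluate import (
    CVPlan,
    ModelGrid,
    RankingConfig,
    argmax_k,
    bootstrap_pearson,
    consistency_intersection,
    evaluate,
    make_folds,
    rank_features,
    roc_auc,
    sample_consistency,
    selection_sweep,
)

from _oracles import oracle_auc
from conftest import make_feature_table

SMALL_GRID = ModelGrid(svm_C=(1.0,), rf_mtry=(3,), rf_ntree=50)


def signal_table(rng, n_per_class=20, n_features=8, shift=2.5):
    labels = np.repeat([0, 1], n_per_class)
    x = rng.normal(size=(2 * n_per_class, n_features))
    x[labels == 1, 0] += shift
    return make_feature_table(x, labels)


# ---------------------------------------------------------------------------
# folds


def test_folds_default_plan_counts():
    labels = np.repeat([0, 1], 50)
    folds = make_folds(labels, CVPlan())
    assert len(folds) == 50
    for train, test in folds:
        assert len(test) == 20
        assert (labels[test] == 1).sum() == 10


def test_folds_partition_per_repetition():
    labels = np.repeat([0, 1], 10)
    plan = CVPlan(k=5, repeats=3, base_seed=7)
    folds = make_folds(labels, plan)
    for r in range(3):
        rep = folds[r * 5:(r + 1) * 5]
        tests = np.concatenate([t for _, t in rep])
        assert sorted(tests) == list(range(20))
        for (tr, te) in rep:
            assert set(tr) | set(te) == set(range(20))
            assert not set(tr) & set(te)


def test_folds_tiny_balanced():
    folds = make_folds([0, 0, 1, 1], CVPlan(k=2, repeats=1))
    for _, test in folds:
        assert len(test) == 2


def test_folds_deterministic_and_seeded():
    labels = np.repeat([0, 1], 15)
    a = make_folds(labels, CVPlan(base_seed=3))
    b = make_folds(labels, CVPlan(base_seed=3))
    c = make_folds(labels, CVPlan(base_seed=4))
    assert all((x[0] == y[0]).all() and (x[1] == y[1]).all() for x, y in zip(a, b))
    assert any(not (x[1] == y[1]).all() for x, y in zip(a, c))


def test_folds_small_class_raises():
    with pytest.raises(ValueError):
        make_folds([0, 0, 0, 1], CVPlan(k=5))


# ---------------------------------------------------------------------------
# AUC


def test_auc_perfect_and_ties():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5


def test_auc_example():
    assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)


def test_auc_single_class_nan():
    assert np.isnan(roc_auc([0.1, 0.2], [1, 1]))


@pytest.mark.parametrize("seed", range(30))
def test_auc_matches_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    scores = rng.integers(0, 4, size=n).astype(float)  # plenty of ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert roc_auc(scores, labels) == pytest.approx(
        oracle_auc(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# ranking


def test_label_equal_feature_ranks_first(rng):
    labels = np.repeat([0, 1], 15)
    x = rng.normal(size=(30, 6))
    x[:, 3] = labels
    t = make_feature_table(x, labels)
    for method in ("pvalue", "mic"):
        ranking = rank_features(t, RankingConfig(method=method))
        assert ranking[0].endswith("F003"), method


def test_ranking_stable_tie_break(rng):
    labels = np.repeat([0, 1], 10)
    x = rng.normal(size=(20, 4))
    x[:, 2] = x[:, 1]  # identical features tie; name order decides
    t = make_feature_table(x, labels)
    ranking = rank_features(t, RankingConfig(method="pvalue"))
    i1 = ranking.index([c for c in t.data.columns if c.endswith("F001")][0])
    i2 = ranking.index([c for c in t.data.columns if c.endswith("F002")][0])
    assert i1 < i2


def test_ranking_ignores_test_rows(rng):
    t = signal_table(rng)
    train_ids = t.data.index[:30]
    ranking1 = rank_features(t.subset_rows(train_ids), RankingConfig())
    mutated = t.data.copy()
    mutated.iloc[35] = 1e6  # a held-out row
    t2 = make_feature_table(mutated.to_numpy(), t.labels.to_numpy())
    ranking2 = rank_features(t2.subset_rows(t2.data.index[:30]), RankingConfig())
    assert ranking1 == ranking2


def test_ranking_single_class_raises(rng):
    t = make_feature_table(rng.normal(size=(10, 3)), np.zeros(10))
    with pytest.raises(ValueError):
        rank_features(t, RankingConfig())


def test_signal_feature_rank_one_under_reseeding(rng):
    hits = 0
    for rep in range(25):
        r = np.random.default_rng(rep)
        t = signal_table(r, n_per_class=15, n_features=10, shift=3.0)
        ranking = rank_features(t, RankingConfig(method="pvalue"))
        hits += ranking[0].endswith("F000")
    assert hits >= 24


# ---------------------------------------------------------------------------
# evaluate


def test_iteration_count_is_50_at_defaults(rng):
    t = signal_table(rng, n_per_class=10)
    res = evaluate(t, ModelGrid(svm_C=(1.0,), rf_mtry=(2,), rf_ntree=25), CVPlan())
    assert res.n_iterations == 50
    for c in res.configs.values():
        assert len(c.aucs) == 50
        assert np.isfinite(c.aucs).all()


def test_strong_signal_high_auc(rng):
    t = signal_table(rng, n_per_class=15, shift=3.0)
    res = evaluate(t, SMALL_GRID, CVPlan(k=5, repeats=2))
    assert res.best("svm").mean_auc > 0.9
    assert res.best("rf").mean_auc > 0.9


def test_permuted_labels_auc_near_half(rng):
    aucs = []
    for rep in range(20):
        r = np.random.default_rng(rep)
        labels = r.permutation(np.repeat([0, 1], 12))
        t = make_feature_table(r.normal(size=(24, 6)), labels)
        res = evaluate(t, ModelGrid(svm_C=(1.0,), rf_mtry=(2,), rf_ntree=25),
                       CVPlan(k=4, repeats=1, base_seed=rep))
        aucs.append(res.best("svm").mean_auc)
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_determinism(rng):
    t = signal_table(rng)
    a = evaluate(t, SMALL_GRID, CVPlan(k=5, repeats=2, base_seed=1))
    b = evaluate(t, SMALL_GRID, CVPlan(k=5, repeats=2, base_seed=1))
    for key in a.configs:
        np.testing.assert_array_equal(a.configs[key].aucs, b.configs[key].aucs)
        np.testing.assert_array_equal(a.tested[key], b.tested[key])
        np.testing.assert_array_equal(a.correct[key], b.correct[key])


def test_leakage_audit_selection_traces(rng):
    # mutating a sample's features must not change rankings of iterations
    # where that sample sat in the test fold
    t = signal_table(rng, n_per_class=10, n_features=6)
    plan = CVPlan(k=5, repeats=2, base_seed=0)
    folds = make_folds(t.labels.to_numpy(), plan)
    res1 = evaluate(t, SMALL_GRID, plan, selection=RankingConfig(), top_k=3)
    x2 = t.data.to_numpy().copy()
    victim = 7
    x2[victim] += 100.0
    t2 = make_feature_table(x2, t.labels.to_numpy())
    res2 = evaluate(t2, SMALL_GRID, plan, selection=RankingConfig(), top_k=3)
    checked = 0
    for it, (_, test_idx) in enumerate(folds):
        if victim in test_idx:
            assert res1.selection_trace[it] == res2.selection_trace[it]
            checked += 1
    assert checked == plan.repeats  # in a test fold once per repetition


def test_metrics_within_bounds(rng):
    t = signal_table(rng)
    res = evaluate(t, SMALL_GRID, CVPlan(k=5, repeats=2))
    for c in res.configs.values():
        for arr in (c.aucs, c.sensitivities, c.specificities, c.accuracies):
            finite = arr[np.isfinite(arr)]
            assert ((finite >= 0) & (finite <= 1)).all()


def test_per_sample_tallies(rng):
    t = signal_table(rng, n_per_class=10)
    plan = CVPlan(k=5, repeats=4)
    res = evaluate(t, ModelGrid(svm_C=(1.0,), rf_mtry=(2,), rf_ntree=25), plan)
    for key in res.configs:
        # each sample is tested exactly once per repetition
        assert (res.tested[key] == plan.repeats).all()
        assert (res.correct[key] <= res.tested[key]).all()


# ---------------------------------------------------------------------------
# selection sweep


def test_sweep_full_k_matches_plain_evaluate(rng):
    t = signal_table(rng, n_per_class=10, n_features=5)
    grid = ModelGrid(svm_C=(1.0,), rf_mtry=(2,), rf_ntree=25)
    plan = CVPlan(k=5, repeats=2, base_seed=3)
    profile, _ = selection_sweep(t, grid, plan, RankingConfig(method="pvalue"),
                                 top_ks=[t.n_features])
    plain = evaluate(t, grid, plan)
    for model in ("svm", "rf"):
        swept = profile[(profile.model == model)]["mean_auc"].iloc[0]
        assert swept == pytest.approx(plain.best(model).mean_auc, abs=1e-12)


def test_sweep_profile_shape_and_argmax(rng):
    t = signal_table(rng, n_per_class=12, n_features=6, shift=3.0)
    profile, _ = selection_sweep(t, ModelGrid(svm_C=(1.0,), rf_mtry=(2,), rf_ntree=25),
                                 CVPlan(k=4, repeats=2),
                                 RankingConfig(method="pvalue"))
    assert set(profile["top_k"]) == set(range(1, 7))
    k, auc = argmax_k(profile, "svm")
    assert 1 <= k <= 6 and 0.5 < auc <= 1.0


# ---------------------------------------------------------------------------
# consistency + bootstrap


def test_sample_consistency_proportions(rng):
    t = signal_table(rng, n_per_class=10, shift=4.0)
    res = evaluate(t, SMALL_GRID, CVPlan(k=5, repeats=10))
    key_svm = ("svm", 1.0, None)
    key_rf = ("rf", 3, None)
    cons_svm = sample_consistency(res, key_svm)
    assert (cons_svm["times_tested"] == 10).all()
    assert ((cons_svm["proportion_correct"] >= 0)
            & (cons_svm["proportion_correct"] <= 1)).all()
    # strongly separated data: most samples are consistently correct
    assert (cons_svm["proportion_correct"] >= 0.8).mean() >= 0.75
    inter = consistency_intersection(cons_svm, sample_consistency(res, key_rf))
    assert inter.sum() <= (cons_svm["proportion_correct"] >= 0.8).sum()


def test_bootstrap_pearson_exact_linear():
    x = np.arange(10, dtype=float)
    r, (lo, hi) = bootstrap_pearson(x, 2 * x + 1, n_boot=200, seed=0)
    assert r == pytest.approx(1.0)
    assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)


def test_bootstrap_pearson_three_points():
    r, _ = bootstrap_pearson([1, 2, 3], [1, 3, 2], n_boot=200, seed=1)
    assert r == pytest.approx(0.5)


def test_bootstrap_pearson_deterministic(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    assert bootstrap_pearson(x, y, seed=5) == bootstrap_pearson(x, y, seed=5)


def test_bootstrap_pearson_validation(rng):
    with pytest.raises(ValueError):
        bootstrap_pearson([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        bootstrap_pearson(np.ones(10), rng.normal(size=10))
    with pytest.raises(ValueError):
        bootstrap_pearson(rng.normal(size=10), rng.normal(size=10), n_boot=10)
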