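"""Grouped splits, weighted training, grid search, McNemar, serialization."""

import numpy as np
import pytest

from epochsift.classifier import (
    DEFAULT_GRID,
    ForestConfig,
    TrainedForest,
    classify,
    grid_search,
    grouped_stratified_split,
    load_model,
    loso_folds,
    mcnemar,
    predict_proba,
    save_model,
    train,
)
from epochsift.consensus import ConsensusLabel
from epochsift.synthetic import DEFAULT_GRID as REGISTRY_GRID
from epochsift.synthetic import DEFAULT_INFANTS_PER_GROUP, GeneratorSpec, gen_dataset


def cons_from_labels(y, weight=1.0):
    return [ConsensusLabel(label=int(v), n_agree=7, weight=weight) for v in y]


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 31))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += 4 * y  # widen the margin
    return X, y


# ---------------------------------------------------------------------------
# folds and splits

def test_loso_folds_cover_and_group():
    ids = ["a", "a", "b", "c", "c"]
    folds = loso_folds(ids)
    assert len(folds) == 3
    all_val = np.sort(np.concatenate([v for _, v in folds]))
    np.testing.assert_array_equal(all_val, np.arange(5))
    for tr, va in folds:
        assert set(tr) & set(va) == set()
        val_ids = {ids[i] for i in va}
        assert len(val_ids) == 1
        assert val_ids.isdisjoint({ids[i] for i in tr})


def test_loso_single_infant_errors():
    with pytest.raises(ValueError):
        loso_folds(["only", "only"])


@pytest.fixture(scope="module")
def registry():
    spec = GeneratorSpec(seed=20)
    _, _, _, reg = gen_dataset(spec)
    return reg


def test_grouped_stratified_split_sizes(registry):
    ids = [r["infant_id"] for r in registry]
    ages = [r["age_group"] for r in registry]
    stims = [r["stimulus"] for r in registry]
    train_idx, test_idx = grouped_stratified_split(ids, ages, stims, 70 / 410, seed=5)
    assert len(train_idx) + len(test_idx) == 410
    # close to the 340/70 design
    assert abs(len(test_idx) - 70) <= 10
    # no infant straddles the split
    assert {ids[i] for i in train_idx}.isdisjoint({ids[i] for i in test_idx})
    # per-stratum counts near target
    from collections import Counter

    totals = Counter(zip(ages, stims))
    intest = Counter((ages[i], stims[i]) for i in test_idx)
    for key, total in totals.items():
        target = 70 / 410 * total
        assert abs(intest.get(key, 0) - target) <= 3


def test_grouped_split_deterministic(registry):
    ids = [r["infant_id"] for r in registry]
    ages = [r["age_group"] for r in registry]
    stims = [r["stimulus"] for r in registry]
    s1 = grouped_stratified_split(ids, ages, stims, 0.2, seed=9)
    s2 = grouped_stratified_split(ids, ages, stims, 0.2, seed=9)
    np.testing.assert_array_equal(s1[0], s2[0])
    np.testing.assert_array_equal(s1[1], s2[1])


# ---------------------------------------------------------------------------
# training

def test_train_separable_perfect():
    X, y = separable_data()
    model = train(X, cons_from_labels(y), ForestConfig(n_trees=50, seed=0))
    pred = classify(model, X)
    np.testing.assert_array_equal(pred, y)


def test_train_single_class_errors():
    X = np.zeros((10, 31))
    with pytest.raises(ValueError):
        train(X, cons_from_labels(np.zeros(10)))


def test_weight_scale_invariance():
    X, y = separable_data(seed=2)
    rng = np.random.default_rng(0)
    w = rng.uniform(0.5, 1.0, len(y))
    c1 = [ConsensusLabel(int(v), 7, wi) for v, wi in zip(y, w)]
    c2 = [ConsensusLabel(int(v), 7, 2 * wi) for v, wi in zip(y, w)]
    m1 = train(X, c1, ForestConfig(n_trees=30, seed=1))
    m2 = train(X, c2, ForestConfig(n_trees=30, seed=1))
    np.testing.assert_array_equal(predict_proba(m1, X), predict_proba(m2, X))


def test_determinism_same_seed():
    X, y = separable_data(seed=3)
    cons = cons_from_labels(y)
    m1 = train(X, cons, ForestConfig(n_trees=40, seed=5))
    m2 = train(X, cons, ForestConfig(n_trees=40, seed=5))
    np.testing.assert_array_equal(predict_proba(m1, X), predict_proba(m2, X))


# ---------------------------------------------------------------------------
# posterior and threshold

def test_predict_proba_is_tree_average():
    X, y = separable_data(seed=4)
    model = train(X, cons_from_labels(y), ForestConfig(n_trees=3, seed=0))
    post = predict_proba(model, X)
    art_col = int(np.where(model.forest.classes_ == 1)[0][0])
    per_tree = np.stack(
        [t.predict_proba(X)[:, art_col] for t in model.forest.estimators_]
    )
    np.testing.assert_allclose(post, per_tree.mean(axis=0), atol=1e-12)
    assert np.all((post >= 0) & (post <= 1))
    comp = model.forest.predict_proba(X).sum(axis=1)
    np.testing.assert_allclose(comp, 1.0)


def test_threshold_extremes_and_monotonicity():
    X, y = separable_data(seed=5)
    model = train(X, cons_from_labels(y), ForestConfig(n_trees=30, seed=0))
    assert classify(model, X, threshold=0.0).all()
    post = predict_proba(model, X)
    at_one = classify(model, X, threshold=1.0)
    np.testing.assert_array_equal(at_one, (post >= 1.0).astype(int))
    prev = None
    for thr in np.linspace(0, 1, 21):
        called = set(np.where(classify(model, X, threshold=thr))[0])
        if prev is not None:
            assert called.issubset(prev)
        prev = called


def test_manifest_mismatch_refused(trained_model, labelled_set):
    bad = list(trained_model.feature_names)
    bad[0] = "not_a_feature"
    with pytest.raises(ValueError, match="not_a_feature"):
        predict_proba(trained_model, labelled_set["X_test"], feature_names=bad)


# ---------------------------------------------------------------------------
# grid search

def test_grid_search_single_point():
    X, y = separable_data(n=40, seed=6)
    ids = [f"i{k // 2}" for k in range(40)]
    folds = loso_folds(ids)[:5]
    grid = {"n_trees": [25], "max_depth": [3], "min_samples_leaf": [2],
            "max_features": ["sqrt"]}
    best, results = grid_search(X, cons_from_labels(y), folds, grid)
    assert best == ForestConfig(25, 3, 2, "sqrt", seed=0)
    assert len(results) == 1


def test_grid_search_planted_depth_optimum():
    # XOR-style interaction needs depth >= 2; depth-1 stumps cannot learn it
    rng = np.random.default_rng(7)
    n = 120
    X = np.zeros((n, 31))
    X[:, :2] = rng.integers(0, 2, (n, 2)) * 2.0 - 1.0
    X[:, 2:] = 0.01 * rng.standard_normal((n, 29))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    ids = [f"i{k % 10}" for k in range(n)]
    folds = loso_folds(ids)
    grid = {"n_trees": [50], "max_depth": [1, 4], "min_samples_leaf": [1],
            "max_features": [None]}
    best, results = grid_search(X, cons_from_labels(y), folds, grid, seed=1)
    assert best.max_depth == 4
    scores = {cfg.max_depth: s for cfg, s in results}
    assert scores[4] > scores[1]


def test_grid_search_order_invariant():
    X, y = separable_data(n=30, seed=8)
    ids = [f"i{k // 3}" for k in range(30)]
    folds = loso_folds(ids)[:4]
    g1 = {"n_trees": [20, 40], "max_depth": [2], "min_samples_leaf": [1],
          "max_features": ["sqrt"]}
    g2 = {k: list(reversed(v)) for k, v in g1.items()}
    b1, r1 = grid_search(X, cons_from_labels(y), folds, g1)
    b2, r2 = grid_search(X, cons_from_labels(y), folds, g2)
    assert b1 == b2
    assert dict((c, s) for c, s in r1) == dict((c, s) for c, s in r2)


def test_default_grid_shape():
    assert set(DEFAULT_GRID) == {"n_trees", "max_depth", "min_samples_leaf",
                                 "max_features"}
    assert len(DEFAULT_GRID["min_samples_leaf"]) >= 4


# ---------------------------------------------------------------------------
# McNemar

def test_mcnemar_identical_predictions():
    t = np.array([0, 1, 0, 1, 1])
    p = np.array([0, 1, 1, 1, 0])
    assert mcnemar(p, p, t) == 1.0


def test_mcnemar_exact_binomial():
    # 15 vs 5 discordant pairs: p = 2 * P(X <= 5 | n=20, p=1/2)
    truth = np.zeros(40, dtype=int)
    a = np.zeros(40, dtype=int)
    b = np.zeros(40, dtype=int)
    b[:15] = 1   # a right, b wrong: 15
    a[15:20] = 1  # b right, a wrong: 5
    from scipy.stats import binom

    expect = 2 * binom.cdf(5, 20, 0.5)
    assert expect == pytest.approx(0.0414, abs=5e-5)
    assert mcnemar(a, b, truth) == pytest.approx(expect, rel=1e-12)
    assert mcnemar(b, a, truth) == pytest.approx(mcnemar(a, b, truth), rel=1e-12)


def test_mcnemar_matches_statsmodels_exact():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    truth = np.zeros(30, dtype=int)
    a = np.zeros(30, dtype=int)
    b = np.zeros(30, dtype=int)
    b[:8] = 1
    a[8:11] = 1
    table = [[19, 8], [3, 0]]
    expect = sm_mcnemar(table, exact=True).pvalue
    assert mcnemar(a, b, truth) == pytest.approx(expect, rel=1e-9)


# ---------------------------------------------------------------------------
# serialization

def test_serialization_round_trip(tmp_path, trained_model, labelled_set):
    path = tmp_path / "model.joblib"
    save_model(trained_model, path)
    back = load_model(path)
    assert isinstance(back, TrainedForest)
    assert back.feature_names == trained_model.feature_names
    assert back.config == trained_model.config
    assert back.fingerprint == trained_model.fingerprint
    X = labelled_set["X_test"]
    np.testing.assert_array_equal(
        predict_proba(back, X), predict_proba(trained_model, X)
    )
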