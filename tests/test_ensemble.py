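"""Ensemble behaviour: method policies, determinism, OOB, importances."""

import numpy as np
import pytest

from voxsol.ensemble import (
    EnsembleConfig,
    EnsembleMethod,
    TrainedEnsemble,
    TreeEnsemble,
    feature_importance,
    fit_ensemble,
    oob_error,
    predict_ensemble,
)
from voxsol.features import drop_incomplete_features, drop_zero_variance
from voxsol.metrics import evaluate
from voxsol.simulate import GeneratorSpec, generate
from voxsol.tree import fit_tree, predict_tree_matrix


def _xy(bench):
    t, _ = drop_incomplete_features(bench.table)
    t, _ = drop_zero_variance(t)
    return t, bench.solubility.align_with(t)


@pytest.mark.parametrize(
    "method,n_default",
    [
        (EnsembleMethod.BAGGING, 100),
        (EnsembleMethod.RANDOM_FOREST, 1000),
        (EnsembleMethod.EXTRA_TREES, 500),
    ],
)
def test_default_tree_counts(method, n_default):
    cfg = EnsembleConfig(method).resolved(n_features=173)
    assert cfg.n_trees == n_default


def test_mtry_defaults_follow_regression_conventions():
    rf = EnsembleConfig(EnsembleMethod.RANDOM_FOREST).resolved(173)
    et = EnsembleConfig(EnsembleMethod.EXTRA_TREES).resolved(173)
    bag = EnsembleConfig(EnsembleMethod.BAGGING).resolved(173)
    assert rf.mtry == 57  # floor(173/3)
    assert et.mtry == 58  # ceil(173/3)
    assert bag.mtry == 173


def test_bootstrap_flag_per_method():
    assert EnsembleConfig(EnsembleMethod.BAGGING).bootstrap
    assert EnsembleConfig(EnsembleMethod.RANDOM_FOREST).bootstrap
    assert not EnsembleConfig(EnsembleMethod.EXTRA_TREES).bootstrap


def test_constant_target_predicts_constant():
    rng = np.random.default_rng(0)
    x = rng.random((20, 4))
    y = np.full(20, -3.7)
    model = fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.BAGGING, n_trees=5, seed=1))
    assert all(t.is_leaf for t in model.trees)
    np.testing.assert_allclose(predict_ensemble(model, x), -3.7)


def test_invalid_configs_rejected():
    rng = np.random.default_rng(0)
    x, y = rng.random((10, 3)), rng.standard_normal(10)
    with pytest.raises(ValueError):
        fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.BAGGING, n_trees=0))
    with pytest.raises(ValueError):
        fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.RANDOM_FOREST, n_trees=2, mtry=9))


def test_identity_bootstrap_reduces_to_single_exhaustive_tree():
    """A one-tree bagger whose bootstrap is forced to the identity must equal
    a single exhaustive CART fit; its OOB set is then empty (NaN, count 0)."""
    rng = np.random.default_rng(5)
    x = rng.random((25, 3))
    y = rng.standard_normal(25)
    cfg = EnsembleConfig(EnsembleMethod.BAGGING, n_trees=1, seed=0).resolved(3)
    single = fit_tree(x, y, cfg.policy(3), cfg.min_node_size, np.random.default_rng(0))
    forced = TrainedEnsemble(
        config=cfg,
        trees=[single],
        bootstrap_indices=[np.arange(25)],
        feature_names=[f"f{i}" for i in range(3)],
        y_train_min=float(y.min()),
        y_train_max=float(y.max()),
    )
    np.testing.assert_allclose(
        predict_ensemble(forced, x), predict_tree_matrix(single, x)
    )
    res = oob_error(forced, x, y)
    assert res.n_oob == 0 and np.isnan(res.rmse)


@pytest.mark.parametrize(
    "method",
    [EnsembleMethod.BAGGING, EnsembleMethod.RANDOM_FOREST, EnsembleMethod.EXTRA_TREES],
)
def test_seeded_determinism_bit_identical(method, bench_small):
    t, y = _xy(bench_small)
    cfg = EnsembleConfig(method, n_trees=8, seed=123)
    p1 = predict_ensemble(fit_ensemble(t, y, cfg), t)
    p2 = predict_ensemble(fit_ensemble(t, y, cfg), t)
    assert np.array_equal(p1, p2)


def test_prediction_is_mean_of_trees(bench_small):
    t, y = _xy(bench_small)
    model = fit_ensemble(t, y, EnsembleConfig(EnsembleMethod.EXTRA_TREES, n_trees=7, seed=2))
    stacked = np.stack([predict_tree_matrix(tree, t.values) for tree in model.trees])
    np.testing.assert_allclose(predict_ensemble(model, t), stacked.mean(axis=0))


def test_predictions_bounded_by_training_range(bench_small):
    t, y = _xy(bench_small)
    model = fit_ensemble(t, y, EnsembleConfig(EnsembleMethod.RANDOM_FOREST, n_trees=10, seed=3))
    rng = np.random.default_rng(0)
    queries = rng.random((100, t.n_features)) * 200 - 100
    preds = predict_ensemble(model, queries)
    assert preds.min() >= y.min() - 1e-12 and preds.max() <= y.max() + 1e-12


def test_oob_requires_bootstrap(bench_small):
    t, y = _xy(bench_small)
    model = fit_ensemble(t, y, EnsembleConfig(EnsembleMethod.EXTRA_TREES, n_trees=3, seed=0))
    with pytest.raises(ValueError):
        oob_error(model, t, y)


def test_oob_rmse_tracks_heldout_rmse():
    """OOB error is an internal validation estimate: averaged over seeds it
    should sit within 25% of a genuine held-out RMSE."""
    oob_vals, held_vals = [], []
    for seed in range(5):
        spec = GeneratorSpec(n_compounds=150, n_features=40, n_correlated_blocks=2,
                             block_size=3, n_missing_columns=0,
                             n_zero_variance_columns=0, noise_sd=0.17, seed=seed)
        data = generate(spec)
        x = data.table.values
        y = data.solubility.align_with(data.table)
        x_tr, y_tr = x[:110], y[:110]
        x_te, y_te = x[110:], y[110:]
        cfg = EnsembleConfig(EnsembleMethod.RANDOM_FOREST, n_trees=60, seed=seed)
        model = fit_ensemble(x_tr, y_tr, cfg)
        oob_vals.append(oob_error(model, x_tr, y_tr).rmse)
        held_vals.append(evaluate(predict_ensemble(model, x_te), y_te).rmse)
    oob_m, held_m = np.mean(oob_vals), np.mean(held_vals)
    assert abs(oob_m - held_m) / held_m < 0.25


def test_feature_importance_identifies_signal_feature():
    """y = f1 exactly: both scores must rank f1 above a pure-noise feature."""
    perm_wins = purity_wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        x = rng.random((50, 2))
        y = x[:, 0].copy()
        model = fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.RANDOM_FOREST,
                                                  n_trees=30, mtry=1, seed=seed))
        imp = feature_importance(model, x, y, seed=seed)
        perm_wins += imp["permutation"].iloc[0] > imp["permutation"].iloc[1]
        purity_wins += imp["purity"].iloc[0] > imp["purity"].iloc[1]
    assert perm_wins == 10 and purity_wins == 10


def test_unused_feature_scores_zero():
    """A constant column can never define a split: both scores exactly zero."""
    rng = np.random.default_rng(11)
    x = rng.random((40, 3))
    x[:, 2] = 0.5  # never splittable, hence never used by any tree
    y = 2 * x[:, 0] - x[:, 1]
    model = fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.BAGGING, n_trees=10, seed=1))
    imp = feature_importance(model, x, y, seed=0)
    assert imp["purity"].iloc[2] == 0.0
    assert imp["permutation"].iloc[2] == 0.0


def test_crowd_variance_shrinks_as_forest_grows():
    """Across seeds, the across-seed variance of the ensemble prediction at a
    fixed query decreases (within simulation tolerance) as trees double."""
    spec = GeneratorSpec(n_compounds=60, n_features=20, n_correlated_blocks=1,
                         block_size=3, n_missing_columns=0,
                         n_zero_variance_columns=0, noise_sd=0.17, seed=0)
    data = generate(spec)
    x = data.table.values
    y = data.solubility.align_with(data.table)
    query = x[:5]
    sizes = [1, 2, 4, 8, 16, 32, 64]
    variances = []
    for n_trees in sizes:
        preds = [
            predict_ensemble(
                fit_ensemble(x, y, EnsembleConfig(EnsembleMethod.BAGGING,
                                                  n_trees=n_trees, seed=seed)),
                query,
            )
            for seed in range(20)
        ]
        variances.append(float(np.mean(np.var(np.stack(preds), axis=0))))
    # monotone decrease within a 15% simulation slack at each doubling
    for small, large in zip(variances[:-1], variances[1:]):
        assert large < small * 1.15
    assert variances[-1] < variances[0] / 4


@pytest.mark.parametrize(
    "method",
    [EnsembleMethod.BAGGING, EnsembleMethod.RANDOM_FOREST, EnsembleMethod.EXTRA_TREES],
)
def test_each_ensemble_beats_mean_baseline_held_out(method):
    """RMSE/SD < 1 on held-out synthetic data with signal at tight noise."""
    spec = GeneratorSpec(n_compounds=150, seed=21, noise_sd=0.17)
    data = generate(spec)
    t, _ = drop_incomplete_features(data.table)
    t, _ = drop_zero_variance(t)
    y = data.solubility.align_with(t)
    x = t.values
    x_tr, y_tr, x_te, y_te = x[:112], y[:112], x[112:], y[112:]
    model = fit_ensemble(x_tr, y_tr, EnsembleConfig(method, n_trees=100, seed=5))
    rep = evaluate(predict_ensemble(model, x_te), y_te)
    assert rep.rmse_over_sd < 1.0


def test_serialization_round_trip(tmp_path, bench_small):
    t, y = _xy(bench_small)
    model = fit_ensemble(t, y, EnsembleConfig(EnsembleMethod.RANDOM_FOREST, n_trees=4, seed=9))
    path = tmp_path / "model.json"
    model.save(path)
    back = TrainedEnsemble.load(path)
    np.testing.assert_array_equal(predict_ensemble(back, t), predict_ensemble(model, t))


def test_results_object_surface(bench_small):
    t, y = _xy(bench_small)
    res = TreeEnsemble(t, y, EnsembleConfig(EnsembleMethod.RANDOM_FOREST, n_trees=10, seed=4)).fit()
    assert res.fittedvalues.shape == (t.n_compounds,)
    text = res.summary()
    assert "random_forest" in text and "OOB RMSE" in text
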