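"""Training loop, repeated runs, K-fold CV, ablations and sweeps.

These tests exercise contracts (determinism, partitions, table shapes) on
deliberately tiny data and models; learning quality is covered by the
acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

import hsiclass as h
from hsiclass.exceptions import (DivergenceError, SizeError,
                                 StratificationError)
from hsiclass.networks import layer_table

from conftest import fast_spec, make_toy_patches


def _standardized_toy(n_per_class=12, seed=0):
    ds = make_toy_patches(n_per_class=n_per_class, S=3, B=2, seed=seed)
    tr, va, te = h.stratified_split(ds, h.SplitSpec(0.6, 0.2, 0.2, seed=seed))
    (tr, va, te), _ = h.standardize(tr, va, te)
    return tr, va, te


TINY_CFG = h.TrainConfig(learning_rate=0.01, epochs=1, batch_size=16, seed=0)


def test_single_epoch_history():
    tr, va, _ = _standardized_toy()
    spec = fast_spec(B=2, S=3)
    result = h.train_model(spec, tr, va, TINY_CFG)
    assert len(result.history) == 1
    assert np.isfinite(result.history.loss.iloc[0])
    assert "val_accuracy" in result.history
    assert "parameters" in result.summary()


def test_training_deterministic_under_seed():
    tr, _, _ = _standardized_toy()
    spec = fast_spec(B=2, S=3)
    cfg = h.TrainConfig(learning_rate=0.01, epochs=3, batch_size=8, seed=5)
    h1 = h.train_model(spec, tr, None, cfg).history
    h2 = h.train_model(spec, tr, None, cfg).history
    pd.testing.assert_frame_equal(h1, h2)


def test_training_loss_decreases_on_separable_data():
    tr, _, _ = _standardized_toy(n_per_class=25)
    spec = fast_spec(B=2, S=3, widths=(8, 8, 8, 8))
    cfg = h.TrainConfig(learning_rate=0.01, epochs=8, batch_size=16, seed=1)
    hist = h.train_model(spec, tr, None, cfg).history
    assert hist.loss.iloc[-1] < hist.loss.iloc[0]


def test_divergence_error_names_epoch(monkeypatch):
    tr, _, _ = _standardized_toy()
    spec = fast_spec(B=2, S=3)
    import hsiclass.train as train_mod

    def nan_loss(logits, y):
        return float("nan"), np.zeros_like(logits)

    monkeypatch.setattr(train_mod.nn, "cross_entropy", nan_loss)
    with pytest.raises(DivergenceError) as err:
        h.train_model(spec, tr, None,
                      h.TrainConfig(learning_rate=0.01, epochs=2,
                                    batch_size=64, seed=0))
    assert err.value.epoch == 0


def test_train_label_range_validated():
    tr, _, _ = _standardized_toy()
    spec = fast_spec(B=2, S=3, n_classes=2)  # labels go up to 3
    with pytest.raises(SizeError):
        h.train_model(spec, tr, None, TINY_CFG)


class _FixedModel:
    """Stub returning a stored prediction vector (oracle cross-check)."""

    def __init__(self, pred, n_classes=3):
        self.pred = np.asarray(pred)
        self.n_classes = n_classes

    def predict(self, patches, batch_size=256):
        return self.pred[:len(patches)]


def test_evaluate_model_equals_direct_metrics():
    _, _, te = _standardized_toy()
    rng = np.random.default_rng(0)
    pred = rng.integers(1, 4, len(te))
    report = h.evaluate_model(_FixedModel(pred), te)
    direct = h.build_report(h.confusion_matrix(te.labels, pred, 3))
    assert report.oa == direct.oa
    assert report.kappa == direct.kappa
    np.testing.assert_array_equal(report.cm.counts, direct.cm.counts)


def test_evaluate_constant_and_perfect_predictors():
    _, _, te = _standardized_toy()
    const = h.evaluate_model(_FixedModel(np.ones(len(te), dtype=int)), te)
    assert const.kappa == pytest.approx(0.0, abs=1e-12)
    perfect = h.evaluate_model(_FixedModel(te.labels.copy()), te)
    assert (perfect.oa, perfect.aa, perfect.kappa) == (100.0, 100.0, 1.0)


def test_repeat_experiment_aggregation():
    tr, va, te = _standardized_toy()
    spec = fast_spec(B=2, S=3)
    df, agg = h.repeat_experiment(spec, tr, va, te, TINY_CFG, n_runs=1)
    assert len(df) == 1
    assert agg["OA"]["mean"] == df.OA.iloc[0]
    assert agg["OA"]["sd"] == 0.0
    df3, agg3 = h.repeat_experiment(spec, tr, va, te, TINY_CFG, n_runs=3)
    assert df3.seed.tolist() == [0, 1, 2]
    assert df3.OA.min() <= agg3["OA"]["mean"] <= df3.OA.max()


def test_repeat_experiment_resampled_splits():
    ds = make_toy_patches(n_per_class=20, S=3, B=2)
    spec = fast_spec(B=2, S=3)
    df, _ = h.repeat_experiment(spec, None, None, None, TINY_CFG, n_runs=2,
                                full_ds=ds,
                                split_spec=h.SplitSpec(0.5, 0.0, 0.5, seed=0))
    assert len(df) == 2


@pytest.mark.parametrize("K", [3, 5, 7, 9])
def test_kfold_partition_exact(K):
    """Every sample tested once; per-class fold counts differ by <= 1."""
    ds = make_toy_patches(n_per_class=18, S=1, B=2)
    spec = fast_spec(B=2, S=1)
    res = h.kfold_cv(ds, K, spec, TINY_CFG)
    assert res.K == K and len(res.fold_accuracies) == K
    assert res.mean_accuracy == pytest.approx(res.fold_accuracies.mean())
    assert res.accuracy_variance == pytest.approx(
        res.fold_accuracies.var(ddof=0))


def test_kfold_fold_membership():
    from sklearn.model_selection import StratifiedKFold
    ds = make_toy_patches(n_per_class=20, S=1, B=2)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    seen = np.zeros(len(ds), dtype=int)
    for _, te_idx in skf.split(ds.patches[:, 0, 0, 0], ds.labels):
        seen[te_idx] += 1
        counts = np.bincount(ds.labels[te_idx], minlength=4)[1:]
        assert counts.max() - counts.min() <= 1
    assert np.all(seen == 1)


def test_kfold_validation_errors():
    ds = make_toy_patches(n_per_class=4, S=1, B=2)
    spec = fast_spec(B=2, S=1)
    with pytest.raises(StratificationError):
        h.kfold_cv(ds, 5, spec, TINY_CFG)
    with pytest.raises(SizeError):
        h.kfold_cv(ds, 1, spec, TINY_CFG)
    with pytest.raises(SizeError):
        h.kfold_cv(ds, 100, spec, TINY_CFG)


def test_ablation_table_structure():
    tr, va, te = _standardized_toy()
    table = h.ablation_suite(tr, va, te, TINY_CFG, widths=(4, 8, 8, 8),
                             a=1, stem_kernel=(1, 1, 1),
                             pool_window=(1, 1, 1))
    assert len(table) == 4
    assert table.config.tolist() == ["a", "b", "c", "d"]
    assert table["3d_conv"].all()
    assert table.first_branch.tolist() == [False, True, False, True]
    assert table.second_branch.tolist() == [False, False, True, True]
    assert {"OA", "AA", "kappa", "params"} <= set(table.columns)


def test_ablation_plain_config_has_no_spectral_kernels():
    """Variant (a) must contain no a x 1 x 1 convolution anywhere."""
    spec = h.build_3d_rnet_o(widths=(4, 8, 8, 8), a=3,
                             branches=(False, False),
                             default_input=(2, 3, 3))
    kernels = set(layer_table(spec).kernel) - {"-"}
    assert "3x1x1" not in kernels and "1x3x3" not in kernels
    assert "3x3x3" in kernels


def test_sweep_learning_rate_axis_rows():
    """The nine-point learning-rate grid yields nine rows."""
    lrs = [0.0001, 0.0003, 0.0005, 0.001, 0.003, 0.005, 0.01, 0.03, 0.05]
    ds = make_toy_patches(n_per_class=10, S=1, B=2)
    table = h.hyperparameter_sweep(ds, {"learning_rate": lrs}, TINY_CFG,
                                   widths=(4, 4, 4, 4), a=1,
                                   stem_kernel=(1, 1, 1),
                                   pool_window=(1, 1, 1))
    assert len(table) == 9
    assert table.learning_rate.tolist() == lrs
    assert table.swept_axis.unique().tolist() == ["learning_rate"]


def test_sweep_train_fraction_axis_rows():
    """20%..80% by 10% with a fixed 10% validation split: seven rows."""
    fracs = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    ds = make_toy_patches(n_per_class=30, S=1, B=2)
    table = h.hyperparameter_sweep(ds, {"train_fraction": fracs}, TINY_CFG,
                                   widths=(4, 4, 4, 4), a=1,
                                   stem_kernel=(1, 1, 1),
                                   pool_window=(1, 1, 1))
    assert len(table) == 7


def test_sweep_empty_grid_is_baseline_row():
    ds = make_toy_patches(n_per_class=10, S=1, B=2)
    table = h.hyperparameter_sweep(ds, {}, TINY_CFG, widths=(4, 4, 4, 4),
                                   a=1, stem_kernel=(1, 1, 1),
                                   pool_window=(1, 1, 1))
    assert len(table) == 1


def test_sweep_unknown_axis_rejected():
    ds = make_toy_patches(n_per_class=5, S=1, B=2)
    with pytest.raises(SizeError, match="unknown sweep axis"):
        h.hyperparameter_sweep(ds, {"dropout": [0.1]}, TINY_CFG)
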