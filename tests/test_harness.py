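"""Metrics, split protocols, training loop, cross-dataset eval, ablation."""

import numpy as np
import pytest

from lungprior import fusion, harness
from lungprior.harness import (MetricsReport, ModelSpec, TrainConfig, kfold,
                               pixel_metrics, split_holdout)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_pixel_metrics_counting_oracle():
    pred = np.zeros((10, 10), bool)
    ref = np.zeros((10, 10), bool)
    pred.ravel()[:30] = True
    ref.ravel()[10:60] = True  # overlap = 20
    rep = pixel_metrics(pred, ref)
    assert rep.dice == pytest.approx(40 / 80)
    assert rep.iou == pytest.approx(20 / 60)
    assert rep.precision == pytest.approx(20 / 30)
    assert rep.recall == pytest.approx(20 / 50)
    assert rep.accuracy == pytest.approx((20 + 40) / 100)  # TN = 100-20-10-30


def test_pixel_metrics_degenerate_conventions():
    empty = np.zeros((5, 5), bool)
    full = np.ones((5, 5), bool)
    rep = pixel_metrics(empty, empty)
    assert rep.dice == rep.iou == rep.precision == rep.recall == 1.0
    assert pixel_metrics(full, full).dice == 1.0
    a = np.zeros((5, 5), bool)
    a[0, 0] = True
    b = np.zeros((5, 5), bool)
    b[4, 4] = True
    rep = pixel_metrics(a, b)
    assert rep.dice == rep.iou == 0.0
    with pytest.raises(ValueError):
        pixel_metrics(a, np.zeros((3, 3), bool))


def test_dice_iou_identity_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        pred = rng.random((16, 16)) > 0.5
        ref = rng.random((16, 16)) > 0.5
        rep = pixel_metrics(pred, ref)
        assert abs(rep.dice - 2 * rep.iou / (1 + rep.iou)) < 1e-12
        assert rep.iou <= rep.dice + 1e-15


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------

def test_holdout_sizes_and_determinism():
    ids = list(range(100))
    plan = split_holdout(ids, 0.2, seed=1)
    assert len(plan.test_ids) == 20 and len(plan.train_ids) == 80
    assert set(plan.test_ids) | set(plan.train_ids) == set(ids)
    assert not set(plan.test_ids) & set(plan.train_ids)
    plan2 = split_holdout(ids, 0.2, seed=1)
    assert plan.test_ids == plan2.test_ids
    others = [split_holdout(ids, 0.2, seed=s).test_ids for s in range(2, 7)]
    assert any(o != plan.test_ids for o in others)


def test_kfold_partition_sizes():
    folds = kfold(list(range(10)), k=5, seed=0)
    assert sorted(len(f) for f in folds) == [2] * 5
    folds11 = kfold(list(range(11)), k=5, seed=0)
    assert sorted(len(f) for f in folds11) == [2, 2, 2, 2, 3]
    flat = [i for f in folds11 for i in f]
    assert sorted(flat) == list(range(11))


def test_holdout_and_folds_never_leak():
    ids = [f"im{i}" for i in range(23)]
    plan = split_holdout(ids, 0.2, seed=5)
    folds = kfold(plan.train_ids, 5, seed=5)
    for fold in folds:
        assert not set(fold) & set(plan.test_ids)


def test_split_input_validation():
    with pytest.raises(ValueError):
        split_holdout([1, 2, 3], 0.2, 0)
    with pytest.raises(ValueError):
        kfold([1, 2, 3], 5, 0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _cfg(**kw):
    base = dict(learning_rate=1e-4, epochs=1, batch_size=2, input_size=64,
                seed=0, model=ModelSpec("unet", 2, 4))
    base.update(kw)
    return TrainConfig(**base)


def test_loss_decreases_after_first_steps(tiny_channel_dataset):
    cfg = _cfg(max_steps=10, learning_rate=1e-3)
    combo = fusion.enumerate_combinations()[-1]
    seg = harness.train_model(cfg, tiny_channel_dataset, combo)
    assert seg.loss_history[-1] < seg.loss_history[0]


def test_identity_at_init_reproduces_grayscale_baseline(tiny_channel_dataset):
    """Step-0 logits are combo-independent because the mixer passes only Io."""
    X, _ = harness._stack_dataset(tiny_channel_dataset, 64)
    combos = fusion.enumerate_combinations()
    logits = []
    for combo in (combos[0], combos[-1]):
        from lungprior.nn import FusionModel, Tensor
        model = FusionModel("unet", 2, 4, seed=0)
        sel = fusion.apply_selection(X, combo).astype(np.float32)
        logits.append(model.forward(Tensor(sel)).data)
    np.testing.assert_array_equal(logits[0], logits[1])


def test_training_is_seed_reproducible(tiny_channel_dataset):
    cfg = _cfg(max_steps=6)
    combo = fusion.enumerate_combinations()[3]
    a = harness.train_model(cfg, tiny_channel_dataset, combo)
    b = harness.train_model(cfg, tiny_channel_dataset, combo)
    assert a.loss_history == b.loss_history
    for pa, pb in zip(a.model.parameters(), b.model.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)


def test_train_rejects_empty_dataset():
    with pytest.raises(ValueError):
        harness.train_model(_cfg(), [], fusion.enumerate_combinations()[0])


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def test_cross_dataset_eval_populates_all_metrics(tiny_channel_dataset):
    cfg = _cfg(max_steps=5)
    seg = harness.train_model(cfg, tiny_channel_dataset[:2],
                              fusion.enumerate_combinations()[-1])
    reports = harness.cross_dataset_eval(
        seg, {"A": tiny_channel_dataset[:2], "B": tiny_channel_dataset[2:]})
    assert set(reports) == {"A", "B"}
    for rep in reports.values():
        d = rep.as_dict()
        assert all(np.isfinite(d[k]) for k in
                   ("dice", "iou", "accuracy", "precision", "recall"))
    with pytest.raises(ValueError):
        harness.cross_dataset_eval(seg, {"empty": []})


def test_ablation_sweep_table_contract(tiny_channel_dataset):
    cfg = _cfg(max_steps=1, model=ModelSpec("unet", 2, 2), input_size=64)
    table = harness.ablation_sweep(cfg, tiny_channel_dataset[:2])
    assert len(table) == 16
    assert list(table["combo"])[0] == "Io"
    assert table["delta_dice"].iloc[0] == 0.0
    assert table["delta_iou"].iloc[0] == 0.0
    assert len(set(table["combo"])) == 16
    table2 = harness.ablation_sweep(cfg, tiny_channel_dataset[:2])
    assert np.allclose(table["dice"], table2["dice"])
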