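"""Loss decomposition, augmentation and the training loops."""

import numpy as np
import pytest

from cellseg.train import (TrainConfig, apply_rotation_scale, augment, finetune,
                           loss, loss_and_grad, soft_jaccard, train)
from cellseg.unet import UNetConfig, build_unet, init_weights, softmax
from tests.conftest import loss_oracle


def one_hot_prob(true, num_classes=3, eps=1e-9):
    p = np.full((num_classes,) + true.shape, eps)
    for c in range(num_classes):
        p[c][true == c] = 1.0 - (num_classes - 1) * eps
    return p


# ---------------------------------------------------------------------------
# soft Jaccard and combined loss


def test_perfect_prediction_has_unit_jaccard_and_near_zero_loss(rng):
    true = rng.integers(0, 3, (32, 32))
    prob = one_hot_prob(true)
    j = soft_jaccard(prob, true)
    assert j > 1 - 1e-3  # eps-smoothing keeps it just below 1 on 32x32
    lv = loss(prob, true)
    assert lv.total < 1e-3
    assert lv.cross_entropy < 1e-6


def test_imperfect_prediction_has_positive_loss(rng):
    true = rng.integers(0, 3, (16, 16))
    prob = np.full((3, 16, 16), 1 / 3)
    lv = loss(prob, true)
    assert lv.total > 0
    assert lv.jaccard < 1
    assert lv.total == pytest.approx(lv.cross_entropy - np.log(lv.jaccard), abs=1e-12)


def test_loss_matches_direct_formula_oracle(rng):
    for _ in range(5):
        logits = rng.normal(0, 1, (3, 6, 6))
        prob = softmax(logits, axis=0)
        true = rng.integers(0, 3, (6, 6))
        lv = loss(prob, true)
        want_l, want_h, want_j = loss_oracle(prob, true)
        assert lv.total == pytest.approx(want_l, abs=1e-9)
        assert lv.cross_entropy == pytest.approx(want_h, abs=1e-9)
        assert lv.jaccard == pytest.approx(want_j, abs=1e-9)


def test_uniform_prediction_jaccard_matches_summation_oracle():
    true = np.zeros((8, 8), dtype=np.uint8)
    true[:4] = 1  # half class 1
    prob = np.full((3, 8, 8), 1 / 3)
    _, _, want_j = loss_oracle(prob, true)
    assert soft_jaccard(prob, true) == pytest.approx(want_j, abs=1e-12)


def test_jaccard_increases_as_mass_moves_to_true_class():
    true = np.zeros((4, 4), dtype=np.uint8)
    true[1, 1] = 1
    js = []
    for w in (0.4, 0.6, 0.8, 0.95):
        prob = np.full((3, 4, 4), 1 / 3)
        prob[:, 1, 1] = [(1 - w) / 2, w, (1 - w) / 2]
        js.append(soft_jaccard(prob, true))
    assert all(a < b for a, b in zip(js, js[1:]))


def test_loss_strictly_decreases_in_one_pixel_example():
    true = np.array([[1]], dtype=np.uint8)
    losses = []
    for w in (0.34, 0.5, 0.7, 0.9, 0.99):
        prob = np.array([(1 - w) / 2, w, (1 - w) / 2]).reshape(3, 1, 1)
        losses.append(loss(prob, true).total)
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_loss_gradient_matches_finite_differences(rng):
    logits = rng.normal(0, 1, (1, 5, 5, 3))
    true = rng.integers(0, 3, (1, 5, 5))
    lv, g = loss_and_grad(logits, true)
    assert lv.total == pytest.approx(lv.cross_entropy - np.log(lv.jaccard), abs=1e-9)
    for _ in range(10):
        idx = tuple(rng.integers(0, s) for s in logits.shape)
        lp = logits.copy()
        lp[idx] += 1e-6
        lm = logits.copy()
        lm[idx] -= 1e-6
        num = (loss_and_grad(lp, true)[0].total
               - loss_and_grad(lm, true)[0].total) / 2e-6
        assert num == pytest.approx(float(g[idx]), abs=1e-5)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        soft_jaccard(np.full((3, 4, 4), 1 / 3), np.zeros((5, 5), dtype=np.uint8))


# ---------------------------------------------------------------------------
# augmentation


def aug_config(**kw):
    kw.setdefault("rotation_deg", 30.0)
    kw.setdefault("scale_range", (0.9, 1.1))
    kw.setdefault("gray_shift", 20.0)
    return TrainConfig(**kw)


def test_zero_range_augmentation_is_identity(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    mask = rng.integers(0, 3, (16, 16), dtype=np.uint8)
    cfg = aug_config(rotation_deg=0.0, scale_range=(1.0, 1.0), gray_shift=0.0)
    out_img, out_mask = augment(img, mask, cfg, np.random.default_rng(0))
    assert np.array_equal(out_img, img)
    assert np.array_equal(out_mask, mask)


def test_augmented_mask_contains_only_original_classes(rng):
    img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    mask = rng.integers(0, 3, (32, 32), dtype=np.uint8)
    cfg = aug_config()
    for i in range(10):
        _, out_mask = augment(img, mask, cfg, np.random.default_rng(i))
        assert set(np.unique(out_mask)) <= set(np.unique(mask))
        assert out_mask.dtype == np.uint8


def test_quarter_turn_matches_index_remap_oracle(rng):
    """Rotation by exactly 90 degrees on an even-sized grid lands on
    pixel centers, so the nearest-neighbor mask equals a quarter turn by
    index remapping (positive theta turns clockwise in (row, col) view)."""
    mask = rng.integers(0, 3, (32, 32), dtype=np.uint8)
    img = (mask * 80).astype(np.uint8)
    out_img, out_mask = apply_rotation_scale(img, mask, np.pi / 2, 1.0)
    assert np.array_equal(out_mask, np.rot90(mask, k=-1))
    # bilinear image lands within float interpolation slack of the remap
    assert np.allclose(out_img, np.rot90(img, k=-1).astype(np.float32), atol=0.51)


def test_augmentation_is_reproducible_under_seed(rng):
    img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
    mask = rng.integers(0, 3, (16, 16), dtype=np.uint8)
    cfg = aug_config()
    a = augment(img, mask, cfg, np.random.default_rng(42))
    b = augment(img, mask, cfg, np.random.default_rng(42))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# training loops


def tiny_model(seed=0):
    return init_weights(build_unet(
        UNetConfig(in_channels=1, num_classes=3, depth=2, widths=(4, 8, 12))), seed)


def blob_pairs(rng, n, size=16):
    pairs = []
    for _ in range(n):
        mask = np.zeros((size, size), dtype=np.uint8)
        r, c = rng.integers(3, size - 5, 2)
        cls = int(rng.integers(1, 3))
        mask[r:r + 4, c:c + 4] = cls
        img = np.full((size, size), 180, dtype=np.uint8)
        img[mask > 0] = 90 if cls == 1 else 120
        pairs.append((img, mask))
    return pairs


def test_one_epoch_logs_once_and_checkpoints(tmp_path, rng):
    pairs = blob_pairs(rng, 4)
    model = tiny_model()
    cfg = TrainConfig(epochs=1, seed=0, augment=False)
    res = train(model, pairs, cfg, val_data=pairs,
                log_path=tmp_path / "log.csv", checkpoint_path=tmp_path / "m.npz")
    assert len(res.epochs) == 1
    assert (tmp_path / "log.csv").exists()
    assert (tmp_path / "m.npz").exists()
    assert res.best_val_miou is not None
    # every logged step obeys the loss decomposition exactly
    for step in res.steps:
        assert step.total == pytest.approx(
            step.cross_entropy - np.log(step.jaccard), abs=1e-9)


def test_training_reduces_loss(rng):
    pairs = blob_pairs(rng, 8)
    model = tiny_model()
    cfg = TrainConfig(epochs=6, seed=1, augment=False)
    res = train(model, pairs, cfg)
    assert res.epochs[-1].loss < res.epochs[0].loss


def test_training_is_deterministic_under_seed(rng):
    pairs = blob_pairs(rng, 4)
    cfg = TrainConfig(epochs=2, seed=3)
    m1 = tiny_model(5)
    train(m1, pairs, cfg)
    m2 = tiny_model(5)
    train(m2, pairs, cfg)
    for a, b in zip(m1.get_weights(), m2.get_weights()):
        assert np.array_equal(a, b)


def test_empty_split_and_shape_mismatch_are_rejected(rng):
    model = tiny_model()
    with pytest.raises(ValueError):
        train(model, [], TrainConfig(epochs=1))
    bad = [(np.zeros((16, 16), dtype=np.uint8), np.zeros((8, 8), dtype=np.uint8))]
    with pytest.raises(ValueError):
        train(model, bad, TrainConfig(epochs=1))


def test_zero_epoch_finetune_leaves_weights_unchanged(rng):
    model = tiny_model(9)
    before = model.get_weights()
    res = finetune(model, blob_pairs(rng, 2), TrainConfig.transfer(epochs=0))
    assert res.epochs == []
    for a, b in zip(before, model.get_weights()):
        assert np.array_equal(a, b)


def test_finetune_defaults_to_half_learning_rate():
    cfg = TrainConfig.transfer()
    assert cfg.learning_rate == pytest.approx(5e-4)
    assert cfg.phase == "transfer"
    base = TrainConfig()
    assert base.learning_rate == pytest.approx(1e-3)
    assert base.batch_size == 4
    assert (base.beta1, base.beta2) == (0.9, 0.999)
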