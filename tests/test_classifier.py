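"""CNN architectures, training loop, channel inflation, augmentation."""

import numpy as np
import pytest

from polamat.classifier import (
    Model,
    TrainConfig,
    _bce_with_logits,
    augment,
    build_cnn,
    evaluate,
    he_std,
    inflate_first_layer,
    train,
)
from polamat.dataset import ModelInput


def _toy_inputs(n_per_class=4, size=16, channels=36, seed=0):
    """Linearly separable 36-channel toy inputs: class shifts channel means."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            base = 0.3 + 0.4 * label
            t = np.clip(base + 0.05 * rng.standard_normal((size, size, channels)), 0, 1)
            xs.append(ModelInput(tensor=t, class_label="cancer" if label else "normal"))
            ys.append(label)
    return xs, np.array(ys)


# ---------------------------------------------------------------------------
# Architecture
# ---------------------------------------------------------------------------

def test_cnn_manifest_head_and_input_contract():
    m = build_cnn("cnn", widths=(128, 256, 512))
    man = m.manifest()
    convs = [l for l in man["layers"] if l["type"] == "Conv2D"]
    assert convs[0]["in_ch"] == 36 and convs[0]["out_ch"] == 128
    dense = [l for l in man["layers"] if l["type"] == "Dense"]
    assert [(d["n_in"], d["n_out"]) for d in dense] == [(512, 256), (256, 1)]
    drops = [l for l in man["layers"] if l["type"] == "Dropout"]
    assert all(d["p"] == 0.2 for d in drops)


def test_cnn2_manifest_has_no_dense_layers_and_uses_strides():
    m = build_cnn("cnn_2", widths=(128, 256, 512))
    man = m.manifest()
    assert not any(l["type"] == "Dense" for l in man["layers"])
    assert not any(l["type"] == "MaxPool2D" for l in man["layers"])
    strides = [l["stride"] for l in man["layers"] if l["type"] == "Conv2D"]
    assert 2 in strides
    kernels = [l["kernel"] for l in man["layers"] if l["type"] == "Conv2D"]
    assert 1 in kernels  # 1x1 head replacing the FC layers


def test_invalid_variant_rejected():
    with pytest.raises(ValueError):
        build_cnn("vgg")


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def test_gradient_matches_finite_differences():
    m = build_cnn("cnn", in_channels=2, widths=(3, 4), head_width=5, dropout=0.0, seed=0)
    x = np.random.default_rng(1).random((2, 2, 8, 8))
    y = np.array([0.0, 1.0])
    _, gz = _bce_with_logits(m.forward(x, train=True), y)
    m.backward(gz)
    layer = m.layers[0]
    eps = 1e-6
    w = layer.params["w"]
    analytic = layer.grads["w"][0, 0, 1, 1]
    w[0, 0, 1, 1] += eps
    up, _ = _bce_with_logits(m.forward(x, train=True), y)
    w[0, 0, 1, 1] -= 2 * eps
    dn, _ = _bce_with_logits(m.forward(x, train=True), y)
    w[0, 0, 1, 1] += eps
    assert analytic == pytest.approx((up - dn) / (2 * eps), rel=1e-4)


def test_single_gradient_step_reduces_batch_loss():
    from polamat.classifier import _AdamW

    m = build_cnn("cnn", in_channels=4, widths=(4, 8), head_width=8, dropout=0.0, seed=2)
    rng = np.random.default_rng(3)
    x = rng.random((4, 4, 12, 12))
    y = np.array([0.0, 1.0, 0.0, 1.0])
    opt = _AdamW(m, lr=1e-4, weight_decay=0.0)
    before, gz = _bce_with_logits(m.forward(x, train=True), y)
    m.backward(gz)
    opt.step()
    after, _ = _bce_with_logits(m.forward(x, train=True), y)
    assert after < before


def test_training_overfits_separable_toy_problem():
    xs, ys = _toy_inputs(n_per_class=4, size=12)
    m = build_cnn("cnn", widths=(4, 8), head_width=8, seed=0)
    cfg = TrainConfig(batch_size=4, max_epochs=60, learning_rate=0.01, seed=0)
    hist = train(m, xs, ys, xs, ys, cfg)
    assert hist["train_acc"][-1] == 1.0
    assert hist["epochs_run"] <= 60


def test_training_history_deterministic_given_seed():
    xs, ys = _toy_inputs(n_per_class=2, size=8)
    hists = []
    for _ in range(2):
        m = build_cnn("cnn", widths=(4,), head_width=4, seed=1)
        cfg = TrainConfig(batch_size=4, max_epochs=5, learning_rate=0.005, seed=1)
        hists.append(train(m, xs, ys, xs, ys, cfg))
    assert hists[0]["train_loss"] == hists[1]["train_loss"]
    assert hists[0]["val_loss"] == hists[1]["val_loss"]


def test_training_rejects_degenerate_sets():
    xs, ys = _toy_inputs(n_per_class=2, size=8)
    m = build_cnn("cnn", widths=(4,), head_width=4, seed=0)
    with pytest.raises(ValueError, match="both classes"):
        train(m, xs[:2], np.zeros(2), xs, ys, TrainConfig(max_epochs=1))
    with pytest.raises(ValueError, match="validation"):
        train(m, xs, ys, [], [], TrainConfig(max_epochs=1))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def test_evaluate_counts_and_order_invariance():
    xs, ys = _toy_inputs(n_per_class=3, size=8)
    m = build_cnn("cnn", widths=(4,), head_width=4, seed=0)
    counts, metrics, preds = evaluate(m, xs, ys)
    assert counts.TP + counts.FN == int(ys.sum())
    assert counts.TN + counts.FP == int((1 - ys).sum())
    perm = np.random.default_rng(0).permutation(len(xs))
    counts2, _, _ = evaluate(m, [xs[i] for i in perm], ys[perm])
    assert counts == counts2


def test_model_outputs_are_probabilities():
    xs, _ = _toy_inputs(n_per_class=2, size=8)
    m = build_cnn("cnn_2", widths=(4,), head_width=4, seed=0)
    from polamat.classifier import _as_nchw

    probs = m.predict_proba(_as_nchw(xs))
    assert np.all(probs > 0.0) and np.all(probs < 1.0)


def test_all_positive_predictor_metrics():
    from polamat.stats import ConfusionCounts, classification_metrics

    m = classification_metrics(ConfusionCounts(TP=5, TN=0, FP=5, FN=0))
    assert m["recall"] == 1.0 and m["precision"] == 0.5


# ---------------------------------------------------------------------------
# Channel inflation
# ---------------------------------------------------------------------------

def test_inflate_copies_first_three_channels_bit_exact(rng):
    w3 = rng.normal(size=(8, 3, 3, 3))
    w36 = inflate_first_layer(w3, 36, seed=0)
    assert w36.shape == (8, 36, 3, 3)
    assert np.array_equal(w36[:, :3], w3)


def test_inflate_deterministic_and_he_scaled(rng):
    w3 = rng.normal(size=(32, 3, 3, 3))
    a = inflate_first_layer(w3, 36, seed=9)
    b = inflate_first_layer(w3, 36, seed=9)
    assert np.array_equal(a, b)
    target_var = he_std(36 * 9) ** 2
    sample_var = a[:, 3:].var()
    assert abs(sample_var - target_var) / target_var < 0.2


def test_inflate_rejects_wrong_channel_count(rng):
    with pytest.raises(ValueError):
        inflate_first_layer(rng.normal(size=(8, 4, 3, 3)), 36)


def test_inflated_layer_preserves_three_channel_response(rng):
    from polamat.classifier import _Conv2D

    w3 = rng.normal(size=(6, 3, 3, 3))
    w36 = inflate_first_layer(w3, 36, seed=1)
    x3 = rng.random((2, 3, 10, 10))
    x36 = np.zeros((2, 36, 10, 10))
    x36[:, :3] = x3

    conv3 = _Conv2D(3, 6, k=3)
    conv3.params["w"] = w3
    conv3.params["b"] = np.zeros(6)
    conv36 = _Conv2D(36, 6, k=3)
    conv36.params["w"] = w36
    conv36.params["b"] = np.zeros(6)
    out3 = conv3.forward(x3, train=False)
    out36 = conv36.forward(x36, train=False)
    assert np.max(np.abs(out3 - out36)) < 1e-6


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_rotation_by_zero_is_identity(rng):
    t = rng.random((16, 16, 36))
    assert np.array_equal(augment(t, "rotation", angle=0.0), np.clip(t, 0, 1))


@pytest.mark.parametrize("op", ["rotation", "clahe", "blur"])
def test_augment_preserves_shape_and_range(op, rng):
    t = rng.random((16, 16, 36))
    out = augment(t, op, seed=4)
    assert out.shape == t.shape
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_unknown_augmentation_rejected(rng):
    with pytest.raises(ValueError):
        augment(rng.random((8, 8, 36)), "mixup")


def test_rotation_applied_jointly_across_channels():
    # a constant-gradient stack: if channels rotated independently with
    # different angles they would decorrelate; joint rotation keeps every
    # channel identical, i.e. zero cross-channel shift
    g = np.linspace(0, 1, 24)
    t = np.broadcast_to(g[:, None, None], (24, 24, 36)).copy()
    out = augment(t, "rotation", angle=30.0)
    for c in range(1, 36):
        assert np.array_equal(out[..., c], out[..., 0])
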