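"""Classifier: shape inference, initialization, gradients, training behavior."""

import numpy as np
import pandas as pd
import pytest

from mammocalc.cnn import (CNNClassifier, CNNConfig, TrainConfig, build_model,
                           infer_shapes, predict, train)


# ---------------------------------------------------------------------------
# shape inference

def test_default_architecture_shapes():
    layers, flatten = infer_shapes(CNNConfig())
    d = {name: (r, c, ch) for name, r, c, ch in layers}
    assert d["conv1"] == (506, 506, 16)
    assert d["pool1"] == (253, 253, 16)
    assert d["conv2"] == (251, 251, 16)
    assert d["pool2"] == (125, 125, 16)
    assert flatten == 250_000


def test_tiny_architecture_shapes():
    layers, flatten = infer_shapes(CNNConfig(input_shape=(10, 10, 1),
                                             conv_blocks=((1, 3, 2),)))
    d = {name: (r, c, ch) for name, r, c, ch in layers}
    assert d["conv1"] == (8, 8, 1)
    assert d["pool1"] == (4, 4, 1)
    assert flatten == 16


def test_shape_inference_matches_arithmetic_oracle(rng):
    """Independent layer-by-layer arithmetic over random feasible configs."""
    for _ in range(100):
        side = int(rng.integers(20, 200))
        n_blocks = int(rng.integers(1, 4))
        blocks = []
        for _b in range(n_blocks):
            blocks.append((int(rng.integers(1, 32)),
                           int(rng.choice([3, 5])),
                           int(rng.choice([2, 3]))))
        cfg = CNNConfig(input_shape=(side, side, int(rng.integers(1, 9))),
                        conv_blocks=tuple(blocks))
        # oracle: explicit recurrence
        s = side
        feasible = True
        flatten_expected = None
        for f, k, p in blocks:
            s = s - (k - 1)
            if s <= 0:
                feasible = False
                break
            s = s // p
            if s <= 0:
                feasible = False
                break
        if feasible:
            flatten_expected = s * s * blocks[-1][0]
            _, flatten = infer_shapes(cfg)
            assert flatten == flatten_expected
        else:
            with pytest.raises(ValueError):
                infer_shapes(cfg)


def test_infeasible_config_raises():
    with pytest.raises(ValueError):
        infer_shapes(CNNConfig(input_shape=(4, 4, 1),
                               conv_blocks=((8, 3, 2), (8, 3, 2))))


# ---------------------------------------------------------------------------
# model construction

TINY = CNNConfig(input_shape=(16, 16, 2), conv_blocks=((4, 3, 2),), dense_units=6)


def test_build_deterministic(rng):
    x = rng.random((2, 16, 16, 2))
    p1, _ = build_model(TINY, seed=7).forward(x)
    p2, _ = build_model(TINY, seed=7).forward(x)
    np.testing.assert_array_equal(p1, p2)
    p3, _ = build_model(TINY, seed=8).forward(x)
    assert not np.array_equal(p1, p3)


def test_forward_probability_contract():
    model = build_model(TINY, seed=0)
    p, _ = model.forward(np.zeros((1, 16, 16, 2)))
    assert np.isfinite(p).all() and 0.0 <= p[0] <= 1.0


def test_parameter_count_closed_form():
    model = build_model(TINY, seed=0)
    # conv: (3*3*2)*4+4 ; dense: flatten*6+6 ; out: 6*1+1
    _, flatten = infer_shapes(TINY)
    expected = (3 * 3 * 2) * 4 + 4 + flatten * 6 + 6 + 6 + 1
    assert model.n_parameters() == expected


def test_gradients_match_finite_differences(rng):
    cfg = CNNConfig(input_shape=(10, 10, 2), conv_blocks=((3, 3, 2),), dense_units=4)
    model = build_model(cfg, seed=1)
    x = rng.random((3, 10, 10, 2))
    y = np.array([0.0, 1.0, 1.0])
    _, _, _, grads = model.loss_and_grads(x, y, l2=0.01)
    rng2 = np.random.default_rng(0)
    for key, g in grads.items():
        flat_idx = rng2.choice(model.params[key].size,
                               size=min(6, model.params[key].size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, model.params[key].shape)
            eps = 1e-6
            model.params[key][idx] += eps
            lp, _, _, _ = model.loss_and_grads(x, y, l2=0.01)
            model.params[key][idx] -= 2 * eps
            lm, _, _, _ = model.loss_and_grads(x, y, l2=0.01)
            model.params[key][idx] += eps
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-7)


def test_l2_penalty_increases_loss(rng):
    model = build_model(TINY, seed=2)
    x = rng.random((4, 16, 16, 2))
    y = np.array([0.0, 1.0, 0.0, 1.0])
    loss_l2, data_loss, _, _ = model.loss_and_grads(x, y, l2=0.05)
    loss_plain, _, _, _ = model.loss_and_grads(x, y, l2=0.0)
    assert loss_l2 > loss_plain
    assert loss_plain == pytest.approx(data_loss)


# ---------------------------------------------------------------------------
# training

def _easy_data(n, rng, side=16):
    """Separable toy task: positives carry a bright central blob."""
    X = rng.random((n, side, side, 2)) * 0.3
    y = np.arange(n) % 2
    for i in range(n):
        if y[i]:
            X[i, 6:10, 6:10, :] += 1.0
    return X, y.astype(float)


def test_training_reduces_loss(rng):
    X, y = _easy_data(16, rng)
    model = build_model(TINY, seed=0)
    hist = train(model, X, y, tcfg=TrainConfig(learning_rate=1e-3, epochs=10,
                                               batch_size=4, dropout=0.0,
                                               l2=0.0, seed=0))
    assert len(hist) == 10
    assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]


def test_training_deterministic(rng):
    X, y = _easy_data(12, rng)
    tcfg = TrainConfig(learning_rate=1e-3, epochs=4, batch_size=4,
                       dropout=0.2, l2=0.01, seed=5)
    h1 = train(build_model(TINY, seed=3), X, y, tcfg=TrainConfig(**vars(tcfg)))
    h2 = train(build_model(TINY, seed=3), X, y, tcfg=TrainConfig(**vars(tcfg)))
    pd.testing.assert_frame_equal(h1, h2)


def test_single_class_rejected(rng):
    X = rng.random((6, 16, 16, 2))
    with pytest.raises(ValueError, match="single class"):
        train(build_model(TINY, seed=0), X, np.ones(6))


def test_permuted_labels_yield_chance_accuracy(rng):
    """Null-label control: with labels shuffled independently of the images,
    held-out accuracy stays within the binomial noise band around 0.5."""
    X, y = _easy_data(32, rng)
    y_perm = rng.permutation(y)
    Xv, yv = _easy_data(32, rng)
    yv_perm = rng.permutation(yv)
    model = build_model(TINY, seed=1)
    hist = train(model, X, y_perm, Xv, yv_perm,
                 tcfg=TrainConfig(learning_rate=1e-3, epochs=8, batch_size=8,
                                  dropout=0.0, l2=0.0, seed=1))
    acc = hist["val_acc"].iloc[-1]
    # 95% band for n=32 around 0.5 is roughly +/- 0.17; allow a full margin
    assert 0.2 <= acc <= 0.8


def test_best_checkpoint_restored(rng):
    X, y = _easy_data(16, rng)
    Xv, yv = _easy_data(8, rng)
    model = build_model(TINY, seed=0)
    hist = train(model, X, y, Xv, yv,
                 tcfg=TrainConfig(learning_rate=1e-3, epochs=6, batch_size=4,
                                  dropout=0.0, l2=0.0, seed=0))
    vprob, _ = model.forward(Xv)
    eps = 1e-12
    vloss = float(-np.mean(yv * np.log(vprob + eps) + (1 - yv) * np.log(1 - vprob + eps)))
    assert vloss == pytest.approx(hist["val_loss"].min(), rel=1e-9)


# ---------------------------------------------------------------------------
# prediction

def test_predict_threshold_strict():
    model = build_model(TINY, seed=0)
    stack = np.zeros((16, 16, 2))
    res = predict(model, stack)
    # exactly at the threshold the decision must be negative (strict '>')
    at_threshold = predict(model, stack, threshold=res.probability)
    assert at_threshold.label == 0
    below = predict(model, stack, threshold=res.probability - 1e-9)
    assert below.label == 1


def test_positive_rate_monotone_in_threshold(rng):
    model = build_model(TINY, seed=4)
    X = rng.random((16, 16, 16, 2))
    probs, _ = model.forward(X)
    rates = [np.mean(probs > t) for t in (0.3, 0.5, 0.7)]
    assert rates[0] >= rates[1] >= rates[2]


def test_classifier_estimator_api(rng):
    X, y = _easy_data(12, rng)
    clf = CNNClassifier(conv_blocks=((4, 3, 2),), dense_units=6,
                        learning_rate=1e-3, epochs=3, batch_size=4,
                        dropout=0.0, l2=0.0, random_state=0)
    assert clf.get_params()["epochs"] == 3
    clf.fit(X, y)
    proba = clf.predict_proba(X)
    assert proba.shape == (12, 2)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert set(np.unique(clf.predict(X))) <= {0, 1}
    from sklearn.base import clone
    clone(clf)   # sklearn-compatible construction
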