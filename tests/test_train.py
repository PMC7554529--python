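"""Optimizer update rules against hand-iterated oracles; training loop."""

import numpy as np
import pytest

from midecode import (AdamState, SGDMState, adam_step, cross_entropy_loss,
                      fit, sgdm_step)
from midecode.cnn import (ArchitectureSpec, AvgPoolSpec, ConvBlockSpec,
                          MegaBlock)
from midecode.train import TrainConfig, TrainingDiverged, _epoch_lr


# -- cross-entropy -----------------------------------------------------------

def test_perfect_prediction_zero_loss():
    p = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert cross_entropy_loss(p, p) == 0.0


def test_uniform_prediction_ln2():
    p = np.full((4, 2), 0.5)
    t = np.eye(2)[[0, 1, 0, 1]]
    assert cross_entropy_loss(p, t) == pytest.approx(np.log(2), abs=1e-12)


def test_hand_computed_three_sample_batch():
    p = np.array([[0.7, 0.3], [0.2, 0.8], [0.5, 0.5]])
    t = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    expected = -(np.log(0.7) + np.log(0.8) + np.log(0.5)) / 3
    assert cross_entropy_loss(p, t) == pytest.approx(expected, abs=1e-12)


def test_unnormalized_prediction_rejected():
    with pytest.raises(ValueError, match="normalized"):
        cross_entropy_loss(np.array([[0.9, 0.3]]), np.array([[1.0, 0.0]]))


# -- SGDM --------------------------------------------------------------------

def test_sgdm_hand_iteration():
    # theta0=1, g=2 const, eta=0.1, mu=0.5:
    # v1 = -0.2, theta1 = 0.8; v2 = 0.5*(-0.2) - 0.2 = -0.3, theta2 = 0.5
    state = SGDMState(learning_rate=0.1, momentum=0.5)
    theta, state = sgdm_step(1.0, 2.0, state)
    assert theta == pytest.approx(0.8, abs=1e-12)
    theta, state = sgdm_step(theta, 2.0, state)
    assert theta == pytest.approx(0.5, abs=1e-12)
    assert state.velocity[0] == pytest.approx(-0.3, abs=1e-12)


def test_sgdm_momentum_free_is_plain_sgd(rng):
    theta = rng.standard_normal(5)
    g = rng.standard_normal(5)
    new, _ = sgdm_step(theta, g, SGDMState(learning_rate=0.05, momentum=0.0))
    np.testing.assert_allclose(new, theta - 0.05 * g, atol=1e-15)


def test_sgdm_velocity_decays_by_mu():
    state = SGDMState(learning_rate=0.1, momentum=0.7)
    theta, state = sgdm_step(0.0, 1.0, state)
    v1 = state.velocity[0].copy()
    for _ in range(2):
        theta, state = sgdm_step(theta, 0.0, state)
        assert state.velocity[0] == pytest.approx(0.7 * v1, abs=1e-15)
        v1 = state.velocity[0]


def test_sgdm_shape_mismatch():
    with pytest.raises(ValueError, match="shapes"):
        sgdm_step(np.zeros(3), np.zeros(4), SGDMState(0.1))
    with pytest.raises(ValueError, match="momentum"):
        SGDMState(0.1, momentum=1.0)


# -- Adam --------------------------------------------------------------------

def test_adam_first_step_magnitude():
    # at t=1 the bias-corrected ratio is g/|g|, so with eps added to the
    # corrected sqrt(vhat) the closed form is |dtheta| = eta*|g|/(|g|+eps),
    # i.e. |dtheta| ~ eta for any g != 0
    eta, g, eps = 0.01, 3.0, 1e-8
    theta, _ = adam_step(0.0, g, AdamState(learning_rate=eta))
    expected = eta * g / (g + eps)
    assert -theta == pytest.approx(expected, abs=1e-15)
    assert abs(theta) == pytest.approx(eta, rel=1e-6)
    # the approximation holds for tiny gradients too
    theta, _ = adam_step(0.0, 1e-6, AdamState(learning_rate=eta))
    assert abs(theta) == pytest.approx(eta, rel=1e-2)


def test_adam_zero_gradient_no_motion():
    state = AdamState(learning_rate=0.1)
    theta = 1.5
    for _ in range(3):
        theta, state = adam_step(theta, 0.0, state)
    assert theta == 1.5


def test_adam_three_steps_hand_tabulated():
    """Minimize theta^2/2 (g = theta) from theta=1: compare against an
    independent scalar iteration of the three update equations."""
    eta, b1, b2, eps = 0.1, 0.9, 0.999, 1e-8
    # oracle: explicit loop
    theta_o, m, v = 1.0, 0.0, 0.0
    oracle = []
    for t in range(1, 4):
        g = theta_o
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1 ** t)
        vhat = v / (1 - b2 ** t)
        theta_o = theta_o - eta * mhat / (np.sqrt(vhat) + eps)
        oracle.append(theta_o)
    # implementation
    theta, state = 1.0, AdamState(learning_rate=eta)
    for t in range(3):
        theta, state = adam_step(theta, theta, state)
        assert theta == pytest.approx(oracle[t], abs=1e-12)


# -- fit ---------------------------------------------------------------------

def tiny_arch():
    return ArchitectureSpec(
        stages=(MegaBlock(ConvBlockSpec(4, (3, 3), l2=0.0)),
                AvgPoolSpec((8, 8), (1, 1))),
        input_shape=(8, 8, 2))


def separable_data(n_per_class=40):
    # two constant patterns that differ in which channel is active, so the
    # classes survive the global average pooling
    a = np.zeros((n_per_class, 8, 8, 2))
    a[..., 0] = 1.0
    b = np.zeros((n_per_class, 8, 8, 2))
    b[..., 1] = 1.0
    x = np.concatenate([a, b])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


def test_fit_separable_patterns_reach_full_accuracy():
    x, y = separable_data()
    config = TrainConfig(optimizer="adam", epochs=6, batch_size=16,
                         learning_rate=0.01, validation_size=0, seed=0,
                         dtype="float64")
    model, history = fit(tiny_arch(), x, y, config)
    losses = history["train_loss"]
    assert all(b < a for a, b in zip(losses[:5], losses[1:6]))
    pred = model.predict_proba(x).argmax(axis=1)
    assert np.mean(pred == y) == 1.0


def test_fit_deterministic_under_seed():
    x, y = separable_data(10)
    config = TrainConfig(optimizer="sgdm", epochs=3, batch_size=8,
                         learning_rate=0.05, seed=123, dtype="float64")
    _, h1 = fit(tiny_arch(), x, y, config)
    _, h2 = fit(tiny_arch(), x, y, config)
    assert h1["train_loss"] == h2["train_loss"]
    assert h1["val_loss"] == h2["val_loss"]


def test_history_length_and_lr_schedule():
    x, y = separable_data(10)
    config = TrainConfig(optimizer="adam", epochs=7, batch_size=8,
                         learning_rate=0.01, lr_drop_factor=0.1,
                         lr_drop_period=3, seed=0)
    _, history = fit(tiny_arch(), x, y, config)
    assert len(history["train_loss"]) == 7
    np.testing.assert_allclose(
        history["lr"],
        [0.01, 0.01, 0.01, 0.001, 0.001, 0.001, 1e-4], rtol=1e-12)


def test_lr_schedule_piecewise_constant():
    config = TrainConfig(lr_drop_factor=0.5, lr_drop_period=2,
                         learning_rate=1.0)
    assert [_epoch_lr(config, e) for e in range(6)] == \
        [1.0, 1.0, 0.5, 0.5, 0.25, 0.25]


def test_empty_data_rejected():
    with pytest.raises(ValueError, match="no training data"):
        fit(tiny_arch(), np.empty((0, 8, 8, 2)), np.empty(0), TrainConfig())


def test_divergence_aborts_with_diagnostics():
    # a non-finite input propagates to a non-finite loss, which must abort
    # with context rather than train on
    x, y = separable_data(10)
    x[0, 0, 0, 0] = np.nan
    config = TrainConfig(optimizer="sgdm", epochs=5, batch_size=20,
                         learning_rate=0.01, validation_size=0, seed=0,
                         dtype="float64")
    with pytest.raises(TrainingDiverged, match="epoch"):
        fit(tiny_arch(), x, y, config)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(lr_drop_factor=0.0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="rmsprop")


def test_checkpoint_round_trip(tmp_path, rng):
    from midecode.train import load_checkpoint, save_checkpoint, \
        write_training_log
    x, y = separable_data(10)
    config = TrainConfig(optimizer="adam", epochs=2, batch_size=8,
                         learning_rate=0.01, validation_size=4, seed=1)
    model, history = fit(tiny_arch(), x, y, config)
    ckpt = tmp_path / "model.npz"
    save_checkpoint(model, ckpt)
    back = load_checkpoint(ckpt)
    np.testing.assert_array_equal(back.predict_proba(x),
                                  model.predict_proba(x))
    log = tmp_path / "log.tsv"
    write_training_log(history, log)
    lines = log.read_text().strip().splitlines()
    assert len(lines) == 1 + config.epochs
    assert lines[0].startswith("epoch\t")
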