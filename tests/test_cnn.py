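"""Architecture specs, shape tracing, parameter audit, forward/backward."""

import numpy as np
import pytest

from midecode import (ArchitectureSpec, CNNModel, build_architecture,
                      count_parameters, forward_classify, parameter_audit,
                      shape_trace)
from midecode.cnn import (AvgPoolSpec, ConvBlockSpec, MaxPoolSpec, MegaBlock,
                          ShapeError, softmax)
from midecode.train import cross_entropy_loss, one_hot


def n_conv_layers(arch):
    return sum(st.repeats for st in arch.stages if isinstance(st, MegaBlock))


# -- build_architecture ------------------------------------------------------

def test_arch2_repeat_counts():
    assert n_conv_layers(build_architecture("arch2", (1, 1, 1))) == 3  # S01
    assert n_conv_layers(build_architecture("arch2", (5, 5, 5))) == 15  # S04/Adam
    assert n_conv_layers(build_architecture("arch2", (3, 1, 2))) == 6


def test_arch2_filter_plan():
    arch = build_architecture("arch2", (2, 2, 2))
    mbs = [st for st in arch.stages if isinstance(st, MegaBlock)]
    assert [mb.block.n_filters for mb in mbs] == [9, 18, 36]
    assert [mb.block.kernel for mb in mbs] == [(5, 5), (3, 3), (3, 3)]


@pytest.mark.parametrize("bad", [(0, 1, 1), (1, 6, 1), (1, 1, -2)])
def test_arch2_repeats_out_of_range_rejected(bad):
    with pytest.raises(ValueError, match="repeats"):
        build_architecture("arch2", bad)


def test_unknown_variant():
    with pytest.raises(ValueError, match="variant"):
        build_architecture("arch3")


def test_arch_round_trips_through_dict():
    arch = build_architecture("arch2", (2, 3, 1))
    back = ArchitectureSpec.from_dict(arch.to_dict())
    assert back == arch


# -- shape tracing -----------------------------------------------------------

def test_arch1_flatten_192():
    assert shape_trace(build_architecture("arch1"))[-1][1] == (192,)


@pytest.mark.parametrize("repeats", [(1, 1, 1), (3, 3, 3), (5, 5, 5), (2, 4, 1)])
def test_arch2_flatten_108_for_all_repeats(repeats):
    # repeats leave spatial dims unchanged under same padding
    assert shape_trace(build_architecture("arch2", repeats))[-1][1] == (108,)


def test_double_maxpool_spatial_dims():
    # ceil(40/2)=20, ceil(20/2)=10; ceil(32/2)=16, ceil(16/2)=8
    trace = dict(shape_trace(build_architecture("arch1")))
    assert trace["stage1.maxpool"][:2] == (20, 16)
    assert trace["stage3.maxpool"][:2] == (10, 8)
    assert trace["stage5.avgpool"] == (3, 1, 64)


def test_shape_error_names_layer():
    arch = ArchitectureSpec(
        stages=(MegaBlock(ConvBlockSpec(4, (3, 3))), AvgPoolSpec((8, 8), (1, 1))),
        input_shape=(5, 5, 1))
    with pytest.raises(ShapeError, match="avgpool"):
        shape_trace(arch)


def test_trace_matches_forward_shapes(rng):
    arch = build_architecture("arch2", (2, 1, 1))
    model = CNNModel(arch, rng)
    x = rng.standard_normal((2, 40, 32, 3))
    probs = forward_classify(model, x)
    assert probs.shape == (2, 2)


# -- parameter counting ------------------------------------------------------

def test_toy_conv_parameter_count():
    arch = ArchitectureSpec(
        stages=(MegaBlock(ConvBlockSpec(2, (3, 3))), AvgPoolSpec((8, 8), (1, 1))),
        input_shape=(8, 8, 3))
    audit = dict(parameter_audit(arch))
    assert audit["stage0.conv0"] == 3 * 3 * 3 * 2 + 2  # 56, hand count


def test_parameter_count_monotone_in_repeats():
    counts = [count_parameters(build_architecture("arch2", (r, r, r)))
              for r in range(1, 6)]
    assert all(b > a for a, b in zip(counts, counts[1:]))


def test_audit_sums_to_count():
    arch = build_architecture("arch1")
    assert sum(n for _, n in parameter_audit(arch)) == count_parameters(arch)


def test_arch1_documented_count():
    # audited convention: conv W+b, BN gamma+beta, dense W+b
    assert count_parameters(build_architecture("arch1")) == 24194


# -- forward pass ------------------------------------------------------------

def test_softmax_rows_normalized(rng):
    model = CNNModel(build_architecture("arch1"), rng)
    probs = forward_classify(model, rng.standard_normal((3, 40, 32, 3)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_zeroed_head_gives_uniform(rng):
    model = CNNModel(build_architecture("arch1"), rng)
    model.layers[-1].w[...] = 0.0
    model.layers[-1].b[...] = 0.0
    probs = forward_classify(model, rng.standard_normal((4, 40, 32, 3)))
    np.testing.assert_allclose(probs, 0.5, atol=1e-7)


def test_shape_mismatch_rejected(rng):
    model = CNNModel(build_architecture("arch1"), rng)
    with pytest.raises(ValueError, match="shape"):
        model.forward_logits(rng.standard_normal((1, 20, 32, 3)))


def test_hand_computed_forward_pass(rng):
    """1x1-conv toy network against explicit arithmetic: conv (w*x+b),
    batch-norm with unit running stats, ReLU, 2x2 mean, dense, softmax."""
    arch = ArchitectureSpec(
        stages=(MegaBlock(ConvBlockSpec(1, (1, 1))), AvgPoolSpec((2, 2), (1, 1))),
        input_shape=(2, 2, 1))
    model = CNNModel(arch, rng, dtype=np.float64)
    conv, bn, dense = model.layers[0], model.layers[1], model.layers[-1]
    conv.w[...] = 2.0
    conv.b[...] = -1.0
    dense.w[...] = np.array([[1.0, -1.0]])
    dense.b[...] = np.array([0.25, 0.0])
    x = np.array([[1.0, 2.0], [0.5, -3.0]]).reshape(1, 2, 2, 1)
    # by hand: conv -> 2x-1 = [1, 3, 0, -7]; bn (running mean 0, var 1)
    # -> a/sqrt(1+1e-5); relu -> [1,3,0,0]/s; mean -> 1/s; dense -> (1/s+.25, -1/s)
    s = np.sqrt(1 + 1e-5)
    logits = np.array([1.0 / s + 0.25, -1.0 / s])
    expected = np.exp(logits - logits.max())
    expected /= expected.sum()
    np.testing.assert_allclose(forward_classify(model, x)[0], expected,
                               atol=1e-12)


def test_relu_idempotent(rng):
    from midecode.cnn import _ReLU
    x = rng.standard_normal((2, 3, 3, 1))
    r = _ReLU()
    once = r.forward(x, True)
    np.testing.assert_array_equal(r.forward(once, True), once)


# -- backward pass (numerical gradient check) --------------------------------

def test_backprop_matches_numerical_gradient(rng):
    """Central-difference check of every parameter family on a tiny net
    containing conv, batch norm, ReLU, ceil-mode maxpool, avgpool, dense."""
    arch = ArchitectureSpec(
        stages=(MegaBlock(ConvBlockSpec(3, (3, 3)), repeats=1),
                MaxPoolSpec((3, 3), (2, 2)),
                AvgPoolSpec((3, 3), (1, 1))),
        input_shape=(8, 6, 2))
    model = CNNModel(arch, rng, dtype=np.float64)
    x = rng.standard_normal((4, 8, 6, 2))
    y = np.array([0, 1, 1, 0])
    t = one_hot(y)

    def loss_fn():
        logits = model.forward_logits(x, training=True)
        return cross_entropy_loss(softmax(logits), t)

    logits = model.forward_logits(x, training=True)
    probs = softmax(logits)
    model.backward((probs - t) / len(x))
    grads = model.gradients()
    params = model.parameters
    eps = 1e-6
    checked = 0
    for p, g in zip(params, grads):
        flat = p.ravel()
        idx = rng.choice(flat.size, size=min(5, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss_fn()
            flat[i] = orig - eps
            lm = loss_fn()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert g.ravel()[i] == pytest.approx(num, abs=1e-5, rel=1e-4)
            checked += 1
    assert checked >= 20
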