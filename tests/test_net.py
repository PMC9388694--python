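"""Multitask U-Net: shapes, losses, gradients, checkpoints."""

import numpy as np
import pytest

from octskin._nn import Adam
from octskin.labels import make_contour_mask, one_hot
from octskin.net import (
    MultitaskUNet,
    NetConfig,
    ProbMaps,
    build_model,
    load_checkpoint,
    loss_total,
    loss_transfer,
    save_checkpoint,
    train_step,
)


@pytest.fixture
def tiny_net():
    return build_model(NetConfig(depth=1, base_channels=4, seed=0))


@pytest.fixture
def small_batch(rng):
    x = rng.random((2, 16, 16)).astype(np.float32)
    lo = rng.integers(0, 3, (2, 16, 16))
    lc = rng.integers(0, 2, (2, 16, 16))
    return x, lo, lc


def test_forward_shapes_and_softmax_normalization():
    net = build_model(NetConfig(depth=3, base_channels=8, seed=0))
    x = np.random.default_rng(0).random((1, 64, 64))
    probs = net.forward(x)
    assert probs.object.shape == (1, 3, 64, 64)
    assert probs.contour.shape == (1, 64, 64)
    assert np.allclose(probs.object.sum(axis=1), 1.0, atol=1e-5)
    assert probs.contour.min() >= 0 and probs.contour.max() <= 1


def test_indivisible_input_size_rejected(tiny_net):
    net = build_model(NetConfig(depth=3, base_channels=4, seed=0))
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 60, 64)))


def test_seeded_initialization_is_deterministic():
    a = build_model(NetConfig(depth=2, base_channels=4, seed=42))
    b = build_model(NetConfig(depth=2, base_channels=4, seed=42))
    for pa, pb in zip(a.params(), b.params()):
        assert (pa.value == pb.value).all()
    c = build_model(NetConfig(depth=2, base_channels=4, seed=43))
    assert any((pa.value != pc.value).any() for pa, pc in zip(a.params(), c.params()))


def test_perfect_confident_predictions_give_zero_loss():
    lo = np.array([[0, 1], [2, 0]])
    lc = np.array([[1, 0], [0, 1]])
    po = one_hot(lo)[None]
    pc = lc[None].astype(float)
    probs = ProbMaps(object=po, contour=pc)
    assert loss_total(probs, lo, lc, l2=0.0) == pytest.approx(0.0)
    assert loss_transfer(po, lo) == pytest.approx(0.0)


def test_uniform_prediction_losses_match_analytic_values():
    p = 16 * 16
    lo = np.random.default_rng(0).integers(0, 3, (16, 16))
    lc = np.random.default_rng(1).integers(0, 2, (16, 16))
    po = np.full((1, 3, 16, 16), 1 / 3)
    pc = np.full((1, 16, 16), 1 / 2)
    probs = ProbMaps(object=po, contour=pc)
    expected = p * np.log(3) + p * np.log(2)
    assert loss_total(probs, lo, lc, l2=0.0) == pytest.approx(expected, abs=1e-6)
    assert loss_transfer(po, lo) == pytest.approx(np.log(3), abs=1e-6)


def test_l2_term_is_sum_of_squared_conv_weights(tiny_net):
    lo = np.zeros((8, 8), dtype=int)
    lc = np.zeros((8, 8), dtype=int)
    probs = ProbMaps(object=one_hot(lo)[None], contour=lc[None].astype(float))
    psi = tiny_net.l2_penalty()
    manual = sum(
        float(np.sum(p.value.astype(np.float64) ** 2)) for p in tiny_net.params() if p.decay
    )
    assert psi == pytest.approx(manual)
    assert loss_total(probs, lo, lc, net=tiny_net, l2=1.0) == pytest.approx(psi, rel=1e-6)


def test_transfer_loss_equals_object_term_of_total_per_pixel(rng):
    po = rng.dirichlet(np.ones(3), size=(12, 12)).transpose(2, 0, 1)[None]
    lo = rng.integers(0, 3, (12, 12))
    lc = np.zeros((12, 12), dtype=int)
    pc = np.zeros((1, 12, 12))  # contour prob 0 on all-zero labels: term = 0
    total = loss_total(ProbMaps(object=po, contour=pc), lo, lc, l2=0.0)
    assert loss_transfer(po, lo) == pytest.approx(total / (12 * 12), rel=1e-6)


def test_losses_nonnegative(rng, tiny_net):
    for _ in range(5):
        po = rng.dirichlet(np.ones(3), size=(8, 8)).transpose(2, 0, 1)[None]
        pc = rng.random((1, 8, 8))
        lo = rng.integers(0, 3, (8, 8))
        lc = rng.integers(0, 2, (8, 8))
        assert loss_total(ProbMaps(po, pc), lo, lc, net=tiny_net, l2=1e-4) >= 0
        assert loss_transfer(po, lo) >= 0


def test_loss_shape_mismatch_rejected():
    po = np.full((1, 3, 8, 8), 1 / 3)
    pc = np.full((1, 8, 8), 0.5)
    with pytest.raises(ValueError, match="match"):
        loss_total(ProbMaps(po, pc), np.zeros((4, 4), int), np.zeros((8, 8), int))
    with pytest.raises(ValueError, match="match"):
        loss_transfer(po, np.zeros((4, 4), int))
    with pytest.raises(ValueError):
        loss_total(ProbMaps(po, pc), np.zeros((8, 8), int), np.zeros((8, 8), int), l2=-1)


def test_gradients_match_finite_differences(small_batch):
    """Hand-written backprop agrees with central finite differences."""
    x, lo, lc = small_batch
    net = build_model(NetConfig(depth=1, base_channels=4, seed=3, dtype="float64"))
    l2 = 1e-3

    probs = net.forward(x, train=True, heads="both")
    y = np.stack([one_hot(m) for m in lo]).astype(np.float64)
    for p in net.params():
        p.zero_grad()
    net.backward(probs.object - y, probs.contour - lc)
    for p in net.params():
        if p.decay:
            p.grad += 2 * l2 * p.value

    def loss_value():
        pr = net.forward(x, train=True, heads="both")
        return loss_total(pr, lo, lc, net=net, l2=l2)

    rng = np.random.default_rng(0)
    params = net.params()
    for pi in rng.choice(len(params), size=8, replace=False):
        p = params[pi]
        flat = p.value.ravel()
        idx = int(rng.integers(flat.size))
        eps = 1e-5
        old = flat[idx]
        flat[idx] = old + eps
        lp = loss_value()
        flat[idx] = old - eps
        lm = loss_value()
        flat[idx] = old
        numeric = (lp - lm) / (2 * eps)
        analytic = p.grad.ravel()[idx]
        assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-7)


def test_object_step_changes_encoder_and_object_head_only(small_batch):
    """Shared-encoder wiring: object-only gradients leave the contour path
    bit-unchanged, and symmetrically for contour-only gradients."""
    x, lo, lc = small_batch
    net = build_model(NetConfig(depth=2, base_channels=4, seed=1))

    before = {k: [p.value.copy() for p in net.params(k)] for k in ("encoder", "object", "contour")}
    train_step(net, Adam(net.params(), lr=1e-3), x, lo, lc, mode="transfer")
    after = {k: [p.value for p in net.params(k)] for k in ("encoder", "object", "contour")}
    assert all((a == b).all() for a, b in zip(after["contour"], before["contour"]))
    assert any((a != b).any() for a, b in zip(after["encoder"], before["encoder"]))
    assert any((a != b).any() for a, b in zip(after["object"], before["object"]))

    before = {k: [p.value.copy() for p in net.params(k)] for k in ("encoder", "object", "contour")}
    train_step(net, Adam(net.params(), lr=1e-3), x, lo, lc, mode="contour")
    after = {k: [p.value for p in net.params(k)] for k in ("encoder", "object", "contour")}
    assert all((a == b).all() for a, b in zip(after["object"], before["object"]))
    assert any((a != b).any() for a, b in zip(after["contour"], before["contour"]))
    assert any((a != b).any() for a, b in zip(after["encoder"], before["encoder"]))


def test_loss_decreases_over_short_training():
    from octskin.phantom import PhantomParams, make_volume
    from octskin.train import pretrain_source

    params = PhantomParams(height=32, width=32, surface_depth_px=8, seed=2)
    vol, truth = make_volume(params, 4)
    net = build_model(NetConfig(depth=2, base_channels=4, seed=0))
    trace = pretrain_source(net, vol, truth.class_masks, epochs=8, lr=1e-3, seed=0)
    assert len(trace) == 8
    assert trace[-1] < trace[0]


def test_checkpoint_round_trip_and_config_guard(tmp_path, small_batch):
    x, _, _ = small_batch
    net = build_model(NetConfig(depth=2, base_channels=4, seed=5))
    path = tmp_path / "model.npz"
    save_checkpoint(net, path)
    restored = load_checkpoint(path)
    p1 = net.forward(x)
    p2 = restored.forward(x)
    assert (p1.object == p2.object).all()
    with pytest.raises(ValueError, match="hash"):
        load_checkpoint(path, expect_config=NetConfig(depth=3, base_channels=4))


def test_copy_is_independent(small_batch):
    x, lo, lc = small_batch
    net = build_model(NetConfig(depth=1, base_channels=4, seed=0))
    clone = net.copy()
    opt = Adam(clone.params(), lr=1e-2)
    train_step(clone, opt, x, lo, lc, mode="total")
    assert any(
        (a.value != b.value).any() for a, b in zip(clone.params(), net.params())
    )
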