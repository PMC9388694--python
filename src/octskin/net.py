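"""Multitask U-Net: shared encoder, object head, contour head, and losses.

The network is a U-Net whose decoder is duplicated: the shared down-sampling
path ``A_s`` feeds an object decoder/head ``A_O`` (3-class softmax over
background / epidermis / scab) and a contour decoder/head ``A_C``
(single-channel sigmoid for the boundary band).  Both heads see the same
encoder skip connections, so gradients from either task update ``A_s``.

Losses:

* :func:`loss_total` — pretraining objective: L2 penalty ``lam * psi(theta)``
  (sum of squared convolution weights) plus pixel-summed negative
  log-likelihood of the object labels under the softmax head and of the
  binary contour labels under the sigmoid head.
* :func:`loss_transfer` — fine-tuning objective: per-pixel mean three-class
  cross-entropy of the object head alone.

Probabilities are clamped to ``>= 1e-12`` before logarithms.
"""

from __future__ import annotations

import hashlib

import json
from dataclasses import dataclass

import numpy as np

from ._nn import Adam, BatchNorm2d, Conv2d, ConvBlock, ConvTranspose2, MaxPool2, Param
from .labels import one_hot

__all__ = [
    "NetConfig",
    "ProbMaps",
    "MultitaskUNet",
    "build_model",
    "loss_total",
    "loss_transfer",
    "train_step",
    "save_checkpoint",
    "load_checkpoint",
]

_CLAMP = 1e-12


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of 2x2 down-samplings (input height/width must be
    divisible by ``2 ** depth``); ``base_channels`` is the channel count of
    the first encoder block, doubling at each scale; ``l2`` is the weight of
    the L2 penalty on convolution weights.
    """

    depth: int = 3
    base_channels: int = 12
    negative_slope: float = 0.01
    l2: float = 1e-4
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.l2 < 0:
            raise ValueError("l2 weight must be >= 0")

    @property
    def arch_hash(self) -> str:
        key = json.dumps(
            [self.depth, self.base_channels, self.negative_slope, self.dtype], sort_keys=True
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class ProbMaps:
    """Network outputs: 3-channel object probabilities and contour probability.

    ``object`` has shape (N, 3, H, W) with channels summing to 1 per pixel;
    ``contour`` has shape (N, H, W) in [0, 1].  Either may be ``None`` when
    only one head was evaluated.
    """

    object: np.ndarray | None
    contour: np.ndarray | None


class MultitaskUNet:
    """U-Net with a shared encoder and two decoder/head paths."""

    N_CLASSES = 3

    def __init__(self, config: NetConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        d, b, slope = config.depth, config.base_channels, config.negative_slope

        self.enc_blocks = []
        cin = 1
        for i in range(d):
            self.enc_blocks.append(ConvBlock(cin, b * 2**i, rng, slope, dtype))
            cin = b * 2**i
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(b * 2 ** (d - 1), b * 2**d, rng, slope, dtype)

        def make_decoder(out_channels: int):
            ups, blocks = [], []
            for i in reversed(range(d)):
                ups.append(ConvTranspose2(b * 2 ** (i + 1), b * 2**i, rng, dtype))
                blocks.append(ConvBlock(b * 2 ** (i + 1), b * 2**i, rng, slope, dtype))
            head = Conv2d(b, out_channels, 1, rng, dtype)
            return ups, blocks, head

        self.obj_ups, self.obj_blocks, self.obj_head = make_decoder(self.N_CLASSES)
        self.con_ups, self.con_blocks, self.con_head = make_decoder(1)

    # -- parameter groups -------------------------------------------------
    def encoder_params(self) -> list[Param]:
        ps = [p for blk in self.enc_blocks for p in blk.params()]
        return ps + self.bottleneck.params()

    def object_params(self) -> list[Param]:
        ps = [p for layer in self.obj_ups + self.obj_blocks for p in layer.params()]
        return ps + self.obj_head.params()

    def contour_params(self) -> list[Param]:
        ps = [p for layer in self.con_ups + self.con_blocks for p in layer.params()]
        return ps + self.con_head.params()

    def params(self, which: str = "all") -> list[Param]:
        groups = {
            "all": self.encoder_params() + self.object_params() + self.contour_params(),
            "encoder": self.encoder_params(),
            "object": self.object_params(),
            "contour": self.contour_params(),
        }
        return groups[which]

    def l2_penalty(self) -> float:
        return float(sum(np.sum(p.value.astype(np.float64) ** 2) for p in self.params() if p.decay))

    # -- forward / backward ------------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        div = 2**self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2**depth = {div} "
                f"(depth {self.config.depth})"
            )

    def forward(self, x: np.ndarray, train: bool = False, heads: str = "both") -> ProbMaps:
        """Run the network on a batch (N, H, W) or (N, 1, H, W) in [0, 1].

        ``heads`` selects which decoder paths to evaluate
        (``both`` / ``object`` / ``contour``).
        """
        if heads not in ("both", "object", "contour"):
            raise ValueError(f"unknown heads selector {heads!r}")
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 3:
            x = x[:, None]
        self._check_size(x.shape[2], x.shape[3])

        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_shapes = [s.shape for s in skips]
        self._heads = heads

        def decode(ups, blocks, head):
            d = h
            for up, blk, skip in zip(ups, blocks, reversed(skips)):
                d = up.forward(d, train)
                d = np.concatenate([skip, d], axis=1)
                d = blk.forward(d, train)
            return head.forward(d, train)

        po = pc = None
        if heads in ("both", "object"):
            logits = decode(self.obj_ups, self.obj_blocks, self.obj_head)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            po = e / e.sum(axis=1, keepdims=True)
            self._po = po
        if heads in ("both", "contour"):
            logit_c = decode(self.con_ups, self.con_blocks, self.con_head)[:, 0]
            pc = 1.0 / (1.0 + np.exp(-logit_c))
            self._pc = pc
        return ProbMaps(object=po, contour=pc)

    def backward(self, d_logits_o: np.ndarray | None = None, d_logit_c: np.ndarray | None = None) -> None:
        """Backpropagate gradients given w.r.t. the head pre-activations.

        For the softmax object head with cross-entropy, ``d_logits_o`` is
        ``probs - one_hot``; for the sigmoid contour head with binary
        cross-entropy, ``d_logit_c`` is ``probs - labels``.  Gradients
        accumulate into the ``Param`` objects.
        """
        n_skip = len(self.enc_blocks)
        skip_grads = [None] * n_skip
        bottom = None

        def undecode(ups, blocks, head, g):
            nonlocal bottom
            g = head.backward(g)
            for level, (up, blk) in enumerate(zip(reversed(ups), reversed(blocks))):
                # level 0 here is the shallowest decoder stage
                g = blk.backward(g)
                c_skip = self._skip_shapes[level][1]
                g_skip, g_up = g[:, :c_skip], g[:, c_skip:]
                if skip_grads[level] is None:
                    skip_grads[level] = g_skip.copy()
                else:
                    skip_grads[level] += g_skip
                g = up.backward(np.ascontiguousarray(g_up))
            bottom = g if bottom is None else bottom + g

        if d_logits_o is not None:
            undecode(self.obj_ups, self.obj_blocks, self.obj_head, d_logits_o)
        if d_logit_c is not None:
            undecode(self.con_ups, self.con_blocks, self.con_head, d_logit_c[:, None])
        if bottom is None:
            return
        g = self.bottleneck.backward(bottom)
        for i in reversed(range(n_skip)):
            g = self.pools[i].backward(g)
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)

    # -- state -------------------------------------------------------------
    def _layers_with_state(self):
        layers = self.enc_blocks + [self.bottleneck] + self.obj_ups + self.obj_blocks
        layers += [self.obj_head] + self.con_ups + self.con_blocks + [self.con_head]
        return layers

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.value for p in self.params()]
        for layer in self._layers_with_state():
            if isinstance(layer, ConvBlock):
                for sub in layer.layers:
                    if isinstance(sub, BatchNorm2d):
                        arrays += [sub.running_mean, sub.running_var]
        return arrays

    def set_state_arrays(self, arrays: list[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(current) != len(arrays):
            raise ValueError("state array count mismatch")
        it = iter(arrays)
        for p, a in zip(self.params(), arrays):
            if p.value.shape != a.shape:
                raise ValueError("parameter shape mismatch")
        k = len(self.params())
        for p, a in zip(self.params(), arrays[:k]):
            p.value[...] = a
        rest = arrays[k:]
        i = 0
        for layer in self._layers_with_state():
            if isinstance(layer, ConvBlock):
                for sub in layer.layers:
                    if isinstance(sub, BatchNorm2d):
                        sub.running_mean[...] = rest[i]
                        sub.running_var[...] = rest[i + 1]
                        i += 2

    def copy(self) -> "MultitaskUNet":
        clone = MultitaskUNet(self.config)
        clone.set_state_arrays([a.copy() for a in self.state_arrays()])
        return clone


def build_model(config: NetConfig) -> MultitaskUNet:
    """Construct a seeded, deterministically initialized multitask U-Net."""
    return MultitaskUNet(config)


# -- losses ----------------------------------------------------------------


def _as_batch(a: np.ndarray, ndim: int) -> np.ndarray:
    a = np.asarray(a)
    return a[None] if a.ndim == ndim - 1 else a


def loss_total(
    probs: ProbMaps,
    class_mask: np.ndarray,
    contour_mask: np.ndarray,
    net: MultitaskUNet | None = None,
    l2: float = 0.0,
) -> float:
    """Pretraining loss: ``l2 * psi + sum NLL(object) + sum NLL(contour)``.

    Sums run over all pixels (and the batch).  ``psi`` is the sum of squared
    convolution weights of ``net``; ``net`` may be omitted when ``l2 == 0``.
    """
    if l2 < 0:
        raise ValueError("l2 weight must be >= 0")
    po = _as_batch(probs.object, 4)
    pc = _as_batch(probs.contour, 3)
    lo = _as_batch(class_mask, 3).astype(np.intp)
    lc = _as_batch(contour_mask, 3)
    if po.shape[0] != lo.shape[0] or po.shape[2:] != lo.shape[1:]:
        raise ValueError(f"object probability shape {po.shape} does not match mask {lo.shape}")
    if pc.shape != lc.shape:
        raise ValueError(f"contour probability shape {pc.shape} does not match mask {lc.shape}")

    p_true = np.take_along_axis(po, lo[:, None], axis=1)[:, 0]
    obj = -np.log(np.clip(p_true, _CLAMP, None)).sum()
    p_c = np.where(lc > 0, pc, 1.0 - pc)
    con = -np.log(np.clip(p_c, _CLAMP, None)).sum()
    reg = 0.0
    if l2 > 0:
        if net is None:
            raise ValueError("net is required to evaluate the L2 penalty when l2 > 0")
        reg = l2 * net.l2_penalty()
    return float(reg + obj + con)


def loss_transfer(predicted: np.ndarray, class_mask: np.ndarray) -> float:
    """Fine-tuning loss: per-pixel mean three-class cross-entropy.

    ``predicted`` is the object head's probability map (3, H, W) or
    (N, 3, H, W); the target is the one-hot encoding of ``class_mask``.
    """
    po = _as_batch(predicted, 4)
    lo = _as_batch(class_mask, 3).astype(np.intp)
    if po.shape[0] != lo.shape[0] or po.shape[2:] != lo.shape[1:]:
        raise ValueError(f"probability shape {po.shape} does not match mask {lo.shape}")
    if lo.max() >= po.shape[1]:
        raise ValueError("class label out of range for probability channels")
    p_true = np.take_along_axis(po, lo[:, None], axis=1)[:, 0]
    return float(-np.log(np.clip(p_true, _CLAMP, None)).mean())


def train_step(
    net: MultitaskUNet,
    opt: Adam,
    images: np.ndarray,
    class_masks: np.ndarray,
    contour_masks: np.ndarray | None,
    mode: str = "total",
    l2: float = 0.0,
) -> float:
    """One optimizer step on a batch; returns the loss value.

    ``mode='total'`` optimizes :func:`loss_total` (both heads);
    ``mode='transfer'`` optimizes :func:`loss_transfer` (object head only);
    ``mode='contour'`` optimizes the contour NLL alone (used for the
    gradient-wiring checks).
    """
    images = _as_batch(images, 3)
    lo = _as_batch(class_masks, 3).astype(np.intp)
    n, h, w = images.shape
    opt.zero_grad()

    if mode == "total":
        lc = _as_batch(contour_masks, 3)
        probs = net.forward(images, train=True, heads="both")
        y = np.stack([one_hot(m, net.N_CLASSES) for m in lo]).astype(probs.object.dtype)
        d_o = probs.object - y
        d_c = (probs.contour - lc).astype(probs.contour.dtype)
        loss = loss_total(probs, lo, lc, net=net, l2=l2)
        net.backward(d_o, d_c)
        if l2 > 0:
            for p in net.params():
                if p.decay:
                    p.grad += (2.0 * l2) * p.value
    elif mode == "transfer":
        probs = net.forward(images, train=True, heads="object")
        y = np.stack([one_hot(m, net.N_CLASSES) for m in lo]).astype(probs.object.dtype)
        d_o = (probs.object - y) / (n * h * w)
        loss = loss_transfer(probs.object, lo)
        net.backward(d_o, None)
    elif mode == "contour":
        lc = _as_batch(contour_masks, 3)
        probs = net.forward(images, train=True, heads="contour")
        d_c = (probs.contour - lc).astype(probs.contour.dtype)
        p_c = np.where(lc > 0, probs.contour, 1.0 - probs.contour)
        loss = float(-np.log(np.clip(p_c, _CLAMP, None)).sum())
        net.backward(None, d_c)
    else:
        raise ValueError(f"unknown train mode {mode!r}")

    opt.step()
    return loss


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(net: MultitaskUNet, path) -> None:
    """Save config + seed + parameter blobs, with an architecture hash that
    guards against loading into a mismatched config."""
    import dataclasses as _dc

    arrays = {f"arr_{i}": a for i, a in enumerate(net.state_arrays())}
    meta = json.dumps({"config": _dc.asdict(net.config), "arch_hash": net.config.arch_hash})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_config: NetConfig | None = None) -> MultitaskUNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        config = NetConfig(**meta["config"])
        if expect_config is not None and expect_config.arch_hash != meta["arch_hash"]:
            raise ValueError(
                f"checkpoint architecture hash {meta['arch_hash']} does not match "
                f"expected config hash {expect_config.arch_hash}"
            )
        net = MultitaskUNet(config)
        n = len(net.state_arrays())
        net.set_state_arrays([data[f"arr_{i}"] for i in range(n)])
    return net
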