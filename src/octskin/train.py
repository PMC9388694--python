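"""Three-step transfer strategy: pretrain, select few labels, fine-tune.

The workflow mirrors the study design the package validates: a multitask
U-Net is first pretrained on the source domain (thin, high-contrast rodent
-like B-scans) with the joint object+contour loss; then a small labeled
subset of the target domain (one or three B-scans per volume) is drawn, and
the pretrained parameters are fine-tuned on it with the single-task
cross-entropy transfer loss at a lowered learning rate.  ``baseline`` applies
the pretrained model to the target domain without any update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam
from .labels import make_contour_mask
from .net import MultitaskUNet, train_step

__all__ = [
    "Strategy",
    "STRATEGIES",
    "VolumeData",
    "pretrain_source",
    "select_labeled_subset",
    "finetune_target",
    "run_strategy",
]


@dataclass(frozen=True)
class Strategy:
    """A transfer-learning strategy.

    ``k_per_volume`` labeled target B-scans are used per volume: 0 for the
    no-fine-tuning baseline, 1 for method #1, 3 for method #2.
    """

    name: str
    k_per_volume: int
    finetune_epochs: int = 50
    finetune_lr: float = 1e-4


STRATEGIES = {
    "baseline": Strategy("baseline", 0),
    "method1": Strategy("method1", 1),
    "method2": Strategy("method2", 3),
}


@dataclass
class VolumeData:
    """In-memory labeled volume: images (n_bscans, H, W) plus class masks."""

    volume_id: str
    session: str
    images: np.ndarray
    class_masks: np.ndarray

    @property
    def n_bscans(self) -> int:
        return self.images.shape[0]


def _stack_training_set(images, class_masks, contour_masks, contour_width: int):
    images = np.asarray(images, dtype=np.float32)
    class_masks = np.asarray(class_masks)
    if len(images) == 0:
        raise ValueError("empty training set")
    if contour_masks is None:
        contour_masks = np.stack([make_contour_mask(m, contour_width) for m in class_masks])
    contour_masks = np.asarray(contour_masks)
    if not (len(images) == len(class_masks) == len(contour_masks)):
        raise ValueError("images, class masks and contour masks must have equal length")
    return images, class_masks, contour_masks


def pretrain_source(
    net: MultitaskUNet,
    images: np.ndarray,
    class_masks: np.ndarray,
    contour_masks: np.ndarray | None = None,
    *,
    epochs: int = 30,
    lr: float = 1e-3,
    batch_size: int = 4,
    l2: float | None = None,
    seed: int = 0,
    contour_width: int = 5,
) -> list[float]:
    """Pretrain ``net`` in place on source-domain data; returns the per-epoch
    mean total loss trace (length ``epochs``).

    Optimizes the joint object+contour loss with Adam over seeded shuffled
    mini-batches; contour masks are derived from the class masks when not
    provided.  ``epochs=0`` leaves the parameters untouched.
    """
    images, class_masks, contour_masks = _stack_training_set(
        images, class_masks, contour_masks, contour_width
    )
    if l2 is None:
        l2 = net.config.l2
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=lr)
    trace: list[float] = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = train_step(
                net, opt, images[idx], class_masks[idx], contour_masks[idx], mode="total", l2=l2
            )
            total += loss
        trace.append(total / n)
    return trace


def select_labeled_subset(
    volumes: "list[VolumeData] | list[tuple[str, int]]",
    k_per_volume: int,
    seed: int = 0,
) -> dict[str, list[int]]:
    """Draw ``k`` labeled B-scan indices per volume, uniformly without
    replacement.

    Returns ``{volume_id: sorted indices}``.  Selection is nested across
    ``k``: for a fixed seed, each volume's indices are the first ``k`` of a
    seeded permutation, so method #2's three images per volume contain
    method #1's one.
    """
    if k_per_volume < 0:
        raise ValueError("k_per_volume must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, list[int]] = {}
    for vol in volumes:
        if isinstance(vol, VolumeData):
            vid, n = vol.volume_id, vol.n_bscans
        else:
            vid, n = vol
        if k_per_volume > n:
            raise ValueError(f"k={k_per_volume} exceeds {n} B-scans in volume {vid}")
        perm = rng.permutation(n)
        out[str(vid)] = sorted(int(i) for i in perm[:k_per_volume])
    return out


def finetune_target(
    net: MultitaskUNet,
    images: np.ndarray,
    class_masks: np.ndarray,
    *,
    lr: float = 1e-4,
    epochs: int = 50,
    batch_size: int = 4,
    seed: int = 0,
    include_contour: bool = False,
    freeze_encoder: bool = False,
    contour_width: int = 5,
    val_images: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
) -> tuple[list[float], list[float]]:
    """Fine-tune ``net`` in place on a labeled target subset.

    Optimizes the transfer cross-entropy (object head only; the contour head
    receives no gradient unless ``include_contour``).  All parameters are
    updated by default; ``freeze_encoder`` restricts the update to the
    decoder/head paths.  Returns ``(train_trace, val_trace)``; the
    validation trace is empty unless validation data is given.
    ``epochs=0`` or ``lr=0`` leaves the parameters unchanged.
    """
    images = np.asarray(images, dtype=np.float32)
    class_masks = np.asarray(class_masks)
    if len(images) == 0:
        raise ValueError("empty fine-tuning subset; use the baseline strategy instead")
    contour_masks = None
    if include_contour:
        contour_masks = np.stack([make_contour_mask(m, contour_width) for m in class_masks])
    rng = np.random.default_rng(seed)
    trainable = (
        net.params("object") + net.params("contour") if freeze_encoder else net.params()
    )
    opt = Adam(trainable, lr=lr)
    trace: list[float] = []
    val_trace: list[float] = []
    n = len(images)
    mode = "total" if include_contour else "transfer"
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            cm = contour_masks[idx] if contour_masks is not None else None
            total += train_step(net, opt, images[idx], class_masks[idx], cm, mode=mode, l2=0.0)
        trace.append(total / n)
        if val_images is not None and val_masks is not None:
            from .net import loss_transfer

            probs = net.forward(val_images, train=False, heads="object")
            val_trace.append(loss_transfer(probs.object, val_masks))
    return trace, val_trace


def run_strategy(
    strategy: "Strategy | str",
    pretrained: MultitaskUNet,
    target_volumes: list[VolumeData],
    *,
    seed: int = 0,
    finetune_batch_size: int = 4,
) -> tuple[MultitaskUNet, dict]:
    """Apply a transfer strategy to a pretrained model.

    ``baseline`` returns the pretrained parameters untouched; ``method1`` /
    ``method2`` fine-tune a copy on 1 / 3 labeled B-scans per target volume.
    Returns the resulting model and a provenance record (strategy, seed,
    labeled indices, epochs, learning rate).
    """
    if isinstance(strategy, str):
        try:
            strategy = STRATEGIES[strategy]
        except KeyError:
            raise ValueError(
                f"unknown strategy {strategy!r}; expected one of {sorted(STRATEGIES)}"
            ) from None
    provenance = {
        "strategy": strategy.name,
        "seed": seed,
        "k_per_volume": strategy.k_per_volume,
        "labeled_indices": {},
        "epochs": 0,
        "lr": None,
        "arch_hash": pretrained.config.arch_hash,
    }
    if strategy.k_per_volume == 0:
        return pretrained, provenance

    subset = select_labeled_subset(target_volumes, strategy.k_per_volume, seed=seed)
    images = np.concatenate(
        [vol.images[subset[vol.volume_id]] for vol in target_volumes], axis=0
    )
    masks = np.concatenate(
        [vol.class_masks[subset[vol.volume_id]] for vol in target_volumes], axis=0
    )
    net = pretrained.copy()
    trace, _ = finetune_target(
        net,
        images,
        masks,
        lr=strategy.finetune_lr,
        epochs=strategy.finetune_epochs,
        batch_size=finetune_batch_size,
        seed=seed,
    )
    provenance.update(
        labeled_indices=subset,
        epochs=strategy.finetune_epochs,
        lr=strategy.finetune_lr,
        final_loss=trace[-1] if trace else None,
    )
    return net, provenance
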