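"""Scikit-learn-style estimator for multitask OCT skin segmentation.

:class:`MultitaskUNetSegmenter` packages the full method behind the familiar
``fit`` / ``predict`` surface: ``fit`` pretrains the shared-encoder multitask
U-Net on labeled B-scans with the joint object+contour loss; ``finetune``
adapts a fitted model to a new domain from a handful of labeled images with
the single-task transfer cross-entropy; ``predict`` fuses the probability
maps into 3-class masks.  It is clonable and composes with sklearn model
selection (``get_params`` / ``set_params``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import infer
from .net import MultitaskUNet, NetConfig
from .train import finetune_target, pretrain_source

__all__ = ["MultitaskUNetSegmenter"]


class MultitaskUNetSegmenter(BaseEstimator):
    """Pixel-wise 3-class skin segmenter (background / epidermis / scab).

    Parameters
    ----------
    depth, base_channels, negative_slope, l2 : network architecture and the
        L2 penalty weight on convolution weights.
    learning_rate, epochs, batch_size : pretraining optimizer settings.
    contour_width : width of the auto-generated boundary band labels, px.
    fusion : "practical" (argmax + contour refinement, default) or "eq2"
        (the literal thresholded rule).
    thresholds : the four fusion thresholds (t_o1, t_o2, t_c1, t_c2).
    cleanup : keep only the largest connected component per class.
    random_state : seeds initialization and batch shuffling.

    Attributes (after ``fit``)
    --------------------------
    net_ : the trained :class:`~octskin.net.MultitaskUNet`.
    loss_trace_ : per-epoch mean pretraining loss.
    finetune_trace_ : per-epoch transfer loss (after ``finetune``).
    """

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 12,
        negative_slope: float = 0.01,
        l2: float = 1e-4,
        learning_rate: float = 1e-3,
        epochs: int = 30,
        batch_size: int = 4,
        contour_width: int = 5,
        fusion: str = "practical",
        thresholds: tuple = (0.5, 0.5, 0.5, 0.5),
        cleanup: bool = True,
        pitch_um: float = 8.0,
        random_state: int = 0,
        dtype: str = "float32",
    ):
        self.depth = depth
        self.base_channels = base_channels
        self.negative_slope = negative_slope
        self.l2 = l2
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.contour_width = contour_width
        self.fusion = fusion
        self.thresholds = thresholds
        self.cleanup = cleanup
        self.pitch_um = pitch_um
        self.random_state = random_state
        self.dtype = dtype

    # ------------------------------------------------------------------
    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"expected B-scans of shape (n, H, W), got {X.shape}")
        return X

    def _config(self) -> NetConfig:
        return NetConfig(
            depth=self.depth,
            base_channels=self.base_channels,
            negative_slope=self.negative_slope,
            l2=self.l2,
            seed=self.random_state,
            dtype=self.dtype,
        )

    def fit(self, X, y, contours: np.ndarray | None = None):
        """Pretrain on labeled B-scans.

        ``X`` is (n, H, W) in [0, 1]; ``y`` is the matching stack of
        3-class masks.  Contour-band labels are derived from ``y`` unless
        given.
        """
        X = self._validate_images(X)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"mask stack shape {y.shape} does not match images {X.shape}")
        self.net_ = MultitaskUNet(self._config())
        self.loss_trace_ = pretrain_source(
            self.net_,
            X,
            y,
            contours,
            epochs=self.epochs,
            lr=self.learning_rate,
            batch_size=self.batch_size,
            l2=self.l2,
            seed=self.random_state,
            contour_width=self.contour_width,
        )
        return self

    def finetune(
        self,
        X,
        y,
        *,
        learning_rate: float = 1e-4,
        epochs: int = 50,
        batch_size: int | None = None,
        include_contour: bool = False,
        seed: int | None = None,
    ):
        """Adapt the fitted model to a new domain from few labeled images."""
        self._check_fitted()
        X = self._validate_images(X)
        self.finetune_trace_, _ = finetune_target(
            self.net_,
            X,
            np.asarray(y),
            lr=learning_rate,
            epochs=epochs,
            batch_size=batch_size or self.batch_size,
            seed=self.random_state if seed is None else seed,
            include_contour=include_contour,
            contour_width=self.contour_width,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("this MultitaskUNetSegmenter is not fitted yet; call fit first")

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> "infer.ProbMaps":
        """Object and contour probability maps for a batch of B-scans."""
        self._check_fitted()
        X = self._validate_images(X)
        return self.net_.forward(X, train=False, heads="both")

    def predict(self, X) -> np.ndarray:
        """Fused 3-class masks, shape (n, H, W)."""
        self._check_fitted()
        X = self._validate_images(X)
        return infer.segment_volume(
            self.net_,
            X,
            thresholds=infer.FusionThresholds(*self.thresholds),
            fusion=self.fusion,
            cleanup=self.cleanup,
        )

    def score(self, X, y) -> float:
        """Mean epidermis Dice over the batch (higher is better)."""
        from .metrics import dsc

        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([dsc(p == 1, t == 1) for p, t in zip(pred, y)]))

    def thickness(self, X) -> "infer.ThicknessMap":
        """En-face epidermal thickness map of a predicted volume."""
        return infer.thickness_map(self.predict(X), pitch_um=self.pitch_um)
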