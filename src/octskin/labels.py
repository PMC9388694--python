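"""Label-space conventions: 3-class masks, contour bands, one-hot encoding.

Class masks use literal pixel values 0 (background / other tissue),
1 (epidermis), 2 (scab).  Contour masks are binary bands centered on class
interfaces: a pixel is 1 iff its Chebyshev distance to a boundary pixel is at
most (width - 1) / 2, where the boundary pixels are the foreground pixels
(class 1 or 2) whose 4-neighborhood contains a different class; pixels outside
the image count as background.  Both the object/background edge and the
epidermis/scab interface generate band pixels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation

__all__ = ["make_contour_mask", "one_hot", "boundary_pixels", "read_mask_png", "write_mask_png"]

# display-only palette (RGB): background black, epidermis green, scab red
PALETTE = np.array([[0, 0, 0], [0, 200, 0], [220, 30, 30]], dtype=np.uint8)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of foreground pixels with a differently-labeled 4-neighbor."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    padded = np.pad(m, 1, mode="constant", constant_values=0)
    center = padded[1:-1, 1:-1]
    differs = np.zeros(m.shape, dtype=bool)
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        differs |= padded[1 + dr : 1 + dr + m.shape[0], 1 + dc : 1 + dc + m.shape[1]] != center
    return (m > 0) & differs


def make_contour_mask(mask: np.ndarray, width_px: int = 5) -> np.ndarray:
    """Binary contour band of ``width_px`` centered on class interfaces.

    ``width_px`` must be odd so the band can be centered; along an edge
    normal (away from corners) the band is exactly ``width_px`` pixels
    thick.  Returns uint8 {0, 1}.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError(f"contour width must be odd and >= 1, got {width_px}")
    b = boundary_pixels(mask)
    if width_px == 1:
        return b.astype(np.uint8)
    se = np.ones((width_px, width_px), dtype=bool)  # Chebyshev ball, radius (w-1)/2
    return binary_dilation(b, structure=se).astype(np.uint8)


def one_hot(mask: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Channel-first one-hot encoding, shape (n_classes, H, W), float32."""
    m = np.asarray(mask)
    if m.min() < 0 or m.max() >= n_classes:
        raise ValueError(
            f"mask values must lie in [0, {n_classes - 1}], got range [{m.min()}, {m.max()}]"
        )
    out = np.zeros((n_classes,) + m.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = m == c
    return out


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a mask as single-channel PNG with literal values 0/1/2 (or 0/1)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def read_mask_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    m = np.asarray(iio.imread(Path(path)))
    if m.ndim == 3:  # tolerate palette/RGB expansions of our own writes
        m = m[..., 0]
    return m.astype(np.uint8)
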