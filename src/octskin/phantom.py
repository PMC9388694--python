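"""Synthetic layered skin OCT phantoms with analytic ground truth.

A phantom B-scan is a depth x lateral grid (row 0 = shallowest) built from a
piecewise-constant reflectivity field: air above a smoothly curved tissue
surface, an optional scab cap sitting on top of the epidermis, a bright
epidermis band, and dermis below.  The field is attenuated exponentially with
depth below the tissue entry point of each A-line, multiplied by gamma
speckle, and perturbed by additive Gaussian noise.

Two domains emulate the interspecies thickness/contrast shift the segmentation
method has to bridge: ``source`` (rodent-like) phantoms have a thin epidermis
(< 25 um, i.e. <= 3 px at 8 um/px) and high epidermis/dermis contrast;
``target`` (human-like) phantoms have a thick epidermis (> 50 um, >= 7 px) and
reduced contrast.  Wound sessions S1-S3 add a scab cap whose lateral extent
shrinks as healing progresses; ``control`` has none.

Every generated volume carries a :class:`PhantomTruth` with the exact layer
boundaries, class masks and the en-face thickness map they imply.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "make_bscan",
    "make_volume",
    "domain_preset",
    "write_phantom",
    "DOMAINS",
    "SESSIONS",
]

DOMAINS = ("source", "target")
SESSIONS = ("S1", "S2", "S3", "control")


class GeometryError(ValueError):
    """Sampled layer boundaries do not fit in the image."""


@dataclass
class PhantomParams:
    """Full parameterization of a phantom volume.

    Lengths are in pixels unless suffixed ``_um``; reflectivities are mean
    backscatter amplitudes in [0, 1]; ``attenuation_per_px`` is the decay
    rate applied per pixel of depth below the tissue entry row of each
    A-line (air is unattenuated).  ``speckle_shape`` is the gamma shape
    parameter of the multiplicative speckle (mean 1); 0 disables speckle.
    """

    domain: str = "source"
    session: str = "control"
    height: int = 128
    width: int = 128
    pitch_um: float = 8.0
    surface_depth_px: float = 28.0
    surface_amplitude_px: float = 3.0
    surface_corr_px: float = 24.0
    epi_thickness_mean_px: float = 2.5
    epi_thickness_var_px: float = 0.5
    epi_thickness_min_px: int = 1
    epi_thickness_max_px: int | None = 3
    thickness_corr_px: float = 24.0
    scab: bool = False
    scab_thickness_mean_px: float = 2.0
    scab_thickness_var_px: float = 0.5
    scab_extent_frac: float = 0.5
    refl_air: float = 0.02
    refl_scab: float = 0.9
    refl_epidermis: float = 0.75
    refl_dermis: float = 0.35
    attenuation_per_px: float = 0.015
    speckle_shape: float = 4.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom height and width must both be >= 16")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        for name in ("refl_air", "refl_scab", "refl_epidermis", "refl_dermis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.epi_thickness_mean_px < 1:
            raise ValueError("epidermis mean thickness must be >= 1 px")
        if self.scab and self.scab_thickness_mean_px < 1:
            raise ValueError("scab mean thickness must be >= 1 px where present")
        if self.epi_thickness_min_px < 1:
            raise ValueError("epidermis minimum thickness must be >= 1 px")
        if not 0.0 <= self.scab_extent_frac <= 1.0:
            raise ValueError("scab lateral extent fraction must lie in [0, 1]")
        if self.attenuation_per_px < 0 or self.speckle_shape < 0 or self.noise_sigma < 0:
            raise ValueError("attenuation, speckle shape and noise sigma must be >= 0")


@dataclass
class PhantomTruth:
    """Analytic ground truth for a phantom volume.

    ``upper``/``lower`` are per-A-line epidermis boundary rows with ``lower``
    exclusive (the dermal junction row), so thickness = lower - upper.
    ``scab_top`` is the tissue entry row (equals ``upper`` where no scab).
    ``thickness_px`` is the en-face map, shape (width, n_bscans).
    """

    class_masks: np.ndarray  # (n_bscans, H, W) uint8, values {0,1,2}
    upper: np.ndarray  # (n_bscans, W) int
    lower: np.ndarray  # (n_bscans, W) int, exclusive
    scab_top: np.ndarray  # (n_bscans, W) int
    thickness_px: np.ndarray  # (W, n_bscans) int
    pitch_um: float = 8.0

    @property
    def n_bscans(self) -> int:
        return self.class_masks.shape[0]

    @property
    def thickness_um(self) -> np.ndarray:
        return self.thickness_px * self.pitch_um

    def masks_from_boundaries(self) -> np.ndarray:
        """Rebuild the class masks from the boundary rows (consistency check)."""
        n, h, w = self.class_masks.shape
        rows = np.arange(h)[None, :, None]
        upper = self.upper[:, None, :]
        lower = self.lower[:, None, :]
        top = self.scab_top[:, None, :]
        out = np.zeros((n, h, w), dtype=np.uint8)
        out[(rows >= upper) & (rows < lower)] = 1
        out[(rows >= top) & (rows < upper)] = 2
        return out


def _smooth_profile(
    rng: np.random.Generator,
    shape: tuple[int, int],
    corr_lateral: float,
    corr_bscan: float,
    amplitude: float,
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to a target standard deviation.

    Returns a zero-mean (width, n_bscans) field truncated to +-2 amplitudes
    (bounded excursions keep preset geometries feasible); amplitude 0 gives
    zeros (the random draw still happens, keeping the stream layout fixed).
    """
    noise = rng.standard_normal(shape)
    if amplitude == 0:
        return np.zeros(shape)
    f = gaussian_filter(noise, sigma=(max(corr_lateral, 1e-6) / 4.0, corr_bscan), mode="nearest")
    f -= f.mean()
    sd = f.std()
    if sd > 0:
        f *= amplitude / sd
    return np.clip(f, -2.0 * amplitude, 2.0 * amplitude)


def make_volume(params: PhantomParams, n_bscans: int = 16) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a phantom volume and its analytic truth.

    Returns ``(volume, truth)`` with ``volume`` of shape
    (n_bscans, height, width), float32 in [0, 1].  Identical ``params``
    (including seed) give bit-identical output.  Raises
    :class:`GeometryError` if any sampled layer overflows the image,
    naming the offending A-line.
    """
    if n_bscans < 1:
        raise ValueError("n_bscans must be >= 1")
    p = params
    h, w = p.height, p.width
    rng = np.random.default_rng(p.seed)

    surface = p.surface_depth_px + _smooth_profile(
        rng, (w, n_bscans), p.surface_corr_px, 2.0, p.surface_amplitude_px
    )
    thick = p.epi_thickness_mean_px + _smooth_profile(
        rng, (w, n_bscans), p.thickness_corr_px, 2.0, p.epi_thickness_var_px
    )
    scab_thick = p.scab_thickness_mean_px + _smooth_profile(
        rng, (w, n_bscans), p.thickness_corr_px, 2.0, p.scab_thickness_var_px
    )

    upper = np.rint(surface).astype(int).T  # (n_bscans, W)
    t = np.rint(thick).astype(int).T
    t = np.clip(t, p.epi_thickness_min_px, p.epi_thickness_max_px)
    lower = upper + t

    st = np.zeros_like(upper)
    if p.scab:
        st_full = np.clip(np.rint(scab_thick).astype(int).T, 1, None)
        half = int(round(p.scab_extent_frac * w / 2.0))
        c = w // 2
        cols = np.zeros(w, dtype=bool)
        cols[max(0, c - half) : min(w, c + half)] = True
        st = np.where(cols[None, :], st_full, 0)
    scab_top = upper - st

    bad = (scab_top < 0) | (lower > h)
    if bad.any():
        b, x = np.argwhere(bad)[0]
        raise GeometryError(
            f"phantom layers overflow image height {h} at A-line x={x}, B-scan {b} "
            f"(scab top {scab_top[b, x]}, dermal junction {lower[b, x]})"
        )

    rows = np.arange(h)[None, :, None]
    up = upper[:, None, :]
    lo = lower[:, None, :]
    top = scab_top[:, None, :]

    mask = np.zeros((n_bscans, h, w), dtype=np.uint8)
    mask[(rows >= up) & (rows < lo)] = 1
    mask[(rows >= top) & (rows < up)] = 2

    refl = np.full((n_bscans, h, w), p.refl_dermis)
    refl[rows < top] = p.refl_air
    refl[mask == 1] = p.refl_epidermis
    refl[mask == 2] = p.refl_scab

    depth = np.clip(rows - top, 0, None)
    img = refl * np.exp(-p.attenuation_per_px * depth)
    img[rows < top] = p.refl_air  # air is unattenuated

    if p.speckle_shape > 0:
        img = img * rng.gamma(p.speckle_shape, 1.0 / p.speckle_shape, size=img.shape)
    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    truth = PhantomTruth(
        class_masks=mask,
        upper=upper,
        lower=lower,
        scab_top=scab_top,
        thickness_px=t.T.copy(),  # (W, n_bscans)
        pitch_um=p.pitch_um,
    )
    return img, truth


def make_bscan(params: PhantomParams) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a single B-scan; equivalent to a one-B-scan volume."""
    vol, truth = make_volume(params, n_bscans=1)
    return vol[0], truth


_SCAB_EXTENT = {"S1": 0.6, "S2": 0.4, "S3": 0.2}


def domain_preset(
    domain: str,
    session: str,
    *,
    height: int = 128,
    width: int = 128,
    seed: int = 0,
) -> PhantomParams:
    """Parameter preset for a (domain, session) study condition.

    ``source`` presets emulate thin (<= 3 px at 8 um/px), high-contrast
    rodent-like epidermis; ``target`` presets emulate thick (>= 7 px),
    lower-contrast human-like epidermis.  Sessions S1-S3 enable a scab cap
    of decreasing lateral extent; ``control`` disables it.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session!r}; expected one of {SESSIONS}")

    amplitude = max(2.0, height / 48.0)
    scab_mean = 2.0 if domain == "source" else 4.0
    # keep the scab cap above row 0 even at the deepest excursions
    min_surface = int(np.ceil(scab_mean + 2 * 0.5 + 2 * amplitude)) + 1
    kw: dict = dict(
        domain=domain,
        session=session,
        height=height,
        width=width,
        seed=seed,
        surface_depth_px=max(round(0.22 * height), min_surface),
        surface_amplitude_px=amplitude,
        surface_corr_px=width / 5.0,
        thickness_corr_px=width / 5.0,
    )
    if domain == "source":
        kw.update(
            epi_thickness_mean_px=2.5,
            epi_thickness_var_px=0.5,
            epi_thickness_min_px=1,
            epi_thickness_max_px=3,
            refl_epidermis=0.75,
            refl_dermis=0.35,
            scab_thickness_mean_px=2.0,
        )
    else:
        kw.update(
            epi_thickness_mean_px=9.0,
            epi_thickness_var_px=1.5,
            epi_thickness_min_px=7,
            epi_thickness_max_px=12,
            refl_epidermis=0.55,
            refl_dermis=0.40,
            scab_thickness_mean_px=4.0,
        )
    if session in _SCAB_EXTENT:
        kw.update(scab=True, scab_extent_frac=_SCAB_EXTENT[session])
    else:
        kw.update(scab=False)
    return PhantomParams(**kw)


def write_phantom(out_dir: str | Path, volume: np.ndarray, truth: PhantomTruth, params: PhantomParams) -> Path:
    """Write a phantom to disk: 16-bit multi-page TIFF volume, per-B-scan PNG
    label masks (literal pixel values 0/1/2) and a JSON sidecar with the
    boundaries and full params (including the seed) for exact regeneration.
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data16 = np.clip(np.rint(volume.astype(np.float64) * 65535), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        out / "volume.tiff",
        data16,
        photometric="minisblack",
        description=json.dumps({"pitch_um": params.pitch_um}),
    )
    for b in range(truth.n_bscans):
        iio.imwrite(out / f"mask_{b:03d}.png", truth.class_masks[b])
    sidecar = {
        "params": dataclasses.asdict(params),
        "n_bscans": truth.n_bscans,
        "upper": truth.upper.tolist(),
        "lower": truth.lower.tolist(),
        "scab_top": truth.scab_top.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return out
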