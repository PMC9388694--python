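"""Segmentation evaluation: IoU, Dice, ASSD, Hausdorff, cohort reports.

Surface points of a binary mask are its foreground pixels with at least one
background 4-neighbor, with pixels outside the image treated as background
(so the border pixels of a full-foreground mask count as surface).  Surface
distances are Euclidean in isotropic pixel space and scaled to microns by the
axial pixel pitch.  ASSD is the standard symmetric form

    ASSD = (sum_p d(p, S_gt) + sum_q d(q, S_pred)) / (n_pred + n_gt)

and the Hausdorff distance is the larger of the two directed maxima.

Conventions (documented, checked in tests): a pair of empty masks scores
IoU = DSC = 1 and ASSD = HD = 0 (perfect agreement); when exactly one mask is
empty the overlap scores are 0 and the surface distances are undefined
(functions raise; the cohort report records NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

__all__ = [
    "iou",
    "dsc",
    "surface_points",
    "assd",
    "hausdorff",
    "evaluate_cohort",
    "MetricsReport",
]

DEFAULT_PITCH_UM = 8.0
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _as_bool(pred, gt):
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return p, g


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Intersection over union; 1 for a pair of empty masks (convention)."""
    p, g = _as_bool(pred, gt)
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def dsc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A| + |B|); equals 2*IoU/(1+IoU)."""
    p, g = _as_bool(pred, gt)
    total = p.sum() + g.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / total)


def surface_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixel coordinates of a binary mask, row-major order.

    A surface point is a foreground pixel with a background 4-neighbor
    (outside the image counts as background).  Returns an (n, 2) int array
    of (row, col); empty for an empty mask.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    if not m.any():
        return np.empty((0, 2), dtype=int)
    interior = binary_erosion(m, structure=_CROSS, border_value=0)
    return np.argwhere(m & ~interior)


def _surface_distances(pred, gt):
    sp = surface_points(pred)
    sg = surface_points(gt)
    if sp.size == 0 or sg.size == 0:
        raise ValueError("surface distance undefined: one of the masks is empty")
    d_pg = cKDTree(sg).query(sp)[0]
    d_gp = cKDTree(sp).query(sg)[0]
    return d_pg, d_gp


def assd(pred: np.ndarray, gt: np.ndarray, pitch_um: float = DEFAULT_PITCH_UM) -> float:
    """Average symmetric surface distance in microns."""
    p, g = _as_bool(pred, gt)
    if not p.any() and not g.any():
        return 0.0
    d_pg, d_gp = _surface_distances(p, g)
    return float((d_pg.sum() + d_gp.sum()) / (len(d_pg) + len(d_gp)) * pitch_um)


def hausdorff(pred: np.ndarray, gt: np.ndarray, pitch_um: float = DEFAULT_PITCH_UM) -> float:
    """Hausdorff (worst-case) surface distance in microns; symmetric."""
    p, g = _as_bool(pred, gt)
    if not p.any() and not g.any():
        return 0.0
    d_pg, d_gp = _surface_distances(p, g)
    return float(max(d_pg.max(), d_gp.max()) * pitch_um)


@dataclass
class MetricsReport:
    """Cohort evaluation: per-volume rows and per-session summary."""

    per_volume: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


_TARGETS = {
    "foreground": lambda m: m > 0,  # epidermis + scab pooled
    "epidermis": lambda m: m == 1,
    "scab": lambda m: m == 2,
}


def _pair_metrics(pred_stack, gt_stack, pitch_um):
    """Per-B-scan metrics averaged over a volume, per evaluation target."""
    rows = {}
    for target, sel in _TARGETS.items():
        ious, dscs, assds, hds = [], [], [], []
        for pm, gm in zip(pred_stack, gt_stack):
            p, g = sel(pm), sel(gm)
            ious.append(iou(p, g))
            dscs.append(dsc(p, g))
            if p.any() == g.any():  # both empty scores 0; one-sided empty -> NaN
                assds.append(assd(p, g, pitch_um))
                hds.append(hausdorff(p, g, pitch_um))
            else:
                assds.append(np.nan)
                hds.append(np.nan)
        rows[target] = (
            float(np.mean(ious)),
            float(np.mean(dscs)),
            float(np.nanmean(assds)) if not np.all(np.isnan(assds)) else np.nan,
            float(np.nanmean(hds)) if not np.all(np.isnan(hds)) else np.nan,
        )
    return rows


def evaluate_cohort(
    preds: dict,
    gts: dict,
    sessions: dict | None = None,
    pitch_um: float = DEFAULT_PITCH_UM,
) -> MetricsReport:
    """Evaluate paired mask-stack volumes and summarize by session.

    ``preds`` and ``gts`` map volume id -> (n_bscans, H, W) class-mask
    stacks and must have identical keys; ``sessions`` maps volume id ->
    session tag (a single pseudo-session is used when omitted).  Metrics
    are computed per B-scan on the pooled foreground (epidermis + scab)
    and per class, averaged within volumes, then aggregated as
    mean +- sd per (session, target).
    """
    if set(preds) != set(gts):
        missing = set(preds) ^ set(gts)
        raise ValueError(f"unpaired volume ids: {sorted(missing)}")
    sessions = sessions or {}
    records = []
    for vid in sorted(preds):
        pred_stack = np.asarray(preds[vid])
        gt_stack = np.asarray(gts[vid])
        if pred_stack.shape != gt_stack.shape:
            raise ValueError(f"volume {vid}: prediction and truth shapes differ")
        for target, (i, d, a, h) in _pair_metrics(pred_stack, gt_stack, pitch_um).items():
            records.append(
                {
                    "volume_id": vid,
                    "session": sessions.get(vid, "all"),
                    "target": target,
                    "mean_iou": i,
                    "dsc": d,
                    "assd_um": a,
                    "hd_um": h,
                }
            )
    per_volume = pd.DataFrame.from_records(records)
    grouped = per_volume.groupby(["session", "target"], sort=True)
    summary = grouped.agg(
        mean_iou=("mean_iou", "mean"),
        mean_iou_sd=("mean_iou", lambda s: float(np.std(s))),
        dsc=("dsc", "mean"),
        dsc_sd=("dsc", lambda s: float(np.std(s))),
        assd_um=("assd_um", "mean"),
        assd_um_sd=("assd_um", lambda s: float(np.std(s))),
        hd_um=("hd_um", "mean"),
        hd_um_sd=("hd_um", lambda s: float(np.std(s))),
        n=("volume_id", "count"),
    ).reset_index()
    return MetricsReport(per_volume=per_volume, summary=summary)
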