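"""Volume and manifest I/O.

Coordinate convention, fixed project-wide: a B-scan array is (depth row,
lateral column) with row 0 the shallowest; a volume stack is (B-scan index,
depth, width); en-face maps are (lateral column, B-scan index).

Volumes are stored as multi-page TIFF (one page per B-scan, 16-bit) with the
axial pixel pitch in a JSON image description.  Manifests are CSV (one row
per volume: volume_id, domain, session, n_bscans, path, split) with a JSON
sidecar for labeled B-scan indices — diff-able plain text rather than a
database.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("octskin")

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "Manifest",
    "build_manifest",
    "split_train_val",
    "write_provenance",
]

DEFAULT_PITCH_UM = 8.0
MANIFEST_COLUMNS = ["volume_id", "domain", "session", "n_bscans", "path", "split"]


@dataclass
class Volume:
    """An OCT volume: (n_bscans, depth, width) array plus pixel pitch."""

    data: np.ndarray
    pitch_um: float = DEFAULT_PITCH_UM

    @property
    def n_bscans(self) -> int:
        return self.data.shape[0]


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF with pitch metadata.

    Integer data is stored losslessly; float data in [0, 1] is scaled to
    16 bits (documented quantization).
    """
    path = Path(path)
    data = volume.data
    if data.ndim != 3:
        raise ValueError(f"volume data must be 3D (n_bscans, depth, width), got {data.shape}")
    if np.issubdtype(data.dtype, np.floating):
        data = np.clip(np.rint(data.astype(np.float64) * 65535), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps({"pitch_um": volume.pitch_um}),
    )
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a multi-page TIFF volume; pages must share one shape.

    A missing pitch entry falls back to 8 um/px with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = [p.shape for p in tif.pages]
        first = shapes[0]
        for i, s in enumerate(shapes):
            if s != first:
                raise ValueError(
                    f"inconsistent page shapes in {path}: page {i} has {s}, expected {first}"
                )
        data = tif.asarray()
        if data.ndim == 2:
            data = data[None]
        pitch = None
        desc = tif.pages[0].description
        if desc:
            try:
                pitch = json.loads(desc).get("pitch_um")
            except (json.JSONDecodeError, AttributeError):
                pitch = None
    if pitch is None:
        logger.warning("no pitch metadata in %s; assuming %.1f um/px", path, DEFAULT_PITCH_UM)
        pitch = DEFAULT_PITCH_UM
    return Volume(data=data, pitch_um=float(pitch))


@dataclass
class Manifest:
    """Volume listing plus per-volume labeled B-scan indices."""

    table: pd.DataFrame
    labeled_indices: dict = field(default_factory=dict)

    def volumes(self) -> list[tuple[str, int]]:
        return [(str(r.volume_id), int(r.n_bscans)) for r in self.table.itertuples()]

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.table.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".labels.json")
        sidecar.write_text(json.dumps(self.labeled_indices, indent=1))

    @classmethod
    def read(cls, csv_path: str | Path) -> "Manifest":
        csv_path = Path(csv_path)
        table = pd.read_csv(csv_path)
        if "path" in table.columns:
            table["path"] = table["path"].fillna("")
        missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"manifest {csv_path} missing columns {missing}")
        sidecar = csv_path.with_suffix(".labels.json")
        labeled = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(table=table, labeled_indices=labeled)


def build_manifest(volume_specs: list[dict]) -> tuple[Manifest, dict]:
    """Build a manifest from volume specs and compute cohort totals.

    Each spec requires ``volume_id`` and ``n_bscans``; ``domain``,
    ``session``, ``path``, ``split`` and ``n_labeled`` are optional.
    Returns ``(manifest, summary)`` where the summary holds total volumes,
    total images, per-split image counts and the labeled-image total.
    """
    ids = [str(s["volume_id"]) for s in volume_specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate volume ids: {dupes}")
    rows = []
    for s in volume_specs:
        rows.append(
            {
                "volume_id": str(s["volume_id"]),
                "domain": s.get("domain", "source"),
                "session": s.get("session", "control"),
                "n_bscans": int(s["n_bscans"]),
                "path": s.get("path", ""),
                "split": s.get("split", "train"),
            }
        )
    table = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    images_per_split = table.groupby("split")["n_bscans"].sum().to_dict()
    summary = {
        "n_volumes": len(table),
        "total_images": int(table["n_bscans"].sum()),
        "images_per_split": {k: int(v) for k, v in images_per_split.items()},
        "labeled_total": int(sum(int(s.get("n_labeled", 0)) for s in volume_specs)),
    }
    return Manifest(table=table), summary


def split_train_val(
    items: "list | np.ndarray", fraction: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Seeded disjoint, exhaustive train/validation split.

    The training half receives ``ceil(fraction * n)`` items; warns when the
    validation side is left empty by rounding.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty set")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = math.ceil(fraction * len(items))
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:]]
    if not val:
        warnings.warn("validation split is empty after rounding", stacklevel=2)
    return train, val


def write_provenance(path: str | Path, config: dict) -> Path:
    """Record a run's full configuration (seeds included) as JSON."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("octskin")
    except PackageNotFoundError:
        pkg_version = "unknown"
    payload = {"package": "octskin", "version": pkg_version, "config": config}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, default=str))
    return path
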