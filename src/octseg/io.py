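"""Core data types, readers/writers and coordinate conventions.

Axial convention: row 0 is the shallowest pixel (closest to the probe) and
row indices increase with depth.  All boundary positions are 0-based row
indices, stored as floats (sub-pixel positions are permitted after
smoothing).  A layer ``k`` occupies the half-open row interval
``[upper, lower)`` at each column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

#: The five tissue compositions of the atrial wall, in fixed (alphabetical)
#: order.  This ordering is used for confusion matrices and one-vs-rest
#: submodels everywhere.
TISSUE_CLASSES: tuple[str, ...] = (
    "adipose",
    "dense_collagen",
    "fibrotic_myocardium",
    "loose_collagen",
    "normal_myocardium",
)


@dataclass
class BScan:
    """A 2-D OCT cross-section.

    Parameters
    ----------
    intensity : ndarray, shape (depth, width)
        Linear-scale backscattered intensity, indexed ``(z, x)`` with
        ``z`` axial (row) and ``x`` lateral (column).
    axial_um_per_px, lateral_um_per_px : float
        Pixel spacing in micrometres; must be positive.
    id : str
        Free-form identifier (propagated into feature tables).
    """

    intensity: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    id: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D (depth, width) array")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def depth_px(self) -> int:
        return self.intensity.shape[0]

    @property
    def width_px(self) -> int:
        return self.intensity.shape[1]

    @property
    def axial_mm_per_px(self) -> float:
        return self.axial_um_per_px / 1000.0


@dataclass
class BoundarySet:
    """K ordered per-column boundaries; boundary 0 is the tissue surface.

    ``boundaries`` has shape ``(K, n_columns)``; at every column the rows
    satisfy ``boundary_k < boundary_{k+1}`` (each boundary intersects each
    column exactly once, and boundaries never cross).
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.atleast_2d(np.asarray(self.boundaries, dtype=float))
        if self.boundaries.size and not np.all(np.isfinite(self.boundaries)):
            raise ValueError("boundary positions must be finite")
        self.validate()

    def validate(self) -> None:
        b = self.boundaries
        if b.shape[0] >= 2 and not np.all(b[:-1] < b[1:]):
            raise ValueError("boundaries must be strictly increasing with depth at every column")

    @property
    def n_boundaries(self) -> int:
        return self.boundaries.shape[0]

    @property
    def n_columns(self) -> int:
        return self.boundaries.shape[1]


@dataclass
class LayerRegion:
    """One layer of one B-scan: rows ``[upper, lower)`` at each column."""

    bscan_id: str
    upper: np.ndarray
    lower: np.ndarray
    layer_index: int

    def __post_init__(self) -> None:
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper and lower must have equal length")
        if not np.all(self.upper < self.lower):
            raise ValueError("region is empty: upper must be < lower at every column")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean in-layer mask for an image of the given (depth, width)."""
        z = np.arange(shape[0])[:, None]
        up = _rasterize(self.upper)[None, :]
        lo = _rasterize(self.lower)[None, :]
        return (z >= up) & (z < lo)


def _rasterize(positions: np.ndarray) -> np.ndarray:
    """Round half-up to integer rows (the package-wide rasterization rule)."""
    return np.floor(np.asarray(positions, dtype=float) + 0.5).astype(int)


@dataclass
class LabelMap:
    """Per-layer tissue classes over a BoundarySet."""

    labels: list[str]
    pixel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {lab!r}; expected one of {TISSUE_CLASSES}")


# ---------------------------------------------------------------------------
# unit conversions


def px_to_um(value_px, spacing_um_per_px: float):
    """Convert pixels to micrometres (exact linear scaling)."""
    if spacing_um_per_px <= 0:
        raise ValueError("spacing must be positive")
    return np.asarray(value_px, dtype=float) * spacing_um_per_px


def um_to_px(value_um, spacing_um_per_px: float):
    """Convert micrometres to pixels; inverse of :func:`px_to_um`."""
    if spacing_um_per_px <= 0:
        raise ValueError("spacing must be positive")
    return np.asarray(value_um, dtype=float) / spacing_um_per_px


# ---------------------------------------------------------------------------
# volume I/O


def write_volume(bscans: list[BScan], path: str | Path) -> None:
    """Write a stack of B-scans as a multi-page TIFF plus a JSON sidecar.

    The sidecar (``<path>.json``) records pixel spacings and per-page ids;
    reading back without it is an error (no silent spacing defaults).
    """
    path = Path(path)
    stack = np.stack([b.intensity for b in bscans]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {
        "axial_um_per_px": bscans[0].axial_um_per_px,
        "lateral_um_per_px": bscans[0].lateral_um_per_px,
        "ids": [b.id for b in bscans],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_volume(path: str | Path, format: str = "tiff_stack") -> list[BScan]:
    """Read a volume written by :func:`write_volume`.

    Raises
    ------
    FileNotFoundError
        If the TIFF or its metadata sidecar is missing.
    KeyError
        If the sidecar lacks a pixel spacing.
    """
    if format not in ("tiff_stack", "raw+sidecar"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar} not found; pixel spacings are required"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("axial_um_per_px", "lateral_um_per_px"):
        if key not in meta:
            raise KeyError(f"sidecar missing required spacing {key!r}")
    if format == "tiff_stack":
        stack = tifffile.imread(path)
    else:
        stack = np.load(path)
    stack = np.atleast_3d(stack)
    if stack.ndim == 2:
        stack = stack[None]
    ids = meta.get("ids") or [f"bscan{i:04d}" for i in range(stack.shape[0])]
    return [
        BScan(stack[i].astype(float), meta["axial_um_per_px"], meta["lateral_um_per_px"], ids[i])
        for i in range(stack.shape[0])
    ]


# ---------------------------------------------------------------------------
# boundary I/O


def write_boundaries(bs: BoundarySet, path: str | Path) -> None:
    """Write boundaries as CSV: one row per column, one column per boundary."""
    bs.validate()
    df = pd.DataFrame(
        bs.boundaries.T,
        columns=[f"boundary_{k}" for k in range(bs.n_boundaries)],
    )
    df.index.name = "column"
    df.to_csv(path)


def read_boundaries(path: str | Path) -> BoundarySet:
    df = pd.read_csv(path, index_col="column")
    return BoundarySet(df.to_numpy().T)


def write_labels(labels: LabelMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"labels": labels.labels}))


def read_labels(path: str | Path) -> LabelMap:
    return LabelMap(json.loads(Path(path).read_text())["labels"])


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
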