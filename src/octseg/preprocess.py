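"""Denoising, surface detection and flattening.

The tissue surface is found as the axial argmax of (downsampled) A-lines —
in cardiac OCT the endocardial surface is the most hyper-reflective
structure — and the image is flattened by integer per-column shifts so the
surface lies on one common row.  Flattening reduces the axial range the
boundary search has to cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .io import BScan


@dataclass
class SurfaceProfile:
    """Per-column axial position of the tissue surface (real px)."""

    positions: np.ndarray
    method: str = "argmax"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("surface positions must be finite")


@dataclass
class FlattenResult:
    flattened: BScan
    shifts: np.ndarray          # integer shift applied per column (positive = moved down)
    surface_row: int            # common row the surface was aligned to


def denoise(img: BScan, method: str = "median", params: dict | None = None) -> BScan:
    """Denoise a B-scan.

    ``method`` is one of ``{"bm3d", "median", "none"}``.  BM3D is a
    pluggable external denoiser; if the ``bm3d`` package is not installed a
    clear error is raised advising the median fallback — never a silent
    substitution.  The median filter default kernel is 5x5.
    """
    params = dict(params or {})
    if method == "none":
        return BScan(img.intensity.copy(), img.axial_um_per_px, img.lateral_um_per_px, img.id)
    if method == "median":
        size = int(params.pop("size", 5))
        out = median_filter(img.intensity, size=size, mode="reflect")
        return BScan(out, img.axial_um_per_px, img.lateral_um_per_px, img.id)
    if method == "bm3d":
        try:
            import bm3d  # type: ignore
        except ImportError as exc:
            raise RuntimeError(
                "denoise method 'bm3d' requires the optional 'bm3d' package, "
                "which is not installed; use method='median' as a fallback"
            ) from exc
        sigma = float(params.pop("sigma_psd", 0.1))
        out = bm3d.bm3d(img.intensity, sigma_psd=sigma)
        return BScan(np.asarray(out, float), img.axial_um_per_px, img.lateral_um_per_px, img.id)
    raise ValueError(f"unknown denoise method {method!r}")


def detect_surface(img: BScan, downsample_factor: int = 10, outlier_px: float = 3.0,
                   lateral_smooth: int = 15) -> SurfaceProfile:
    """Locate the tissue surface as the per-A-line intensity argmax.

    Columns are retained every ``downsample_factor`` px; on each retained
    A-line the surface is the argmax along depth (ties resolved to the
    shallowest row), and the full-width profile is linear interpolation
    between retained columns.  All-zero A-lines are filled from neighbours
    with a warning.

    Two safeguards make the argmax robust to fully developed speckle
    while keeping it exact on clean images.  A reference argmax is taken
    on a copy averaged over ``lateral_smooth`` neighbouring columns: the
    specular surface is laterally continuous whereas bright speckle
    clusters are not, so averaging leaves the surface as the clear
    maximum.  The raw per-column argmax is kept wherever it agrees with
    this reference within ``outlier_px`` (on noise-free images it always
    does, so detection stays exact) and replaced by the reference where
    it jumped to a speckle cluster.  A median-trend outlier rejection
    pass then replaces any remaining stragglers by interpolation.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    data = img.intensity
    cols = np.arange(0, img.width_px, downsample_factor)
    sub = data[:, cols]
    pos = np.argmax(sub, axis=0).astype(float)
    if lateral_smooth and lateral_smooth > 1 and img.width_px >= lateral_smooth:
        smooth = uniform_filter1d(data, int(lateral_smooth), axis=1, mode="nearest")
        ref = np.argmax(smooth[:, cols], axis=0).astype(float)
        jumped = np.abs(pos - ref) > outlier_px
        pos[jumped] = ref[jumped]

    dead = ~np.any(sub > 0, axis=0)
    if np.any(dead):
        warnings.warn("all-zero A-line(s) encountered; surface filled from neighbours")

    if len(pos) >= 3 and outlier_px > 0:
        # two passes with a wide trend window: speckle outliers can occur
        # in short runs that a narrow single pass would follow
        bad = dead.copy()
        for _ in range(2):
            trend = median_filter(pos, size=min(9, len(pos) | 1), mode="nearest")
            bad = bad | (np.abs(pos - trend) > outlier_px)
            if np.any(bad) and not np.all(bad):
                good = np.flatnonzero(~bad)
                pos[bad] = np.interp(np.flatnonzero(bad), good, pos[good])
    else:
        bad = dead
        if np.any(bad) and not np.all(bad):
            good = np.flatnonzero(~bad)
            pos[bad] = np.interp(np.flatnonzero(bad), good, pos[good])
    if np.all(bad):
        pos[:] = 0.0

    full = np.interp(np.arange(img.width_px), cols, pos)
    return SurfaceProfile(full)


def flatten(img: BScan, surface: SurfaceProfile) -> FlattenResult:
    """Shift each column by an integer so the surface lies on one row.

    The common row is the median of the input surface positions (rounded
    half-up).  Vacated rows are filled with that column's minimum
    intensity.  Shifting only moves values: each A-line's in-frame multiset
    of values is preserved up to rows shifted out of the image.
    """
    pos = surface.positions
    if np.any(pos < 0) or np.any(pos >= img.depth_px):
        raise ValueError("surface positions outside image depth")
    target = int(np.floor(np.median(pos) + 0.5))
    src_rows = np.floor(pos + 0.5).astype(int)
    shifts = target - src_rows
    if np.any(np.abs(shifts) >= img.depth_px):
        raise ValueError("flattening shift would move the entire A-line out of frame")

    depth = img.depth_px
    out = np.empty_like(img.intensity)
    for x in range(img.width_px):
        col = img.intensity[:, x]
        s = shifts[x]
        fill = col.min()
        shifted = np.full(depth, fill)
        if s >= 0:
            shifted[s:] = col[: depth - s] if s else col
        else:
            shifted[: depth + s] = col[-s:]
        out[:, x] = shifted
    flat = BScan(out, img.axial_um_per_px, img.lateral_um_per_px, img.id)
    return FlattenResult(flattened=flat, shifts=shifts, surface_row=target)
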