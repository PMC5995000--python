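"""Greedy per-column boundary search over a three-term cost map.

Each boundary is tracked column by column, starting from the voted initial
point at the centre column and progressing outward to the right and left.
The per-pixel cost rewards a high axial gradient, high intensity and
proximity to the estimated changing points:

    c(x, z) = c1 * g(x, z) + c2 * i(x, z) + c3 * p(x, z),   c1 + c2 + c3 = 1

with default weights (0.56, 0.38, 0.06).  At each new column the boundary
row is the cost argmax within +-delta_z of the previous column's row, so a
boundary intersects every column exactly once and stays smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import BScan, BoundarySet, LayerRegion
from .layers import LayerInfo
from .preprocess import SurfaceProfile

DEFAULT_WEIGHTS = (0.56, 0.38, 0.06)


@dataclass
class SearchParams:
    delta_z: int = 5
    start_column: int | None = None  # None = centre column

    def __post_init__(self) -> None:
        if self.delta_z < 0:
            raise ValueError("delta_z must be >= 0")


@dataclass
class CostMaps:
    g: np.ndarray
    i: np.ndarray
    p: np.ndarray
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        if not (self.g.shape == self.i.shape == self.p.shape):
            raise ValueError("cost maps must share one shape")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def combined(self) -> np.ndarray:
        c1, c2, c3 = self.weights
        return c1 * self.g + c2 * self.i + c3 * self.p


def _rescale01(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def shape_prior(initial_points, depth_px: int, floor: float = 0.1, default_halfwidth: int = 30) -> np.ndarray:
    """Axial shape-prior profile in [0, 1] (broadcast over columns).

    The prior is 1 exactly at each initial boundary point and decays
    linearly with axial distance, reaching its minimum (``floor``) midway
    between adjacent points; it is strictly positive everywhere.  With no
    points the prior is uniformly 1.
    """
    pts = sorted(int(p) for p in initial_points)
    if not pts:
        return np.ones(depth_px)
    z = np.arange(depth_px, dtype=float)
    prof = np.full(depth_px, floor)
    for k, p in enumerate(pts):
        left_gap = (p - pts[k - 1]) / 2 if k > 0 else default_halfwidth
        right_gap = (pts[k + 1] - p) / 2 if k + 1 < len(pts) else default_halfwidth
        left_gap = max(left_gap, 1.0)
        right_gap = max(right_gap, 1.0)
        d = z - p
        tri = np.where(d < 0, 1.0 + d / left_gap, 1.0 - d / right_gap)
        prof = np.maximum(prof, floor + (1.0 - floor) * np.clip(tri, 0.0, 1.0))
    return prof


def build_cost_maps(
    img: BScan,
    layer_info: LayerInfo | None = None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    prior_floor: float = 0.1,
    lateral_smooth: int = 7,
) -> CostMaps:
    """Build gradient, intensity and shape-prior maps from a flattened image.

    ``g`` is the positive part of the axial derivative, ``i`` the raw
    intensity, both min-max rescaled to [0, 1] per image so the printed
    weights are comparable across inputs; ``p`` comes from
    :func:`shape_prior` over the voted initial points.  Because the image
    is flattened, boundaries are locally horizontal, so ``g`` and ``i``
    are averaged over ``lateral_smooth`` neighbouring columns to suppress
    residual speckle without blurring the axial edge (set 1 to disable).
    """
    data = img.intensity
    if lateral_smooth and lateral_smooth > 1:
        data = uniform_filter1d(data, int(lateral_smooth), axis=1, mode="nearest")
    grad = np.gradient(data, axis=0)
    g = _rescale01(np.clip(grad, 0.0, None))
    i = _rescale01(data)
    pts = layer_info.initial_points if layer_info is not None else []
    p = np.broadcast_to(shape_prior(pts, img.depth_px, floor=prior_floor)[:, None], data.shape).copy()
    return CostMaps(g=g, i=i, p=p, weights=tuple(weights))


def search_boundary(cost: np.ndarray, start: tuple[int, int], params: SearchParams) -> np.ndarray:
    """Track one boundary across all columns of a cost map.

    ``start`` is (column, row).  From the start column the search proceeds
    rightward then leftward; at each new column the row is the argmax of
    cost within +-delta_z of the previous column's row (ties resolve to the
    shallower row; windows are clipped at image edges, never wrapped).
    """
    depth, width = cost.shape
    c0, r0 = start
    if not (0 <= c0 < width and 0 <= r0 < depth):
        raise ValueError("start position outside the map")
    rows = np.empty(width, dtype=int)
    rows[c0] = r0
    dz = params.delta_z
    for x in range(c0 + 1, width):
        prev = rows[x - 1]
        lo, hi = max(prev - dz, 0), min(prev + dz + 1, depth)
        rows[x] = lo + int(np.argmax(cost[lo:hi, x]))
    for x in range(c0 - 1, -1, -1):
        prev = rows[x + 1]
        lo, hi = max(prev - dz, 0), min(prev + dz + 1, depth)
        rows[x] = lo + int(np.argmax(cost[lo:hi, x]))
    return rows


def segment_layers(
    img: BScan,
    layer_info: LayerInfo,
    surface: SurfaceProfile,
    params: SearchParams | None = None,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    prior_floor: float = 0.1,
    snap_window: int = 10,
) -> tuple[BoundarySet, list[LayerRegion]]:
    """Search every interior boundary and assemble ordered layer regions.

    One boundary is searched per voted changing point (run independently,
    as the per-layer searches are decoupled); the surface profile enters as
    boundary 0.  Before the column scan each initial point is snapped to
    the cost argmax within ``+-snap_window`` rows at the start column,
    compensating the systematic lag of window-end changing points.  After
    the search, boundaries are clamped so that ``boundary_k + 1 <=
    boundary_{k+1}`` at every column; boundaries that collapse onto their
    neighbour over more than half the columns are merged (layer count
    reduced) with a warning.
    """
    params = params or SearchParams()
    maps = build_cost_maps(img, layer_info, weights=weights, prior_floor=prior_floor)
    cost = maps.combined
    depth, width = cost.shape
    c0 = params.start_column if params.start_column is not None else width // 2

    found = []
    for pt in layer_info.initial_points:
        lo = max(int(pt) - snap_window, 0)
        hi = min(int(pt) + snap_window + 1, depth)
        r0 = lo + int(np.argmax(cost[lo:hi, c0]))
        found.append(search_boundary(cost, (c0, r0), params))

    rows = [np.asarray(surface.positions, dtype=float)]
    for b in found:
        rows.append(b.astype(float))
    # enforce strict ordering by clamping each boundary below its predecessor
    collapsed = []
    for k in range(1, len(rows)):
        clamped = np.maximum(rows[k], rows[k - 1] + 1.0)
        n_clamped = int(np.sum(rows[k] <= rows[k - 1] + 1.0 - 1e-9))
        collapsed.append(n_clamped > width / 2)
        rows[k] = np.minimum(clamped, depth - 1)
    keep = [True] + [not c for c in collapsed]
    if not all(keep):
        warnings.warn("collapsed boundary merged; layer count reduced")
        rows = [r for r, k in zip(rows, keep) if k]
        # re-clamp after the merge
        for k in range(1, len(rows)):
            rows[k] = np.minimum(np.maximum(rows[k], rows[k - 1] + 1.0), depth - 1)

    bset = BoundarySet(np.stack(rows))
    regions = []
    for k in range(bset.n_boundaries):
        upper = bset.boundaries[k]
        lower = bset.boundaries[k + 1] if k + 1 < bset.n_boundaries else np.full(width, float(depth))
        regions.append(LayerRegion(img.id, upper, lower, layer_index=k))
    return bset, regions
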