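"""Layer-count and initial-boundary estimation from averaged A-lines.

In log scale, the intensity of a homogeneous layer decays linearly with
depth (slope -2*mu per unit depth), so an A-line crossing K layers is
approximately piecewise linear with K pieces.  The estimator fits a line
in a sliding window that grows while the fit stays good (RMSD below a
threshold) and records a *changing point* where it breaks; changing points
that are too close are merged and spurious points caused by the bright
surface peak are deleted.  Several averaged A-lines vote on the global
layer count and the initial boundary depths.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import BScan, um_to_px

#: default calibration of the piecewise-fit break criterion (see
#: :func:`piecewise_linear_fit`): threshold = max(RANGE_FACTOR * dynamic
#: range, NOISE_FACTOR * second-difference noise estimate)
RMSD_RANGE_FACTOR = 0.035
RMSD_NOISE_FACTOR = 3.0


@dataclass
class AveragedAline:
    """Log-intensity depth profile averaged over neighbouring columns."""

    values: np.ndarray
    center_column: int
    n_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")


@dataclass
class ChangingPointSet:
    """Sorted changing-point depths of one profile; anchor = profile argmax."""

    points: list[int]
    anchor: int
    n_layers: int

    def __post_init__(self) -> None:
        pts = list(self.points)
        if pts != sorted(pts):
            raise ValueError("points must be sorted")
        if any(p <= self.anchor for p in pts):
            raise ValueError("all changing points must lie deeper than the anchor")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class LayerInfo:
    n_layers: int
    initial_points: list[int]
    votes: list[ChangingPointSet] = field(default_factory=list)


def rmsd(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Root mean square deviation between a profile and its fit."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted must have equal length")
    if observed.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((fitted - observed) ** 2)))


def select_averaged_alines(
    img: BScan,
    n: int = 5,
    spacing_um: float = 200.0,
    avg_width: int = 20,
    log_floor: float = 1e-6,
    axial_smooth: int = 13,
) -> list[AveragedAline]:
    """Pick ``n`` averaged A-lines around the centre of the B-scan.

    Centres are ``spacing_um`` apart (converted to px via the lateral
    spacing), straddling the middle column; each profile is the log of the
    mean of ``avg_width`` neighbouring A-lines (averaging in the linear
    intensity domain suppresses speckle before the logarithm).  The linear
    profile is additionally smoothed by an ``axial_smooth``-px axial moving
    average before the log: a moving average of an exponential decay is an
    exponential with the same rate, so within-layer log-linearity is
    preserved, while speckle residue and periodic texture oscillation (for
    example the adipose honeycomb) are strongly attenuated.
    """
    spacing_px = int(round(float(um_to_px(spacing_um, img.lateral_um_per_px))))
    mid = img.width_px // 2
    centers = [mid + (i - (n - 1) // 2) * spacing_px for i in range(n)]
    span = (n - 1) * spacing_px + avg_width
    while n > 1 and (centers[0] - avg_width // 2 < 0 or centers[-1] + avg_width // 2 >= img.width_px):
        n -= 1
        warnings.warn(f"image too narrow for requested A-line layout; reduced to n={n}")
        centers = [mid + (i - (n - 1) // 2) * spacing_px for i in range(n)]
    out = []
    for c in centers:
        lo = max(c - avg_width // 2, 0)
        hi = min(lo + avg_width, img.width_px)
        lin = img.intensity[:, lo:hi].mean(axis=1)
        if axial_smooth and axial_smooth > 1:
            lin = uniform_filter1d(lin, int(axial_smooth), mode="nearest")
        prof = np.log(np.clip(lin, log_floor, None))
        out.append(AveragedAline(prof, center_column=c, n_averaged=hi - lo))
    return out


def piecewise_linear_fit(
    aline: AveragedAline,
    init_window: int = 10,
    extend_by: int = 3,
    rmsd_threshold: float | None = None,
    anchor_offset: int | None = None,
    anchor: int | None = None,
) -> ChangingPointSet:
    """Sliding-window piecewise linear fit of one averaged A-line.

    The first anchor defaults to the profile argmax (the hyper-reflective
    tissue surface); on a flattened image the caller should pass the known
    common surface row instead, which is robust to bright speckle clusters
    deeper in the tissue.  A line is fitted (ordinary
    least squares) in the window starting at the anchor; while the RMSD is
    below threshold the window grows by ``extend_by`` px, otherwise the
    window end is recorded as a changing point and a new anchor is placed
    one ``init_window`` beyond it.  The number of layers is the number of
    linear pieces.

    ``rmsd_threshold`` defaults to 3.5% of the dynamic range of the profile
    below the anchor (the tissue part; the air region above the surface
    would otherwise inflate the range), floored at 3x a second-difference
    noise estimate of the tissue profile so that texture- and
    speckle-induced oscillation within a layer does not register as a
    slope break.

    The first linear piece starts just below the bright specular surface
    plateau (contiguous rows within 5% of the peak value): the plateau
    belongs to the surface reflection, not to the first layer's decay,
    and would otherwise contaminate the first window's fit.
    """
    v = aline.values
    peak = int(np.argmax(v)) if anchor is None else int(anchor)
    if anchor_offset is None:
        anchor_offset = init_window
    n = v.size
    if n <= init_window:
        raise ValueError("profile shorter than the initial window")
    # the deepest rows of a flattened image may hold fill values from the
    # per-column shifts; exclude them from the analysis domain
    if n >= 60:
        n -= 10
        v = v[:n]

    anchor = peak
    plateau_delta = 0.05 * float(np.ptp(v[peak:]))
    # the specular band is a thin feature: never walk more than a few px
    while anchor + 1 < min(n, peak + 6) and v[anchor + 1] > v[peak] - plateau_delta:
        anchor += 1
    if anchor > peak and anchor + 1 < n:
        anchor += 1

    # truncate at the penetration limit: once the profile has decayed to
    # the detection noise-floor level, slope changes no longer carry layer
    # information (the floor transition itself would register as a break).
    # The floor is recognized by a *flat* tail (|slope| < 0.007 / px over
    # the last 40 px) that sits far below the anchor (a drop of at least
    # 3 log units, ~20x in intensity); a slowly decaying deep layer fails
    # one of the two conditions and is not truncated.
    if n >= 60:
        tail = v[-40:]
        tail_slope = float(np.polyfit(np.arange(tail.size, dtype=float), tail, 1)[0])
        floor_level = float(np.median(v[-15:]))
        if abs(tail_slope) < 0.007 and floor_level < v[anchor] - 3.0:
            crossed = np.flatnonzero(v[anchor:] <= floor_level + 1.5)
            if crossed.size:
                n = max(anchor + int(crossed[0]), anchor + init_window + 1)
                v = v[:n]

    if rmsd_threshold is None:
        tissue = v[anchor:]
        rng = float(np.ptp(tissue))
        sigma = 0.0
        if tissue.size > 4:
            sigma = float(np.median(np.abs(np.diff(tissue, 2))) / (np.sqrt(6) * 0.6745))
        rmsd_threshold = max(RMSD_RANGE_FACTOR * rng, RMSD_NOISE_FACTOR * sigma, 1e-12)
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")

    points: list[int] = []
    x = np.arange(n, dtype=float)

    while anchor + init_window <= n:
        end = anchor + init_window
        while True:
            seg = slice(anchor, end)
            coef = np.polyfit(x[seg], v[seg], 1)
            err = rmsd(v[seg], np.polyval(coef, x[seg]))
            # texture-adaptive floor: the window's own high-frequency noise
            # (second differences) must not register as a slope break
            win_sigma = float(np.median(np.abs(np.diff(v[seg], 2))) / (np.sqrt(6) * 0.6745)) if end - anchor > 4 else 0.0
            if err < max(rmsd_threshold, RMSD_NOISE_FACTOR * win_sigma):
                if end >= n:
                    return ChangingPointSet(points, anchor=peak, n_layers=len(points) + 1)
                end = min(end + extend_by, n)
            else:
                cp = min(end, n - 1)
                points.append(cp)
                anchor = cp + anchor_offset
                break
    return ChangingPointSet(points, anchor=peak, n_layers=len(points) + 1)


def prune_changing_points(
    cps: ChangingPointSet,
    min_sep: int = 30,
    profile: np.ndarray | None = None,
    peak_std_window: int = 10,
    peak_std_factor: float = 1.5,
) -> ChangingPointSet:
    """Merge changing points closer than ``min_sep`` and delete peak artefacts.

    Adjacent pairs closer than ``min_sep`` px are replaced by their midpoint
    (rounded half-down), iterated until stable.  A point within
    ``peak_std_window`` px of the anchor is deleted when the intensity
    standard deviation around the peak-to-point span exceeds
    ``peak_std_factor`` times the standard deviation of the tissue part of
    the profile (below the anchor) — such points are artefacts of the
    bright, highly variable surface peak rather than layer boundaries.
    """
    pts = sorted(cps.points)

    if profile is not None and pts:
        prof = np.asarray(profile, dtype=float)
        tissue_std = prof[cps.anchor:].std()
        half = max(peak_std_window // 2, 1)
        kept = []
        for p in pts:
            if abs(p - cps.anchor) <= peak_std_window:
                lo = max(min(p, cps.anchor) - half, 0)
                hi = min(max(p, cps.anchor) + half + 1, prof.size)
                if prof[lo:hi].std() > peak_std_factor * tissue_std:
                    continue
            kept.append(p)
        pts = kept

    changed = True
    while changed:
        changed = False
        for i in range(len(pts) - 1):
            if pts[i + 1] - pts[i] < min_sep:
                merged = (pts[i] + pts[i + 1]) // 2  # round half-down
                pts = pts[:i] + [merged] + pts[i + 2:]
                changed = True
                break
    return ChangingPointSet(pts, anchor=cps.anchor, n_layers=len(pts) + 1)


def validate_changing_points(
    cps: ChangingPointSet,
    profile: np.ndarray,
    step_window: int = 13,
    min_step: float | None = None,
) -> ChangingPointSet:
    """Keep only changing points accompanied by an upward intensity step.

    Layer interfaces in cardiac OCT appear as transitions into a brighter
    layer (the premise behind the gradient term of the boundary-search
    cost), so the log profile must rise by at least ``min_step`` within
    ``step_window`` px somewhere near a genuine boundary.  Slope breaks
    produced by texture wander inside a layer lack such a step and are
    rejected.  ``min_step`` defaults to 12% of the below-anchor dynamic
    range.
    """
    v = np.asarray(profile, dtype=float)
    n = v.size
    if n >= 60:
        n -= 10          # exclude flattening fill rows at the bottom
        v = v[:n]
    if min_step is None:
        rng = float(np.ptp(v[cps.anchor:])) if cps.anchor < n else 0.0
        min_step = 0.12 * rng
    kept = []
    for p in cps.points:
        lo = max(p - 2 * step_window, cps.anchor)
        hi = min(p + step_window // 2, n - 1)
        best = -np.inf
        for z in range(lo, hi + 1):
            zz = min(z + step_window, n - 1)
            best = max(best, v[zz] - v[z])
        if best >= min_step:
            kept.append(p)
    return ChangingPointSet(kept, anchor=cps.anchor, n_layers=len(kept) + 1)


def vote_layer_info(per_aline: list[ChangingPointSet]) -> LayerInfo:
    """Vote across A-lines for the layer count and initial boundary depths.

    The layer count is the mode of per-A-line counts (ties go to the
    smaller count, favouring under-segmentation); each initial boundary is
    the median of the corresponding changing point across the A-lines that
    voted for the winning count.
    """
    if not per_aline:
        raise ValueError("at least one ChangingPointSet is required")
    counts = Counter(c.n_layers for c in per_aline)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    winners = [c for c in per_aline if c.n_layers == best]
    if best == 1:
        return LayerInfo(1, [], votes=list(per_aline))
    pts = np.array([w.points for w in winners])           # (n_winners, best-1)
    medians = np.median(pts, axis=0)
    initial = [int(np.floor(m + 0.5)) for m in medians]
    return LayerInfo(best, initial, votes=list(per_aline))
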