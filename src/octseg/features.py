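"""Per-layer feature extraction: optical properties, moments and texture.

Sixteen features are computed for each layer region of a B-scan, in fixed
order (see :data:`FEATURE_NAMES`): per-A-line attenuation coefficient and
penetration depth (mean/std over columns), local standard-deviation and
range filter responses (mean/std), histogram entropy, texture-code-number
(TCN) coarseness and homogeneity, GLCM contrast and energy, the distance
from the layer centre to the tissue surface, and the skewness and kurtosis
of the equalized region intensities.  GLCM correlation is also computed
but carried as side metadata, outside the 16-entry vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import binary_erosion, maximum_filter, median_filter, minimum_filter, uniform_filter
from skimage import exposure

from .io import BScan, LayerRegion, _rasterize
from .preprocess import SurfaceProfile

#: Frozen feature order of the per-layer vector.
FEATURE_NAMES: tuple[str, ...] = (
    "att_mean",
    "att_std",
    "pen_depth_mean",
    "pen_depth_std",
    "stdfilt_mean",
    "stdfilt_std",
    "rangefilt_mean",
    "rangefilt_std",
    "entropy",
    "tcn_coarseness",
    "tcn_homogeneity",
    "glcm_contrast",
    "glcm_energy",
    "dist_to_surface",
    "skewness",
    "kurtosis",
)

# eight neighbours in fixed clockwise order starting at the top-left
_NEIGHBOUR_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


@dataclass
class FeatureVector:
    """The 16 per-layer features, plus side metadata (flags, correlation)."""

    values: dict
    flags: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature vector must have exactly the 16 named entries (missing={missing}, extra={extra})")

    def to_array(self) -> np.ndarray:
        return np.array([float(self.values[k]) for k in FEATURE_NAMES])

    def __len__(self) -> int:
        return len(FEATURE_NAMES)


@dataclass
class TcnMap:
    """Per-pixel ternary texture codes and equal-neighbour fractions."""

    codes: np.ndarray         # int codes in [0, 3**8)
    equal_frac: np.ndarray    # per-pixel fraction of neighbours within epsilon
    epsilon: float


# ---------------------------------------------------------------------------
# optical properties


def attenuation_fit(aline_segment: np.ndarray, axial_mm_per_px: float) -> float:
    """Attenuation coefficient (mm^-1) from a log-linear least-squares fit.

    Under the round-trip single-scattering model the detected intensity
    decays as ``exp(-2 mu z)``, so mu is minus half the slope of
    ``log I(z)`` versus depth in mm.
    """
    seg = np.asarray(aline_segment, dtype=float)
    if seg.size < 5:
        raise ValueError("attenuation fit needs a segment of at least 5 samples")
    if np.any(seg <= 0):
        warnings.warn("nonpositive intensities in attenuation segment; offset applied")
        seg = seg + np.finfo(float).eps - min(seg.min(), 0.0)
    z_mm = np.arange(seg.size) * axial_mm_per_px
    slope = np.polyfit(z_mm, np.log(seg), 1)[0]
    return float(-slope / 2.0)


def penetration_depth(aline_segment: np.ndarray, axial_mm_per_px: float) -> tuple[float, bool]:
    """Depth (mm, from segment start) at which intensity first drops to 1/e.

    Linear interpolation between samples; returns ``(depth, reached)`` —
    if the 1/e level is never reached, the full segment length is returned
    with ``reached=False``.
    """
    seg = np.asarray(aline_segment, dtype=float)
    if seg.size == 0:
        raise ValueError("empty segment")
    i0 = seg[0]
    if i0 <= 0:
        return 0.0, True
    target = i0 / np.e
    below = np.flatnonzero(seg <= target)
    if below.size == 0:
        return float((seg.size - 1) * axial_mm_per_px), False
    i = int(below[0])
    if i == 0:
        return 0.0, True
    frac = (seg[i - 1] - target) / (seg[i - 1] - seg[i])
    return float((i - 1 + frac) * axial_mm_per_px), True


# ---------------------------------------------------------------------------
# statistics


def equalize_and_median(img: np.ndarray, median_kernel: int = 3, mask: np.ndarray | None = None) -> np.ndarray:
    """Histogram-equalize (to a uniform target on [0, 1]) then median filter."""
    img = np.asarray(img, dtype=float)
    if np.ptp(img[mask] if mask is not None else img) == 0:
        eq = img.copy()
    else:
        eq = exposure.equalize_hist(img, nbins=256, mask=mask)
    if median_kernel > 1:
        eq = median_filter(eq, size=median_kernel, mode="reflect")
    return eq


def moments(region_values: np.ndarray) -> tuple[float, float]:
    """Skewness and (non-excess) kurtosis; a normal sample gives (0, 3)."""
    v = np.asarray(region_values, dtype=float).ravel()
    if v.size < 3 or np.ptp(v) == 0 or v.std() == 0:
        return 0.0, 3.0
    return float(sps.skew(v)), float(sps.kurtosis(v, fisher=False))


def shannon_entropy(region_values: np.ndarray, bins: int = 256) -> float:
    """Base-2 Shannon entropy of the intensity histogram of the region."""
    v = np.asarray(region_values, dtype=float).ravel()
    if v.size == 0 or np.ptp(v) == 0:
        return 0.0
    counts, _ = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log2(p)))


def local_stat_filters(img: np.ndarray, kernel: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel local standard deviation and local range (max - min) maps."""
    img = np.asarray(img, dtype=float)
    if min(img.shape) < kernel:
        raise ValueError("region smaller than the filter kernel")
    m = uniform_filter(img, size=kernel, mode="reflect")
    m2 = uniform_filter(img * img, size=kernel, mode="reflect")
    std_map = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    range_map = maximum_filter(img, size=kernel, mode="reflect") - minimum_filter(img, size=kernel, mode="reflect")
    return std_map, range_map


# ---------------------------------------------------------------------------
# texture codes and co-occurrence


def tcn_encode(img: np.ndarray, epsilon: float) -> TcnMap:
    """Ternary texture code of each pixel against its eight neighbours.

    Neighbour ``k`` (fixed clockwise order) contributes ``t_k * 3**k`` with
    ``t_k`` = 0 if the neighbour is lower by more than ``epsilon``, 1 if
    within ``epsilon``, 2 if higher by more than ``epsilon``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("TCN needs a region of at least 3x3 pixels")
    padded = np.pad(img, 1, mode="edge")
    codes = np.zeros(img.shape, dtype=np.int64)
    equal_count = np.zeros(img.shape, dtype=np.int64)
    for k, (dz, dx) in enumerate(_NEIGHBOUR_OFFSETS):
        nb = padded[1 + dz : 1 + dz + img.shape[0], 1 + dx : 1 + dx + img.shape[1]]
        diff = nb - img
        t = np.ones(img.shape, dtype=np.int64)
        t[diff < -epsilon] = 0
        t[diff > epsilon] = 2
        codes += t * 3**k
        equal_count += t == 1
    return TcnMap(codes=codes, equal_frac=equal_count / 8.0, epsilon=float(epsilon))


def tcn_stats(tcn: TcnMap, mask: np.ndarray | None = None) -> tuple[float, float]:
    """(coarseness, homogeneity) of the texture-code map within a mask.

    Coarseness is the mean fraction of "within epsilon" neighbours per
    pixel; homogeneity is the sum of squared normalized code-histogram
    frequencies (1 iff one code dominates everywhere).  Only pixels whose
    eight neighbours all lie inside the mask are counted.
    """
    if mask is None:
        mask = np.ones(tcn.codes.shape, dtype=bool)
    valid = binary_erosion(mask, structure=np.ones((3, 3), bool))
    if not np.any(valid):
        valid = mask
    codes = tcn.codes[valid]
    coarseness = float(tcn.equal_frac[valid].mean())
    _, counts = np.unique(codes, return_counts=True)
    h = counts / codes.size
    homogeneity = float(np.sum(h * h))
    return coarseness, homogeneity


def glcm_features(
    region: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = 16,
) -> tuple[float, float, float]:
    """(contrast, energy, correlation) of the symmetric horizontal GLCM.

    Region intensities are quantized to ``levels`` gray levels over the
    in-mask range; co-occurrence uses offset (0, 1) restricted to pixel
    pairs both inside the mask, symmetrized and normalized.  A
    single-level region returns (0, 1, nan).
    """
    region = np.asarray(region, dtype=float)
    if mask is None:
        mask = np.ones(region.shape, dtype=bool)
    vals = region[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return 0.0, 1.0, float("nan")
    q = np.clip(((region - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    left = mask[:, :-1] & mask[:, 1:]
    if not np.any(left):
        raise ValueError("no in-mask horizontal pixel pairs")
    a = q[:, :-1][left]
    b = q[:, 1:][left]
    pm = np.zeros((levels, levels))
    np.add.at(pm, (a, b), 1.0)
    pm = pm + pm.T
    pm /= pm.sum()
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(np.sum((i - j) ** 2 * pm))
    energy = float(np.sum(pm * pm))
    mu_i = np.sum(i * pm)
    mu_j = np.sum(j * pm)
    var_i = np.sum((i - mu_i) ** 2 * pm)
    var_j = np.sum((j - mu_j) ** 2 * pm)
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * pm) / np.sqrt(var_i * var_j))
    return contrast, energy, correlation


# ---------------------------------------------------------------------------
# the per-layer vector


def extract_features(
    img: BScan,
    region: LayerRegion,
    surface: SurfaceProfile,
    glcm_levels: int = 16,
    tcn_epsilon_frac: float = 0.02,
    median_kernel: int = 3,
    att_margin_px: int = 3,
    min_fit_rows: int = 5,
    max_fit_rows: int = 150,
) -> FeatureVector:
    """Compute the 16-entry feature vector for one layer region.

    Per-A-line attenuation and penetration-depth fits use only the rows
    inside the region at each column, skipping the first ``att_margin_px``
    rows below the upper boundary (the specular surface band), capping the
    segment at ``max_fit_rows`` rows (deeper samples approach the system
    noise floor and would bias the log-linear fit) and skipping columns
    with fewer than ``min_fit_rows`` usable rows.  Texture and moment
    features are computed on the histogram-equalized, median-filtered
    region.
    """
    data = img.intensity
    depth, width = data.shape
    upper = _rasterize(region.upper)
    lower = np.minimum(_rasterize(region.lower), depth)

    mus, pens = [], []
    for x in range(width):
        u, l = upper[x] + att_margin_px, min(lower[x], upper[x] + att_margin_px + max_fit_rows)
        if l - u < min_fit_rows:
            continue
        seg = data[u:l, x]
        mus.append(attenuation_fit(seg, img.axial_mm_per_px))
        pens.append(penetration_depth(seg, img.axial_mm_per_px)[0])
    flags = {}
    if not mus:
        flags["optical_fit_failed"] = True
        mus, pens = [0.0], [0.0]
    mus, pens = np.asarray(mus), np.asarray(pens)

    zmin = int(upper.min())
    zmax = int(min(lower.max(), depth))
    crop = data[zmin:zmax, :]
    cmask = region.mask(data.shape)[zmin:zmax, :]
    eq = equalize_and_median(crop, median_kernel=median_kernel, mask=cmask)

    std_map, range_map = local_stat_filters(eq, kernel=3)
    in_vals = eq[cmask]
    ent = shannon_entropy(in_vals, bins=256)
    eps = tcn_epsilon_frac * (float(np.ptp(in_vals)) if in_vals.size else 0.0)
    coarse, homog = tcn_stats(tcn_encode(eq, eps), mask=cmask)
    contrast, energy, correlation = glcm_features(eq, mask=cmask, levels=glcm_levels)
    skew, kurt = moments(in_vals)

    centre = (region.upper + region.lower) / 2.0
    dist_mm = float(np.mean(centre - surface.positions) * img.axial_mm_per_px)

    values = dict(
        att_mean=float(mus.mean()),
        att_std=float(mus.std()),
        pen_depth_mean=float(pens.mean()),
        pen_depth_std=float(pens.std()),
        stdfilt_mean=float(std_map[cmask].mean()),
        stdfilt_std=float(std_map[cmask].std()),
        rangefilt_mean=float(range_map[cmask].mean()),
        rangefilt_std=float(range_map[cmask].std()),
        entropy=ent,
        tcn_coarseness=coarse,
        tcn_homogeneity=homog,
        glcm_contrast=contrast,
        glcm_energy=energy,
        dist_to_surface=dist_mm,
        skewness=skew,
        kurtosis=kurt,
    )
    return FeatureVector(values, flags=flags, metadata={"glcm_correlation": correlation})
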