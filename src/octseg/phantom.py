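"""Synthetic layered-speckle OCT phantoms with exact ground truth.

A phantom B-scan is a stack of tissue layers under a flat, tilted or
sinusoidal surface.  Within layer ``l`` the noise-free intensity at depth
``z`` below the layer top follows the round-trip single-scattering decay

    I(z) = base_l * exp(-2 * mu_l * z_mm) * T_l(z, x)

where ``mu_l`` is the attenuation coefficient (mm^-1) and ``T_l`` a
unit-row-mean texture field (smooth, granular, or a honeycomb pattern of
dark cell interiors with bright septa, emulating adipose tissue).  A 3-px
specular reflection band (intensity 2.0, about twice the brightest tissue)
marks the air-tissue interface: in cardiac OCT the endocardial surface is
the most hyper-reflective structure in the scan, and it must remain so
even after speckle and denoising for surface detection to be meaningful.
Speckle is modelled as unit-mean multiplicative exponential noise (fully
developed speckle in intensity), blended by ``noise_scale``.

Everything is generated from one seeded :class:`numpy.random.Generator`
per B-scan, so phantoms are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .io import BScan, TISSUE_CLASSES

#: Per-class optical/texture presets used by the convenience constructors.
#: base intensity (fraction of the dynamic range), attenuation (mm^-1),
#: texture kind and texture scale (px).  Dense collagen is bright and highly
#: attenuating, adipose is honeycomb-textured and weakly attenuating.
CLASS_PRESETS: dict[str, dict] = {
    "normal_myocardium": dict(base_intensity=0.55, attenuation_mm_inv=2.0, texture="granular", texture_scale_px=2),
    "loose_collagen": dict(base_intensity=0.40, attenuation_mm_inv=1.2, texture="smooth", texture_scale_px=0),
    "dense_collagen": dict(base_intensity=0.90, attenuation_mm_inv=4.0, texture="smooth", texture_scale_px=0),
    "adipose": dict(base_intensity=0.50, attenuation_mm_inv=1.0, texture="honeycomb", texture_scale_px=8),
    "fibrotic_myocardium": dict(base_intensity=0.70, attenuation_mm_inv=3.0, texture="granular", texture_scale_px=5),
}

_TEXTURES = ("smooth", "granular", "honeycomb")
_PROFILES = ("flat", "tilt", "sine")


@dataclass
class LayerSpec:
    """One tissue layer of a phantom."""

    tissue_class: str
    thickness_px: int
    base_intensity: float
    attenuation_mm_inv: float
    texture: str = "smooth"
    texture_scale_px: float = 0.0

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        if self.thickness_px <= 0:
            raise ValueError("thickness_px must be positive")
        if not 0 < self.base_intensity <= 1:
            raise ValueError("base_intensity must be in (0, 1]")
        if not np.isfinite(self.attenuation_mm_inv) or self.attenuation_mm_inv <= 0:
            raise ValueError("attenuation must be finite and positive")
        if self.texture not in _TEXTURES:
            raise ValueError(f"texture must be one of {_TEXTURES}")

    @classmethod
    def from_class(cls, tissue_class: str, thickness_px: int) -> "LayerSpec":
        """Build a layer from the per-class preset table."""
        return cls(tissue_class=tissue_class, thickness_px=thickness_px, **CLASS_PRESETS[tissue_class])


@dataclass
class PhantomConfig:
    """Full description of a phantom volume.

    Default geometry matches a 4 mm x 2.51 mm field of view sampled on an
    800 x 512 (width x depth) grid: 5 um lateral, 4.9 um axial per pixel.
    """

    layers: list[LayerSpec]
    width_px: int = 800
    depth_px: int = 512
    n_bscans: int = 1
    surface_profile: str = "flat"
    surface_amplitude_px: float = 0.0
    surface_depth_px: int = 40
    speckle_on: bool = True
    noise_scale: float = 1.0
    axial_um_per_px: float = 4.9
    lateral_um_per_px: float = 5.0
    surface_reflection: float = 2.0
    noise_floor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one layer is required")
        if self.surface_profile not in _PROFILES:
            raise ValueError(f"surface_profile must be one of {_PROFILES}")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        total = sum(l.thickness_px for l in self.layers[:-1]) + 1
        deepest_surface = self.surface_depth_px + self.surface_amplitude_px
        if deepest_surface + total > self.depth_px:
            raise ValueError(
                f"layers (>= {total} px) exceed image depth below the surface "
                f"({self.depth_px - deepest_surface:.0f} px available)"
            )

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "layers"}
        d["layers"] = [dict(l.__dict__) for l in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["layers"] = [LayerSpec(**l) for l in d["layers"]]
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-column boundary rows and per-layer classes of a phantom.

    ``boundaries`` has shape (K, width): row 0 is the surface, rows 1..K-1
    the interior interfaces; ``labels[k]`` is the class of the layer that
    starts at ``boundaries[k]``.
    """

    boundaries: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.boundaries = np.atleast_2d(np.asarray(self.boundaries))
        if len(self.labels) != self.boundaries.shape[0]:
            raise ValueError("label count must equal interface count")
        if self.boundaries.shape[0] > 1:
            if not np.all(self.boundaries[:-1] < self.boundaries[1:]):
                raise ValueError("boundaries must strictly increase with depth")


# ---------------------------------------------------------------------------


def apply_speckle(image: np.ndarray, noise_scale: float, seed) -> np.ndarray:
    """Multiply an intensity image by unit-mean exponential speckle.

    The field is ``S = 1 + noise_scale * (E - 1)`` with ``E ~ Exp(1)``
    i.i.d., so ``E[S] = 1`` and the expected pixelwise mean is preserved;
    ``noise_scale = 0`` returns the input unchanged and ``noise_scale = 1``
    is fully developed speckle.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("image values must be non-negative")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if noise_scale == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    s = 1.0 + noise_scale * (rng.exponential(1.0, size=image.shape) - 1.0)
    return image * np.clip(s, 0.0, None)


def _surface_rows(config: PhantomConfig, bscan_index: int) -> np.ndarray:
    x = np.arange(config.width_px)
    base = float(config.surface_depth_px)
    a = config.surface_amplitude_px
    if config.surface_profile == "flat" or a == 0:
        prof = np.full(config.width_px, base)
    elif config.surface_profile == "tilt":
        prof = base - a / 2.0 + a * x / max(config.width_px - 1, 1)
    else:  # sine; slow phase drift across B-scans keeps neighbours similar
        phase = 0.05 * bscan_index
        prof = base + a * np.sin(2 * np.pi * x / config.width_px + phase)
    return np.floor(prof + 0.5).astype(int)


def _texture_field(spec: LayerSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    depth, width = shape
    if spec.texture == "smooth" or depth == 0:
        return np.ones(shape)
    if spec.texture == "granular":
        sigma = max(spec.texture_scale_px, 0.5)
        f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
        sd = f.std()
        if sd > 0:
            f *= 0.25 / sd
        field = np.clip(1.0 + f, 0.1, None)
    else:  # honeycomb: jittered hexagonal lattice of dark cells, bright septa
        scale = max(spec.texture_scale_px, 2.0)
        pts = []
        dy = scale * np.sqrt(3) / 2
        row = 0
        y = -scale
        while y < depth + scale:
            offset = (scale / 2) if row % 2 else 0.0
            xs = np.arange(-scale + offset, width + scale, scale)
            jitter = rng.uniform(-0.15 * scale, 0.15 * scale, size=(len(xs), 2))
            pts.append(np.column_stack([np.full(len(xs), y), xs]) + jitter)
            y += dy
            row += 1
        tree = cKDTree(np.concatenate(pts))
        zz, xx = np.mgrid[0:depth, 0:width]
        d, _ = tree.query(np.column_stack([zz.ravel(), xx.ravel()]), k=1)
        field = np.where(d.reshape(shape) < 0.36 * scale, 0.30, 1.35)
    # normalize each row to unit mean so the axial decay of the layer is
    # exactly the configured exponential
    rowmean = field.mean(axis=1, keepdims=True)
    return field / np.where(rowmean > 0, rowmean, 1.0)


def generate_bscan(config: PhantomConfig, bscan_index: int = 0) -> tuple[BScan, GroundTruth]:
    """Generate one phantom B-scan and its exact ground truth."""
    rng = np.random.default_rng([max(config.seed, 0), bscan_index])
    depth, width = config.depth_px, config.width_px
    img = np.full((depth, width), 1e-4)

    surface = _surface_rows(config, bscan_index)
    tops = [surface.copy()]
    for spec in config.layers[:-1]:
        tops.append(tops[-1] + spec.thickness_px)
    boundaries = np.stack(tops)
    if np.any(boundaries[-1] + 1 > depth):
        raise ValueError("layers exceed image depth")

    z = np.arange(depth)[:, None]
    mm = config.axial_um_per_px / 1000.0
    for k, spec in enumerate(config.layers):
        top = boundaries[k][None, :]
        bottom = (boundaries[k + 1][None, :] if k + 1 < len(config.layers) else np.full((1, width), depth))
        mask = (z >= top) & (z < bottom)
        layer_depth = int((bottom - top).max())
        tex = _texture_field(spec, (layer_depth, width), rng)
        decay = spec.base_intensity * np.exp(-2.0 * spec.attenuation_mm_inv * mm * (z - top))
        rel = (z - top).clip(0, layer_depth - 1)
        img[mask] = (decay * np.take_along_axis(tex, rel, axis=0))[mask]
    # specular reflection band (3 px) at the air-tissue interface; the
    # endocardial surface is the most hyper-reflective structure in the scan
    if config.surface_reflection > 0:
        cols = np.arange(width)
        for dz in range(3):
            rows = np.minimum(surface + dz, depth - 1)
            img[rows, cols] = config.surface_reflection

    if config.speckle_on and config.noise_scale > 0:
        img = apply_speckle(img, config.noise_scale, rng)
    # incoherent detection noise floor (~ -30 dB of the surface peak): in
    # real OCT the signal never decays below the system noise level
    if config.noise_floor > 0:
        if config.speckle_on and config.noise_scale > 0:
            img = img + config.noise_floor * rng.exponential(1.0, size=img.shape)
        else:
            img = img + config.noise_floor

    bscan = BScan(
        img,
        axial_um_per_px=config.axial_um_per_px,
        lateral_um_per_px=config.lateral_um_per_px,
        id=f"phantom-s{config.seed}-b{bscan_index:04d}",
    )
    truth = GroundTruth(boundaries.astype(float), [l.tissue_class for l in config.layers])
    return bscan, truth


def generate_volume(config: PhantomConfig) -> tuple[list[BScan], list[GroundTruth]]:
    """Generate ``config.n_bscans`` consecutive B-scans."""
    if config.n_bscans < 1:
        raise ValueError("n_bscans must be >= 1")
    pairs = [generate_bscan(config, i) for i in range(config.n_bscans)]
    return [p[0] for p in pairs], [p[1] for p in pairs]
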