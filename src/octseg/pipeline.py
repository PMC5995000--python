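"""End-to-end orchestration: segment -> features -> classify over volumes.

Per B-scan the pipeline denoises, detects and flattens the surface,
estimates the layer count and initial boundary points from averaged
A-lines, tracks each boundary with the greedy cost search, extracts the
16-entry feature vector per layer, and classifies each layer with the
one-vs-rest RVM.  Volume-level post-processing median-filters each
boundary surface across (B-scan, column) and re-runs feature extraction
and classification on the fine-tuned regions.  Evaluation is leave-one-
group-out with a confusion matrix (rows = truth, columns = predicted).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import median_filter
from sklearn.metrics import confusion_matrix as _sk_confusion

from . import boundary as boundary_mod
from . import features as features_mod
from . import layers as layers_mod
from . import preprocess as preprocess_mod
from .io import BScan, BoundarySet, LabelMap, LayerRegion, TISSUE_CLASSES
from .rvm import RVMClassifier

#: Class -> hue (degrees) for the HSV overlay: gold, yellow, red, blue for
#: dense collagen, loose collagen, normal myocardium and adipose; fibrotic
#: myocardium is rendered magenta.
CLASS_HUES_DEG: dict[str, float] = {
    "dense_collagen": 45.0,
    "loose_collagen": 60.0,
    "normal_myocardium": 0.0,
    "adipose": 240.0,
    "fibrotic_myocardium": 300.0,
}


@dataclass
class RunConfig:
    """All tunable stage parameters, serialized with every output."""

    denoise_method: str = "median"
    denoise_params: dict = field(default_factory=lambda: {"size": 3})
    surface_downsample: int = 10
    layers_n_alines: int = 5
    layers_spacing_um: float = 200.0
    layers_avg_width: int = 20
    layers_init_window: int = 10
    layers_extend_by: int = 3
    layers_rmsd_threshold: float | None = None   # None = adaptive (see layers module)
    layers_min_sep: int = 30
    layers_peak_std_window: int = 10
    layers_peak_std_factor: float = 1.5
    search_delta_z: int = 5
    search_weights: tuple = boundary_mod.DEFAULT_WEIGHTS
    search_prior_floor: float = 0.1
    features_glcm_levels: int = 16
    features_tcn_epsilon_frac: float = 0.02
    features_median_kernel: int = 5
    smooth_kernel: tuple = (3, 5)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["search_weights"] = list(d["search_weights"])
        d["smooth_kernel"] = list(d["smooth_kernel"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "search_weights" in d:
            d["search_weights"] = tuple(d["search_weights"])
        if "smooth_kernel" in d:
            d["smooth_kernel"] = tuple(d["smooth_kernel"])
        return cls(**d)


@dataclass
class SegmentationResult:
    boundaries: BoundarySet
    regions: list[LayerRegion]
    surface: preprocess_mod.SurfaceProfile
    layer_info: layers_mod.LayerInfo
    flattened: BScan
    shifts: np.ndarray


def segment_bscan(img: BScan, config: RunConfig | None = None) -> SegmentationResult:
    """Run preprocessing, layer estimation and boundary search on one B-scan."""
    config = config or RunConfig()
    den = preprocess_mod.denoise(img, method=config.denoise_method, params=config.denoise_params)
    surface = preprocess_mod.detect_surface(den, downsample_factor=config.surface_downsample)
    flat_res = preprocess_mod.flatten(den, surface)
    flat = flat_res.flattened

    alines = layers_mod.select_averaged_alines(
        flat, n=config.layers_n_alines, spacing_um=config.layers_spacing_um,
        avg_width=config.layers_avg_width,
    )
    votes = []
    for al in alines:
        cps = layers_mod.piecewise_linear_fit(
            al, init_window=config.layers_init_window, extend_by=config.layers_extend_by,
            rmsd_threshold=config.layers_rmsd_threshold, anchor=flat_res.surface_row,
        )
        cps = layers_mod.validate_changing_points(cps, al.values)
        votes.append(layers_mod.prune_changing_points(
            cps, min_sep=config.layers_min_sep, profile=al.values,
            peak_std_window=config.layers_peak_std_window,
            peak_std_factor=config.layers_peak_std_factor,
        ))
    info = layers_mod.vote_layer_info(votes)

    flat_surface = preprocess_mod.SurfaceProfile(np.full(flat.width_px, float(flat_res.surface_row)))
    bset, regions = boundary_mod.segment_layers(
        flat, info, flat_surface,
        params=boundary_mod.SearchParams(delta_z=config.search_delta_z),
        weights=tuple(config.search_weights), prior_floor=config.search_prior_floor,
        snap_window=config.layers_init_window,
    )
    return SegmentationResult(bset, regions, flat_surface, info, flat, flat_res.shifts)


def extract_layer_features(
    flat: BScan,
    regions: list[LayerRegion],
    surface: preprocess_mod.SurfaceProfile,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Feature table with one row per layer, 16 feature columns plus ids."""
    config = config or RunConfig()
    rows = []
    for region in regions:
        fv = features_mod.extract_features(
            flat, region, surface,
            glcm_levels=config.features_glcm_levels,
            tcn_epsilon_frac=config.features_tcn_epsilon_frac,
            median_kernel=config.features_median_kernel,
        )
        row = {"bscan_id": flat.id, "layer_index": region.layer_index}
        row.update({k: fv.values[k] for k in features_mod.FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def segment_classify_volume(
    volume: list[BScan],
    model: RVMClassifier,
    config: RunConfig | None = None,
    smooth: bool = True,
) -> tuple[list[BoundarySet], list[LabelMap], pd.DataFrame]:
    """Segment and classify every B-scan of a volume.

    With ``smooth=True`` the boundaries are median-filtered across the
    volume and features/classification are re-run on the fine-tuned
    regions.  Failures on individual B-scans are recorded and skipped.
    """
    config = config or RunConfig()
    seg_results: list[SegmentationResult | None] = []
    for img in volume:
        try:
            seg_results.append(segment_bscan(img, config))
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"segmentation failed on {img.id}: {exc}")
            seg_results.append(None)

    ok = [r for r in seg_results if r is not None]
    if smooth and len(ok) == len(seg_results) and len(ok) > 1:
        n_b = min(r.boundaries.n_boundaries for r in ok)
        smoothed = smooth_3d([BoundarySet(r.boundaries.boundaries[:n_b]) for r in ok],
                             kernel=tuple(config.smooth_kernel))
        for r, bs in zip(ok, smoothed):
            width = bs.n_columns
            depth = r.flattened.depth_px
            r.boundaries = bs
            r.regions = []
            for k in range(bs.n_boundaries):
                upper = bs.boundaries[k]
                lower = bs.boundaries[k + 1] if k + 1 < bs.n_boundaries else np.full(width, float(depth))
                r.regions.append(LayerRegion(r.flattened.id, upper, lower, layer_index=k))

    all_bounds, all_labels, tables = [], [], []
    for r in seg_results:
        if r is None:
            all_bounds.append(None)
            all_labels.append(None)
            continue
        table = extract_layer_features(r.flattened, r.regions, r.surface, config)
        X = table[list(features_mod.FEATURE_NAMES)].to_numpy()
        pred = model.predict(X)
        table = table.assign(predicted_class=pred)
        all_bounds.append(r.boundaries)
        all_labels.append(LabelMap(list(pred)))
        tables.append(table)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return all_bounds, all_labels, table


def smooth_3d(boundaries: list[BoundarySet], kernel: tuple[int, int] = (3, 5)) -> list[BoundarySet]:
    """Median-filter each boundary as a surface over (B-scan, column).

    The ordering invariant (strictly increasing with depth, >= 1 px apart)
    is re-enforced after filtering.
    """
    if not boundaries:
        raise ValueError("at least one BoundarySet required")
    n_b = boundaries[0].n_boundaries
    n_cols = boundaries[0].n_columns
    if any(b.n_boundaries != n_b or b.n_columns != n_cols for b in boundaries):
        raise ValueError("inconsistent boundary stacks")
    kr = min(kernel[0], len(boundaries))
    kc = min(kernel[1], n_cols)
    if (kr, kc) != tuple(kernel):
        warnings.warn(f"smoothing kernel clamped to {(kr, kc)}")
    stacks = [
        median_filter(np.stack([b.boundaries[k] for b in boundaries]), size=(kr, kc), mode="nearest")
        for k in range(n_b)
    ]
    out = []
    for i in range(len(boundaries)):
        rows = [stacks[k][i] for k in range(n_b)]
        for k in range(1, n_b):
            rows[k] = np.maximum(rows[k], rows[k - 1] + 1.0)
        out.append(BoundarySet(np.stack(rows)))
    return out


@dataclass
class ConfusionMatrix:
    """5x5 confusion counts; rows are truth, columns predictions."""

    counts: np.ndarray
    classes: tuple[str, ...] = TISSUE_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be KxK nonnegative counts")

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def loo_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    model_factory=None,
    classes: tuple[str, ...] = TISSUE_CLASSES,
) -> tuple[ConfusionMatrix, float, list[dict]]:
    """Leave-one-group-out evaluation (one group = one heart / one phantom).

    For each group, a fresh classifier is trained on every other group and
    scored layer-wise on the held-out one.  Returns the aggregate confusion
    matrix, its accuracy and per-fold records.  Folds whose test group
    contains a class absent from training still score those layers (as
    errors unless the model happens to be right) and are flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups for leave-one-out")
    model_factory = model_factory or (lambda: RVMClassifier())
    present = [c for c in classes if c in set(y)]
    y_true_all, y_pred_all, records = [], [], []
    for g in uniq:
        test = groups == g
        train = ~test
        missing = sorted(set(y[test]) - set(y[train]))
        if missing:
            warnings.warn(f"fold {g}: classes {missing} absent from training")
        model = model_factory().fit(X[train], y[train])
        pred = model.predict(X[test])
        y_true_all.extend(y[test])
        y_pred_all.extend(pred)
        records.append({
            "group": g,
            "n_test": int(test.sum()),
            "n_correct": int(np.sum(pred == y[test])),
            "missing_classes": missing,
        })
    counts = _sk_confusion(y_true_all, y_pred_all, labels=list(classes))
    cm = ConfusionMatrix(counts, classes=classes)
    return cm, cm.accuracy, records


def hsv_overlay(volume: list[BScan], boundaries: list[BoundarySet], labels: list[LabelMap]) -> np.ndarray:
    """Render classification as colour: class -> hue, intensity -> S and V.

    Pixels above the surface or without a label stay grayscale (saturation
    0).  Returns an (n_bscans, depth, width, 3) float RGB stack in [0, 1].
    """
    out = []
    for img, bset, lmap in zip(volume, boundaries, labels):
        data = img.intensity
        norm = data / data.max() if data.max() > 0 else data
        h = np.zeros_like(norm)
        s = np.zeros_like(norm)
        if bset is not None and lmap is not None:
            z = np.arange(img.depth_px)[:, None]
            for k, lab in enumerate(lmap.labels):
                upper = bset.boundaries[k][None, :]
                lower = (bset.boundaries[k + 1][None, :] if k + 1 < bset.n_boundaries
                         else np.full((1, img.width_px), img.depth_px))
                mask = (z >= upper) & (z < lower)
                h[mask] = CLASS_HUES_DEG[lab] / 360.0
                s[mask] = norm[mask]
        out.append(hsv_to_rgb(np.stack([h, s, np.clip(norm, 0, 1)], axis=-1)))
    return np.stack(out)
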