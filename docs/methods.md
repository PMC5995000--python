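# Methods

This note documents the models behind `octseg`, the parameters that
matter, the synthetic phantoms used for validation, and the design
decisions taken where the design was genuinely open. No empirical claim
here goes beyond what the test suite and `scripts/acceptance.py` compute.

## Image model and conventions

A B-scan is a `(depth, width)` grid of linear-scale backscattered
intensity; row 0 is the shallowest pixel and boundary positions are
0-based row indices. A layer `k` occupies the half-open interval
`[upper, lower)` at each column; sub-pixel boundary positions are
rasterized by rounding half-up. Pixel spacings default to the standard
scan geometry of 5 μm lateral and 4.9 μm axial per pixel (an 800 × 512
B-scan spans 4 mm × 2.51 mm).

Under the round-trip single-scattering model the detected intensity in a
homogeneous layer decays as `I(z) = I₀·exp(−2 μ z)` with attenuation
coefficient μ (mm⁻¹), so the *log* A-line is piecewise linear across a
stack of layers — the premise of both the layer estimator and the
attenuation fit. The package stores linear intensity and takes logarithms
where the model is log-linear; this keeps speckle exactly multiplicative
and unit-mean in the stored domain.

## Phantoms (the validation ground truth)

`octseg.phantom` generates layered media under a flat, tilted or
sinusoidal surface. Per layer: a base reflectivity in (0, 1], an
attenuation coefficient, and a texture field normalized to unit row mean
(so the configured exponential decay is exact in expectation):

| class | base | μ (mm⁻¹) | texture |
|---|---|---|---|
| dense collagen | 0.90 | 4.0 | smooth |
| fibrotic myocardium | 0.70 | 3.0 | granular, 5 px |
| normal myocardium | 0.55 | 2.0 | granular, 2 px |
| adipose | 0.50 | 1.0 | honeycomb, 8 px cells |
| loose collagen | 0.40 | 1.2 | smooth |

These presets encode the qualitative contrast the classifier exploits:
dense collagen is bright and strongly attenuating, adipose is weakly
attenuating with a honeycomb microstructure (dark lipid cell interiors,
bright septa, built from a jittered hexagonal lattice), fibrotic tissue
sits between muscle and dense scar. Three further ingredients make the
phantoms behave like real scans rather than idealized stacks:

- a 3-px **specular surface band** at intensity 2.0 — in cardiac OCT the
  endocardial surface is the most hyper-reflective structure, and it must
  remain so after denoising for argmax surface detection to be possible;
- fully developed **speckle**: i.i.d. unit-mean exponential multiplicative
  noise (`noise_scale` interpolates between none and fully developed);
- an additive detection **noise floor** of 10⁻³ (≈ −30 dB of the surface
  peak): real signal never decays below the system noise level, and
  without it the noise-free log dynamic range would be unphysical.

What the phantoms do *not* emulate: the confocal PSF and sensitivity
roll-off, refraction, blood vessels or other circular inclusions, and
lateral speckle correlation (speckle is pixelwise independent). Passing
the phantom experiments therefore demonstrates the algorithmic chain is
correct and robust to heavy multiplicative noise — not that the specific
accuracy numbers transfer to human tissue.

## Preprocessing

Denoising is pluggable (`bm3d` if installed, median, or none); the
default is a 3×3 median. A 5×5 median suppresses more speckle but
destroys the 3-px specular band (a minority feature inside the kernel),
which breaks surface detection; BM3D, which preserves thin structures,
would not have this trade-off.

Surface detection takes the per-A-line argmax on every 10th column and
interpolates linearly in between. Two safeguards handle fully developed
speckle while keeping clean-image detection exact: a reference argmax on
a 15-column lateral average (the surface is laterally continuous, speckle
clusters are not) replaces raw positions that deviate from it by more
than 3 px, and a two-pass median-trend filter interpolates over any
remaining stragglers. Measured on tilted speckled phantoms the mean
surface error is ≈ 1.2 px with single-column worst cases of ≈ 5 px.

Flattening shifts each column by an integer so the surface lies on the
median surface row; vacated rows are filled with the column minimum.

## Layer-count estimation

Five A-lines, 200 μm apart around the centre column, each the mean of 20
columns, are smoothed axially by a 13-px moving average *in the linear
domain* (a moving average of an exponential is an exponential with the
same rate, so log-linearity is preserved while periodic texture such as
the honeycomb is strongly attenuated) and then log-transformed.

The piecewise-linear fit starts at the known flattened surface row (the
argmax by default), skips the specular plateau (contiguous rows within 5%
of the peak, at most 6 px), and truncates the analysis at the penetration
limit — the depth where the profile reaches a *flat* tail (|slope| <
0.007/px over the last 40 px) lying ≥ 3 log-units below the anchor; the
smooth transition into the noise floor would otherwise register as a
spurious layer. The deepest 10 rows are excluded (they may contain
flattening fill). Windows start at 10 px and grow by 3 px while the OLS
RMSD stays below threshold; the window end is recorded as a changing
point and the next anchor placed 10 px beyond it.

The threshold is the central free parameter, calibrated on phantoms so
that clean in-layer texture passes and genuine slope breaks fail:

    threshold = max(0.035 × dynamic range below the anchor,
                    3 × second-difference noise estimate)

with the noise term also applied per window (median |Δ²|/(√6·0.6745)), so
wiggly texture raises its own bar locally. Candidate changing points are
then *validated*: a genuine interface in this tissue is a transition into
a brighter layer (the same premise as the cost function's positive
gradient term), so a candidate must be accompanied by an upward log-step
of ≥ 12% of the dynamic range within 13 px, else it is rejected as
texture wander. Finally, points closer than 30 px are merged at their
midpoint (rounded half-down), points near the bright surface peak whose
window shows anomalously high variance are deleted, and the layer count
is the mode of the per-A-line counts (ties favour fewer layers); each
initial boundary is the median changing-point depth over the winning
A-lines. A slope-only interface with *no* brightness step would be
rejected by the validation rule — a known limitation, deliberate for this
tissue.

## Boundary search

Cost maps are built from the flattened, denoised image: `g` is the
positive part of the axial derivative, `i` the intensity (both min-max
normalized per image so the weights are comparable across inputs), and
`p` a triangular shape prior equal to 1 at each initial point, decaying
to a floor of 0.1 midway between adjacent points (default half-width
30 px beyond the outermost points). Because the image is flattened,
boundaries are locally horizontal, and `g`/`i` are averaged over 7
neighbouring columns to suppress residual speckle. Weights default to
(0.56, 0.38, 0.06) and must sum to 1.

Each boundary starts from its voted initial point — snapped to the cost
argmax within ±10 rows at the centre column, compensating the systematic
lag of window-end changing points — and is tracked greedily outward with
a ±Δz window (default Δz = 5 px; ties go to the shallower row, windows
clip at edges). Searches for different boundaries run independently;
ordering is restored afterwards by clamping to ≥ 1 px separation, and a
boundary that collapses onto its neighbour over more than half the
columns is merged away with a warning. The greedy scan is locally
optimal by construction; on maps with a unique bright non-crossing path
of bandwidth ≤ Δz it equals an exhaustive dynamic-programming oracle
(property-tested). Across volumes, each boundary surface is median
filtered over (B-scan, column) with a (3, 5) kernel and the regions
re-classified.

## Features

All 16 features are averaged within the layer, giving one vector per
layer. Per-A-line optical fits (attenuation, 1/e penetration depth) use
only in-region rows, skip the top 3 rows (specular band), cap the segment
at 150 rows (deeper samples approach the noise floor and would bias the
log-linear fit) and skip columns with fewer than 5 usable rows. Texture
and moment features are computed on the histogram-equalized (256-bin
uniform target), median-filtered region; the feature-path median kernel
defaults to 5 so that structural texture (8-px honeycomb cells) survives
while single-pixel speckle is suppressed. Entropy uses 256 bins, base-2.
The texture code number assigns each pixel Σ tₖ·3ᵏ over its eight
neighbours (tₖ ∈ {lower, within ε, higher}, ε = 2% of the region range);
coarseness is the mean fraction of "within ε" neighbours and homogeneity
the sum of squared code-histogram frequencies, both over pixels whose
eight neighbours lie inside the region. The GLCM uses 16 gray levels over
the region range, symmetric horizontal offset 1, restricted to in-mask
pixel pairs (hand-vectorized: library co-occurrence routines cannot mask
irregular per-column regions; the implementation is cross-checked against
scikit-image on rectangular regions and against brute-force pair
enumeration). GLCM correlation is computed but carried as metadata — the
classifier input is exactly the 16 named entries, order-frozen.
Kurtosis is non-excess (normal → 3); zero-variance regions return
(0, 3) with a flag.

## Relevance vector machine

Binary model: kernel logistic regression with independent Gaussian priors
`N(wᵢ | 0, αᵢ⁻¹)` over the weights; basis = one RBF kernel function per
training point (width = median pairwise distance of the standardized
training features unless set) plus a bias. Training alternates:

- **Newton (IRLS)** minimization of `E(w) = −log p(c|w) + ½ wᵀA w` with
  damped steps until ‖∇E‖ < 10⁻⁶;
- **Gull–MacKay update** `αᵢ ← γᵢ/wᵢ²`, `γᵢ = 1 − αᵢΣᵢᵢ` with Σ the
  posterior covariance at the mode; γᵢ → 0 (or wᵢ = 0) sends αᵢ to the
  pruning threshold (10¹²) and the basis function is removed.

The outer loop stops when ‖Δw‖ < 10⁻⁴ *and* the log-αs move by < 10⁻²
with no pruning (weights alone can stabilize while αs are still
diverging), or after 500 iterations; a final Newton polish makes the
stored weights the posterior mode under the final αs (‖∇E‖ ≈ 10⁻¹²,
exposed as `grad_norm_`). Initialization is αᵢ = 1, w = 0; training is
deterministic given the data. The MacKay fixed point maximizes a
Laplace-approximate evidence: on a 12-point single-basis toy it lands
within ~25% of the exact-quadrature evidence maximizer (both far from
pruning), which is the expected quality of the approximation, while the
Newton mode itself matches an independent BFGS optimizer to 10⁻⁶.

Multiclass uses one-vs-rest submodels; the prediction is the class of
highest probability, ties resolving to the first class in sorted order.
Features are standardized per training fold. On two-class separable
blobs (n = 200) the leave-one-out accuracy is 100% with 1–3% of training
points retained as relevance vectors.

## Evaluation protocol and problem sizes

Segmentation experiments run at the full 800 × 512 geometry: 3-layer
phantoms for boundary error (20 seeds; mean |estimated − true| per
interior boundary, count mismatches penalized by nearest-match distance)
and K ∈ {2, 3, 4} arrangements rotating through a class cycle chosen so
every interface is an upward log-step, for the layer-count vote.

The end-to-end experiment uses 20 groups (one phantom each, emulating
leave-one-heart-out), 400 × 360 px, three layers per phantom rotating
through the five classes; each automatically segmented layer becomes one
sample labelled with the majority ground-truth class of its region, and a
fresh RVM is trained per held-out group. The reduced geometry keeps the
full experiment (segmentation + 20 × 5 RVM fits) to a few minutes on one
CPU; boundary accuracy is insensitive to width here because the A-line
averaging and search operate identically.

The shuffled-label control permutes labels uniformly and averages the
leave-one-group-out accuracy over 10 permutations. Note that this
baseline is systematically a little *below* the nominal 1/5: with no
signal the one-vs-rest models predict near-constant classes, and the
training-majority class is anti-correlated with the held-out fold's label
counts (training counts are 12 − test counts per class). Measured values
are 11–13% versus 93–98% for true labels.

## Numerical details and degenerate inputs

- OLS line fits use `numpy.polyfit`; RMSD is √(mean squared residual).
- Argmax ties resolve to the shallowest row throughout.
- Merged changing-point midpoints round half-down; rasterization
  elsewhere rounds half-up.
- Empty initial-point sets give a uniform shape prior of 1; Δz = 0
  degenerates the search to a constant row.
- All-zero A-lines are filled from neighbours with a warning; nonpositive
  intensities in an attenuation segment are offset by machine epsilon
  with a warning; single-level regions return GLCM (0, 1, NaN-flagged).
- Phantom randomness flows through one seeded generator per B-scan
  (`seed`, `bscan_index`); pipelines and experiments are deterministic
  given their seeds.

## Known limitations

- The changing-point validation assumes boundaries are transitions into
  brighter layers; purely attenuation-contrast interfaces are found only
  if the boundary search's gradient/intensity terms pick them up from a
  nearby initial point.
- The median-filter fallback is much weaker than BM3D; surface detection
  compensates with lateral averaging, at the cost of ~1 px mean error
  under heavy speckle.
- Layer counts are global per B-scan (as designed); laterally
  disappearing layers are not modelled.
- Phantom texture statistics are stylized; feature distributions on real
  tissue will differ, and the classifier must be retrained per instrument
  and preprocessing chain.
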