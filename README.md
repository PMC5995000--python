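# octseg

Automated layer segmentation and tissue classification for optical
coherence tomography (OCT) B-scans of cardiac (atrial) tissue.

Catheter-based OCT can image the first 1–2 mm of the atrial wall during
ablation procedures, but interpreting the images requires knowing which
tissue composition each depth layer is: normal myocardium, loose or dense
collagen, adipose tissue, or fibrotic (scarred) myocardium. `octseg`
implements a fully automated pipeline that needs no prior structural
knowledge of the wall:

1. **Preprocess** — denoise each B-scan, find the tissue surface as the
   per-A-line intensity argmax (the endocardial surface is the most
   hyper-reflective structure), and flatten the image by per-column shifts.
2. **Layer information estimation** — average A-lines around the image
   centre (5 profiles, 200 μm apart, 20 columns each) and fit each
   log-intensity profile with a sliding-window piecewise-linear model: a
   window grows while the fit RMSD stays below threshold and records a
   *changing point* where it breaks. A voting scheme over the profiles
   fixes the global layer count and the initial boundary depths.
3. **Boundary search** — track each boundary column-by-column, outward
   from the centre, choosing at each column the row that maximizes

   `c(x, z) = c₁·g(x, z) + c₂·i(x, z) + c₃·p(x, z)`,  `c₁+c₂+c₃ = 1`

   within ±Δz of the previous column's row, where `g` is the positive
   axial gradient, `i` the intensity and `p` a shape prior around the
   changing points (default weights 0.56 / 0.38 / 0.06).
4. **Features** — for every layer, a 16-entry vector: attenuation
   coefficient μ (mm⁻¹, from the log-linear single-scattering fit
   `I(z) ∝ e^{−2μz}`) and 1/e penetration depth (mean/std over A-lines);
   local std- and range-filter statistics; histogram entropy;
   texture-code-number coarseness and homogeneity; GLCM contrast and
   energy (16 gray levels); distance of the layer centre to the surface;
   skewness and kurtosis.
5. **Classification** — a sparse Bayesian (relevance vector machine)
   classifier, `p(c=1|x) = σ(Σᵢ wᵢ φᵢ(x))` with per-weight Gaussian priors
   `N(wᵢ|0, αᵢ⁻¹)`, trained by alternating Newton weight updates with
   Gull–MacKay evidence updates of αᵢ; one-vs-rest over the five classes.
   The estimators follow the scikit-learn API and compose with sklearn
   pipelines and model selection.

Because no public dataset pairs cardiac OCT with histology ground truth,
the package ships a first-class **phantom generator**: layered speckle
images with per-layer exponential decay, class-specific textures
(including a honeycomb pattern for adipose tissue), a specular surface
band, fully developed multiplicative speckle and a detection noise floor —
with exact per-column boundary and per-layer class ground truth. All
validation numbers are measured against these phantoms.

## Worked example

```python
import numpy as np
from octseg import experiments, pipeline, rvm

# a speckled 3-layer phantom at the standard 800 x 512 scan geometry
cfg = experiments.three_layer_config(seed=1, speckle=True)
from octseg.phantom import generate_bscan
bscan, truth = generate_bscan(cfg)

res = pipeline.segment_bscan(bscan)
est = experiments.boundaries_to_original(res.boundaries, res.shifts)
err = np.abs(est[1:] - truth.boundaries[1:]).mean()
print(res.layer_info.n_layers, round(err, 2))
```

prints

```
3 2.06
```

— the vote recovered the true 3 layers, and the two interior boundaries
were located with a mean absolute error of 2.06 px (≈ 10 μm at 4.9 μm per
pixel) under fully developed speckle.

```python
r = experiments.end_to_end_experiment(n_groups=20, base_seed=1)
print(round(100 * r["accuracy"], 2))
```

prints `98.33`: leave-one-phantom-out classification of the automatically
segmented layers into the five tissue classes is 98.3% accurate on this
set of 60 layers.

The command-line interface mirrors the library:

```
octseg simulate --config phantom.yaml --out sim/
octseg segment  --volume sim/volume.tiff --out seg/
octseg features --volume sim/volume.tiff --out features.csv
octseg train    --features labelled.csv --out model.json
octseg classify --volume sim/volume.tiff --model model.json --out out/
octseg evaluate --features labelled.csv --out eval/
octseg render   --volume sim/volume.tiff --labels out/labels.json \
                --boundaries out/ --out overlay.tiff
```

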