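# residuemap

Pixel classification of **crop-residue cover types** in high-resolution
multispectral imagery, built around multi-scale wavelet feature fusion.

After corn harvest, fields carry residue in visually distinct patterns:
straw stacked in alternating bright/dark rows (Type 1), homogeneous bright
straw mats left by combine harvesters (Type 2), and dark stubble where the
straw was removed (Type 3); everything else (roads, buildings, forest) is
"other".  Mapping these types from ~1 m imagery is how conservation-tillage
compliance is monitored at regional scale.  The difficulty is
*intra-object heterogeneity*: at 1 m resolution a single Type 1 field spans
nearly the full digital-number range, so its pixel spectra overlap both the
bright and the dark classes and spectral-only classifiers produce
salt-and-pepper maps.

`residuemap` addresses this with per-pixel **multi-scale texture features**:

1. **PCA** of the *d* spectral bands, `X = A Z`, where the rows of `A` are
   the eigenvectors of the band covariance; the first component image
   (PC1) typically carries > 90 % of the variance and all spatial detail.
2. For every pixel, neighborhood windows of side `w = 2^M`
   (`w ∈ {2, 4, …, 64}`) centered on it are decomposed `M` levels with a
   separable periodized 2-D discrete wavelet transform (db3).  The four
   final-level coefficients — approximation `A_M` and details
   `H_M, V_M, D_M` — are fused into one value per pixel (largest absolute
   coefficient by default), giving feature images `B_ms2 … B_ms64` that
   compress ever larger neighborhoods into single numbers and so attenuate
   within-field heterogeneity.
3. **Gini importance** (normalized mean decrease in impurity over repeated
   random-forest fits) ranks the 11 candidate layers
   (4 bands + PC1 + 6 multi-scale); nested subsets grown in ranking order
   are compared on validation Kappa to pick the optimal image dataset.
4. Five classifiers share one train/predict interface: Gaussian naive
   Bayes, random forest, RBF support-vector machine, and two
   one-dimensional convolutional networks — a plain 1D-CNN and the
   channel-attention **1D-CNN_CA**, which gates each of the 512
   convolution channels with
   `M(F) = σ(MLP(avgpool F) + MLP(maxpool F))`, `F_c = M(F) ⊗ F`.
5. **Connected-domain calibration** deletes small 4-connected components
   (default < 60 pixels, class order Type 2 → Type 3 → Type 1) from the
   predicted map, absorbing them into the dominant adjacent class.
6. Accuracy is assessed by confusion matrix, overall accuracy
   `OA = Σ p_ii / N`, and chance-corrected agreement
   `Kappa = (OA − P_k) / (1 − P_k)` with `P_k = Σ row_i·col_i / N²`.

Because real field campaigns and satellite acquisitions are rarely
shareable, the package includes a **synthetic scene generator** that
reproduces the statistical structure of residue scenes (per-class gray
ranges, stripe textures, band correlation) so the entire pipeline is
testable end to end.

## Worked example

```python
from residuemap import (
    generate_scene, generate_sample_set, build_feature_stack,
    fit_pca, variance_contributions, train_classifier, predict_map,
    calibrate_map, evaluate, OID_FEATURES,
)
from residuemap.synthetic_scene import overlap_scene_spec

# a 256x256 synthetic scene whose classes overlap spectrally
image, truth = generate_scene(overlap_scene_spec(size=(256, 256), seed=1))
samples = generate_sample_set(truth, n_per_class=500, seed=1)

contrib = variance_contributions(fit_pca(image))
print(f"PC1 variance contribution: {100 * contrib[0]:.2f}%")

stack = build_feature_stack(image)           # bands + PC1 + B_ms2..B_ms64
train, val = samples.train, samples.validation
sub = stack.subset(OID_FEATURES)             # 4 bands + B_ms4..B_ms64
X = sub.sample_table(train["row"].to_numpy(), train["col"].to_numpy())
model = train_classifier("svm", X, train["label"].to_numpy(),
                         feature_names=OID_FEATURES, seed=1)
raw_map, timing = predict_map(model, sub)
calibrated = calibrate_map(raw_map)          # threshold 60 px, order 2-3-1

vr, vc = val["row"].to_numpy(), val["col"].to_numpy()
for tag, cmap in (("raw", raw_map), ("calibrated", calibrated)):
    rep = evaluate(val["label"].to_numpy(), cmap.labels[vr, vc])
    print(f"{tag:>10}: Kappa = {100 * rep.kappa:.2f}%  OA = {100 * rep.oa:.2f}%")
```

Output:

```
PC1 variance contribution: 98.67%
       raw: Kappa = 86.89%  OA = 90.17%
calibrated: Kappa = 88.67%  OA = 91.50%
```

PC1 concentrates almost all image variance, the fused stack classifies a
scene whose single-pixel spectra are ambiguous, and calibration removes
speckle and lifts both agreement scores.

## Command line

```bash
residuemap simulate --size 512 --seed 0 --samples-per-class 500 --out scene/
residuemap features --input scene/scene.tif --out scene/features.tif
residuemap select   --features scene/features.tif --samples scene/samples.csv \
                    --report scene/selection.json
residuemap classify --method svm --features scene/features.tif \
                    --samples scene/samples.csv --out scene/map.tif
residuemap calibrate --map scene/map.tif --threshold 60 --order 2,3,1 \
                     --out scene/map_cal.tif
residuemap evaluate --map scene/map_cal.tif --samples scene/samples.csv \
                    --report scene/metrics.json
residuemap run      --out scene_run --seed 0 --method svm   # everything at once
```

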