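# Methods

This note records the models, conventions and numerical choices behind
`residuemap`, in the order the pipeline applies them.

## Principal component analysis

The band covariance is estimated over all valid (non-nodata) pixels as a
population covariance of the raw digital numbers — bands are mean-centered
but **not** standardized, since the four bands of the target imagery share
one radiometric scale.  Eigenvalues are clamped at zero (round-off can
produce tiny negative values for rank-deficient inputs; constant bands are
legal and simply contribute zero variance).  Eigenvector sign is not
determined by the decomposition, so each rotation row is flipped to make
its largest-magnitude entry positive; results are then reproducible across
linear-algebra backends.  The variance contribution of component *i* is
`λ_i / Σ λ`, reported as a fraction.

PC1 is min-max rescaled to [0, 255] before wavelet processing.  The raw
projection's scale depends on scene contrast; pinning it to the
digital-number range makes the windowed features comparable across scenes.
A constant image (degenerate PC1) rescales to all zeros.

## Multi-scale wavelet features

For window side `w = 2^M` the window is decomposed exactly `M` levels with
the separable 2-D DWT: rows are filtered and downsampled first, then
columns, recursively on the approximation sub-image.  Conventions:

- **Wavelet**: db3 (6-tap, 3 vanishing moments) by default; any orthonormal
  PyWavelets basis can be selected.
- **Within-window boundary**: periodization.  db3's filters are longer than
  the smallest windows, and periodization is the only standard mode in
  which a `2^M` window yields exactly 1×1 sub-bands after `M` levels — a
  prerequisite for "one window → one coefficient".  At `w = 2` the
  periodized 6-tap filter wraps the two samples; this is accepted and
  documented rather than special-cased to a Haar filter.
- **Image edge**: the component image is reflect-padded before windows are
  cut.  Consequently the image must be larger than `w/2` pixels per side.
- **Window anchor**: even windows have no center pixel; the anchor sits at
  position `(w/2, w/2)` inside its window (bottom-right of center).
- **Fusion**: `maxabs` (default) keeps the final-level coefficient of
  largest absolute value among `{A_M, H_M, V_M, D_M}`, with its sign; ties
  resolve in that fixed order.  `approx` keeps `A_M`.  For non-negative
  imagery `A_M` usually dominates, so the two rules often coincide; both
  are exposed and recorded in layer provenance.

**Vectorization.**  With periodized boundaries the four final-level
coefficients are linear functionals of the window, and by separability each
is an outer product of two length-`w` equivalent 1-D filters (the `M`-level
low-pass cascade and the coarsest high-pass cascade).  The sliding-window
extractor therefore computes four cross-correlations of the padded image
with these `w × w` kernels — algebraically identical to decomposing every
window independently (the tests verify agreement with a naive per-pixel
filter bank to 1e-9) but hundreds of times faster.

**Scales.**  Raw coefficients carry the orthonormal gain `2^M` (a constant
image `c` maps to `c·2^M`).  Two consequences:

- Layers placed in a feature stack are standardized to zero mean / unit
  variance (flagged in provenance), so classifiers see comparable ranges.
- The heterogeneity diagnostic (`heterogeneity_profile`, `block_variance`)
  uses the *mean scale* — coefficient divided by `2^M`, i.e. approximately
  the window mean.  On the raw scale the `4^M` variance gain would swamp
  the signal; on the mean scale the overall variance of `B_ms2 … B_ms64`
  decreases monotonically on striped scenes, which is the package's
  quantitative statement of "larger windows attenuate intra-object
  heterogeneity".

## Feature selection

Gini importance is the normalized mean decrease in impurity from
`RandomForestClassifier`, averaged over ten independent fits with
consecutive seeds (repeats and seed configurable); importances are
re-normalized to sum to one.  The subset search grows nested subsets in
ranking order, adds any explicitly configured trials (the spectral-only
baseline and spectral + PC1 are always tried by the pipeline), trains the
evaluation classifier on the train split, and scores validation Kappa.
Ties prefer the smaller subset, then lexicographic names.  The evaluation
classifier defaults to a 200-tree forest — fast and of the same family as
the importance estimator — and is swappable via a factory argument; the
published forest sizes remain the defaults of the user-facing trainers.

## Classifiers

- **NB**: Gaussian, maximum-likelihood priors.
- **RF**: 1,411 trees / depth 281 / `sqrt` features for the fused optimal
  dataset; 1,091 / 381 / `auto` for the spectral-only variant.  The legacy
  `auto` string is preserved in the configuration and translated to `sqrt`
  (its historical meaning for classifiers) when the estimator is built.
- **SVM**: RBF kernel, `C = 510.0`, `gamma = 'scale'`, explicit one-vs-rest
  multi-class wrapping.
- **1D-CNN / 1D-CNN_CA**: implemented as a numpy layer stack (forward and
  backward passes hand-derived; Adam optimizer; softmax cross-entropy).
  The input feature vector is treated as a length-`n_f` sequence with one
  channel.  Layer widths follow the published table: 512 conv filters,
  flatten to `n_f × 512`, dropout 0.4, dense 2048 → 1024 → `n_class`.
  Choices the published table leaves open: conv kernel 3 with zero
  same-padding (keeps the length axis at `n_f`); Adam at the printed
  initial rate 0.01 with no schedule; attention bottleneck ratio 8 with a
  ReLU hidden layer and the MLP shared between the average- and max-pooled
  paths, their outputs **added** before the sigmoid (the standard
  channel-attention formulation).  Disabling attention is exactly
  equivalent to forcing the gate to 1 (verified at logit level).
  A `NetworkConfig.fast()` preset (64 filters, 256/128 dense, 30 epochs)
  exists for quick experiments; the test suite uses it, full widths remain
  the defaults.

Feature scaling: NB and RF receive raw digital numbers; SVM and the
networks receive features standardized with train-split statistics stored
in the model.  All stochastic fits are seeded; two fits with one seed give
identical predictions.

## Connected-domain calibration

Components are maximal 4-connected (optionally 8-connected) same-class
regions, labeled deterministically in raster-scan order.  For each class in
the configured order (default Type 2 → Type 3 → Type 1, threshold 60
pixels), every component smaller than the threshold is deleted and its
pixels reassigned to the majority class among the component's adjacent
pixels; ties go to the class with the larger adjacent component, then the
lower class id.  Later classes see earlier reassignments.  Nodata (0) is
never created, consumed, or used as a reassignment target; a component
bordered only by nodata is left in place.  The "other" class is not cleaned
by default.  Reassignment can only grow other classes' components, so a
single pass is idempotent; `until_stable` repeats the pass until no change,
after which no ordered class retains a sub-threshold component.

## Accuracy assessment

`OA = trace / N`; `P_k = Σ row_i·col_i / N²`; `Kappa = (OA − P_k)/(1 − P_k)`.
Kappa is undefined when a single cell holds all mass (`P_k = 1`) and raises.
Time cost is wall-clock seconds around the prediction call; it is reported
in metrics output but never asserted, being hardware-dependent.

## Synthetic scenes

The generator emulates the statistical structure of residue-covered
fields, not their radiometry.  Patches tile the grid (default: a 4×4 block
layout cycling the four classes on a 512×512 grid); each class has a gray
range and texture: Type 1 alternating bright/dark rows spanning 0–250
(stripe period 3 px by default), Type 2 homogeneous bright within 130–255,
Type 3 homogeneous dark within 25–175, "other" wide-range speckle.  All
bands share one latent texture with near-unity per-band gains/offsets plus
independent Gaussian noise (default sd 8 DN, clipped to [0, 255]), which
concentrates > 90 % of variance in PC1 as in real four-band imagery.  Small
class-specific band offsets give the spectral bands genuine but imperfect
discriminative power.

`overlap_scene_spec` is the stress configuration for feature-fusion
experiments: the bright and dark classes drift smoothly across their full
(mutually overlapping) ranges, the striped class spans both, and no
class-specific band signature is applied — single-pixel spectra are then
ambiguous and only neighborhood texture separates the classes.

What the scenes do **not** model: sensor PSF and pan-sharpening artifacts,
atmospheric and illumination gradients, mixed pixels at field boundaries,
irregular field geometry, and within-class spectral trends from soil or
residue moisture.  Passing tests therefore demonstrate correctness of the
algorithms and the direction of the methodological effects (fusion benefit,
heterogeneity attenuation, calibration denoising), not accuracy levels
attainable on real acquisitions.

## Problem sizes

The test suite and the acceptance script favor sizes that keep full runs in
the minutes range on one core: 256×256 scenes with 500 labeled pixels per
class (stratified 7:3) for classification experiments, a 512×512 scene for
the variance-attenuation diagnostic, the fast network preset for trained
networks, and oracle comparisons on 64×64 images.  All sizes are arguments,
not constants; the defaults above are the package's chosen experiment
scale.

## Known limitations

- GeoTIFF support covers north-up affine geotransforms, a single nodata
  sentinel and band-name metadata; rotated geotransforms, CRS definitions
  and tiled/windowed access of larger-than-memory scenes are out of scope.
- The per-pixel sliding-window features are dense: every pixel owns six
  windows.  The kernel-correlation implementation makes this cheap up to a
  few thousand pixels per side; truly large scenes would need tiling.
- The numpy networks run on CPU only and train the full-width published
  configuration slowly; they are faithful, not fast.
- `block_variance` drops trailing partial blocks, matching the block-count
  convention of square scenes divisible by the block size.
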