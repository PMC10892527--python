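# Methods

## Problem and scope

`hsiclass` classifies each pixel of a drone-borne hyperspectral reflectance
cube (400–1000 nm) into grassland-degradation indicator classes — a dominant
grass community (*Stipa breviflora*), a drought-stressed indicator community
(*Artemisia frigida*) and non-vegetation (withered grass / bare soil) — and
assesses the result with the standard remote-sensing accuracy measures.  The
classifier at its core is a dual-branch spectral/spatial 3-D residual network
(3D_RNet-O); a 2-D residual baseline (DGRNet) and a plain 3-D residual
network (3D_DGRNet) are provided for comparison.  The original field data are
not publicly deposited, so a parametric scene simulator provides data with
the same statistical structure, and all learning claims in the test suite are
made against that simulator's stated world.

## Pipeline

1. **Scene assembly** (`hsiclass.data`). ENVI header + flat-binary cubes
   (BSQ/BIL/BIP read, BSQ written), center cropping with ties broken toward
   the top-left, row-major stitching of equal quadrat tiles, and
   region-of-interest mean spectra. Coordinates are 0-based `(line, sample)`,
   line-major, matching ENVI's lines/samples terminology.
2. **Band reduction** (`hsiclass.preprocess.pca_reduce`). PCA is fitted on
   *all* scene pixels (labeled and unlabeled) so that full-scene map
   rendering and patch extraction share one consistent embedding. The
   retained count B is the smallest component count whose cumulative
   explained-variance ratio reaches the threshold (default 0.98). Component
   signs are fixed (largest-magnitude loading element positive) for
   run-to-run determinism.
3. **Patch extraction** (`extract_patches`). One S×S×B block per labeled
   pixel, centered on it, default S = 9. Scene borders use reflect padding:
   the alternative (zero padding) would inject artificial dark spectra into
   scenes whose vegetation is already near-dark.
4. **Splitting** (`stratified_split`). Per class, `floor(f·n)` samples go to
   train and validation; the remainder is the test set. A published table of
   per-class counts cannot be reproduced by any single rounding rule (its
   three rows imply three different rules), so floor-with-remainder-to-test
   is adopted and documented rather than claimed as the original procedure.
   Sample order within a class is canonicalized by coordinates before the
   seeded shuffle, so splits depend only on sample identity and seed.
5. **Standardization** (`standardize`). Per-band mean/sd fitted on the
   training split only; zero-spread bands are centered, not divided. The
   source study is silent on input scaling; standardized inputs are the
   conventional choice for batch-normalized networks.

## Network families

All tensors are `(N, C, depth, height, width)`; 2-D networks are expressed
with a singleton depth axis so one convolution implementation serves both.

* **DGRNet (2-D)**: the standard 18/34/50-layer residual topology — 7×7/2
  stem to 64 channels, 3×3/2 max pool, stages of basic blocks (18/34) or
  4×-expanded bottlenecks (50) at widths 64/128/256/512, batch norm + ReLU
  after every convolution, global average pooling, linear softmax head.
  Convolutions carry no bias (a batch norm always follows); this convention
  is required to reproduce the published count of 21,370,883 trainable
  parameters at 30 input channels and 3 classes, which decomposes as
  21,286,211 (3-channel, 3-class standard 34-layer net) + 64·7·7·27 for the
  widened stem.
* **3D_DGRNet**: the 3-D analogue — single-channel B×S×S volume, 7×7×7 stem,
  3×3×3 block kernels, 1×1×1 projection shortcuts, stride 2 on all three
  axes at stage transitions. Under exactly these conventions the 34-layer
  count reproduces the published 63,471,171.
* **3D_RNet-O**: a 34-layer-style backbone whose blocks decompose each
  convolution into a spectral kernel `a×1×1` and a spatial kernel `1×a×a`
  (default a = 3). Branch one applies spectral→spatial, branch two
  spatial→spectral; branch outputs (each `out_width` channels) are
  concatenated and fused by a 1×1×1 convolution back to `out_width` — the
  fusion operator is not specified in the source description beyond
  "concatenate then fuse", and a 1×1×1 projection is the choice that keeps
  the residual addition well-typed. With a single branch enabled the fusion
  is the identity; with both disabled the block degenerates to a plain
  `a×a×a` basic block (the ablation baseline). Default configuration: stage
  widths (128, 256, 512, 1024), stem kernel (3, 5, 5), pool window (2, 2, 2),
  reflecting the sweep optima of the source study. The published
  3D_RNet-O parameter total (28,357,699) depends on undisclosed branch-width
  and fusion details and is *not* reproduced by this faithful reading; it is
  treated as a reference value, not a target.

Numerical conventions: "same" padding of `k//2` per axis; output sizes floor
at 1 along the spectral axis (padding is raised when a volume is shallower
than its kernel) so deep stacks remain valid on thin volumes after
downsampling; pooling windows are clamped to the padded input; He-normal
initialization for convolutions, Xavier-uniform for the head, seeded through
`numpy.random.default_rng`.

The networks run on a small numpy layer library (`hsiclass.nn`) written for
this package: im2col + BLAS matmul convolutions with exact hand-written
backward passes, batch norm with running statistics, max/global-average
pooling, Adam and SGD. No deep-learning framework is required at install or
test time.

## Training protocol

Cross-entropy on softmax outputs (implied by the probability head), Adam by
default — the fixed learning-rate grid the sweeps cover (1e-4 … 5e-2, no
schedule) is only workable with an adaptive method; SGD + momentum is
available by config. The reference protocol trains 200 epochs and averages
10 repeated runs; the test suite and acceptance script scale this down
(≤ 30 epochs, small stage widths) to fit a single CPU. Repeated runs derive
their seeds as `base + run_index` and may either reinitialize only or also
resample the split (both readings of "repeated experiments" are provided).
K-fold cross-validation uses stratified folds (per-class counts differ by at
most one across folds); the reported variance is the population variance
over fold accuracies.

## Metrics

Confusion matrices are oriented rows = reference, columns = predicted;
producer's accuracy (PA) is the row-wise diagonal share, user's accuracy
(UA) the column-wise share, OA the overall diagonal share, AA the unweighted
mean of *defined* PA values, and kappa the chance-corrected agreement
`(p_o − p_e)/(1 − p_e)`. Empty classes yield missing (NaN) per-class values,
excluded from AA with a warning — never zero. Percentages print at two
decimals, rounded half away from zero. This orientation was confirmed by
recomputing the published optimal-configuration table exactly (PA 98.96 /
98.72 / 99.53, UA 97.34 / 99.84 / 99.24, OA 99.07). The published
initial-configuration table is internally inconsistent: its own counts give
OA 98.18 (printed 98.21), kappa 0.972 (printed 0.979), third-class UA 97.74
(printed 95.6) and first-class PA 94.53 (printed 94.51). The implementation
reproduces the matrix arithmetic, not those printed aggregates.

## Synthetic scenes: what they emulate and what they do not

`hsiclass.simulate` draws per-class smooth Gaussian latent fields (white
noise blurred to a correlation length, default 8 px), labels each pixel by
argmax of offset-calibrated fields so class fractions track the priors,
assigns parametric endmembers, blends a two-endmember convex mixture within
a border band (weight 0.75…1 toward the own class), adds i.i.d. Gaussian
sensor noise and hides a seeded fraction of labels (ground truth is kept in
a sidecar). Vegetation endmembers are logistic red-edge curves whose
`flatness` parameter interpolates toward the flat, featureless spectra of
drought-stressed canopies; non-vegetation is an affine ramp.

Stated-world defaults: class priors (0.215, 0.408, 0.377) and an unlabeled
fraction of 0.75 mirror the published labeled-sample composition (33,582
labeled pixels of 135,000); 64 bands over 400–1000 nm keep the suite fast
while preserving the point of the PCA step (256 bands are supported); noise
sd 0.01 reflectance units makes the default scene cleanly separable (a
nearest-centroid classifier on raw spectra scores ≥ 99%); the
intermediate-difficulty variant (noise sd 0.05, flatter indicator spectrum,
2-px borders) is used where only a ranking between models is asserted.

What a green test therefore establishes: the pipeline learns and scores
correctly on data with the right *structure* (low-reflectance vegetation,
flattened indicator spectra, patchy cover, mixed borders, sensor noise).
What it does not establish: the published accuracy percentages on the
authors' field data, which are not desk-reproducible (data available on
request only); BRDF/illumination effects, nonlinear (intimate) mixing and
UAV flight geometry are out of scope.

## Scaled-down configuration choices

The end-to-end check uses a 120×120×64 scene, PCA at 0.98 (B ≈ 25 on this
world), 9×9 patches, a 7:3 split and a small-width (8, 16, 32, 64)
dual-branch network for 30 epochs. Within that fixed epoch budget the
reference learning rate 0.003 underfits the small network (held-out OA
≈ 93%); learning rate 0.01 — inside the grid the source study sweeps — is
the package's default for the scaled configuration and reaches ≥ 95% with a
nearest-centroid reference at ≥ 99%. Errors concentrate at community
boundaries, where a 9×9 patch mixes classes; this mirrors the mixed-pixel
discussion in the source study.

On the intermediate-difficulty world the dual-branch blocks hold a small mean
advantage over plain 3×3×3 blocks (the ordering the ablation table reports),
but the gap is far smaller than on the original field data: the simulator's
classes are close to pixel-separable by mean spectrum, which leaves little
room for the factorized spectral/spatial kernels to shine. Only the ordering
is asserted, never the magnitude.

## Known limitations

* The numpy backend is single-threaded BLAS-bound; full-width
  (128…1024-channel) 3-D training is out of reach on CPU. Builders and
  parameter accounting cover the full-width models; training-quality tests
  use small widths.
* Bit-exact reproducibility holds per platform/BLAS build; across BLAS
  builds results agree only to floating-point reassociation.
* The simulator's linear two-endmember border mixing is the simplest stand-in
  for mixed pixels; no radiative-transfer realism is attempted.
* `repeat_experiment` wall-times are not comparable to the published
  hardware-bound timing table, which is deliberately not reproduced.
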