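# Methods

This note documents the models, the synthetic data generator, and the
numerical choices behind `paddy`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Problem setting

The package targets intra-field yield prediction in production rice: given
co-registered UAV rasters (five reflectance bands plus thermal) over a
single field, predict the combine-harvester yield map (Mg/ha) on a 50 cm
grid. The working unit is a non-overlapping 5×5-pixel tile (2.5 m × 2.5 m).
Seven features feed every model: six vegetation indices — CIgreen, GNDVI,
NAVI, NDVI, RENDVI, TGI, in that fixed canonical order — plus the thermal
layer.

Index formulas (ρ = band reflectance):

| Index   | Formula |
|---------|---------|
| NDVI    | (ρ_NIR − ρ_r) / (ρ_NIR + ρ_r) |
| CIgreen | ρ_NIR / ρ_g − 1 |
| RENDVI  | (ρ_NIR − ρ_RE) / (ρ_NIR + ρ_RE) |
| GNDVI   | (ρ_NIR − ρ_g) / (ρ_NIR + ρ_g) |
| NAVI    | 1 − ρ_r / ρ_NIR |
| TGI     | −0.5·[(670−480)(ρ_r − ρ_g) − (670−550)(ρ_r − ρ_b)] |

The TGI wavelength constants (670/550/480 nm, the red/green/blue band
centers) are hard-coded because the formula embeds them. NAVI satisfies the
algebraic identity NAVI = 2·NDVI/(1+NDVI) wherever both are defined; the
tests verify this to 1e−10 as an internal consistency check. Cells with a
vanishing denominator are masked invalid rather than clipped — downstream
tiling drops any tile containing a missing value, so masking is the
conservative choice.

## The five models

All models map tile features to a 5×5 yield patch and are evaluated on
pixels:

* **Null** — the mean training-pixel yield everywhere. Its training RMSE
  equals the population standard deviation of the training yields (an exact
  identity the tests assert), and its R² is undefined (constant
  predictions have no correlation with anything); reports encode this as an
  explicit not-defined marker, never 0 or silent NaN.
* **Linear** — ordinary least squares on the 7 features, per pixel, no
  spatial context. Rank-deficient designs are handled by QR with column
  pivoting on mean-centered columns: aliased columns are reported by name
  and dropped (zero coefficient). Centering first means the intercept is
  always retained and a constant feature is what gets flagged.
* **Boosted trees** — gradient-boosted regression trees on the same
  per-pixel features (XGBoost backend, core `xgb.train` API): learning rate
  0.2, maximum depth 2 (pairwise feature interactions only), 200 rounds,
  squared-error objective, no subsampling, exact tree method, base score =
  training-mean yield. Zero rounds degenerates to the base score.
* **2D-CNN** — an autoencoder-like network over one acquisition date:
  encoder conv 64@3×3 (same) → conv 128@2×2 (same) → conv 256@1×1 (valid),
  bottleneck flatten → dense 256 → dense 6,400 → reshape (5,5,256), decoder
  conv 128@2×2 → conv 64@3×3 → conv 1@1×1 (linear). ReLU everywhere except
  the output. 3,558,529 parameters (hand-computed and asserted).
* **3D-CNN** — identical except the encoder convolves across space *and*
  five acquisition dates: kernels (3,3,3) same, (2,2,3) same, (1,1,5)
  valid — the last collapses the date axis to a singleton — then the same
  bottleneck/decoder tail. 3,763,201 parameters.

The dense bottleneck is 6,400 units because the following reshape to
(5,5,256) requires 6,400 values; no other width is geometrically possible
with that reshape.

Networks train for 50 epochs with Adam (step size 1e−3, β₁ 0.9, β₂ 0.999,
ε 1e−7), MSE loss, batch size 32; after every epoch the validation loss is
computed and the weights of the best validation epoch are the ones kept.
Training aborts with a diagnostic on non-finite loss.

### Network implementation

The conv-net stack is implemented directly on NumPy (float32, stride-1
convolutions as one GEMM per layer via im2col, TensorFlow-style
"same"/"valid" padding — even kernels pad at the trailing edge). The
backward pass is verified against central finite differences in float64
(relative error below 1e−5 on both the 2D and 3D stacks), and the forward
convolution against a brute-force sliding-window oracle. All parameters
live in one flat buffer so the Adam update is a single fused pass
(numba-compiled elementwise kernel). Training is bit-reproducible given a
seed: initialization (Glorot uniform), shuffling, and everything downstream
derive from one `numpy.random.Generator`.

### Normalization

Inputs are standardized per feature — mean and standard deviation fitted on
the training fold only, applied to validation/test — because thermal (~28)
and the indices (~0–4) differ by orders of magnitude. The yield target is
likewise standardized on the training fold and predictions are mapped back
to Mg/ha; with a zero-initialized output bias and a 9 Mg/ha mean target,
Adam at 1e−3 would otherwise spend most of the 50-epoch budget drifting the
output bias instead of learning structure. Feature *blanking* (below)
always happens on the raw feature scale, before the model-internal
normalizer, so "replace by the test-set mean" reads exactly as a raw-data
operation.

## Spatial cross-validation

The tile grid is cut into a 4×4 lattice of rectangular blocks; horizontal
strip boundaries are placed at the quartiles of the cumulative retained-tile
count, so an edge buffer does not skew the split. Each fold assigns one
strip of 4 blocks to test, another to validation, and the remaining 8
blocks to training (≈50/25/25); across folds A–D every strip serves as the
test region exactly once, so the union of test regions covers the field.
Holding out contiguous regions (rather than scattering tiles randomly)
prevents leakage through spatial autocorrelation — test tiles are never
adjacent to training tiles except along block borders.

The statistical models (null, linear, boosted trees) have no epoch loop, so
train and validation data are equivalent for them; the driver fits them on
train+validation merged and evaluates on test.

## Evaluation

RMSE, MAE, MBE = mean(predicted − observed) (positive = overprediction),
and R² = the squared product-moment correlation between observed and
predicted — deliberately the correlation form rather than 1 − SSE/SST, so
it is bounded in [0,1] and undefined for constant series. rRMSE is RMSE as
a percentage of mean observed yield. All four are verified against an
independent plain-Python summation oracle to 1e−12.

Feature importance is estimated by *blanking*: one feature at a time is
replaced everywhere in the test set by its test-set pixel mean, the model
is re-evaluated, and ΔRMSE = blanked − original is reported (also as
ΔrRMSE, in points of mean yield). Negative values are possible and
meaningful: removing the observed variation in a feature the model misuses
can help. The machinery is model-agnostic.

## The synthetic field generator

No raster or yield data from the original field study is available, so the
generator is the package's study system. It emulates, feature by feature,
the structure the analysis depends on:

* **Latent vigor** — a stationary Gaussian random field (zero mean, unit
  variance) standing in for spatial variation in nutrient and water
  availability. Covariance exp(−(d/ℓ)²), so the autocorrelation at lag ℓ is
  exactly e⁻¹. Synthesis is spectral (circulant embedding, FFT): exact
  stationarity on the torus in O(N log N), cross-checked against direct
  covariance-matrix Cholesky sampling on a 50×50 grid. Default ℓ = 15 m
  (30 cells): farm-machinery-scale management zones; no published value
  exists for the original field, so this is a package choice, fixed once.
* **Yield** — mean + sd·vigor with defaults 9.06 ± 0.9 Mg/ha (the field
  moments the study reports), clipped at 0, masked within a 10 m (20-cell)
  edge buffer.
* **Harvester label noise** — combine yield maps carry curvilinear track
  artifacts from the circular driving pattern. Emulated as concentric
  sinusoidal rings about the field center with a gentle angular wobble:
  amplitude 0.3 Mg/ha, period 17 cells (the 8.5 m header width). The
  geometry of the real artifact is not published; only its curvilinear,
  additive, feature-independent character matters to the analysis, because
  it is label noise no feature-based model can explain.
* **Reflectance** — each band is a monotone logistic function of vigor with
  a stage-dependent gain: 0 before emergence (bare soil), 0.3 at tillering,
  0.7 at panicle initiation, 1.0 at booting/flowering, 0.5 at grain fill
  (senescence attenuates the signal). NIR and red-edge increase with vigor,
  visible bands decrease; thermal (°C) decreases with vigor (transpiring,
  well-watered canopies are cooler). I.i.d. Gaussian sensor noise, default
  sd 0.01 reflectance units per band (0.5 °C thermal equivalent), clipped
  into [0,1].

Everything is a pure function of (config, seed); identical seeds give
bit-identical fields.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: radiometric calibration error, orthomosaic
stitching seams and geometric distortion, soil/weed pixels, cloud/shadow
variation between dates, spatially *correlated* sensor noise, and
cultivar- or management-driven nonstationarity. The generator's
vigor→reflectance link is also smoother than nature's; absolute RMSE values
on synthetic fields are therefore not comparable to field results — only
orderings and qualitative behavior (denoising, importance recovery,
reduced-data degradation) transfer.

## Scaled-down experiment sizes

The reference synthetic experiment (tests and acceptance script) uses one
400×400-cell field (4 ha at 50 cm) — 5,184 retained tiles after the edge
buffer, of which ~2,600 train in a fold — versus ~21,000 tiles for the
16-ha field of the original study. These sizes were chosen so the full
pipeline, including three independently seeded 50-epoch network trainings,
runs on a single CPU in minutes while leaving every qualitative contrast
(model ranking, denoising, importance, reduced-data robustness)
measurable. The spatio-temporal network is demonstrated at the same tile
geometry with five dates.

## Numerical choices and degenerate inputs

* Aggregation (5 cm → 50 cm) is the block mean over valid cells; an output
  cell is invalid only if its whole block is; trailing partial blocks are
  dropped, at both aggregation and tiling.
* Coordinates are 0-based, row-major, half-open everywhere.
* Zero-variance yield (sd = 0) produces a constant field; zero-round
  boosting returns the base score; constant-label network training
  converges to the constant; empty tile sets and shape mismatches raise
  typed errors (`InputError` exit 1, `ConfigurationError` exit 2).
* Batch size 32 and Adam step 1e−3 are conventional defaults at this input
  size; neither is tuned.
* Per-task seeds in the experiment driver are derived from the run seed via
  a CRC-based mix, stable across runs and below 2³¹.

## Known limitations

* The fold-block geometry is a deterministic lattice template; the original
  study's exact region layout is only shown pictorially and is not
  reproduced.
* TIFF output carries no CRS/geotransform (plain float32 TIFF + JSON
  sidecar, nodata −9999); the package is not a GIS.
* R² of the null model is undefined by construction; comparisons against it
  use RMSE/MAE/MBE only.
* The NumPy networks are CPU-bound and single-threaded by design; they are
  sized for 5×5 patches and would be slow for materially larger inputs.
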