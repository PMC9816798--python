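# Methods

## The estimation problem

Grid-scale winter-wheat yield (t/ha on a 5 m grid) is regressed on
spectral observations of the canopy: either a season of monthly
multispectral vegetation-index composites (October sowing to June
harvest, 9 steps), or custom two-band indices extracted from
single-date 163-band hyperspectral spectra on a few acquisition dates.
The package implements the full chain — data simulation, feature
construction, model fitting, evaluation and interpretation — with the
simulator standing in for field and satellite data.

## The synthetic scene generator

No field data ship with the package; the generator reproduces the
*statistical structure* the analysis relies on, with every link
controllable and documented.

**Yield grid.** A radial centre-high/edge-low trend (amplitude
`trend_amplitude`) plus spatially correlated Gaussian noise
(`spatial_noise_sd`, smoothed with a sigma-2 Gaussian kernel), min-max
rescaled into `[yield_min, yield_max]` (defaults 1.39-6.75 t/ha).
Rescaling guarantees range containment for every seed; a flat,
noise-free configuration collapses to the range midpoint.

**Latent-trait reflectance model.** Each cell carries two latent canopy
traits, greenness and water content, both *linear* in normalized yield
and scaled by fixed seasonal envelopes (near-zero in winter dormancy,
peak in May). Band reflectances are affine in the latents with
N(0, `noise_sd`) noise, clipped to [0, 1]. The red and blue bands are
held at their soil baseline so that the simple ratio B8/B4 is exactly
linear in yield in the noiseless limit — a deliberate identifiability
anchor; NDWI rises with yield through the SWIR water term. Per month,
`n_scenes_per_month` scenes (default 3) are drawn; each scene's cloud
fraction comes from a clear/cloudy mixture (cloudy with probability
`cloudy_scene_prob`, uniform 35-90% cover; clear scenes uniform 0-28%),
so the >30% filter has real work to do.

**Hyperspectral spectra.** Band centres mimic a spliced VNIR/SWIR
instrument: 76 bands 396-1040 nm plus 90 bands 1006-2501 nm with the
three overlapping SWIR bands dropped — 163 strictly increasing centres.
Spectra start from a smooth vegetation-like baseline (green bump, red
edge, water absorption, two SWIR peaks), scaled per sample by a random
brightness factor and perturbed by additive noise (both tied to
`noise_sd`). Each *planted pair* (i, j, sign) pushes the two bands
apart in proportion to standardized yield, so the difference, ratio and
normalized pair indices all correlate with yield with the requested
sign. Defaults plant a visible-NIR pair (516/765 nm, negative) and a
SWIR pair (1779/2216 nm, positive), mirroring the sign pattern of
ripening-wheat field spectra.

**Planted-signal recovery threshold.** Any pair sharing a band with a
planted pair also carries signal (at roughly half the slope), so
recovery of the exact planted pair is a genuine statistical contest.
With 39 samples and one planted pair, the exhaustive search returns the
planted pair as its extreme in ≥ 95% of 20 seeds for
`noise_sd ≤ 0.002`; this is the documented recovery threshold used by
the acceptance suite. Recovery degrades structurally — not through
noise — when the planted bands have very unequal baseline reflectance
(e.g. 516 vs 765 nm): the normalized index is then dominated by the
brighter band and a half-planted pair can legitimately attain a higher
|r|. The recovery settings therefore plant pairs with comparable
baselines (red/red 671-679 nm for the negative sign, SWIR/SWIR for the
positive); the unequal-baseline default pairs still produce the correct
correlation *signs*, which is what the sign tests assert.

**Direct VI-sequence simulation.** For model-behaviour studies the
generator can emit 4 × 9 index trajectories directly: one dominant
index encodes yield through amplitude and (optionally) the timing and
width of its seasonal peak — a nonlinear temporal code — while the
other three indices are seasonal shapes with sample-level random
scaling, uncorrelated with yield. This isolates what the models can
read from temporal shape alone.

**Management trials.** Yield = midpoint + additive factor effects +
N(0, 0.12) noise, clipped to the yield range. Seeding rate follows an
inverted-U peaking at 225 kg/ha (dense sowing depresses yield);
irrigation adds up to +0.5 t/ha linearly to 60 mm; rotational tillage
+0.35; variable-rate fertilization +0.30. `management_effect_scale`
scales all effects (0 gives null groups).

**What the simulator does not emulate.** No radiative-transfer physics
(no PROSAIL), no spatial autocorrelation in reflectance noise, no
per-pixel cloud masks, no atmospheric or geometric artefacts, no
soil-type variation, and monotone yield-trait links with no saturation.
Passing tests therefore demonstrate that the *pipeline* is correct and
that the models can extract the encoded signals — not that comparable
accuracy would be reached on real imagery.

## Feature construction

Vegetation indices are computed per scene and then averaged within
months (not bands averaged first): the mean of a ratio is not the ratio
of means, and per-scene indices are what whole-scene cloud filtering
naturally composes with. The cloud threshold is a strict "greater
than": a scene at exactly 30.0% cover is retained. Months left with no
usable scene are filled by linear interpolation over month index (flat
extrapolation at the season ends) so the sequence model always sees a
dense 4 × 9 matrix; an all-empty season is an error. Red-edge position
values outside 600-820 nm arise from a near-degenerate interpolation
denominator (B6 ≈ B5) and are treated as missing at scene level.
Flattening is index-major (the first nine entries are the first index's
trajectory) and invertible; the order is fixed so baseline models are
reproducible.

Guarded formula evaluations (zero denominators: B4 = 0 for SR,
B8 + B11 = 0 for NDWI, B6 = B5 for REP, R_j = 0 for RSI,
R_i + R_j = 0 for NDSI) return NaN missing flags rather than raising —
missingness is data, not a programming error.

## Band-pair screening

Pearson correlation (two-sided p from the t distribution with n − 2
degrees of freedom) is computed for every pair index against yield,
vectorized over all pairs with NaN-aware sums; pairs with fewer than
three valid samples or a constant index are flagged missing. SSI and
NDSI are antisymmetric in (i, j), so only the upper triangle is
computed and the lower is filled by sign flip — and extreme-pair
selection also searches only unordered pairs for these types, otherwise
the strongest negative would always be the mirror of the strongest
positive. RSI is not antisymmetric and is searched over ordered pairs.
Extremes must pass p < 0.001; ties break to the lexicographically
smaller (i, j); a sign with no significant pair is reported empty with
a warning. Selected pairs are reported as wavelengths (nm); applying a
selection to another instrument's spectra uses nearest-wavelength band
matching.

## Models

**LSTM.** Two stacked LSTM layers (default 100 units) with the
standard gate equations (sigmoid input/forget/output gates, tanh
candidate, Hadamard combinations), forget-gate bias initialized to 1,
Glorot-uniform weights; the last hidden state passes through ReLU and a
dense head. Dropout (default 0.3) applies between the layers and
before the head during training; L2 weight decay (default 1e-4 — the
coefficient is a package default, configurable) applies to all weight
matrices but not biases. Training is full BPTT with Adam at lr 0.001,
batch 64, MSE loss, 700 epochs by default; inputs and targets are
z-scored with training statistics (the RBF kernel and the recurrent
nonlinearities are scale-sensitive), predictions returned in t/ha.
Sequences run time-major in calendar order October → June. A non-finite
loss aborts with a diagnostic rather than continuing. Correctness is
pinned by a hand-evaluated cell oracle and a finite-difference gradient
check; given a seed, training is exactly reproducible (pure numpy, no
threading nondeterminism).

**Baselines.** scikit-learn regressors at the tuned settings: RF
(150 trees, random_state 200, OOB R² reported), GBDT (1250 trees,
subsample 0.6, lr 0.1), SVR (RBF, C = 1e5, gamma = 0.5, features
z-scored in a pipeline). They consume the flattened vector, whose
length is exactly n_indices × n_steps (36 or 12).

**Split.** A seeded permutation partition, train fraction 0.9; sizes
are within one sample of the fraction, the partition is disjoint and
exhaustive.

At the default SVR settings on z-scored 36-dimensional inputs the RBF
kernel radius is far smaller than typical inter-sample distances, so
the fit memorizes training points and predicts near the mean elsewhere;
this is the mechanism behind the asserted ordering (median LSTM test
RMSE below median SVR test RMSE over seeds) — asserted as an ordering
only, not as specific RMSE values.

## Evaluation and interpretation

MAE, RMSE and R² follow the standard definitions (R² flagged NaN for
zero-variance targets). RMSE ≥ MAE (power-mean inequality) and the
identity R² = 1 − m·RMSE²/Σ(yᵢ − ȳ)² are asserted property-based.

Permutation importance shuffles the *whole trajectory* of one feature
across samples (within-sample temporal structure preserved; for flat
inputs, the feature's columns move together under one permutation),
recomputes the loss (default MSE, configurable) without retraining,
and averages over `n_repeats` (default 10; a reproducible single
shuffle is `n_repeats=1` with a seed). Features are ranked by descending
shuffled loss. Reported importances are data- and model-dependent;
no specific loss values are claimed.

Yield maps are float32 GeoTIFFs (tifffile) with ModelPixelScale,
ModelTiepoint and GDAL-nodata tags over the synthetic affine grid; no
CRS is attached.

## Problem sizes and reproducibility

Default test and example scenes use 10²-10³ grid cells, 39
hyperspectral samples, and 40-150 training epochs; the full-survey
scale (~15,709 cells, 700 epochs) is reachable through configuration.
These sizes were chosen so that every property (signal recovery, model
ordering, importance ranking) is decided by the encoded signal rather
than by scale. One global seed derives per-stage seeds by fixed
offsets (scene +0, split +1, LSTM +2, importance +3; generator
sub-streams likewise), so any stage can be rerun in isolation with
identical results.

## Known limitations

- The simulator's yield-reflectance links are monotone and noise is
  i.i.d.; none of the results quantify robustness to atmospheric
  artefacts, mixed pixels or label noise.
- The LSTM is CPU-bound numpy; it is sized for thousands, not
  millions, of sequences.
- The 5 m yield grid and coarser satellite pixels are emitted
  co-registered; resolution mismatch and resampling effects are out of
  scope.
- RSI extremes over ordered pairs report both orientations of the same
  physical pair; consumers should read |r| and the wavelength pair
  together.
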