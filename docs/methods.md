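# Methods

`airsurf` estimates daily surface PM2.5 concentrations by fusing sparse
ground-station measurements with gridded satellite-style covariates
through a masked bidirectional recurrent network with multiplicative
attention. This note documents the model, the synthetic worlds it is
exercised on, the numerical choices, and what the tests do and do not
show.

## The estimation problem

Regulatory monitors measure surface PM2.5 directly but sparsely and, at
many sites, only every third or sixth day. Satellite aerosol optical
depth (AOD) covers the whole grid but is an indirect column measure with
large retrieval gaps (clouds, bright surfaces). The estimator combines
both, plus meteorology, wildfire smoke density (WSD), elevation, NDVI,
location, and temporal encodings, to produce a continuous daily surface.

## Predictor roster

Each (location, day) feature vector has 21 entries: two AOD bands
(0.47/0.55 um), six meteorological surfaces (day length, precipitation,
shortwave radiation, max/min temperature, vapor pressure), wind direction
and speed, the ordinal WSD category {0 none, 1 light, 2 medium, 3 heavy},
elevation, 16-day NDVI (nearest dated layer; ties to the earlier one),
the KNN-IDW fused station feature, latitude/longitude, and five temporal
encodings — cos/sin of 2π·(doy−1)/365 and 2π·(month−1)/12 (zero angle at
Jan 1 / January) plus the numeric year, all MinMax-scaled like any other
feature. Wind direction enters as the raw degree value to keep the
roster's one-column-per-variable layout; a cyclic encoding was considered
and left out to preserve the fixed 21-entry schema.

## KNN-IDW fusion and leakage control

For a target (lon, lat, date), the k = 9 nearest stations *reporting on
that date* (haversine distance, Earth radius 6371.0088 km) are averaged
with weights ∝ d⁻¹ (power configurable); a collocated station (d = 0)
short-circuits to its own value; distance ties break on station id. In
`leave_target_out` mode the target station's record is removed before the
search — the feature then carries only neighboring-station information,
so training and evaluation never see the answer through this channel. A
property test perturbs every station-day's own measurement and asserts
the feature is bit-invariant. Production surfaces use `full` mode.
Neighbors are never borrowed across days; a day with no usable signal
becomes a masked timestep instead.

## Sequence construction and masking

Each sample is the 21-day window t−20…t of scaled features with the
day-t measurement as target. Scaling is feature-wise MinMax onto [−1, 1]
(x′ = 2(x−min)/(max−min) − 1), fitted on training-split day-t rows only;
constant features map to 0; out-of-range test values are *not* clipped.
The target is scaled with the same scheme and predictions are
inverse-scaled (and clamped at 0) for reporting.

A timestep is masked all-or-nothing: when its feature row is absent, or
when both the fused feature and AOD are missing. Masked rows are stored
as the sentinel −2.0 (outside the scaled range), but the network consumes
the boolean mask, never the sentinel: masked inputs are zeroed, recurrent
states carry through masked steps unchanged, and masked steps get
attention weight exactly 0 — making the output *exactly* invariant to
masked-row contents (tested to bit equality). Partial missingness within
an unmasked day is filled with the training-split median.

## Network

Three stacked bidirectional LSTM layers with widths (256, 128, 128) read
as total units per layer (half per direction; a config switch selects the
per-direction reading), each followed by layer normalization over the
feature dimension and dropout (rate 0.2, training only). Attention is
multiplicative: score(ĥ_t, ĥ_s) = ĥ_tᵀ W ĥ_s with the day-t normalized
state as query, masked softmax into weights α (max-subtraction for
stability), context c_t = Σ_s α_s ĥ_s, combined output
h̃_t = tanh(W_c [c_t ; ĥ_t]), and a linear head to one scalar per
sequence in scaled target space (linear because the target is unbounded).

The network and its training loop are implemented in numpy on a small
reverse-mode autodiff engine (`airsurf.nn`); the LSTM cell is a fused op
with a hand-written backward pass for speed. Gradients of every primitive
and of the fused cell are tested against central finite differences
(relative error ≲ 1e−8 observed, asserted at 1e−4).

## Training

Huber loss (δ = 1.0 in scaled-target units — the transition point is a
package choice; its gradient continuity at |r| = δ is tested), Adam, and
an exponential learning-rate schedule lr(step) = lr₀ · 0.8^(step/30000),
continuous by default with a staircase flag. Gradients are clipped to a
global norm of 5 (configurable), the usual guard against exploding
recurrent gradients. Defaults lr₀ = 1e−3 and
batch 256 suit production-scale sample counts; the desk-scale studies
(below) use lr₀ = 5e−3 and batch 48 because only a few hundred gradient
steps fit in their budget, and the temporal study trains two random
restarts per run, keeping the one with the better validation loss (test
data plays no part in the choice). Mini-batch order and dropout are seeded;
training is bit-reproducible per seed on one device. Early stopping
(patience 10 by default, disable-able) retains the best-validation
weights. Non-finite loss aborts with a diagnostic.

## Evaluation protocol

R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE, MBE = mean(ŷ−y) (positive =
overestimation), overall and stratified: AQI-style concentration
categories (values rounded to one decimal before binning, reconciling the
gapped breakpoints such as 12.0 vs 12.1), the >35 ug/m³ subset, season
(MAM/JJA/SON/DJF), and region (grid quadrants in synthetic runs; a
polygon map is out of scope for tests). The split protocol is a random
10% held-out test set plus 10-fold CV on the remainder; validation
numbers are fold averages and test numbers come from the best-validation
fold's model. Single-split experiments use fold 0 as validation. A
log(1+x) metric mode supports density-plot-style reporting. CV folds are
sample-random; a station-blocked option exists but is not the default.

Baselines: a point-to-point random forest consuming only day-t feature
vectors (median-filled; hyperparameters from a fixed-budget random search
over trees × depth × min-leaf scored out-of-bag) and a unidirectional
variant of the sequence model — both on identical sample-level splits.

## Synthetic worlds

The generator emulates the estimator's data regime, never its weights:

    PM2.5(s,t) = μ + A·cos(2π(doy−1)/365) + G(s,t) + β·density(s,t) + ε

with G an exponential-covariance Gaussian field (circulant-embedding FFT
sampler; non-PSD embedding eigenvalues clamped at 0 — adequacy is defined
by stationarity tests: unit variance and 1/e correlation at the range)
evolving as AR(1) in time, ε white noise, and negative values clamped.
Smoke events are spatiotemporal disks with density 3/2/1 from core to
fringe; overlaps take the maximum. AOD is linear in PM2.5 per band with
retrieval noise and i.i.d. cell-day masking shared by both bands; an
optional elevated masking probability on smoke-covered cell-days
(`aod_smoke_missing_rate`) emulates retrieval loss under heavy plumes;
meteorology is seasonal-plus-texture and deliberately weakly informative;
stations sit on distinct uniform-random cells (a clustered option exists)
and report every `station_reporting_period` days with a per-station
phase, plus measurement noise (sd 1 ug/m³ by default). Everything is a
pure function of (config, seed).

What the worlds do *not* emulate: atmospheric transport, plume shapes,
station siting bias, instrument drift, or retrieval artifacts that
correlate with concentration. Passing tests demonstrate that the pipeline
recovers structure it was built for under its own assumptions — not
field performance on real data.

## Study conditions (frozen in `airsurf.studies`)

All simulation studies run at desk scale: reduced widths (16, 8, 8),
grids of a few hundred cells, 30 or fewer stations, ~120 days.

- **Temporal vs point-to-point** (`temporal_study_world`): AR(1) ρ = 0.9,
  1-in-3 reporting, 50% AOD missingness, AOD noise 0.15 (band sd ≈ 0.12),
  station noise 2 ug/m³. Here single-day features genuinely
  underdetermine the field, so a 21-day window carries information a
  day-t model cannot access — the regime the sequence model exists for.
  The check is directional (sequence model beats the forest in ≥4 of 5
  seeds), not a magnitude claim.
- **Smoke ablation** (`ablation_study_world`): β = 15 ug/m³ per density
  level with 16 six-day events, and AOD masked with probability 0.85 on
  smoke-covered cell-days — the mechanism that makes a smoke-density
  product informative in the first place: where retrievals survive, AOD
  already reflects the smoke, and the ablation would only measure
  training noise. The null world sets β = 0 with the same varying
  density field. The ablated arm removes smoke density everywhere it
  enters the pipeline, including the AOD gap filler's predictors.
  Comparison: >35 ug/m³ RMSE with vs without WSD on the full held-out
  portion (validation + test — the 10% test sliver alone holds only a
  handful of >35 samples at desk scale), identical seeds and splits; the
  null case uses a paired t-test across seeds.
- **Gap-fill recovery** (`imputation_study_world`): AOD an exact linear
  function of PM2.5, no white noise, 2-km cells against a 120-km
  correlation range, ρ = 0.95 — the fine-product regime in which held-back
  retrievals are reconstructible. Smoke is disabled because density-ring
  edges are step discontinuities no smooth interpolator can cross; the
  white-noise term is disabled because it is unpredictable from any other
  cell and would only add an irreducible floor to the comparison.

## AOD gap filler

A gradient-boosted regressor (LightGBM) trained on observed cell-days;
predictors are the meteorology, WSD, elevation, NDVI, lat/lon, temporal
encodings, and three spatiotemporal context features: the
inverse-distance average of the same day's observed AOD cells (k ≤ 6) and
the same cell's previous/next-day retrievals (missing values routed
natively by the booster). Observed cells pass through unchanged; the
output is gap-free. The exact predictor set and hyperparameters are a
package reconstruction of a generic gap-filling design.

## Numerical choices and degenerate inputs

- Masked softmax rather than sentinel-value attention: exact invariance.
- Softmax stabilized by (gradient-constant) row-max subtraction.
- Scaler span 0 → feature maps to 0 (no division blow-up); round-trip
  identity holds to 1e−9 for non-degenerate features.
- A sample with every timestep masked is an error, as is an all-missing
  AOD stack; a target whose window would cross the record start is
  skipped with a logged warning.
- Zero reporting stations on a date → the fused feature is missing (and
  masks the timestep if AOD is also absent), never an exception.
- Forget-gate bias initialized to 1; Glorot init elsewhere, seeded.
- Checkpoints store weights + config + scaler + a feature-order schema
  hash, validated on load.
- GeoTIFF output is float32, north-up, WGS84 geographic tags, nodata
  −9999, written via tifffile; NetCDF via xarray's scipy backend
  (NETCDF3), CF-style coordinates.

## Known limitations

- The numpy training loop is single-core and suits desk-scale studies
  (minutes); production-scale sample counts would need a GPU framework.
- IDW fusion oversimplifies spatial dependence; kriging or graph models
  are out of scope.
- Imputed AOD is indistinguishable from retrieved AOD downstream (no
  per-entry quality flag reaches the network beyond the timestep mask).
- The season × region table uses calendar seasons and quadrant regions in
  synthetic runs; real-region analyses require an external polygon map.
- The directional studies are sign tests over 5 seeds, adequate for
  direction, not for effect-size estimation.
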