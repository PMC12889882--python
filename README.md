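# airsurf

Daily surface-PM2.5 estimation from fused ground-station and
satellite-style covariates, built for exposure assessment work
(epidemiological cohorts, air-quality monitoring) where concentrations
are needed at places and times no monitor covers.

The estimator is a masked three-layer bidirectional LSTM with Luong
multiplicative attention over a 21-day covariate window. For a target
location and day *t* it consumes the scaled feature sequence
x_{t−20}, …, x_t (two AOD bands, meteorology, wildfire smoke density,
elevation, NDVI, an inverse-distance-weighted station feature, location,
and temporal encodings), computes normalized hidden states ĥ_s, and
predicts

    score(ĥ_t, ĥ_s) = ĥ_tᵀ W ĥ_s
    α_{t,s}          = softmax_s score(ĥ_t, ĥ_s)      (masked; Σ_s α = 1)
    c_t              = Σ_s α_{t,s} ĥ_s
    h̃_t             = tanh(W_c [c_t ; ĥ_t])  →  dense  →  PM2.5(t)

trained with Huber loss under Adam and an exponential learning-rate
decay (×0.8 every 30 000 steps). The station feature is the
inverse-distance-weighted mean of the nine nearest same-day reporting
monitors; during training and evaluation the target's own record is
excluded (leave-target-out) so the feature cannot leak the answer.
Missing timesteps are masked, and the model's output is exactly
invariant to whatever a masked row stores.

Because real multi-source archives are not required here, the package
ships a seeded synthetic-world generator with the statistical structure
the estimator assumes — a seasonal, spatially correlated, AR(1)-in-time
PM2.5 field; episodic smoke events; gappy AOD linearly tied to PM2.5;
sparse stations reporting every n-th day — so the whole pipeline is
testable end to end. The network and its training loop are pure
numpy on a small reverse-mode autodiff engine; gradients are verified
against finite differences.

## Worked example

```python
from airsurf import generate_world
from airsurf.pipeline import run_experiment
from airsurf.studies import temporal_study_world

world = generate_world(temporal_study_world(seed=5))
result = run_experiment(world, widths=(16, 8, 8), seed=0,
                        train_overrides={"max_epochs": 60, "patience": 12,
                                         "batch_size": 48, "initial_lr": 5e-3})
print(result.report.render())
```

prints (about two minutes on one core):

```
n=100  R2=0.479  RMSE=4.102  MBE=-0.542 ug/m3
-- by category --
           n      rmse       mbe
Good      54  3.746205  0.772583
Moderate  46  4.483859 -2.086115
-- by season --
         n      rmse       mbe
winter  46  4.110724  0.051151
spring  54  4.094617 -1.048051
...
```

The held-out test set (n = 100 station-days) is scored with R² (variance
explained), RMSE (typical error, µg/m³), and MBE (systematic bias,
positive = overestimation), stratified by AQI-style concentration
category, season, and grid-quadrant region. On this world the day-t
features are deliberately gappy and noisy, so ~0.5 R² at a 4 µg/m³ RMSE
reflects a model extracting most of what the 21-day window offers; a
point-to-point random forest on the same splits lands at 4.03 µg/m³ at
this short training budget (`airsurf.pipeline.compare_baselines` runs
the multi-seed comparison at the full budget, where the sequence model
leads on most seeds).

The `examples/` scripts walk each capability: world simulation, KNN-IDW
fusion and its leakage control, training/evaluation, attention-weight
introspection, and gridded GeoTIFF surfaces. A thin CLI covers the same
pipeline from the shell:

```bash
airsurf simulate --config w.yaml --seed 7 --out world/
airsurf fuse --world world/ --out idw.csv
airsurf features --world world/ --idw idw.csv --out features.csv
airsurf train --world world/ --features features.csv --out model.npz
airsurf evaluate --world world/ --features features.csv --checkpoint model.npz --out report.json
airsurf predict --world world/ --checkpoint model.npz --date 2020-02-15 --outdir rasters/
```

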