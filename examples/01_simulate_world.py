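"""Generate a synthetic monitoring world and inspect its structure.

The world carries a ground-truth PM2.5 field (seasonal cycle + spatially
correlated AR(1) Gaussian field + smoke term + noise, clamped at zero),
gridded covariates including two gappy AOD bands, an ordinal smoke-density
stack, and a sparse station network reporting every third day.
"""

import numpy as np

from airsurf import WorldConfig, generate_world

cfg = WorldConfig(grid_nx=16, grid_ny=16, cell_km=12.0, n_stations=20,
                  n_days=90, station_reporting_period=3,
                  aod_missing_rate=0.35, seed=42)
world = generate_world(cfg)

pm = world.true_pm25.values
print(f"grid {cfg.grid_ny}x{cfg.grid_nx}, {cfg.n_days} days, "
      f"{cfg.n_stations} stations, {len(world.observations)} observations")
print(f"true PM2.5: mean {pm.mean():.2f}, sd {pm.std():.2f} ug/m3 "
      "(seasonal + spatial field + smoke + noise)")
d = world.smoke_density.values
print(f"smoke cover: {(d > 0).mean():.1%} of cell-days; "
      f"heavy (level 3): {(d == 3).mean():.2%}")
aod = world.covariates['aod_047'].values
print(f"AOD missing: {np.isnan(aod).mean():.1%} of cell-days "
      "(emulating cloud/bright-surface retrieval gaps)")
ok = ~np.isnan(aod)
r = np.corrcoef(aod[ok], pm[ok])[0, 1]
print(f"corr(observed AOD, true PM2.5) = {r:.2f} — the satellite signal is "
      "informative where retrieved, but a third of cell-days have no retrieval")
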