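"""Produce continuous daily PM2.5 surfaces from a trained model.

After evaluation the fusion switches to full mode (all station data), each
grid cell gets its own masked 21-day sequence, and the model emits one
non-negative surface per day, written as GeoTIFF.
"""

import tempfile
from pathlib import Path

from airsurf import generate_world, predict_grid, write_geotiff
from airsurf.pipeline import run_experiment
from airsurf.studies import e2e_study_world

world = generate_world(e2e_study_world(seed=11))
result = run_experiment(world, widths=(8, 8), seed=0,
                        train_overrides={"max_epochs": 15, "batch_size": 64,
                                         "initial_lr": 5e-3})

dates = world.dates[[40, 41]]
surfaces = predict_grid(result.model, result.pipeline, world, dates)
print(f"surfaces: {surfaces.shape} (day, y, x), all >= 0: "
      f"{(surfaces.values >= 0).all()}")
for i, d in enumerate(dates):
    s = surfaces.values[i]
    print(f"  {d.date()}: min {s.min():.1f}, mean {s.mean():.1f}, "
          f"max {s.max():.1f} ug/m3")

outdir = Path(tempfile.mkdtemp())
p = write_geotiff(outdir / f"pm25_{dates[0].date()}.tif",
                  surfaces.values[0], world.lon, world.lat)
print(f"wrote {p} (float32 GeoTIFF, WGS84 tags, nodata -9999)")
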