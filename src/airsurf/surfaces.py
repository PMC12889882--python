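"""Gridded inference and raster output.

``predict_grid`` builds, for every grid cell and requested date, the same
masked 21-day sequence the estimator was trained on — with the station
feature in full mode ("all available data"), since production surfaces are
not subject to the leave-target-out leakage control — runs inference,
inverse-scales, and clamps at zero. Rasters are written as float32 GeoTIFF
(WGS84 georeferencing tags, nodata -9999) or a CF-style NetCDF stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import FusionConfig, ModelConfig
from .features import FeaturePipeline, SENTINEL, assign_ndvi, encode_time, impute_aod
from .fusion import grid_idw_feature
from .model import PM25SequenceModel
from .world import World

__all__ = ["predict_grid", "write_geotiff", "write_netcdf_stack",
           "save_checkpoint", "load_checkpoint"]

NODATA = -9999.0


def _grid_feature_cube(world: World, pipeline: FeaturePipeline,
                       dates: pd.DatetimeIndex,
                       fusion_config: FusionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Raw (unscaled) features for every cell over ``dates``.

    Returns (cube (n_dates, n_cells, F), missing-any flags) with NaN for
    missing entries, feature order per the pipeline.
    """
    cfg = world.config
    cov = world.covariates
    names = pipeline.feature_names
    ny, nx = cfg.grid_ny, cfg.grid_nx
    lon2, lat2 = np.meshgrid(world.lon, world.lat)
    lonf, latf = lon2.ravel(), lat2.ravel()

    aod47, aod55 = cov["aod_047"], cov["aod_055"]
    if np.isnan(aod47.values).any():
        aod47 = impute_aod(aod47, cov, world.ndvi_layers)
        aod55 = impute_aod(aod55, cov, world.ndvi_layers)

    idw = grid_idw_feature(world.observations, lonf, latf, dates, fusion_config)
    ndvi_dates = pd.DatetimeIndex(world.ndvi_layers["ndvi_time"].values)
    tmap = {pd.Timestamp(d): i for i, d in enumerate(world.dates)}

    n_cells = ny * nx
    cube = np.empty((len(dates), n_cells, len(names)))
    for ti, d in enumerate(dates):
        wt = tmap[pd.Timestamp(d)]
        enc = encode_time(d)
        cols = {}
        cols["aod_047"] = aod47.values[wt].ravel()
        cols["aod_055"] = aod55.values[wt].ravel()
        for v in ("dayl", "prcp", "srad", "tmax", "tmin", "vp",
                  "wind_th", "wind_vs", "wsd"):
            cols[v] = cov[v].values[wt].ravel()
        cols["elevation"] = cov["elevation"].values.ravel()
        cols["ndvi"] = world.ndvi_layers.values[assign_ndvi(d, ndvi_dates)].ravel()
        cols["idw_pm25"] = idw[ti]
        cols["lat"] = latf
        cols["lon"] = lonf
        for j, nm in enumerate(("cos_doy", "sin_doy", "cos_month",
                                "sin_month", "year")):
            cols[nm] = np.full(n_cells, enc[j])
        cube[ti] = np.column_stack([cols[nm] for nm in names])
    return cube, idw


def predict_grid(model: PM25SequenceModel, pipeline: FeaturePipeline,
                 world: World, dates: pd.DatetimeIndex | list,
                 fusion_config: FusionConfig | None = None,
                 batch_size: int = 2048) -> xr.DataArray:
    """Daily PM2.5 surfaces for the requested dates (ug/m3, clamped >= 0)."""
    fusion_config = fusion_config or FusionConfig(mode="full")
    dates = pd.DatetimeIndex(pd.to_datetime(list(np.atleast_1d(dates))))
    W = pipeline.window
    earliest = world.dates[W - 1]
    bad = dates[dates < earliest]
    if len(bad):
        raise ValueError(
            f"insufficient look-back for {[str(b.date()) for b in bad]}; "
            f"earliest valid date is {earliest.date()}")

    # features for the union of all needed window days
    need = pd.date_range(min(dates) - pd.Timedelta(days=W - 1), max(dates), freq="D")
    cube, _ = _grid_feature_cube(world, pipeline, need, fusion_config)
    pos = {pd.Timestamp(d): i for i, d in enumerate(need)}

    names = pipeline.feature_names
    idw_col = names.index("idw_pm25")
    aod_cols = [names.index(c) for c in ("aod_047", "aod_055") if c in names]
    cfg = world.config
    n_cells = cfg.grid_ny * cfg.grid_nx
    out = np.empty((len(dates), cfg.grid_ny, cfg.grid_nx))

    for ti, d in enumerate(dates):
        t_end = pos[pd.Timestamp(d)]
        block = cube[t_end - W + 1: t_end + 1]              # (W, n_cells, F)
        absent = np.isnan(block).all(axis=2)
        no_signal = np.isnan(block[:, :, idw_col])
        if aod_cols:
            no_signal &= np.isnan(block[:, :, aod_cols]).all(axis=2)
        mask = (absent | no_signal).T                        # (n_cells, W)
        filled = np.where(np.isnan(block), pipeline.medians[None, None, :], block)
        scaled = pipeline.scaler.transform(
            filled.reshape(-1, len(names))).reshape(block.shape)
        X = scaled.transpose(1, 0, 2).copy()                 # (n_cells, W, F)
        X[mask] = SENTINEL
        pred = model.predict(X, mask, batch_size=batch_size)
        pm = np.maximum(pipeline.unscale_y(pred), 0.0)
        out[ti] = pm.reshape(cfg.grid_ny, cfg.grid_nx)

    return xr.DataArray(out, dims=("time", "y", "x"),
                        coords={"time": dates, "y": world.lat, "x": world.lon},
                        name="pm25", attrs={"units": "ug/m3"})


# ---------------------------------------------------------------------------
# Raster writers
# ---------------------------------------------------------------------------

def write_geotiff(path: str | Path, arr2d: np.ndarray, lon: np.ndarray,
                  lat: np.ndarray, nodata: float = NODATA) -> Path:
    """Float32 north-up GeoTIFF with WGS84 geographic georeferencing."""
    import tifffile

    arr = np.asarray(arr2d, dtype=np.float32)
    lat = np.asarray(lat, float)
    if lat[0] < lat[-1]:                 # store north-up
        arr = arr[::-1]
        lat = lat[::-1]
    arr = np.where(np.isfinite(arr), arr, np.float32(nodata))
    dlon = float(abs(lon[1] - lon[0]))
    dlat = float(abs(lat[0] - lat[1]))
    top = float(lat[0]) + dlat / 2.0
    left = float(lon[0]) - dlon / 2.0
    geokeys = [1, 1, 0, 3,               # version, rev, minor, nkeys
               1024, 0, 1, 2,            # GTModelType = geographic
               1025, 0, 1, 1,            # RasterType = PixelIsArea
               2048, 0, 1, 4326]         # GeographicType = WGS84
    extratags = [
        (33550, "d", 3, (dlon, dlat, 0.0)),                 # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, left, top, 0.0)),   # ModelTiepoint
        (34735, "H", len(geokeys), tuple(geokeys)),         # GeoKeyDirectory
        (42113, "s", 0, str(nodata)),                       # GDAL_NODATA
    ]
    path = Path(path)
    tifffile.imwrite(path, arr, extratags=extratags)
    return path


def write_netcdf_stack(path: str | Path, surfaces: xr.DataArray) -> Path:
    ds = surfaces.to_dataset(name="pm25")
    ds.x.attrs.update(standard_name="longitude", units="degrees_east")
    ds.y.attrs.update(standard_name="latitude", units="degrees_north")
    ds.to_netcdf(Path(path), engine="scipy")
    return Path(path)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: PM25SequenceModel,
                    pipeline: FeaturePipeline) -> Path:
    """Versioned archive: weights + model config + scaler + feature schema."""
    meta = {
        "format_version": 1,
        "model_config": {**vars(model.config),
                         "layer_widths": list(model.config.layer_widths)},
        "pipeline": pipeline.to_dict(),
        "schema_hash": model.schema_hash(pipeline.feature_names),
    }
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(Path(path), meta=json.dumps(meta), **weights)
    return Path(path)


def load_checkpoint(path: str | Path) -> tuple[PM25SequenceModel, FeaturePipeline]:
    """Load and validate a checkpoint; the stored schema hash must match
    the reconstructed model + feature order."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
    mc = meta["model_config"]
    mc["layer_widths"] = tuple(mc["layer_widths"])
    model = PM25SequenceModel(ModelConfig(**mc))
    model.set_weights(weights)
    pipeline = FeaturePipeline.from_dict(meta["pipeline"])
    if model.schema_hash(pipeline.feature_names) != meta["schema_hash"]:
        raise ValueError("checkpoint schema hash mismatch")
    return model, pipeline
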