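"""Seeded synthetic spatiotemporal worlds for exercising the estimator.

The generator emulates the data regime the estimator is built for: a sparse,
irregularly reporting monitoring network over a grid; a ground-truth PM2.5
field with a seasonal cycle, spatial correlation, and day-to-day
persistence; episodic wildfire-smoke events that elevate PM2.5 in
proportion to an ordinal density category; aerosol optical depth (AOD)
linearly related to PM2.5 and subject to masking; and weakly informative
meteorological covariates.

Ground truth:

    PM2.5(s,t) = baseline_mu + seasonal_amp*cos(2*pi*(doy-1)/365)
                 + G(s,t) + smoke_beta*density(s,t) + eps(s,t),   clamped >= 0

where G is a unit-range exponential-covariance Gaussian field (simulated by
circulant embedding on the grid) evolving as an AR(1) in time with
stationary sd ``field_sd``, and eps is white noise of sd ``noise_sd``.
Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import WorldConfig

__all__ = ["World", "generate_world", "inject_smoke_events",
           "apply_aod_missingness", "sample_station_observations",
           "write_world", "load_world"]

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON_EQ = 111.320

MET_VARS = ("dayl", "prcp", "srad", "tmax", "tmin", "vp", "wind_th", "wind_vs")


# ---------------------------------------------------------------------------
# Gaussian random field via circulant embedding
# ---------------------------------------------------------------------------

class GaussianFieldSampler:
    """Unit-variance stationary field with exponential covariance
    exp(-d / range_km), sampled exactly on a torus embedding of the grid.

    Negative embedding eigenvalues (the exponential kernel is not always
    exactly embeddable) are clamped to zero; the resulting approximation
    error is negligible at the ranges used here and is covered by the
    stationarity checks in the test suite.
    """

    def __init__(self, ny: int, nx: int, cell_km: float, range_km: float):
        self.ny, self.nx = ny, nx
        my, mx = 2 * ny, 2 * nx
        iy = np.minimum(np.arange(my), my - np.arange(my))
        ix = np.minimum(np.arange(mx), mx - np.arange(mx))
        d = np.hypot(iy[:, None] * cell_km, ix[None, :] * cell_km)
        lam = np.fft.fft2(np.exp(-d / range_km)).real
        self._sqrt_lam = np.sqrt(np.maximum(lam, 0.0))
        self._norm = np.sqrt(my * mx)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        shape = self._sqrt_lam.shape
        eps = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        f = np.fft.fft2(self._sqrt_lam * eps) / self._norm
        return f.real[: self.ny, : self.nx]


# ---------------------------------------------------------------------------
# World container
# ---------------------------------------------------------------------------

@dataclass
class World:
    """A generated synthetic world; all stacks share dims (time, y, x)."""

    config: WorldConfig
    dates: pd.DatetimeIndex
    lon: np.ndarray                  # (nx,)
    lat: np.ndarray                  # (ny,)
    true_pm25: xr.DataArray          # (time, y, x), ug/m3, >= 0
    covariates: xr.Dataset           # aod_047, aod_055, met vars, wsd, elevation
    smoke_density: xr.DataArray      # ordinal {0,1,2,3}
    ndvi_layers: xr.DataArray        # (ndvi_time, y, x), 16-day cadence
    stations: pd.DataFrame           # station_id, lon, lat, ix, iy
    observations: pd.DataFrame = field(default_factory=pd.DataFrame)
    aod_mask: np.ndarray | None = None
    _components: dict = field(default_factory=dict, repr=False)

    def station_cell(self, station_id: str) -> tuple[int, int]:
        row = self.stations.set_index("station_id").loc[station_id]
        return int(row.iy), int(row.ix)


def _grid_coords(cfg: WorldConfig) -> tuple[np.ndarray, np.ndarray]:
    lat = cfg.lat0 + np.arange(cfg.grid_ny) * cfg.cell_km / KM_PER_DEG_LAT
    lon = cfg.lon0 + np.arange(cfg.grid_nx) * cfg.cell_km / (
        KM_PER_DEG_LON_EQ * np.cos(np.deg2rad(cfg.lat0)))
    return lon, lat


def _doy(dates: pd.DatetimeIndex) -> np.ndarray:
    return dates.dayofyear.to_numpy()


def seasonal_cycle(dates: pd.DatetimeIndex, amp: float) -> np.ndarray:
    """amp * cos(2*pi*(doy-1)/365); leap years ignored by convention."""
    return amp * np.cos(2 * np.pi * (_doy(dates) - 1) / 365.0)


def _derive_pm25(world: World) -> None:
    """Recompute true PM2.5 from stored components + current smoke field."""
    cfg = world.config
    comp = world._components
    pm = (cfg.baseline_mu
          + comp["seasonal"][:, None, None]
          + comp["G"]
          + cfg.smoke_beta * world.smoke_density.values
          + comp["eps"])
    world.true_pm25 = xr.DataArray(
        np.maximum(pm, 0.0), dims=("time", "y", "x"),
        coords={"time": world.dates, "y": world.lat, "x": world.lon},
        name="pm25", attrs={"units": "ug/m3"})


def _place_stations(cfg: WorldConfig, lon: np.ndarray, lat: np.ndarray,
                    rng: np.random.Generator) -> pd.DataFrame:
    n_cells = cfg.grid_nx * cfg.grid_ny
    if cfg.station_placement == "uniform":
        cells = rng.choice(n_cells, size=cfg.n_stations, replace=False)
    else:  # clustered: stations drawn around a few centers
        n_clusters = max(2, cfg.n_stations // 10)
        centers = rng.choice(n_cells, size=n_clusters, replace=False)
        cy, cx = np.divmod(centers, cfg.grid_nx)
        chosen: set[int] = set()
        while len(chosen) < cfg.n_stations:
            j = rng.integers(n_clusters)
            iy = int(np.clip(round(cy[j] + rng.normal(0, cfg.grid_ny / 10)), 0, cfg.grid_ny - 1))
            ix = int(np.clip(round(cx[j] + rng.normal(0, cfg.grid_nx / 10)), 0, cfg.grid_nx - 1))
            chosen.add(iy * cfg.grid_nx + ix)
        cells = np.fromiter(chosen, dtype=int)
    iy, ix = np.divmod(np.sort(cells), cfg.grid_nx)
    return pd.DataFrame({
        "station_id": [f"S{i:03d}" for i in range(cfg.n_stations)],
        "lon": lon[ix], "lat": lat[iy], "ix": ix, "iy": iy,
    })


def generate_world(config: WorldConfig, n_smoke_events: int | None = None,
                   event_radius_km: float | None = None,
                   event_duration_days: int = 5) -> World:
    """Generate a complete world: fields, smoke, covariates, stations,
    observations, and AOD masking — a pure function of (config, seed).

    By default one smoke event is seeded per ~15 days of record; pass
    ``n_smoke_events=0`` for a smoke-free world.
    """
    cfg = config.validate()
    root = np.random.SeedSequence(cfg.seed)
    (rng_field, rng_smoke, rng_met, rng_aod, rng_mask,
     rng_station, rng_obs) = (np.random.default_rng(s) for s in root.spawn(7))

    lon, lat = _grid_coords(cfg)
    dates = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
    sampler = GaussianFieldSampler(cfg.grid_ny, cfg.grid_nx, cfg.cell_km,
                                   cfg.spatial_range_km)

    # AR(1)-in-time, spatially correlated Gaussian field, stationary sd field_sd
    G = np.empty((cfg.n_days, cfg.grid_ny, cfg.grid_nx))
    G[0] = cfg.field_sd * sampler.sample(rng_field)
    innov_sd = cfg.field_sd * np.sqrt(1.0 - cfg.ar1_rho ** 2)
    for t in range(1, cfg.n_days):
        G[t] = cfg.ar1_rho * G[t - 1] + innov_sd * sampler.sample(rng_field)
    eps = rng_field.normal(0.0, cfg.noise_sd, size=G.shape) if cfg.noise_sd > 0 \
        else np.zeros_like(G)

    world = World(
        config=cfg, dates=dates, lon=lon, lat=lat,
        true_pm25=xr.DataArray(np.zeros_like(G), dims=("time", "y", "x"),
                               coords={"time": dates, "y": lat, "x": lon}),
        covariates=xr.Dataset(),
        smoke_density=xr.DataArray(np.zeros(G.shape, dtype=np.int8),
                                   dims=("time", "y", "x"),
                                   coords={"time": dates, "y": lat, "x": lon}),
        ndvi_layers=xr.DataArray(),
        stations=_place_stations(cfg, lon, lat, rng_station),
        _components={"seasonal": seasonal_cycle(dates, cfg.seasonal_amp),
                     "G": G, "eps": eps},
    )

    if n_smoke_events is None:
        n_smoke_events = max(1, cfg.n_days // 15) if cfg.smoke_beta != 0 else 0
    if event_radius_km is None:
        event_radius_km = 4.0 * cfg.cell_km
    if n_smoke_events > 0:
        inject_smoke_events(world, n_smoke_events, event_radius_km,
                            event_duration_days, rng_smoke)
    else:
        _derive_pm25(world)

    _build_covariates(world, rng_met, rng_aod)
    if cfg.aod_missing_rate > 0 or cfg.aod_smoke_missing_rate:
        apply_aod_missingness(world, cfg.aod_missing_rate, rng_mask,
                              smoke_rate=cfg.aod_smoke_missing_rate)
    else:
        world.aod_mask = np.zeros(G.shape, dtype=bool)
    world.observations = sample_station_observations(world, cfg, rng_obs)
    return world


def inject_smoke_events(world: World, n_events: int, event_radius_km: float,
                        event_duration_days: int,
                        rng: np.random.Generator) -> World:
    """Place spatiotemporal smoke disks and re-derive the PM2.5 field.

    Each event is a disk of radius ``event_radius_km`` lasting
    ``event_duration_days``; density falls outward: 3 (heavy) inside r/3,
    2 (medium) inside 2r/3, 1 (light) inside r. Overlaps take the maximum.
    """
    if n_events < 0 or event_radius_km <= 0 or event_duration_days <= 0:
        raise ValueError("smoke event parameters must be positive")
    cfg = world.config
    density = np.zeros((cfg.n_days, cfg.grid_ny, cfg.grid_nx), dtype=np.int8)
    yy, xx = np.mgrid[0:cfg.grid_ny, 0:cfg.grid_nx]
    for _ in range(n_events):
        cy = rng.integers(cfg.grid_ny)
        cx = rng.integers(cfg.grid_nx)
        t0 = rng.integers(cfg.n_days)
        d_km = np.hypot(yy - cy, xx - cx) * cfg.cell_km
        disk = np.where(d_km <= event_radius_km / 3.0, 3,
                        np.where(d_km <= 2.0 * event_radius_km / 3.0, 2,
                                 np.where(d_km <= event_radius_km, 1, 0)))
        t1 = min(cfg.n_days, t0 + event_duration_days)
        density[t0:t1] = np.maximum(density[t0:t1], disk.astype(np.int8))
    world.smoke_density = xr.DataArray(
        density, dims=("time", "y", "x"),
        coords={"time": world.dates, "y": world.lat, "x": world.lon})
    _derive_pm25(world)
    if "wsd" in world.covariates:
        world.covariates["wsd"] = world.smoke_density.astype(float)
    return world


def _build_covariates(world: World, rng_met: np.random.Generator,
                      rng_aod: np.random.Generator) -> None:
    """Populate covariate stacks: two AOD bands tied linearly to PM2.5,
    weakly informative meteorology, static elevation, 16-day NDVI, WSD."""
    cfg = world.config
    T, ny, nx = cfg.n_days, cfg.grid_ny, cfg.grid_nx
    angle = 2 * np.pi * (_doy(world.dates) - 1) / 365.0
    sampler = GaussianFieldSampler(ny, nx, cfg.cell_km, cfg.spatial_range_km)

    def smooth(sd):
        return sd * sampler.sample(rng_met)

    season = np.cos(angle)[:, None, None]
    pm = world.true_pm25.values
    data = {}
    # Daymet-like surfaces: seasonal signal + smooth spatial texture + noise
    data["dayl"] = 43200.0 - 14400.0 * season + rng_met.normal(0, 300, (T, ny, nx))
    data["prcp"] = np.maximum(rng_met.exponential(2.0, (T, ny, nx)) - 1.0, 0.0)
    data["srad"] = 280.0 - 120.0 * season + smooth(15.0) + rng_met.normal(0, 10, (T, ny, nx))
    tmax = 16.0 - 11.0 * season + smooth(2.0) + rng_met.normal(0, 1.5, (T, ny, nx))
    data["tmax"] = tmax
    data["tmin"] = tmax - 8.0 + rng_met.normal(0, 1.0, (T, ny, nx))
    data["vp"] = 750.0 + 40.0 * data["tmin"] + rng_met.normal(0, 30, (T, ny, nx))
    data["wind_th"] = rng_met.uniform(0.0, 360.0, (T, ny, nx))
    data["wind_vs"] = rng_met.gamma(2.0, 2.0, (T, ny, nx))
    # AOD bands: linear in true PM2.5 with independent retrieval noise
    for name, band_scale in (("aod_047", 1.0), ("aod_055", 0.85)):
        noise = (rng_aod.normal(0, cfg.aod_noise_sd, (T, ny, nx))
                 if cfg.aod_noise_sd > 0 else 0.0)
        data[name] = band_scale * (cfg.aod_intercept + cfg.aod_slope * pm) + noise
    data["wsd"] = world.smoke_density.values.astype(float)

    coords = {"time": world.dates, "y": world.lat, "x": world.lon}
    ds = xr.Dataset({k: (("time", "y", "x"), v) for k, v in data.items()},
                    coords=coords)
    elev = 500.0 + 300.0 * sampler.sample(rng_met)
    ds["elevation"] = (("y", "x"), elev)
    world.covariates = ds

    # 16-day NDVI layers spanning the record
    ndvi_dates = pd.date_range(world.dates[0], world.dates[-1] + pd.Timedelta(days=15),
                               freq="16D")
    ndvi_angle = 2 * np.pi * (ndvi_dates.dayofyear.to_numpy() - 1) / 365.0
    layers = np.clip(
        0.35 + 0.2 * np.cos(ndvi_angle)[:, None, None]
        + np.stack([0.08 * sampler.sample(rng_met) for _ in ndvi_dates]),
        -1.0, 1.0)
    world.ndvi_layers = xr.DataArray(
        layers, dims=("ndvi_time", "y", "x"),
        coords={"ndvi_time": ndvi_dates, "y": world.lat, "x": world.lon})


def apply_aod_missingness(world: World, rate: float,
                          rng: np.random.Generator,
                          smoke_rate: float | None = None) -> World:
    """Independently mask each AOD cell-day with probability ``rate``.

    ``smoke_rate``, if given, replaces the probability on smoke-covered
    (density > 0) cell-days, emulating retrieval loss under heavy plumes.
    Both bands share a cell-day's retrieval, so they share its mask.
    Masked cells become NaN (the reserved missing marker); the mask is
    recorded on the world. Other covariates are untouched.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("aod missing rate must be in [0, 1)")
    shape = world.true_pm25.shape
    p = np.full(shape, rate)
    if smoke_rate is not None:
        p[world.smoke_density.values > 0] = smoke_rate
    mask = rng.random(shape) < p
    for band in ("aod_047", "aod_055"):
        vals = world.covariates[band].values
        vals[mask] = np.nan
        world.covariates[band] = (("time", "y", "x"), vals)
    world.aod_mask = mask
    return world


def sample_station_observations(world: World, config: WorldConfig,
                                rng: np.random.Generator | None = None
                                ) -> pd.DataFrame:
    """Station reports every ``station_reporting_period`` days (per-station
    phase offset), equal to the true field at the station's cell plus
    Gaussian measurement noise, clamped at zero."""
    cfg = config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0B5]).generate_state(1)[0])
    period = cfg.station_reporting_period
    true = world.true_pm25.values
    rows = []
    for i, st in world.stations.iterrows():
        phase = int(rng.integers(period)) if period > 1 else 0
        days = np.arange(phase, cfg.n_days, period)
        vals = true[days, int(st.iy), int(st.ix)]
        if cfg.obs_noise_sd > 0:
            vals = vals + rng.normal(0.0, cfg.obs_noise_sd, size=vals.shape)
        rows.append(pd.DataFrame({
            "station_id": st.station_id,
            "lon": st.lon, "lat": st.lat,
            "date": world.dates[days],
            "pm25": np.maximum(vals, 0.0),
        }))
    obs = pd.concat(rows, ignore_index=True)
    return obs


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_world(world: World, outdir: str | Path) -> dict:
    """Write stations CSV, CF-style NetCDF covariate stack, and a JSON
    manifest of config + seed. Returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs = world.observations.copy()
    obs["date"] = pd.to_datetime(obs["date"]).dt.strftime("%Y-%m-%d")
    obs[["station_id", "lon", "lat", "date", "pm25"]].to_csv(
        outdir / "stations.csv", index=False)
    ds = world.covariates.copy()
    ds["true_pm25"] = world.true_pm25
    ds.x.attrs.update(standard_name="longitude", units="degrees_east")
    ds.y.attrs.update(standard_name="latitude", units="degrees_north")
    ds.to_netcdf(outdir / "covariates.nc", engine="scipy")
    world.ndvi_layers.to_dataset(name="ndvi").to_netcdf(
        outdir / "ndvi.nc", engine="scipy")
    manifest = {"config": {k: (v.isoformat() if hasattr(v, "isoformat") else v)
                           for k, v in asdict(world.config).items()},
                "seed": world.config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_world(indir: str | Path) -> World:
    """Reconstruct a World from the artifacts written by ``write_world``.

    The generative components are not stored, so a loaded world supports
    fusion, feature building, training, and prediction, but not re-derivation
    of the truth field (``inject_smoke_events``).
    """
    from datetime import date as _Date

    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    cfg_raw = dict(manifest["config"])
    cfg_raw["start_date"] = _Date.fromisoformat(cfg_raw["start_date"])
    cfg = WorldConfig(**cfg_raw)
    ds = xr.load_dataset(indir / "covariates.nc", engine="scipy")
    ndvi = xr.load_dataset(indir / "ndvi.nc", engine="scipy")["ndvi"]
    obs = pd.read_csv(indir / "stations.csv", parse_dates=["date"])
    lon = ds["x"].values
    lat = ds["y"].values
    st = obs.drop_duplicates("station_id")[["station_id", "lon", "lat"]].copy()
    st["ix"] = [int(np.argmin(np.abs(lon - v))) for v in st["lon"]]
    st["iy"] = [int(np.argmin(np.abs(lat - v))) for v in st["lat"]]
    true = ds["true_pm25"]
    cov = ds.drop_vars("true_pm25")
    return World(
        config=cfg, dates=pd.DatetimeIndex(ds["time"].values), lon=lon, lat=lat,
        true_pm25=true, covariates=cov,
        smoke_density=cov["wsd"].astype(np.int8),
        ndvi_layers=ndvi, stations=st.reset_index(drop=True),
        observations=obs,
        aod_mask=np.isnan(cov["aod_047"].values),
    )
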