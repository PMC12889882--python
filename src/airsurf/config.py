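"""Configuration dataclasses for every pipeline stage, plus YAML loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """A configuration field violates its invariant; names the field."""


@dataclass
class WorldConfig:
    """Generative settings for the synthetic spatiotemporal world.

    The ground-truth field follows
    ``PM2.5(s,t) = baseline_mu + seasonal_amp*cos(2*pi*(doy-1)/365)
    + G(s,t) + smoke_beta*density(s,t) + eps``
    with G a spatially correlated (exponential covariance, range
    ``spatial_range_km``) AR(1)-in-time Gaussian field of stationary sd
    ``field_sd``, eps white noise of sd ``noise_sd``, and negative values
    clamped to zero.
    """

    grid_nx: int = 24
    grid_ny: int = 24
    cell_km: float = 10.0
    n_stations: int = 40
    n_days: int = 90
    start_date: Date = Date(2020, 1, 1)
    baseline_mu: float = 8.0      # mean PM2.5, ug/m3
    seasonal_amp: float = 3.0     # ug/m3
    spatial_range_km: float = 60.0
    ar1_rho: float = 0.8
    field_sd: float = 5.0         # stationary sd of G, ug/m3
    noise_sd: float = 1.0         # cell-level white noise, ug/m3
    obs_noise_sd: float = 1.0     # station measurement noise, ug/m3
    smoke_beta: float = 10.0      # ug/m3 added per smoke-density level
    aod_slope: float = 0.02       # AOD per (ug/m3) PM2.5
    aod_intercept: float = 0.05
    aod_noise_sd: float = 0.08   # moderate AOD|PM2.5 correlation, as in retrievals
    aod_missing_rate: float = 0.3
    # retrievals degrade under heavy aerosol loading: extra masking
    # probability for smoke-covered (density > 0) cell-days, optional
    aod_smoke_missing_rate: float | None = None
    station_reporting_period: int = 1
    station_placement: str = "uniform"  # or "clustered"
    lon0: float = -120.0          # grid origin, degrees WGS84
    lat0: float = 40.0
    seed: int = 0

    def validate(self) -> "WorldConfig":
        if self.n_stations < 10:
            raise ConfigError("n_stations must be >= 10 (KNN-IDW needs 9 neighbors + self)")
        if self.n_days < 21:
            raise ConfigError("n_days must be >= 21 (one full sequence window)")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ConfigError("ar1_rho must be in [0, 1)")
        if not 0.0 <= self.aod_missing_rate < 1.0:
            raise ConfigError("aod_missing_rate must be in [0, 1)")
        if self.aod_smoke_missing_rate is not None and \
                not 0.0 <= self.aod_smoke_missing_rate < 1.0:
            raise ConfigError("aod_smoke_missing_rate must be in [0, 1)")
        for name in ("cell_km", "spatial_range_km"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("field_sd", "noise_sd", "obs_noise_sd", "seasonal_amp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.station_reporting_period < 1:
            raise ConfigError("station_reporting_period must be >= 1")
        if self.station_placement not in ("uniform", "clustered"):
            raise ConfigError("station_placement must be 'uniform' or 'clustered'")
        return self


@dataclass
class FusionConfig:
    """KNN-IDW settings. Nine nearest stations, weights ~ 1/distance."""

    k: int = 9
    idw_power: float = 1.0
    mode: str = "leave_target_out"  # or "full"

    def validate(self) -> "FusionConfig":
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.idw_power <= 0:
            raise ConfigError("idw_power must be positive")
        if self.mode not in ("leave_target_out", "full"):
            raise ConfigError("mode must be 'leave_target_out' or 'full'")
        return self


@dataclass
class ModelConfig:
    """Architecture of the masked bidirectional recurrent regressor.

    ``layer_widths`` are read as total units per layer (half per direction)
    when ``width_interpretation == 'total'``; set ``'per_direction'`` for
    the alternative reading.
    """

    layer_widths: tuple[int, ...] = (256, 128, 128)
    dropout_rate: float = 0.2
    window: int = 21
    n_features: int = 21
    bidirectional: bool = True
    width_interpretation: str = "total"
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if any(w <= 0 for w in self.layer_widths):
            raise ConfigError("layer_widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.width_interpretation not in ("total", "per_direction"):
            raise ConfigError("width_interpretation must be 'total' or 'per_direction'")
        if self.width_interpretation == "total" and self.bidirectional \
                and any(w % 2 for w in self.layer_widths):
            raise ConfigError("total layer_widths must be even for a bidirectional model")
        return self


@dataclass
class TrainConfig:
    """Optimization settings: Adam under an exponential learning-rate decay
    (times ``decay_rate`` every ``decay_steps`` steps, continuous) and
    Huber loss with transition point ``huber_delta`` in scaled-target units."""

    initial_lr: float = 1e-3
    decay_rate: float = 0.8
    decay_steps: int = 30_000
    staircase: bool = False
    batch_size: int = 256
    huber_delta: float = 1.0
    max_epochs: int = 100
    patience: int = 10
    early_stopping: bool = True
    clip_norm: float = 5.0       # global gradient-norm clip; 0 disables
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if not 0.0 < self.decay_rate < 1.0:
            raise ConfigError("decay_rate must be in (0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.huber_delta <= 0:
            raise ConfigError("huber_delta must be positive")
        return self


def _coerce(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if fields[k].type in ("Date", "datetime.date") or k == "start_date":
            v = v if isinstance(v, Date) else Date.fromisoformat(str(v))
        if k == "layer_widths":
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs).validate()


def load_config(path: str | Path) -> dict:
    """Load a YAML file with optional ``world``, ``fusion``, ``model``,
    ``train`` sections into validated dataclasses."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, cls in (("world", WorldConfig), ("fusion", FusionConfig),
                     ("model", ModelConfig), ("train", TrainConfig)):
        out[key] = _coerce(cls, raw.get(key, {}))
    return out
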