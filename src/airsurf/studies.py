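"""Frozen study conditions for the simulation experiments.

Each function returns the world configuration (and companion training
settings) for one experiment family, scaled to desk size: grids of a few
hundred cells, tens of stations, a few months of record, and reduced
recurrent widths (16, 8, 8). The generative settings emulate the data
regime the estimator targets — sparse, irregularly reporting stations
(1-in-3 cadence), AOD with retrieval gaps and moderate correlation to
PM2.5, strong day-to-day persistence of the pollution field, and episodic
smoke — and are fixed once here so every consumer (tests, acceptance
script, examples) runs the same conditions.
"""

from __future__ import annotations

from datetime import date

from .config import WorldConfig

__all__ = [
    "temporal_study_world", "TEMPORAL_TRAIN", "STUDY_WIDTHS",
    "ablation_study_world", "ABLATION_TRAIN", "ABLATION_EVENTS",
    "imputation_study_world", "e2e_study_world",
]

STUDY_WIDTHS = (16, 8, 8)

# Training settings for the desk-scale model: a higher initial learning
# rate and smaller batches than the full-scale defaults, since only a few
# hundred gradient steps fit in a desk-scale run.
TEMPORAL_TRAIN = dict(max_epochs=160, patience=25, batch_size=48,
                      initial_lr=5e-3, n_restarts=2)
ABLATION_TRAIN = dict(max_epochs=80, patience=15, batch_size=48,
                      initial_lr=5e-3)

ABLATION_EVENTS = dict(n_smoke_events=16, event_radius_km=60.0,
                       event_duration_days=6)


def temporal_study_world(seed: int) -> WorldConfig:
    """Conditions for the temporal-vs-pointwise comparison: strong daily
    persistence (AR-1 rho 0.9), 1-in-3 station reporting, and AOD that is
    both gappy (50%) and noisy, so single-day features underdetermine the
    field and the 21-day window carries real information."""
    return WorldConfig(
        grid_nx=20, grid_ny=20, cell_km=12.0, n_stations=30, n_days=120,
        ar1_rho=0.9, station_reporting_period=3, obs_noise_sd=2.0,
        aod_missing_rate=0.5, aod_noise_sd=0.15, field_sd=6.0,
        spatial_range_km=60.0, seed=seed)


def ablation_study_world(smoke_beta: float, seed: int) -> WorldConfig:
    """Conditions for the smoke-density ablation: episodic smoke disks
    elevating PM2.5 by ``smoke_beta`` per ordinal level (0 for the null
    world, where the density field still varies but carries no signal)."""
    return WorldConfig(
        grid_nx=16, grid_ny=16, cell_km=12.0, n_stations=24, n_days=120,
        ar1_rho=0.8, station_reporting_period=3, smoke_beta=smoke_beta,
        aod_missing_rate=0.3, aod_smoke_missing_rate=0.85,
        field_sd=5.0, spatial_range_km=60.0, seed=seed)


def imputation_study_world(seed: int) -> WorldConfig:
    """Conditions for AOD gap-fill recovery: AOD an exact linear function
    of PM2.5 (no retrieval noise, no white noise), cells fine relative to
    the correlation range, persistent in time — the regime in which a
    spatiotemporal gap filler should reconstruct held-back retrievals."""
    return WorldConfig(
        grid_nx=14, grid_ny=14, cell_km=2.0, spatial_range_km=120.0,
        ar1_rho=0.95, seasonal_amp=6.0, field_sd=3.0, noise_sd=0.0,
        n_days=60, n_stations=10, start_date=date(2020, 3, 1),
        aod_noise_sd=0.0, aod_missing_rate=0.4, seed=seed)


def e2e_study_world(seed: int) -> WorldConfig:
    """A small daily-reporting world for end-to-end pipeline runs."""
    return WorldConfig(
        grid_nx=10, grid_ny=10, cell_km=15.0, n_stations=14, n_days=60,
        ar1_rho=0.7, station_reporting_period=1, aod_missing_rate=0.2,
        seed=seed)
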