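"""Synthetic trials, weather and rasters with the structure the framework assumes.

Multi-environment phenology trials are emulated as a set of sites spanning
a temperature gradient (the kind an altitudinal transect from highland to
lowland provides, roughly 11–20 °C minima and 24–37 °C maxima).  At each
site the true rate model gives a development rate, Gaussian noise is added
on the rate scale, and the implied duration is rounded to whole days the
way field scorers record phenology dates.  The generating parameters are
returned alongside the observations so recovery can be tested.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fitting import TrialObservation
from .rate_models import get_model, RateParams
from .spatial import ClimatologyStack, Raster
from .thermal import TemperatureSeries

__all__ = [
    "SimulationConfig",
    "generate_weather",
    "generate_trials",
    "generate_raster_stack",
    "DEFAULT_SITE_TEMPERATURES",
]

# representative phase-mean temperatures for a 16-trial altitudinal transect,
# spanning the calibration range without touching the thermal limits
DEFAULT_SITE_TEMPERATURES = tuple(np.linspace(12.0, 36.0, 16).tolist())


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise structure for a synthetic trial set."""

    true_model: str = "briere1"
    true_params: tuple = (2e-5, 9.0, 40.0)  # a, Tb, Tm for briere1
    site_temperatures: tuple = DEFAULT_SITE_TEMPERATURES
    noise_sd_rate: float = 5e-4
    seed: int = 0
    phase: str = "vegetative"
    variety: str = "SYN-1"
    # whole-day rounding mimics field recording of phenology dates; switch
    # off for exact-recovery oracles where the only perturbation must be
    # the configured rate noise
    round_durations: bool = True

    def __post_init__(self) -> None:
        spec = get_model(self.true_model)
        if len(self.site_temperatures) < spec.n_params + 1:
            raise ValueError(
                f"need at least {spec.n_params + 1} sites for {self.true_model!r}"
            )
        if self.noise_sd_rate < 0:
            raise ValueError("noise_sd_rate must be >= 0")
        if not all(0.0 < t < 50.0 for t in self.site_temperatures):
            raise ValueError("site temperatures must lie in (0, 50) °C")


def generate_weather(mean: float, amplitude: float, n_days: int,
                     diurnal_range: float = 10.0, noise_sd: float = 0.0,
                     phase_shift: float = 0.0, seed: int = 0,
                     start: str = "2004-03-01") -> TemperatureSeries:
    """Sinusoidal seasonal daily weather with independent Gaussian noise.

    The seasonal cycle has period 365 days; ``diurnal_range`` separates
    Tmax from Tmin symmetrically about the daily mean, so tmin <= tmax by
    construction.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    seasonal = mean + amplitude * np.sin(2.0 * np.pi * (t / 365.0) + phase_shift)
    noise = rng.normal(0.0, noise_sd, size=n_days) if noise_sd > 0 else 0.0
    mid = seasonal + noise
    half = abs(diurnal_range) / 2.0
    dates = np.datetime64(start, "D") + t
    return TemperatureSeries(dates, mid - half, mid + half)


def generate_trials(config: SimulationConfig):
    """Synthetic trial observations plus the generating truth.

    Per site: duration = round(1/(r_true(T) + eps)), eps ~ N(0, noise_sd);
    draws are rejected until the noisy rate is positive.  Sites outside the
    truth's thermal limits cannot complete the phase and are skipped with a
    warning.

    Returns (observations, truth) where truth is the config itself.
    """
    import warnings

    spec = get_model(config.true_model)
    theta = np.asarray(config.true_params, dtype=float)
    rng = np.random.default_rng(config.seed)
    obs = []
    for k, T in enumerate(config.site_temperatures):
        r_true = float(spec.rate(np.array([T]), theta)[0])
        if r_true <= 0.0:
            warnings.warn(
                f"site at {T} °C is outside the thermal limits of the truth; skipped",
                RuntimeWarning,
            )
            continue
        r_noisy = r_true + rng.normal(0.0, config.noise_sd_rate) if config.noise_sd_rate > 0 else r_true
        while r_noisy <= 0.0:
            r_noisy = r_true + rng.normal(0.0, config.noise_sd_rate)
        duration = max(round(1.0 / r_noisy), 1) if config.round_durations else 1.0 / r_noisy
        obs.append(TrialObservation(
            site=f"site-{k:02d}", variety=config.variety, phase=config.phase,
            duration_days=float(duration), mean_temp=float(T),
        ))
    return obs, config


def generate_raster_stack(nrows: int = 8, ncols: int = 8,
                          south_north_gradient: float = -1.0,
                          base_tmin: float = 16.0, base_tmax: float = 28.0,
                          seasonal_amplitude: float = 1.5,
                          nodata_fraction: float = 0.0,
                          suitable_fraction: float = 1.0,
                          cellsize: float = 0.1, seed: int = 0):
    """A co-registered 24-layer monthly climatology plus a suitability mask.

    Temperature varies linearly with row index (row 0 is the northernmost):
    ``south_north_gradient`` is °C per row moving south (downward in the
    array).  A small sinusoidal seasonal cycle distinguishes the months.
    Nodata cells and the suitable set are placed reproducibly from ``seed``.

    Returns (ClimatologyStack, suitability Raster).
    """
    if nrows < 2 or ncols < 2:
        raise ValueError("raster must be at least 2×2")
    rng = np.random.default_rng(seed)
    nd = -9999.0
    rowgrad = south_north_gradient * np.arange(nrows, dtype=float)[:, None]
    rowgrad = np.broadcast_to(rowgrad, (nrows, ncols)).copy()

    nodata_cells = np.zeros((nrows, ncols), dtype=bool)
    if nodata_fraction > 0:
        n_bad = int(round(nodata_fraction * nrows * ncols))
        flat = rng.choice(nrows * ncols, size=n_bad, replace=False)
        nodata_cells.ravel()[flat] = True

    months = np.arange(12)
    season = seasonal_amplitude * np.sin(2.0 * np.pi * months / 12.0)
    tmin_layers, tmax_layers = [], []
    geo = dict(xllcorner=34.0, yllcorner=-1.0, cellsize=cellsize, nodata_value=nd)
    for m in range(12):
        tmin = base_tmin + rowgrad + season[m]
        tmax = base_tmax + rowgrad + season[m]
        tmin = np.where(nodata_cells, nd, tmin)
        tmax = np.where(nodata_cells, nd, tmax)
        tmin_layers.append(Raster(values=tmin, **geo))
        tmax_layers.append(Raster(values=tmax, **geo))
    stack = ClimatologyStack(tmin=tuple(tmin_layers), tmax=tuple(tmax_layers))

    suitable = np.zeros((nrows, ncols), dtype=float)
    n_suit = int(round(suitable_fraction * nrows * ncols))
    flat = rng.permutation(nrows * ncols)[:n_suit]
    suitable.ravel()[flat] = 1.0
    mask = Raster(values=suitable, **geo)
    return stack, mask
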