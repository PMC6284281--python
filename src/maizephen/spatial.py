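"""Mapping phase durations over gridded temperature climatologies.

The workflow mirrors length-of-growing-period mapping practice: monthly
Tmin/Tmax climatology grids (ESRI ASCII format, the plain-text raster
dialect GIS packages exchange) are combined with a fitted rate curve to
produce a per-cell duration surface, which is then masked by a binary
crop-suitability raster.

Two mapping modes are provided.  ``inverse_rate`` evaluates the curve at
each cell's mean temperature and inverts it (days = 1/r) — the direct
reading of rate-as-inverse-duration.  ``accumulation`` (default) builds a
daily series from the monthly climatology at each cell and runs the daily
accumulation engine from a sowing day, which respects seasonality.  The
two agree exactly when the climate is constant in time.

Cells are nodata when any input layer is nodata there, and also when the
cell is outside the variety's thermal limits (r = 0, the phase can never
complete); the two causes are counted separately in the returned logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .rate_models import RateParams, get_model
from .thermal import (
    OutsideThermalLimits,
    PhaseNotCompletedError,
    TemperatureSeries,
    accumulate_development,
)

__all__ = [
    "Raster",
    "ClimatologyStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "synthesize_daily_series",
    "map_phase_duration",
    "apply_mask",
    "map_total_cycle",
]

log = logging.getLogger(__name__)

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass(frozen=True)
class Raster:
    """Single-band georeferenced grid; row 0 is the northernmost row."""

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return np.isclose(self.values, self.nodata_value) | ~np.isfinite(self.values)

    def same_geometry(self, other: "Raster") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.xllcorner, other.xllcorner)
                and np.isclose(self.yllcorner, other.yllcorner)
                and np.isclose(self.cellsize, other.cellsize))

    def with_values(self, values: np.ndarray) -> "Raster":
        return replace(self, values=values)


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid: 6 header lines, then rows north to south."""
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 7:
        raise ValueError(f"{path}: too short for an ESRI ASCII grid")
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed header at line {i + 1}: {line!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise ValueError(f"{path}: unexpected header key {parts[0]!r} at line {i + 1}")
        header[key] = float(parts[1])
    missing = set(_HEADER_KEYS) - set(header)
    if missing:
        raise ValueError(f"{path}: header lacks {sorted(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for i, line in enumerate(lines[6:], start=7):
        if not line.strip():
            continue
        row = line.split()
        if len(row) != ncols:
            raise ValueError(
                f"{path}: line {i} has {len(row)} values, expected ncols={ncols}"
            )
        rows.append([float(v) for v in row])
    if len(rows) != nrows:
        raise ValueError(f"{path}: {len(rows)} data rows, header says nrows={nrows}")
    return Raster(
        values=np.array(rows, dtype=float),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata_value=header["nodata_value"],
    )


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid with the standard 6-line header."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata_value:g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


@dataclass(frozen=True)
class ClimatologyStack:
    """Twelve monthly Tmin and twelve monthly Tmax rasters, co-registered."""

    tmin: tuple  # 12 Rasters, January..December
    tmax: tuple

    def __post_init__(self) -> None:
        if len(self.tmin) != 12 or len(self.tmax) != 12:
            raise ValueError("climatology stack needs 12 Tmin and 12 Tmax rasters")
        ref = self.tmin[0]
        for r in (*self.tmin, *self.tmax):
            if not ref.same_geometry(r):
                raise ValueError("climatology rasters are not co-registered")
            if not np.isclose(r.nodata_value, ref.nodata_value):
                raise ValueError("climatology rasters disagree on the nodata sentinel")

    @property
    def geometry(self) -> Raster:
        return self.tmin[0]

    def cell_monthly(self, row: int, col: int):
        """(tmin[12], tmax[12]) at one cell, or None if any layer is nodata."""
        tmin = np.array([r.values[row, col] for r in self.tmin])
        tmax = np.array([r.values[row, col] for r in self.tmax])
        nd = self.geometry.nodata_value
        if np.any(np.isclose(tmin, nd)) or np.any(np.isclose(tmax, nd)):
            return None
        return tmin, tmax

    def nodata_mask(self) -> np.ndarray:
        m = np.zeros(self.geometry.values.shape, dtype=bool)
        for r in (*self.tmin, *self.tmax):
            m |= r.mask
        return m


def _monthly_to_daily(monthly: np.ndarray, mode: str) -> np.ndarray:
    """Expand 12 monthly values to 365 daily ones."""
    if mode == "step":
        return np.repeat(monthly, _MONTH_DAYS)
    if mode == "smooth":
        # linear interpolation between month midpoints, wrapping the year
        mid = np.cumsum(_MONTH_DAYS) - _MONTH_DAYS / 2.0  # day-of-year of midpoints
        knots_x = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
        knots_y = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
        days = np.arange(365) + 0.5
        return np.interp(days, knots_x, knots_y)
    raise ValueError(f"unknown daily-synthesis mode {mode!r}")


def synthesize_daily_series(stack: ClimatologyStack, row: int, col: int,
                            sowing_day_of_year: int = 1, n_days: int = 730,
                            mode: str = "smooth") -> Optional[TemperatureSeries]:
    """Daily Tmin/Tmax series at a cell, starting at a sowing day-of-year.

    The 12 monthly normals are expanded to a 365-day year (``step`` holds
    each month constant; ``smooth`` interpolates between month midpoints)
    and tiled to ``n_days``, wrapping across the year end.  Returns None
    when the cell is nodata in any layer.
    """
    cell = stack.cell_monthly(row, col)
    if cell is None:
        return None
    tmin_m, tmax_m = cell
    tmin_d = _monthly_to_daily(tmin_m, mode)
    tmax_d = _monthly_to_daily(tmax_m, mode)
    idx = (sowing_day_of_year - 1 + np.arange(n_days)) % 365
    dates = np.datetime64("2004-01-01", "D") + np.arange(n_days)
    tmin, tmax = tmin_d[idx], tmax_d[idx]
    swap = tmin > tmax  # guard against crossing after interpolation
    tmin[swap], tmax[swap] = tmax[swap], tmin[swap]
    return TemperatureSeries(dates, tmin, tmax)


def _resolve_theta(model, params):
    spec = get_model(model) if isinstance(model, str) else model
    theta = params.to_theta(spec.name) if isinstance(params, RateParams) else np.asarray(params, float)
    return spec, theta


def map_phase_duration(stack: ClimatologyStack, model, params,
                       sowing_day_of_year: int = 1,
                       mode: str = "accumulation",
                       daily_mode: str = "smooth") -> Raster:
    """Per-cell phase duration in days over a climatology stack.

    ``inverse_rate`` computes 1/r at each cell's annual mean temperature;
    ``accumulation`` runs the daily engine on a synthesized series.  Cells
    outside the thermal limits (or where the phase never completes within
    two years) become nodata, counted separately from missing-temperature
    cells in the log.
    """
    spec, theta = _resolve_theta(model, params)
    geom = stack.geometry
    out = np.full(geom.values.shape, geom.nodata_value, dtype=float)
    n_nodata = n_thermal = 0
    for i in range(geom.nrows):
        for j in range(geom.ncols):
            cell = stack.cell_monthly(i, j)
            if cell is None:
                n_nodata += 1
                continue
            if mode == "inverse_rate":
                tmin_m, tmax_m = cell
                t_mean = float(np.mean((tmin_m + tmax_m) / 2.0))
                r = float(spec.rate(np.array([t_mean]), theta)[0])
                if r <= 0.0:
                    n_thermal += 1
                    continue
                out[i, j] = 1.0 / r
            elif mode == "accumulation":
                series = synthesize_daily_series(stack, i, j, sowing_day_of_year,
                                                 mode=daily_mode)
                try:
                    out[i, j] = accumulate_development(series, spec, theta)
                except PhaseNotCompletedError:
                    n_thermal += 1
            else:
                raise ValueError(f"unknown mapping mode {mode!r}")
    log.info("mapped %s: %d missing-temperature cells, %d outside thermal limits",
             spec.name, n_nodata, n_thermal)
    return geom.with_values(out)


def apply_mask(duration: Raster, suitability: Raster) -> Raster:
    """Keep duration only where the suitability raster is nonzero.

    Any nonzero non-nodata suitability value counts as suitable (tolerates
    0/1 and 0/255 dialects); everything else becomes nodata.
    """
    if not duration.same_geometry(suitability):
        raise ValueError("duration and suitability rasters are not co-registered")
    keep = (~suitability.mask) & (suitability.values != 0)
    out = np.where(keep, duration.values, duration.nodata_value)
    return duration.with_values(out)


def map_total_cycle(stack: ClimatologyStack, model, vp_params, rp_params=None,
                    sowing_day_of_year: int = 1, emergence_offset: int = 7,
                    mode: str = "accumulation", daily_mode: str = "smooth") -> Raster:
    """Per-cell length of growing period: offset + vegetative + reproductive.

    Nodata in either phase propagates to the total.
    """
    if rp_params is None:
        rp_params = vp_params
    geom = stack.geometry
    nd = geom.nodata_value
    if mode == "inverse_rate":
        vp = map_phase_duration(stack, model, vp_params, sowing_day_of_year,
                                mode=mode, daily_mode=daily_mode)
        rp = map_phase_duration(stack, model, rp_params, sowing_day_of_year,
                                mode=mode, daily_mode=daily_mode)
        bad = vp.mask | rp.mask
        total = np.where(bad, nd, emergence_offset + vp.values + rp.values)
        return geom.with_values(total)
    if mode != "accumulation":
        raise ValueError(f"unknown mapping mode {mode!r}")
    vspec, vtheta = _resolve_theta(model, vp_params)
    rspec, rtheta = _resolve_theta(model, rp_params)
    vals = np.full(geom.values.shape, nd, dtype=float)
    for i in range(geom.nrows):
        for j in range(geom.ncols):
            series = synthesize_daily_series(stack, i, j, sowing_day_of_year,
                                             mode=daily_mode)
            if series is None:
                continue
            try:
                vp_days = accumulate_development(series, vspec, vtheta,
                                                 start_day=emergence_offset)
                flowering = emergence_offset + int(np.ceil(vp_days))
                rp_days = accumulate_development(series, rspec, rtheta,
                                                 start_day=flowering)
            except PhaseNotCompletedError:
                continue
            vals[i, j] = emergence_offset + vp_days + rp_days
    return geom.with_values(vals)
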