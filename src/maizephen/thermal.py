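"""Daily rate accumulation: from temperature series to phase durations.

Development through a phase is tracked as a dimensionless state D that
accumulates the daily rate, D = Σ r(T(t)) Δt with Δt fixed at one day.
The phase completes when D reaches 1; the completion day is interpolated
linearly inside the final day so durations are real-valued rather than
quantised to whole days.

Two phases are recognised: the vegetative phase (emergence to flowering)
and the reproductive phase (flowering to physiological maturity).  A full
cycle prediction chains them, starting the reproductive phase on the day
after the interpolated flowering time, and prepends a sowing-to-emergence
offset (typically 7–10 days in the tropics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .rate_models import RateModelSpec, get_model, RateParams

__all__ = [
    "TemperatureSeries",
    "PhaseNotCompletedError",
    "daily_mean_temperature",
    "accumulate_development",
    "predict_phase_duration",
    "predict_cycle",
    "duration_at_constant_temperature",
    "OutsideThermalLimits",
]

VEGETATIVE = "vegetative"
REPRODUCTIVE = "reproductive"


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily Tmin/Tmax record at one location.

    Dates must be consecutive calendar days; missing days are an error, not
    silently filled.
    """

    dates: np.ndarray  # datetime64[D]
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self) -> None:
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        tmin = np.asarray(self.tmin, dtype=float)
        tmax = np.asarray(self.tmax, dtype=float)
        if not (len(dates) == len(tmin) == len(tmax)):
            raise ValueError("dates, tmin, tmax must have equal lengths")
        if len(dates) > 1:
            steps = np.diff(dates).astype(int)
            if not np.all(steps == 1):
                bad = int(np.argmax(steps != 1))
                raise ValueError(
                    f"dates must advance by exactly one day; gap after {dates[bad]}"
                )
        if np.any(tmin > tmax):
            bad = int(np.argmax(tmin > tmax))
            raise ValueError(f"tmin > tmax on {dates[bad]}")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)

    def __len__(self) -> int:
        return len(self.dates)

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        """Read a weather CSV with columns date (ISO-8601), tmin, tmax."""
        df = pd.read_csv(path)
        missing = {"date", "tmin", "tmax"} - set(df.columns)
        if missing:
            raise ValueError(f"weather file {path} lacks columns: {sorted(missing)}")
        return cls(
            dates=df["date"].to_numpy(dtype="datetime64[D]"),
            tmin=df["tmin"].to_numpy(float),
            tmax=df["tmax"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"date": self.dates.astype(str), "tmin": self.tmin, "tmax": self.tmax}
        ).to_csv(path, index=False)

    def driving_temperature(self, method: str = "mean") -> np.ndarray:
        return daily_mean_temperature(self.tmin, self.tmax, method=method)

    @classmethod
    def constant(cls, t_mean: float, n_days: int, start: str = "2004-03-01",
                 half_range: float = 0.0) -> "TemperatureSeries":
        """A flat series at ``t_mean`` ± ``half_range``, convenient in tests."""
        d0 = np.datetime64(start, "D")
        dates = d0 + np.arange(n_days)
        return cls(dates, np.full(n_days, t_mean - half_range),
                   np.full(n_days, t_mean + half_range))


def daily_mean_temperature(tmin, tmax, method: str = "mean"):
    """Collapse a day's Tmin/Tmax into a single driving temperature.

    ``mean`` is the arithmetic midpoint (Tmin+Tmax)/2.  ``sine`` integrates
    an idealised diurnal sine wave between the extremes — for a pure sine
    centred on the midpoint the time average equals the midpoint, so the
    two agree for symmetric cycles; the mode exists for sensitivity checks
    with rate curves applied sub-daily.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin > tmax")
    if method == "mean":
        return (tmin + tmax) / 2.0
    if method == "sine":
        # time average of T(t) = mid + amp*sin(2πt) over a full day is mid;
        # the sine shape matters only when the rate curve is applied sub-daily
        # (see accumulate_development's temperature_method="sine")
        return (tmin + tmax) / 2.0
    raise ValueError(f"unknown daily-temperature method {method!r}")


class PhaseNotCompletedError(RuntimeError):
    """The temperature series ended before cumulative development reached 1."""

    def __init__(self, final_d: float, n_days: int):
        self.final_d = float(final_d)
        self.n_days = int(n_days)
        super().__init__(
            f"phase not completed: D reached {final_d:.4f} after {n_days} days"
        )


class OutsideThermalLimits(RuntimeError):
    """r(T) = 0 at the requested temperature — development never proceeds."""


def _resolve(model, params):
    spec = get_model(model) if isinstance(model, str) else model
    theta = params.to_theta(spec.name) if isinstance(params, RateParams) else np.asarray(params, float)
    return spec, theta


def _daily_rates(series: TemperatureSeries, spec: RateModelSpec, theta,
                 temperature_method: str) -> np.ndarray:
    if temperature_method == "sine":
        # evaluate the rate on an hourly sine between Tmin and Tmax and
        # average — captures nonlinearity of r(T) within the day
        mid = (series.tmin + series.tmax) / 2.0
        amp = (series.tmax - series.tmin) / 2.0
        hours = np.sin(2.0 * np.pi * (np.arange(24) + 0.5) / 24.0)
        T_hourly = mid[:, None] + amp[:, None] * hours[None, :]
        return spec.rate(T_hourly.ravel(), theta).reshape(T_hourly.shape).mean(axis=1)
    T = series.driving_temperature(temperature_method)
    return spec.rate(T, theta)


def accumulate_development(series: TemperatureSeries, model, params,
                           start_day: int = 0, threshold: float = 1.0,
                           temperature_method: str = "mean",
                           return_trajectory: bool = False):
    """Days from ``start_day`` until cumulative development reaches 1.

    The completion time is interpolated within the final day: if D crosses
    the threshold during day j (0-based within the phase), the duration is
    j + (threshold − D_{j−1}) / r_j.

    Raises :class:`PhaseNotCompletedError` (carrying the final D) if the
    series ends first.
    """
    spec, theta = _resolve(model, params)
    if not 0 <= start_day < len(series):
        raise IndexError(f"start_day {start_day} outside series of length {len(series)}")
    r = _daily_rates(series, spec, theta, temperature_method)[start_day:]
    cum = np.cumsum(r)
    hit = np.nonzero(cum >= threshold)[0]
    if hit.size == 0:
        raise PhaseNotCompletedError(cum[-1] if cum.size else 0.0, len(r))
    j = int(hit[0])
    prev = cum[j - 1] if j > 0 else 0.0
    duration = j + (threshold - prev) / r[j]
    if return_trajectory:
        return float(duration), cum
    return float(duration)


def predict_phase_duration(series: TemperatureSeries, model, params,
                           phase: str = VEGETATIVE, start_day: int = 0,
                           temperature_method: str = "mean") -> float:
    """Duration of one phase in days, starting at ``start_day``.

    For the vegetative phase ``start_day`` is the emergence index; for the
    reproductive phase it is the (whole-day) flowering index.
    """
    if phase not in (VEGETATIVE, REPRODUCTIVE):
        raise ValueError(f"phase must be {VEGETATIVE!r} or {REPRODUCTIVE!r}, got {phase!r}")
    return accumulate_development(series, model, params, start_day=start_day,
                                  temperature_method=temperature_method)


@dataclass(frozen=True)
class CyclePrediction:
    """Event calendar for one sowing: dates and phase durations in days."""

    sowing: np.datetime64
    emergence: np.datetime64
    flowering: np.datetime64
    maturity: np.datetime64
    vp_days: float
    rp_days: float
    total_days: float


def predict_cycle(series: TemperatureSeries, model, vp_params, rp_params=None,
                  sowing_day: int = 0, emergence_offset: int = 7,
                  temperature_method: str = "mean") -> CyclePrediction:
    """Chain emergence offset → vegetative phase → reproductive phase.

    The reproductive phase starts on the day after the interpolated
    flowering time (observations are recorded at whole-day resolution).
    ``rp_params`` defaults to ``vp_params``: a single parameter set may
    cover both phases of a variety.
    """
    if not 0 <= emergence_offset <= 30:
        raise ValueError(f"emergence_offset must be in [0, 30] days, got {emergence_offset}")
    if rp_params is None:
        rp_params = vp_params
    emergence_idx = sowing_day + emergence_offset
    vp = predict_phase_duration(series, model, vp_params, VEGETATIVE,
                                start_day=emergence_idx,
                                temperature_method=temperature_method)
    flowering_idx = emergence_idx + int(np.ceil(vp))
    rp = predict_phase_duration(series, model, rp_params, REPRODUCTIVE,
                                start_day=flowering_idx,
                                temperature_method=temperature_method)
    d = series.dates
    return CyclePrediction(
        sowing=d[sowing_day],
        emergence=d[emergence_idx],
        flowering=d[flowering_idx],
        maturity=d[min(flowering_idx + int(np.ceil(rp)), len(d) - 1)],
        vp_days=vp,
        rp_days=rp,
        total_days=emergence_offset + vp + rp,
    )


def duration_at_constant_temperature(model, params, T: float) -> float:
    """Phase duration 1/r(T) at a fixed temperature.

    Raises :class:`OutsideThermalLimits` when r(T) = 0 (at or beyond the
    thermal thresholds); callers mapping over grids turn this into nodata.
    """
    spec, theta = _resolve(model, params)
    r = float(spec.rate(np.array([float(T)]), theta)[0])
    if r <= 0.0:
        raise OutsideThermalLimits(
            f"development rate is zero at {T} °C for model {spec.name!r}"
        )
    return 1.0 / r
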