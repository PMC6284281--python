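"""Nonlinear least-squares estimation of rate-curve parameters.

Each multi-environment trial contributes one point: the observed phase
duration at a site is inverted to a development rate (r = 1/days) and
paired with the site's representative mean temperature.  A rate model is
then fitted by damped least squares — Levenberg–Marquardt-style Gauss–
Newton steps, run as a bounded trust-region problem so the cardinal
temperatures stay in their biologically admissible ranges (Tb in [0, 20],
Tm in [25, 50] °C).

Initial values come from a deterministic multi-start grid (Tb × Tm lattice
with the rate constant scaled to the peak observed rate); the start with
the lowest residual sum of squares wins, so repeated runs on identical
inputs are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rate_models import RateModelSpec, get_model, list_models

__all__ = [
    "TrialObservation",
    "FitResult",
    "FitError",
    "observed_rates",
    "fit_model",
    "parameter_standard_errors",
    "fit_all",
    "load_trials_csv",
]


@dataclass(frozen=True)
class TrialObservation:
    """One (site, variety, phase) duration record from a trial."""

    site: str
    variety: str
    phase: str
    duration_days: float
    mean_temp: Optional[float] = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.duration_days > 0:
            raise ValueError(f"duration must be > 0, got {self.duration_days}")
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")


class FitError(RuntimeError):
    """All starts of a fit failed to converge; carries per-start diagnostics."""

    def __init__(self, model_name: str, diagnostics: list):
        self.diagnostics = diagnostics
        super().__init__(
            f"fit of {model_name!r} failed for all {len(diagnostics)} starts: "
            + "; ".join(map(str, diagnostics))
        )


@dataclass
class FitResult:
    """Fitted parameters and diagnostics for one model on one data set."""

    model: str
    theta: np.ndarray
    param_names: tuple
    rss: float
    n_obs: int
    converged: bool
    n_iterations: int
    standard_errors: Optional[np.ndarray] = None
    jacobian_condition: float = np.nan
    at_bounds: bool = False
    message: str = ""
    _jac: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_dict(self) -> dict:
        return dict(zip(self.param_names, self.theta.tolist()))


def observed_rates(observations: Sequence[TrialObservation]):
    """(temperature, rate, weight) arrays; rate is the inverse duration."""
    if len(observations) == 0:
        raise ValueError("no observations")
    T, r, w = [], [], []
    for obs in observations:
        if obs.mean_temp is None:
            raise ValueError(
                f"observation ({obs.site}, {obs.variety}) has no representative temperature"
            )
        T.append(obs.mean_temp)
        r.append(1.0 / obs.duration_days)
        w.append(obs.weight)
    return np.array(T), np.array(r), np.array(w)


def _weighted_rss(spec, theta, T, r, w) -> float:
    resid = r - spec.rate(T, theta)
    return float(np.sum(w * resid**2))


def fit_model(observations, model, init=None, weights=None) -> FitResult:
    """Fit one rate model to trial observations in rate space.

    Minimises Σ wᵢ (r_obs,i − r(Tᵢ; θ))² within the model's parameter
    bounds.  When ``init`` is None a deterministic multi-start is run and
    the lowest-RSS start is kept.
    """
    spec = get_model(model) if isinstance(model, str) else model
    T, r, w = observed_rates(observations)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != r.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and one per observation")
    if len(T) < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} observations to fit "
            f"{spec.name!r} ({spec.n_params} parameters), got {len(T)}"
        )
    if len(np.unique(T)) < 3:
        raise ValueError("temperatures must span at least 3 distinct values")

    sw = np.sqrt(w)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])

    def residuals(theta):
        return sw * (r - spec.rate(T, theta))

    starts = [np.asarray(init, float)] if init is not None else spec.init_grid(T, r)
    best = None
    diagnostics = []
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = least_squares(
                    residuals, theta0, bounds=(lo, hi), method="trf",
                    x_scale="jac", ftol=1e-12, xtol=1e-10, gtol=1e-12,
                    max_nfev=500 * spec.n_params,
                )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            diagnostics.append(f"start {theta0}: {exc}")
            continue
        if not np.all(np.isfinite(sol.x)):
            diagnostics.append(f"start {theta0}: non-finite solution")
            continue
        rss = _weighted_rss(spec, sol.x, T, r, w)
        diagnostics.append(f"start {theta0}: rss={rss:.3e} status={sol.status}")
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
    if best is None:
        raise FitError(spec.name, diagnostics)

    rss, sol = best
    tol = 1e-8 * np.maximum(1.0, np.abs(hi - lo))
    at_bounds = bool(np.any(np.isfinite(lo) & (sol.x - lo < tol))
                     or np.any(np.isfinite(hi) & (hi - sol.x < tol)))
    if at_bounds:
        warnings.warn(
            f"fit of {spec.name!r}: parameter estimate at a bound", RuntimeWarning
        )
    jac = sol.jac
    with np.errstate(all="ignore"):
        sv = np.linalg.svd(jac, compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    result = FitResult(
        model=spec.name,
        theta=sol.x.copy(),
        param_names=spec.param_names,
        rss=rss,
        n_obs=len(T),
        converged=sol.status > 0,
        n_iterations=int(sol.nfev),
        jacobian_condition=cond,
        at_bounds=at_bounds,
        message=sol.message,
        _jac=jac,
    )
    if result.converged:
        result.standard_errors = parameter_standard_errors(result)
    return result


def parameter_standard_errors(fit: FitResult) -> Optional[np.ndarray]:
    """Gauss–Newton standard errors: sqrt(diag(rss/(n−p) · (JᵀJ)⁻¹)).

    Returns None (with a diagnostic warning) when the Jacobian is rank
    deficient rather than fabricating values.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    J = fit._jac
    if J is None:
        raise ValueError("fit carries no Jacobian")
    n, p = fit.n_obs, fit.n_params
    if n <= p:
        warnings.warn("no residual degrees of freedom; SEs undefined", RuntimeWarning)
        return None
    JtJ = J.T @ J
    if np.linalg.matrix_rank(JtJ) < p:
        warnings.warn(
            f"rank-deficient Jacobian for {fit.model!r}; SEs undefined", RuntimeWarning
        )
        return None
    sigma2 = fit.rss / (n - p)
    with np.errstate(all="ignore"):
        cov = sigma2 * np.linalg.inv(JtJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return se


def fit_all(observations, models: Optional[Sequence[str]] = None) -> dict:
    """Fit every registered model; failures are captured, not raised.

    Returns an ordered mapping model name → FitResult or FitError.
    """
    names = sorted(models) if models is not None else list_models()
    if not names:
        raise ValueError("no models to fit (empty registry selection)")
    out = {}
    for name in names:
        try:
            out[name] = fit_model(observations, name)
        except (FitError, ValueError) as exc:
            out[name] = exc
    return out


def load_trials_csv(path) -> list:
    """Read trial observations from CSV.

    Expected columns: site, variety, phase, duration_days, and at least one
    of mean_temp or weather_file; optional weight.
    """
    df = pd.read_csv(path)
    required = {"site", "variety", "phase", "duration_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial file {path} lacks columns: {sorted(missing)}")
    obs = []
    for _, row in df.iterrows():
        mean_temp = row.get("mean_temp")
        if pd.isna(mean_temp):
            wf = row.get("weather_file")
            if wf is None or (isinstance(wf, float) and np.isnan(wf)):
                raise ValueError(
                    f"row ({row['site']}, {row['variety']}): needs mean_temp or weather_file"
                )
            from .thermal import TemperatureSeries
            series = TemperatureSeries.from_csv(wf)
            ndays = min(int(np.ceil(row["duration_days"])), len(series))
            mean_temp = float(series.driving_temperature()[:ndays].mean())
        weight = row.get("weight", 1.0)
        if pd.isna(weight):
            weight = 1.0
        obs.append(TrialObservation(
            site=str(row["site"]), variety=str(row["variety"]),
            phase=str(row["phase"]), duration_days=float(row["duration_days"]),
            mean_temp=float(mean_temp), weight=float(weight),
        ))
    return obs
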