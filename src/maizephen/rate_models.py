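"""Temperature-dependent development-rate models.

A development rate r(T) is the fraction of a phenological phase completed
per day at temperature T (°C).  Most classical response curves share three
cardinal temperatures: a base temperature ``Tb`` below which development
ceases, an optimum ``To`` where the rate peaks, and a ceiling ``Tm`` above
which development ceases again.  The central models here are the two Briere
forms,

    Briere-1:  r(T) = a * T * (T - Tb) * sqrt(Tm - T)
    Briere-2:  r(T) = a * T * (T - Tb) * (Tm - T)**(1/mu)

defined on the open interval (Tb, Tm) and clamped to zero outside it.
Briere-2 with mu = 2 is exactly Briere-1.

Models live in a registry keyed by name so that fitting, selection and
mapping can iterate over an open-ended catalogue; eight classical forms are
registered at import time and users may add their own via
:func:`register_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "RateParams",
    "RateModelSpec",
    "register_model",
    "get_model",
    "list_models",
    "briere1_rate",
    "briere2_rate",
    "evaluate_rate",
    "optimum_temperature",
]


@dataclass(frozen=True)
class RateParams:
    """Cardinal-temperature parameters for the Briere family.

    Parameters
    ----------
    a : float
        Empirical rate constant (> 0), units per day per °C-composite.
    tb : float
        Base temperature (°C) below which development ceases.
    tm : float
        Maximum (ceiling) temperature (°C) above which development ceases.
    mu : float, optional
        Shape exponent of Briere-2 (> 0); ``mu = 2`` recovers Briere-1.
    """

    a: float
    tb: float
    tm: float
    mu: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"rate constant a must be finite and > 0, got {self.a}")
        if not (self.tb < self.tm):
            raise ValueError(f"need Tb < Tm, got Tb={self.tb}, Tm={self.tm}")
        if self.mu is not None and not self.mu > 0:
            raise ValueError(f"shape exponent mu must be > 0, got {self.mu}")

    def to_theta(self, model_name: str) -> np.ndarray:
        """Parameter vector in the order the named registry model expects."""
        if model_name == "briere2":
            if self.mu is None:
                raise ValueError("briere2 requires mu")
            return np.array([self.a, self.tb, self.tm, self.mu])
        if model_name in ("briere1", "quadratic"):
            return np.array([self.a, self.tb, self.tm])
        raise ValueError(f"no canonical mapping from RateParams to model {model_name!r}")


@dataclass(frozen=True)
class RateModelSpec:
    """A registered rate model: its parameterisation and its curve.

    ``fn(T, theta)`` must accept a float array and an ordered parameter
    vector and return nonnegative finite rates.  ``support(theta)`` returns
    the (Tb, Tm) interval outside which the rate is identically zero, or
    ``None`` for models without a bounded support (e.g. Gaussian).
    """

    name: str
    param_names: tuple
    bounds: tuple  # per-parameter (lower, upper)
    default_init: tuple
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)
    support: Optional[Callable[[np.ndarray], tuple]] = field(default=None, repr=False)
    nested_extension: Optional[str] = None  # model that extends this one, e.g. briere2 extends briere1

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if not (len(self.param_names) == len(self.bounds) == len(self.default_init)):
            raise ValueError(f"model {self.name!r}: parameter metadata lengths disagree")
        for nm, (lo, hi) in zip(self.param_names, self.bounds):
            if not lo < hi:
                raise ValueError(f"model {self.name!r}: bound for {nm} has lower >= upper")

    def rate(self, T, theta) -> np.ndarray:
        """Evaluate r(T); clamps to zero, rejects non-finite temperatures."""
        T = np.asarray(T, dtype=float)
        if not np.all(np.isfinite(T)):
            raise ValueError(f"model {self.name!r}: temperature contains non-finite values")
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"model {self.name!r} expects {self.n_params} parameters "
                f"({', '.join(self.param_names)}), got {theta.size}"
            )
        r = self.fn(T, theta)
        return np.maximum(r, 0.0)

    def init_grid(self, T_obs: np.ndarray, r_obs: np.ndarray) -> list:
        """Deterministic multi-start initial values informed by the data."""
        return _INIT_GRIDS.get(self.name, lambda T, r: [np.array(self.default_init)])(
            np.asarray(T_obs, float), np.asarray(r_obs, float)
        )


_REGISTRY: dict = {}


class UnknownModelError(KeyError):
    pass


def register_model(spec: RateModelSpec) -> RateModelSpec:
    """Add a model to the registry; duplicate names are an error."""
    if spec.name in _REGISTRY:
        raise ValueError(f"model {spec.name!r} is already registered")
    _REGISTRY[spec.name] = spec
    return spec


def get_model(name: str) -> RateModelSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; registered models: {', '.join(sorted(_REGISTRY))}"
        ) from None


def list_models() -> list:
    return sorted(_REGISTRY)


def _unregister(name: str) -> None:
    # test helper; not part of the public surface
    _REGISTRY.pop(name, None)


# ---------------------------------------------------------------------------
# built-in curves


def _briere1(T, th):
    a, tb, tm = th
    inside = (T > tb) & (T < tm)
    r = np.zeros_like(T, dtype=float)
    Ti = T[inside]
    r[inside] = a * Ti * (Ti - tb) * np.sqrt(tm - Ti)
    return r


def _briere2(T, th):
    a, tb, tm, mu = th
    if mu <= 0:
        raise ValueError(f"briere2 shape exponent mu must be > 0, got {mu}")
    inside = (T > tb) & (T < tm)
    r = np.zeros_like(T, dtype=float)
    Ti = T[inside]
    r[inside] = a * Ti * (Ti - tb) * (tm - Ti) ** (1.0 / mu)
    return r


def _linear_dd(T, th):
    # degree-day model: rate linear above Tb, 1/TT per degree; no ceiling
    tb, tt = th
    return np.maximum(T - tb, 0.0) / tt


def _quadratic(T, th):
    a, tb, tm = th
    inside = (T > tb) & (T < tm)
    r = np.zeros_like(T, dtype=float)
    Ti = T[inside]
    r[inside] = a * (Ti - tb) * (tm - Ti)
    return r


def _gaussian(T, th):
    rmax, topt, sigma = th
    return rmax * np.exp(-0.5 * ((T - topt) / sigma) ** 2)


def _logan6(T, th):
    psi, rho, tm, dt = th
    r = psi * (np.exp(rho * T) - np.exp(rho * tm - (tm - T) / dt))
    r[T >= tm] = 0.0
    return np.maximum(r, 0.0)


def _lactin2(T, th):
    rho, tm, dt, lam = th
    r = np.exp(rho * T) - np.exp(rho * tm - (tm - T) / dt) + lam
    return np.maximum(r, 0.0)


def _beta_cardinal(T, th):
    # Yin-style beta with explicit cardinal temperatures (Tb, To, Tm)
    rmax, tb, topt, tm = th
    inside = (T > tb) & (T < tm)
    r = np.zeros_like(T, dtype=float)
    Ti = T[inside]
    c = (topt - tb) / (tm - topt)
    r[inside] = rmax * ((tm - Ti) / (tm - topt)) * ((Ti - tb) / (topt - tb)) ** c
    return np.maximum(r, 0.0)


def _briere_grid(T, r, with_mu=False):
    # Tb x Tm lattice; a scaled so the curve peak matches the max observed rate
    starts = []
    rmax = float(np.max(r)) if r.size else 1e-2
    for tb in (5.0, 8.0, 11.0):
        for tm in (35.0, 40.0, 45.0):
            tg = np.linspace(tb + 0.5, tm - 0.5, 200)
            peak = np.max(tg * (tg - tb) * np.sqrt(tm - tg))
            a = rmax / peak if peak > 0 else 1e-5
            starts.append(np.array([a, tb, tm, 2.0]) if with_mu else np.array([a, tb, tm]))
    return starts


def _quad_grid(T, r):
    starts = []
    rmax = float(np.max(r)) if r.size else 1e-2
    for tb in (5.0, 8.0, 11.0):
        for tm in (35.0, 40.0, 45.0):
            a = rmax / ((tm - tb) / 2.0) ** 2
            starts.append(np.array([a, tb, tm]))
    return starts


def _beta_grid(T, r):
    starts = []
    rmax = float(np.max(r)) if r.size else 1e-2
    for tb in (5.0, 8.0, 11.0):
        for tm in (35.0, 40.0, 45.0):
            starts.append(np.array([rmax, tb, 0.5 * (tb + tm) + 4.0, tm]))
    return starts


def _gauss_grid(T, r):
    rmax = float(np.max(r)) if r.size else 1e-2
    topt = float(T[np.argmax(r)]) if r.size else 28.0
    return [np.array([rmax, topt, s]) for s in (4.0, 7.0, 10.0)]


def _lin_grid(T, r):
    pos = r > 0
    tt = float(np.median(T[pos] / r[pos])) if pos.any() else 800.0
    return [np.array([tb, tt]) for tb in (5.0, 8.0, 11.0)]


def _logan_grid(T, r):
    rmax = float(np.max(r)) if r.size else 1e-2
    return [
        np.array([rmax / 20.0, rho, tm, 4.0])
        for rho in (0.10, 0.15)
        for tm in (38.0, 42.0)
    ]


def _lactin_grid(T, r):
    return [
        np.array([rho, tm, 4.0, -1.02])
        for rho in (0.005, 0.01)
        for tm in (38.0, 42.0)
    ]


_INIT_GRIDS = {
    "briere1": lambda T, r: _briere_grid(T, r, with_mu=False),
    "briere2": lambda T, r: _briere_grid(T, r, with_mu=True),
    "quadratic": _quad_grid,
    "beta": _beta_grid,
    "gaussian": _gauss_grid,
    "linear_dd": _lin_grid,
    "logan6": _logan_grid,
    "lactin2": _lactin_grid,
}

_TB_BOUNDS = (0.0, 20.0)
_TM_BOUNDS = (25.0, 50.0)

register_model(RateModelSpec(
    name="briere1",
    param_names=("a", "tb", "tm"),
    bounds=((1e-12, 1.0), _TB_BOUNDS, _TM_BOUNDS),
    default_init=(2e-5, 9.0, 40.0),
    fn=_briere1,
    support=lambda th: (th[1], th[2]),
    nested_extension="briere2",
))

register_model(RateModelSpec(
    name="briere2",
    param_names=("a", "tb", "tm", "mu"),
    bounds=((1e-12, 1.0), _TB_BOUNDS, _TM_BOUNDS, (0.1, 10.0)),
    default_init=(2e-5, 9.0, 40.0, 2.0),
    fn=_briere2,
    support=lambda th: (th[1], th[2]),
))

register_model(RateModelSpec(
    name="linear_dd",
    param_names=("tb", "tt"),
    bounds=(_TB_BOUNDS, (1.0, 1e5)),
    default_init=(9.0, 800.0),
    fn=_linear_dd,
))

register_model(RateModelSpec(
    name="quadratic",
    param_names=("a", "tb", "tm"),
    bounds=((1e-12, 1.0), _TB_BOUNDS, _TM_BOUNDS),
    default_init=(1e-4, 9.0, 40.0),
    fn=_quadratic,
    support=lambda th: (th[1], th[2]),
))

register_model(RateModelSpec(
    name="gaussian",
    param_names=("rmax", "topt", "sigma"),
    bounds=((1e-12, 1.0), (10.0, 40.0), (0.5, 30.0)),
    default_init=(0.02, 28.0, 7.0),
    fn=_gaussian,
))

register_model(RateModelSpec(
    name="logan6",
    param_names=("psi", "rho", "tm", "dt"),
    bounds=((1e-12, 1.0), (1e-3, 1.0), _TM_BOUNDS, (0.1, 20.0)),
    default_init=(1e-3, 0.15, 40.0, 4.0),
    fn=_logan6,
))

register_model(RateModelSpec(
    name="lactin2",
    param_names=("rho", "tm", "dt", "lam"),
    bounds=((1e-4, 0.5), _TM_BOUNDS, (0.1, 20.0), (-2.0, 0.5)),
    default_init=(0.01, 40.0, 4.0, -1.02),
    fn=_lactin2,
))

register_model(RateModelSpec(
    name="beta",
    param_names=("rmax", "tb", "topt", "tm"),
    bounds=((1e-12, 1.0), _TB_BOUNDS, (15.0, 40.0), _TM_BOUNDS),
    default_init=(0.02, 9.0, 30.0, 40.0),
    fn=_beta_cardinal,
    support=lambda th: (th[1], th[3]),
))


# ---------------------------------------------------------------------------
# convenience evaluation API


def briere1_rate(T, params: RateParams):
    """Briere-1 rate a·T·(T−Tb)·sqrt(Tm−T), zero outside (Tb, Tm)."""
    out = get_model("briere1").rate(np.atleast_1d(np.asarray(T, float)), params.to_theta("briere1"))
    return out[0] if np.isscalar(T) or np.ndim(T) == 0 else out


def briere2_rate(T, params: RateParams):
    """Briere-2 rate a·T·(T−Tb)·(Tm−T)^(1/µ); µ = 2 recovers Briere-1."""
    out = get_model("briere2").rate(np.atleast_1d(np.asarray(T, float)), params.to_theta("briere2"))
    return out[0] if np.isscalar(T) or np.ndim(T) == 0 else out


def evaluate_rate(model, theta, T):
    """Dispatch r(T) through the registry, vectorised over T.

    ``model`` may be a registered name or a :class:`RateModelSpec`;
    ``theta`` an ordered parameter vector or a :class:`RateParams`.
    """
    spec = get_model(model) if isinstance(model, str) else model
    if isinstance(theta, RateParams):
        theta = theta.to_theta(spec.name)
    out = spec.rate(np.atleast_1d(np.asarray(T, float)), theta)
    return out[0] if np.isscalar(T) or np.ndim(T) == 0 else out


def optimum_temperature(model, theta, resolution: float = 0.01) -> float:
    """Temperature maximising r(T), to within ``resolution`` °C.

    Searches a dense grid over the model's support (or a broad 0–50 °C
    window for unbounded models) and refines by golden-section search.
    """
    from scipy.optimize import minimize_scalar

    spec = get_model(model) if isinstance(model, str) else model
    if isinstance(theta, RateParams):
        theta = theta.to_theta(spec.name)
    theta = np.asarray(theta, dtype=float)
    if spec.support is not None:
        lo, hi = spec.support(theta)
    else:
        lo, hi = 0.0, 50.0
    if hi - lo < 1e-6:
        raise ValueError(f"degenerate thermal window [{lo}, {hi}] for model {spec.name!r}")
    grid = np.linspace(lo, hi, 2001)
    r = spec.rate(grid, theta)
    i = int(np.argmax(r))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda t: -float(spec.rate(np.array([t]), theta)[0]),
        bounds=(a, b), method="bounded",
        options={"xatol": resolution / 10.0},
    )
    return float(res.x)
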