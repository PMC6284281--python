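"""Goodness-of-fit statistics and model-selection criteria.

For least-squares fits compared on the same data the criteria used are

    AIC = n·ln(WRSS) + 2p              (lower is better)
    MSC = ln(WTSS / WRSS) − 2p/n       (higher is better)

where WRSS and WTSS are the weighted residual and total sums of squares
and p the parameter count.  On identical data the two are linked by the
identity MSC = ln(WTSS) − AIC/n, so they always rank models identically;
both are reported because both are conventional in phenology work.  The
nested-model F test compares an extended model against its special case
(here Briere-2 against Briere-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult
from .rate_models import get_model

__all__ = [
    "r_squared",
    "adjusted_r_squared",
    "aic",
    "msc",
    "rmse",
    "f_test_nested",
    "NestedTestResult",
    "rank_models",
    "SelectionReport",
]

# biologically admissible cardinal temperatures for tropical maize (°C)
PLAUSIBLE_TB = (0.0, 20.0)
PLAUSIBLE_TM = (25.0, 50.0)


def _as_arrays(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size == 0:
        raise ValueError("empty input")
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    return o, p


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − RSS/TSS, TSS about the observed mean."""
    o, p = _as_arrays(observed, predicted)
    tss = float(np.sum((o - o.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observed values are all identical; R² undefined")
    rss = float(np.sum((o - p) ** 2))
    return 1.0 - rss / tss


def adjusted_r_squared(r2: float, n: int, k: int) -> float:
    """Penalise R² for model size: 1 − (1 − R²)(n−1)/(n−k−1)."""
    if n <= k + 1:
        raise ValueError(f"adjusted R² needs n > k + 1 (n={n}, k={k})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _wrss(observed, predicted, weights) -> float:
    o, p = _as_arrays(observed, predicted)
    w = np.ones_like(o) if weights is None else np.asarray(weights, dtype=float)
    return float(np.sum(w * (o - p) ** 2))


def aic(observed, predicted, p: int, weights=None) -> float:
    """Least-squares Akaike criterion n·ln(WRSS) + 2p; lower is better."""
    o, _ = _as_arrays(observed, predicted)
    wrss = _wrss(observed, predicted, weights)
    if wrss == 0.0:
        warnings.warn("zero residual sum of squares; AIC is -inf", RuntimeWarning)
        return -np.inf
    return o.size * float(np.log(wrss)) + 2.0 * p


def msc(observed, predicted, p: int, weights=None) -> float:
    """Model Selection Criterion ln(WTSS/WRSS) − 2p/n; higher is better."""
    o, _ = _as_arrays(observed, predicted)
    w = np.ones_like(o) if weights is None else np.asarray(weights, dtype=float)
    wtss = float(np.sum(w * (o - np.average(o, weights=w)) ** 2))
    if wtss == 0.0:
        raise ValueError("zero total sum of squares; MSC undefined")
    wrss = _wrss(observed, predicted, weights)
    if wrss == 0.0:
        warnings.warn("zero residual sum of squares; MSC is +inf", RuntimeWarning)
        return np.inf
    return float(np.log(wtss / wrss)) - 2.0 * p / o.size


def rmse(observed, predicted) -> float:
    """Root mean squared residual, in the units of the inputs."""
    o, p = _as_arrays(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


@dataclass(frozen=True)
class NestedTestResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    preferred: str


def f_test_nested(fit_small: FitResult, fit_big: FitResult,
                  alpha: float = 0.05) -> NestedTestResult:
    """Extra-sum-of-squares F test of a model against its nested extension.

    F = ((RSS₁ − RSS₂)/(p₂ − p₁)) / (RSS₂/(n − p₂)).  The bigger model is
    preferred only when the reduction in RSS is significant at ``alpha``.
    """
    if fit_small.n_obs != fit_big.n_obs:
        raise ValueError("nested F test requires fits on the same data")
    n = fit_big.n_obs
    p1, p2 = fit_small.n_params, fit_big.n_params
    if p1 >= p2:
        raise ValueError("fit_small must have fewer parameters than fit_big")
    if fit_small.rss < fit_big.rss - 1e-12 * max(fit_small.rss, 1.0):
        raise ValueError(
            "RSS of the smaller model is below the bigger model's: "
            "models are not nested or the big fit failed"
        )
    df1, df2 = p2 - p1, n - p2
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom for the F test")
    rss2 = fit_big.rss
    if rss2 == 0.0:
        f_stat = np.inf if fit_small.rss > 0 else 0.0
    else:
        f_stat = max(fit_small.rss - rss2, 0.0) / df1 / (rss2 / df2)
    p_value = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    preferred = fit_big.model if p_value < alpha else fit_small.model
    return NestedTestResult(float(f_stat), df1, df2, p_value, preferred)


REPORT_COLUMNS = [
    "model", "n_params", "rss", "r2", "r2_adj", "aic", "msc", "rmse",
    "converged", "plausible", "params",
]


@dataclass
class SelectionReport:
    """Ranked comparison of fitted models on one data set.

    ``table`` has one row per successful fit, ordered by AIC ascending
    (ties: fewer parameters, then name).  Columns are fixed:
    model, n_params, rss, r2, r2_adj, aic, msc, rmse, converged,
    plausible, params.
    """

    table: pd.DataFrame
    failures: dict

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        cols = ["model", "n_params", "r2", "r2_adj", "aic", "msc", "rmse", "plausible"]
        lines = [self.table[cols].to_string(index=False,
                                            float_format=lambda v: f"{v: .5g}")]
        if self.failures:
            lines.append("failed fits: " + ", ".join(sorted(self.failures)))
        return "\n".join(lines)


def _plausible(fit: FitResult) -> bool:
    spec = get_model(fit.model)
    if spec.support is None:
        return True
    tb, tm = spec.support(fit.theta)
    return (PLAUSIBLE_TB[0] <= tb <= PLAUSIBLE_TB[1]
            and PLAUSIBLE_TM[0] <= tm <= PLAUSIBLE_TM[1])


def rank_models(fits: dict, observations, nested_f_alpha: float = 0.05) -> SelectionReport:
    """Build the ranked selection table from :func:`maizephen.fitting.fit_all` output.

    ``observations`` are the trial records the fits were computed on; all
    statistics are recomputed here from observed vs predicted rates so the
    table is self-consistent.  Ranking is by AIC ascending (ties: fewer
    parameters, then name), with one adjustment applied before the final
    order: where a registered model extends a nested parent (Briere-2 over
    Briere-1), the extension must justify its extra parameters by the
    extra-sum-of-squares F test at ``nested_f_alpha``, otherwise the parent
    is ranked above it.  Set ``nested_f_alpha=None`` to rank by raw AIC.
    """
    from .fitting import observed_rates

    T, r_obs, w = observed_rates(observations)
    rows = []
    failures = {}
    for name, fit in fits.items():
        if not isinstance(fit, FitResult):
            failures[name] = fit
            continue
        spec = get_model(name)
        r_pred = spec.rate(T, fit.theta)
        r2 = r_squared(r_obs, r_pred)
        rows.append({
            "model": name,
            "n_params": fit.n_params,
            "rss": _wrss(r_obs, r_pred, w),
            "r2": r2,
            "r2_adj": adjusted_r_squared(r2, len(r_obs), fit.n_params),
            "aic": aic(r_obs, r_pred, fit.n_params, weights=w),
            "msc": msc(r_obs, r_pred, fit.n_params, weights=w),
            "rmse": rmse(r_obs, r_pred),
            "converged": fit.converged,
            "plausible": _plausible(fit),
            "params": ";".join(f"{k}={v:.6g}" for k, v in fit.params_dict().items()),
        })
    if not rows:
        raise ValueError("all fits failed; nothing to rank")
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    table = table.sort_values(["aic", "n_params", "model"],
                              kind="mergesort").reset_index(drop=True)
    if nested_f_alpha is not None:
        order = list(table["model"])
        by_model = {row["model"]: row for row in rows}
        n = len(r_obs)
        for parent in list(by_model):
            ext = get_model(parent).nested_extension
            if ext is None or ext not in by_model:
                continue
            ei, pi = order.index(ext), order.index(parent)
            if ei >= pi:
                continue  # extension already ranks below its parent
            rss1, rss2 = by_model[parent]["rss"], by_model[ext]["rss"]
            p1, p2 = by_model[parent]["n_params"], by_model[ext]["n_params"]
            df1, df2 = p2 - p1, n - p2
            if df1 <= 0 or df2 <= 0:
                continue
            f_stat = max(rss1 - rss2, 0.0) / df1 / (rss2 / df2) if rss2 > 0 else np.inf
            if float(stats.f.sf(f_stat, df1, df2)) >= nested_f_alpha:
                # extra parameters not justified: demote the extension to
                # just below its parent
                order.pop(ei)
                order.insert(order.index(parent) + 1, ext)
        table = table.set_index("model").loc[order].reset_index()
        table = table[REPORT_COLUMNS]
    return SelectionReport(table=table, failures=failures)
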