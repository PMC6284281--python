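"""Independent-site validation of phenology predictions.

Model evaluation here means comparing observed against predicted phase
durations at sites not used for calibration.  The package ships two small
reference tables as CSV fixtures:

* ``table3.csv`` — observed and model-predicted days for 22 open-pollinated
  maize varieties (VE-200 … VE-221) at three western-Kenya evaluation sites
  (Kiboswa, Nyahera, Vihiga), with the predictions' standard errors.
* ``table2.csv`` — published Briere parameter estimates (base and ceiling
  temperatures, rate constant, shape exponent where used) with fit
  statistics for eight of those varieties.

Agreement per site is summarised by the Pearson correlation of observed vs
predicted days, its adjusted R² (one predictor, so k = 1), the RMSE in
days and the mean bias (predicted − observed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection import adjusted_r_squared, rmse

__all__ = [
    "EvaluationRecord",
    "AgreementStats",
    "load_table3_fixture",
    "load_table2_fixture",
    "agreement",
    "agreement_by_site",
    "observed_range",
    "table2_summary",
]

EVALUATION_SITES = ("Kiboswa", "Nyahera", "Vihiga")


@dataclass(frozen=True)
class EvaluationRecord:
    variety: str
    site: str
    observed_days: int
    predicted_days: int
    se_days: Optional[float] = None

    def __post_init__(self) -> None:
        if self.observed_days <= 0 or self.predicted_days <= 0:
            raise ValueError(
                f"record ({self.variety}, {self.site}): durations must be positive"
            )


@dataclass(frozen=True)
class AgreementStats:
    """Observed-vs-predicted agreement at one site."""

    pearson_r: float
    r2_adj: float
    rmse_days: float
    bias_days: float
    n: int


def _fixture_path(name: str):
    return resources.files("maizephen.data").joinpath(name)


def load_table3_fixture(path=None) -> list:
    """The packaged 66-record evaluation table (22 varieties × 3 sites)."""
    src = path if path is not None else _fixture_path("table3.csv")
    df = pd.read_csv(src)
    required = {"variety", "site", "observed_days", "predicted_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evaluation fixture lacks columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(EvaluationRecord(
                variety=str(row["variety"]), site=str(row["site"]),
                observed_days=int(row["observed_days"]),
                predicted_days=int(row["predicted_days"]),
                se_days=float(row["se_days"]) if "se_days" in df.columns else None,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed evaluation fixture at row {i + 2}: {exc}") from exc
    return records


def load_table2_fixture(path=None) -> pd.DataFrame:
    """The packaged table of published Briere parameter estimates."""
    src = path if path is not None else _fixture_path("table2.csv")
    df = pd.read_csv(src)
    required = {"variety", "tb", "tm", "a", "aic", "r2", "msc", "rmse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter fixture lacks columns: {sorted(missing)}")
    return df


def agreement(records: Sequence[EvaluationRecord]) -> AgreementStats:
    """Agreement statistics over a set of (observed, predicted) day pairs."""
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    obs = np.array([r.observed_days for r in records], dtype=float)
    pred = np.array([r.predicted_days for r in records], dtype=float)
    if np.ptp(obs) == 0:
        raise ValueError("observed durations have zero variance")
    r = float(stats.pearsonr(obs, pred)[0])
    return AgreementStats(
        pearson_r=r,
        r2_adj=adjusted_r_squared(r * r, n=len(records), k=1),
        rmse_days=rmse(obs, pred),
        bias_days=float(np.mean(pred - obs)),
        n=len(records),
    )


def agreement_by_site(records: Sequence[EvaluationRecord]) -> dict:
    """Per-site agreement statistics, keyed by site name."""
    out = {}
    for site in sorted({r.site for r in records}):
        out[site] = agreement([r for r in records if r.site == site])
    return out


def observed_range(records: Sequence[EvaluationRecord]) -> tuple:
    """(min, max) of observed durations across all records."""
    if not records:
        raise ValueError("no records")
    obs = [r.observed_days for r in records]
    return (min(obs), max(obs))


def table2_summary(df: Optional[pd.DataFrame] = None) -> dict:
    """Extremes of the published base-temperature and RMSE columns."""
    if df is None:
        df = load_table2_fixture()
    for col in ("tb", "rmse"):
        if col not in df.columns:
            raise ValueError(f"parameter table lacks column {col!r}")
    return {
        "Tb_min": float(df["tb"].min()),
        "Tb_max": float(df["tb"].max()),
        "rmse_min": float(df["rmse"].min()),
        "rmse_max": float(df["rmse"].max()),
    }
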