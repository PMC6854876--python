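"""Monthly price-index ingestion and the annualized-inflation transform.

The raw material of the analysis is a monthly consumer-price-index (CPI)
level series per product.  Everything downstream models the *annualized*
inflation rate

    pi_t = p_t / p_{t-12} - 1,

the year-over-year growth of the index, stored as a decimal fraction
(0.05 = 5%).  Month arithmetic is purely positional on a gap-free monthly
grid: month t-12 is simply 12 positions earlier.  Missing months are a hard
error; no imputation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "CPISeries",
    "InflationSeries",
    "DescriptiveStats",
    "read_cpi_csv",
    "read_cpi_panel",
    "annualized_inflation",
    "descriptive_stats",
    "inflation_to_csv",
    "descriptive_stats_table",
]


def _as_period(month) -> pd.Period:
    """Coerce a year-month designator to a monthly pandas Period."""
    if isinstance(month, pd.Period):
        if month.freqstr not in ("M", "ME"):
            return month.asfreq("M")
        return month
    return pd.Period(month, freq="M")


@dataclass(frozen=True)
class CPISeries:
    """Monthly price-index levels anchored at a calendar month.

    Parameters
    ----------
    start_month : str | pandas.Period
        The calendar month of the first observation (e.g. ``"2010-01"``).
    values : array-like of float
        Index levels for consecutive months, all strictly positive.
    """

    start_month: pd.Period
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "start_month", _as_period(self.start_month))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("CPISeries requires a non-empty 1-D value array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("CPISeries values must be finite")
        if np.any(vals <= 0):
            bad = self.start_month + int(np.argmax(vals <= 0))
            raise ValueError(f"non-positive index level at {bad}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=len(self), freq="M")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name="index_level")


@dataclass(frozen=True)
class InflationSeries:
    """Annualized inflation per month, as decimal fractions (> -1)."""

    start_month: pd.Period
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "start_month", _as_period(self.start_month))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("InflationSeries requires a non-empty 1-D value array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("InflationSeries values must be finite")
        if np.any(vals <= -1):
            raise ValueError("annualized inflation must exceed -1 (a -100% year)")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=len(self), freq="M")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.index, name="inflation_decimal")


@dataclass(frozen=True)
class DescriptiveStats:
    """Location/dispersion/shape summary of an inflation series.

    ``kurtosis`` is the Pearson (non-excess) convention, so a normal
    distribution scores 3.  ``skewness`` is the moment coefficient g1.
    A constant series has skewness 0 by convention and undefined (NaN)
    kurtosis.
    """

    mean: float
    sd: float
    min: float
    max: float
    skewness: float
    kurtosis: float
    n: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "n": self.n,
        }


def _parse_months(raw: pd.Series, date_column: str) -> pd.PeriodIndex:
    try:
        return pd.PeriodIndex([_as_period(v) for v in raw], freq="M")
    except Exception as exc:  # noqa: BLE001 - surface the offending column
        raise ValueError(
            f"column {date_column!r} does not parse as year-month values: {exc}"
        ) from exc


def _to_cpi(months: pd.PeriodIndex, values: pd.Series, label: str) -> CPISeries:
    order = np.argsort(months.asi8)
    months = months[order]
    vals = np.asarray(values, dtype=float)[order]

    dup = pd.Index(months).duplicated()
    if dup.any():
        raise ValueError(f"duplicate month {months[dup][0]} in {label}")
    steps = np.diff(months.asi8)
    if np.any(steps != 1):
        gap_at = months[int(np.argmax(steps != 1))] + 1
        raise ValueError(f"missing month {gap_at} in {label}: monthly grid has a gap")
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"non-numeric or missing index value in {label}")
    if np.any(vals <= 0):
        bad = months[int(np.argmax(vals <= 0))]
        raise ValueError(f"non-positive index level at {bad} in {label}")
    return CPISeries(start_month=months[0], values=vals)


def read_cpi_csv(path, date_column: str = "date", value_column: str = "value") -> CPISeries:
    """Read a monthly index series from a two-column CSV.

    Rows may appear in any order; the result is sorted by month.  Duplicate
    months, gaps in the monthly grid, and non-positive index levels are
    errors naming the offending month.
    """
    df = pd.read_csv(path)
    for col in (date_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    months = _parse_months(df[date_column], date_column)
    values = pd.to_numeric(df[value_column], errors="coerce")
    return _to_cpi(months, values, str(path))


def read_cpi_panel(path, date_column: str = "date") -> dict[str, CPISeries]:
    """Read a wide CSV (one date column + one column per product)."""
    df = pd.read_csv(path)
    if date_column not in df.columns:
        raise ValueError(f"column {date_column!r} not found in {path}")
    months = _parse_months(df[date_column], date_column)
    out: dict[str, CPISeries] = {}
    for col in df.columns:
        if col == date_column:
            continue
        values = pd.to_numeric(df[col], errors="coerce")
        out[col] = _to_cpi(months, values, f"{path}:{col}")
    return out


def annualized_inflation(cpi: CPISeries) -> InflationSeries:
    """Year-over-year growth of the index: pi_t = p_t / p_{t-12} - 1.

    The output starts 12 months after the index start and is 12 observations
    shorter than the input; at least 13 index months are required.
    """
    if len(cpi) < 13:
        raise ValueError(
            f"need at least 13 monthly index levels to form annualized inflation, got {len(cpi)}"
        )
    p = cpi.values
    pi = p[12:] / p[:-12] - 1.0
    return InflationSeries(start_month=cpi.start_month + 12, values=pi)


def descriptive_stats(x: InflationSeries | np.ndarray) -> DescriptiveStats:
    """Mean, sample SD, extrema, moment skewness g1 and Pearson kurtosis.

    The SD uses the n-1 denominator; skewness and kurtosis are the
    biased moment coefficients m3/m2^1.5 and m4/m2^2 (normal -> 3).
    """
    vals = x.values if isinstance(x, InflationSeries) else np.asarray(x, dtype=float)
    n = vals.size
    if n < 2:
        raise ValueError("descriptive statistics need at least 2 observations")
    # a constant series: sd and skewness 0 by convention, kurtosis undefined
    if np.all(vals == vals[0]):
        sd, skew, kurt = 0.0, 0.0, float("nan")
    else:
        sd = float(np.std(vals, ddof=1))
        skew = float(_sstats.skew(vals, bias=True))
        kurt = float(_sstats.kurtosis(vals, fisher=False, bias=True))
    return DescriptiveStats(
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        skewness=skew,
        kurtosis=kurt,
        n=n,
    )


def inflation_to_csv(x: InflationSeries, path) -> None:
    """Write an inflation series as a (date, inflation_decimal) CSV."""
    frame = x.to_pandas().rename_axis("date").reset_index()
    frame["date"] = frame["date"].astype(str)
    frame.to_csv(path, index=False)


def descriptive_stats_table(stats: Mapping[str, DescriptiveStats]) -> pd.DataFrame:
    """Stack per-product summaries into one table (products as rows)."""
    rows = {name: s.to_dict() for name, s in stats.items()}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("product")
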