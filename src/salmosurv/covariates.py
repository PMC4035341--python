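"""Covariate transformations, seasonal aggregation, lags and alignment.

Candidate drivers (ocean abundance, ocean harvest rate, hatchery releases
and returns, North Pacific climate indices, summer base flow, April snow
depth, watershed disturbance) arrive as raw annual or monthly series.
Before screening they get:

* a variance-stabilizing transform (identity, ln, or ln(ln(x)) for the
  heavy-tailed hatchery-return counts),
* a seasonal aggregation for monthly series (e.g. mean of May-June climate
  index values at ocean entry; summed July-September base flow),
* a lag that attaches the covariate value at calendar year t+k to brood
  year t (k=0 is the unlagged "t" variable; harvest rates act at ages 3
  and 4, so lags 3 and 4; hatchery releases and snow depth at t+1).

Alignment then matches each prepared column with the survival response:
pairwise on each covariate's own complete-case years for screening (the
reason different correlations carry different n), and on the intersection
of all columns for multi-variable models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import AnnualSeries, MonthlySeries, StockRecruitTable

__all__ = [
    "CovariateSpec",
    "AlignedDataset",
    "apply_transform",
    "aggregate_season",
    "lag_series",
    "prepare_covariate",
    "align",
]

log = logging.getLogger(__name__)

TRANSFORMS = ("identity", "ln", "ln_ln")
CATEGORIES = ("population", "climate", "habitat")
AGGREGATORS = ("mean", "sum")


@dataclass(frozen=True)
class CovariateSpec:
    """Declarative recipe for preparing one raw covariate series."""

    name: str
    category: str = "population"
    transform: str = "identity"
    season: tuple[tuple[int, ...], str] | None = None  # (months, aggregator)
    lags: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.season is not None:
            months, how = self.season
            months = tuple(int(m) for m in months)
            if not months or not set(months) <= set(range(1, 13)):
                raise ValueError(f"months {months} not within 1..12")
            if how not in AGGREGATORS:
                raise ValueError(f"unknown aggregator {how!r}")
            object.__setattr__(self, "season", (months, how))
        object.__setattr__(self, "lags", tuple(int(k) for k in self.lags))

    def column_names(self) -> list[str]:
        return [f"{self.name}@t+{k}" if k > 0
                else (f"{self.name}@t{k}" if k < 0 else f"{self.name}@t")
                for k in self.lags]


def apply_transform(series: AnnualSeries, transform: str) -> AnnualSeries:
    """Apply identity / ln / ln(ln(.)) pointwise, dropping out-of-domain years.

    ln requires x > 0 and ln_ln requires x > 1; years violating the domain
    are excluded from the output (and logged), not zero-filled.  A series
    that would come out empty raises.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if transform == "identity":
        return series
    fn, lo = ((np.log, 0.0) if transform == "ln"
              else (lambda x: np.log(np.log(x)), 1.0))
    values, dropped = {}, []
    for y, v in series.values.items():
        if v > lo:
            values[y] = float(fn(v))
        else:
            dropped.append(y)
    if dropped:
        log.warning("%s: %s undefined for %d year(s) %s; excluded",
                    series.name, transform, len(dropped), sorted(dropped))
    if not values:
        raise ValueError(f"{series.name}: no valid years after {transform}")
    return AnnualSeries(name=f"{transform}({series.name})", unit="index",
                        values=values)


def aggregate_season(monthly: MonthlySeries, months, how: str) -> AnnualSeries:
    """Collapse a monthly series to annual values over the listed months.

    A year is emitted only when *every* requested month is present for it
    (partial seasons are omitted, not averaged over fewer months).
    """
    months = tuple(int(m) for m in months)
    if not months:
        raise ValueError("empty month list")
    if not set(months) <= set(range(1, 13)):
        raise ValueError(f"months {months} not within 1..12")
    if how not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {how!r}")
    agg = np.mean if how == "mean" else np.sum
    values = {}
    for year in monthly.years:
        vals = [monthly.values[(year, m)] for m in months
                if (year, m) in monthly.values]
        if len(vals) == len(months):
            values[year] = float(agg(vals))
    return AnnualSeries(name=f"{monthly.name}[{how} m{months}]",
                        unit=monthly.unit, values=values)


def lag_series(series: AnnualSeries, lag: int) -> AnnualSeries:
    """Attach the calendar-year t+lag value to brood year t.

    ``lag=0`` is the identity ("t" variables); ``lag=3`` reads the series
    three years after the brood year (e.g. harvest on age-3 fish).
    """
    lag = int(lag)
    if lag == 0:
        return series
    return replace(series,
                   name=f"{series.name}@t+{lag}" if lag > 0
                        else f"{series.name}@t{lag}",
                   values={y - lag: v for y, v in series.values.items()})


def prepare_covariate(spec: CovariateSpec,
                      raw: AnnualSeries | MonthlySeries
                      ) -> dict[str, AnnualSeries]:
    """Run one covariate through season -> transform -> each lag.

    Returns a column per lag, keyed by the spec's column names.
    """
    if spec.season is not None:
        if not isinstance(raw, MonthlySeries):
            raise TypeError(f"{spec.name}: seasonal spec needs monthly input")
        annual = aggregate_season(raw, *spec.season)
    else:
        if isinstance(raw, MonthlySeries):
            raise TypeError(f"{spec.name}: monthly input but no season given")
        annual = raw
    annual = apply_transform(annual, spec.transform)
    return {col: replace(lag_series(annual, k), name=col)
            for col, k in zip(spec.column_names(), spec.lags)}


@dataclass(frozen=True)
class AlignedDataset:
    """Survival response matched with prepared covariate columns.

    ``pairwise`` holds, per column, the (x, y, years) triple on that
    column's own complete-case years — the screening view, where n varies
    by covariate.  ``frame`` is the complete-case intersection across all
    columns — the modelling view — with the response in column
    ``"survival"`` and the year set in the index.
    """

    response_name: str
    pairwise: dict[str, pd.DataFrame]
    frame: pd.DataFrame
    min_pair_n: int = 3

    @property
    def years(self) -> list[int]:
        return self.frame.index.tolist()

    @property
    def n(self) -> int:
        return len(self.frame)

    def pair(self, column: str) -> tuple[np.ndarray, np.ndarray, list[int]]:
        df = self.pairwise[column]
        return (df[column].to_numpy(), df["survival"].to_numpy(),
                df.index.tolist())


def align(response: StockRecruitTable | AnnualSeries,
          columns: dict[str, AnnualSeries],
          min_pair_n: int = 3) -> AlignedDataset:
    """Align covariate columns with the survival response by brood year.

    Pairwise views keep each covariate's own overlap with the response
    (requiring at least ``min_pair_n`` shared years); the modelling frame
    is the intersection of all columns' year sets.  No year is ever
    invented: every output year set is a subset of every input's.
    """
    resp = (response.survival_series()
            if isinstance(response, StockRecruitTable) else response)
    resp_pd = resp.to_pandas().rename("survival")
    if resp_pd.empty:
        raise ValueError("empty response series")

    pairwise: dict[str, pd.DataFrame] = {}
    for name, col in columns.items():
        joined = pd.concat([col.to_pandas().rename(name), resp_pd],
                           axis=1, join="inner")
        if len(joined) < min_pair_n:
            raise ValueError(
                f"column {name!r}: only {len(joined)} year(s) shared with "
                f"the response (need >= {min_pair_n})")
        pairwise[name] = joined

    frame = resp_pd.to_frame()
    for name, col in columns.items():
        frame = frame.join(col.to_pandas().rename(name), how="inner")
    if frame.empty:
        raise ValueError(
            "empty year intersection across columns "
            f"{sorted(columns)} and the response")
    frame.index = frame.index.astype(int)
    frame.index.name = "brood_year"
    return AlignedDataset(response_name=resp.name, pairwise=pairwise,
                          frame=frame.sort_index(), min_pair_n=min_pair_n)
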