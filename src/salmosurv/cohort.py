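"""Brood-year cohort reconstruction and the survival index.

Spawning-ground counts observe *returns* in each calendar year, mixed
across cohorts.  To study drivers of survival we need the cohort view:
for a brood year t, total adult production is

    R_t = sum_{n=k}^{K} p_n(t+n) * S_{t+n}

where (k, K) is the range of reproductively mature return ages (3-5 for
Chinook salmon, 4-7 for steelhead), S_{t+n} the spawner count in return
year t+n, and p_n(t+n) the proportion of that return year's spawners
that are n years old.  The survival index is ln(R_t / S_t), the log of
per-spawner adult production; regressed on S_t it is the linearized
Ricker model.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable

import numpy as np
import pandas as pd

from .series import AgeComposition, AnnualSeries, StockRecruitTable

__all__ = [
    "fill_missing_age_composition",
    "reconstruct_recruitment",
    "survival_index",
    "build_stock_recruit_table",
    "detect_autocorrelation",
]

log = logging.getLogger(__name__)


def fill_missing_age_composition(comp: AgeComposition,
                                 years_needed: Iterable[int]) -> AgeComposition:
    """Impute unobserved years with the mean observed age proportions.

    Each missing year receives the arithmetic mean, age by age, of all
    observed years' proportions, renormalized to sum to 1.  Imputed years
    are recorded in ``filled_years``.

    Raises
    ------
    ValueError
        If the composition has no observed years at all.
    """
    observed = comp.observed_years
    if not observed:
        raise ValueError(f"{comp.taxon}: no observed age-composition years")

    mean = {a: float(np.mean([comp.proportions[y][a] for y in observed]))
            for a in comp.ages}
    total = sum(mean.values())
    mean = {a: p / total for a, p in mean.items()}

    props = {y: dict(row) for y, row in comp.proportions.items()}
    filled = set(comp.filled_years)
    for year in years_needed:
        if year not in props:
            props[int(year)] = dict(mean)
            filled.add(int(year))
    if filled - set(comp.filled_years):
        log.info("%s: imputed age composition for %d year(s)",
                 comp.taxon, len(filled - set(comp.filled_years)))
    return replace(comp, proportions=props, filled_years=frozenset(filled))


def reconstruct_recruitment(spawners: AnnualSeries,
                            comp: AgeComposition) -> AnnualSeries:
    """Reconstruct brood-year recruitment from returns and age proportions.

    R_t = sum over return ages n of p_n(t+n) * S_{t+n}.  The proportion is
    read from the *return* year's composition (t+n), the convention under
    which return-year spawners partition exactly into contributing brood
    years.  Brood years whose return window extends beyond the spawner
    series (right-truncation) or contains a spawner gap are omitted; gaps
    are logged, never zero-filled.
    """
    k, K = comp.age_range
    years = spawners.years
    if not years:
        return AnnualSeries(name=f"{comp.taxon}_recruits", unit=spawners.unit)

    # earliest brood year whose full return window the series can cover
    first_brood = min(years) - k
    last_brood = max(years) - K
    values: dict[int, float] = {}
    for t in range(first_brood, last_brood + 1):
        window = range(t + k, t + K + 1)
        missing = [y for y in window if y not in spawners]
        if missing:
            log.warning("brood year %d: spawner gap at %s; R_t omitted",
                        t, missing)
            continue
        try:
            r = sum(comp.proportion(y, y - t) * spawners[y] for y in window)
        except KeyError as exc:
            raise ValueError(
                f"age composition missing for return year {exc.args[0]} "
                f"(brood year {t}); call fill_missing_age_composition first"
            ) from None
        values[t] = r
    return AnnualSeries(name=f"{comp.taxon}_recruits", unit=spawners.unit,
                        values=values)


def survival_index(taxon: str, spawners: AnnualSeries,
                   recruits: AnnualSeries) -> StockRecruitTable:
    """Pair S_t with R_t and attach survival ln(R_t/S_t).

    Rows with S_t <= 0 or R_t <= 0 have no defined survival; they are kept
    with ``survival = NaN`` and ``flagged = True`` so downstream
    regressions can exclude them without losing the record.
    """
    brood_years = sorted(set(spawners.values) & set(recruits.values))
    records = []
    for t in brood_years:
        s, r = spawners[t], recruits[t]
        bad = s <= 0 or r <= 0
        records.append({
            "brood_year": t,
            "spawners": s,
            "recruits": r,
            "survival": np.nan if bad else float(np.log(r / s)),
            "flagged": bad,
        })
    rows = pd.DataFrame.from_records(
        records, columns=list(StockRecruitTable.COLUMNS))
    note = (f"last usable brood year {brood_years[-1]}" if brood_years
            else "no usable brood years")
    return StockRecruitTable(taxon=taxon, rows=rows, truncation_note=note)


def build_stock_recruit_table(taxon: str, spawners: AnnualSeries,
                              comp: AgeComposition) -> StockRecruitTable:
    """Convenience chain: fill composition -> reconstruct R_t -> survival."""
    k, K = comp.age_range
    if spawners.years:
        needed = range(min(spawners.years), max(spawners.years) + 1)
        comp = fill_missing_age_composition(comp, needed)
    recruits = reconstruct_recruitment(spawners, comp)
    return survival_index(taxon, spawners, recruits)


def detect_autocorrelation(series: AnnualSeries, max_lag: int
                           ) -> list[tuple[int, float, bool]]:
    """Sample autocorrelation at lags 1..max_lag with +/-1.96/sqrt(n) bands.

    The series must be on a contiguous year grid (interior gaps would
    misalign the lagged products).  Returns (lag, r_lag, significant)
    triples; significance is the usual white-noise band test used when
    checking a survival index for serial structure before modelling.
    """
    if len(series) <= max_lag + 2:
        raise ValueError(
            f"series length {len(series)} too short for max_lag={max_lag}")
    years = series.years
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("autocorrelation requires a contiguous annual grid")
    x = np.array([series[y] for y in years], dtype=float)
    n = len(x)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0.0:
        raise ValueError("autocorrelation undefined for a constant series")
    band = 1.96 / np.sqrt(n)
    out = []
    for lag in range(1, max_lag + 1):
        r = float(x[lag:] @ x[:-lag]) / denom
        out.append((lag, r, abs(r) > band))
    return out
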