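"""Core year-indexed containers for the survival analysis.

The whole pipeline works on short annual time series (spawner counts,
environmental covariates), per-year age-composition tables, and the
stock-recruit table that pairs brood-year spawners with reconstructed
recruits.  Everything is a thin, validated wrapper around pandas objects
so the statistical modules can stay agnostic about file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "MonthlySeries",
    "AgeComposition",
    "StockRecruitTable",
    "COUNT_UNITS",
]

#: units for which negative values are physically impossible
COUNT_UNITS = frozenset({"fish", "fish/km"})


@dataclass(frozen=True)
class AnnualSeries:
    """A named annual time series: calendar year -> value.

    Parameters
    ----------
    name:
        Label of the quantity (e.g. ``"spawners"``, ``"flow"``).
    unit:
        Unit label; ``"fish"`` and ``"fish/km"`` are count-type units and
        force non-negative values.
    values:
        Mapping from integer calendar year to a finite float.
    """

    name: str
    unit: str
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for year, value in self.values.items():
            y = int(year)
            if y in clean:
                raise ValueError(f"{self.name}: duplicate year {y}")
            v = float(value)
            if not np.isfinite(v):
                raise ValueError(f"{self.name}: non-finite value at year {y}")
            if self.unit in COUNT_UNITS and v < 0:
                raise ValueError(f"{self.name}: negative count at year {y}")
            clean[y] = v
        object.__setattr__(self, "values", clean)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    def __contains__(self, year: int) -> bool:
        return year in self.values

    def __getitem__(self, year: int) -> float:
        return self.values[year]

    @property
    def years(self) -> list[int]:
        return sorted(self.values)

    def to_pandas(self) -> pd.Series:
        s = pd.Series(self.values, name=self.name, dtype=float)
        return s.sort_index()

    @classmethod
    def from_pandas(cls, s: pd.Series, name: str | None = None,
                    unit: str = "index") -> "AnnualSeries":
        return cls(name=name or str(s.name), unit=unit,
                   values={int(k): float(v) for k, v in s.items()
                           if np.isfinite(v)})

    def restrict(self, years) -> "AnnualSeries":
        """Subset to the given years (silently drops absent ones)."""
        keep = {y: v for y, v in self.values.items() if y in set(years)}
        return replace(self, values=keep)

    def scale(self, a: float) -> "AnnualSeries":
        if self.unit in COUNT_UNITS and a < 0:
            raise ValueError("negative scale on a count series")
        return replace(self, values={y: a * v for y, v in self.values.items()})


@dataclass(frozen=True)
class MonthlySeries:
    """A monthly series: (year, month) -> value, months 1..12."""

    name: str
    unit: str
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[int, int], float] = {}
        for (year, month), value in self.values.items():
            m = int(month)
            if not 1 <= m <= 12:
                raise ValueError(f"{self.name}: month {m} outside 1..12")
            key = (int(year), m)
            if key in clean:
                raise ValueError(f"{self.name}: duplicate year/month {key}")
            v = float(value)
            if not np.isfinite(v):
                raise ValueError(f"{self.name}: non-finite value at {key}")
            clean[key] = v
        object.__setattr__(self, "values", clean)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.values})


@dataclass(frozen=True)
class AgeComposition:
    """Per-year proportions of returning adults by age.

    ``age_range`` is the inclusive span of ages counted as reproductively
    mature on the spawning grounds: (3, 5) for Chinook salmon, (4, 7) for
    steelhead.  ``proportions[year][age]`` is the fraction of year's
    returning spawners that are ``age`` years old; within a year the
    proportions sum to 1.  ``filled_years`` records years whose
    composition was imputed rather than observed.
    """

    taxon: str
    age_range: tuple[int, int]
    proportions: dict[int, dict[int, float]] = field(default_factory=dict)
    filled_years: frozenset[int] = frozenset()

    #: raw within-year sums in this band are renormalized to 1; outside it
    #: the year is treated as unobserved (agency tables often omit trace ages)
    RENORM_BAND = (0.9, 1.1)
    SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        k, K = self.age_range
        if k > K:
            raise ValueError(f"age_range {self.age_range} reversed")
        clean: dict[int, dict[int, float]] = {}
        for year, props in self.proportions.items():
            row = {}
            for age, p in props.items():
                a = int(age)
                if not k <= a <= K:
                    raise ValueError(
                        f"{self.taxon}: age {a} outside range {self.age_range}")
                p = float(p)
                if p < 0:
                    raise ValueError(f"{self.taxon}: negative proportion at "
                                     f"year {year} age {a}")
                row[a] = p
            total = sum(row.values())
            lo, hi = self.RENORM_BAND
            if not lo <= total <= hi:
                # unusable year: treat as unobserved
                continue
            row = {a: p / total for a, p in row.items()}
            # explicit zeros for ages absent from the table
            for a in range(k, K + 1):
                row.setdefault(a, 0.0)
            clean[int(year)] = row
        object.__setattr__(self, "proportions", clean)
        object.__setattr__(self, "filled_years",
                           frozenset(self.filled_years) & set(clean))

    @property
    def ages(self) -> list[int]:
        return list(range(self.age_range[0], self.age_range[1] + 1))

    @property
    def observed_years(self) -> list[int]:
        return sorted(set(self.proportions) - self.filled_years)

    def proportion(self, year: int, age: int) -> float:
        return self.proportions[year][age]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.proportions, orient="index")
        return df.sort_index()[self.ages]


@dataclass(frozen=True)
class StockRecruitTable:
    """Brood-year rows of spawners, recruits and the survival index.

    ``survival`` is ln(R_t/S_t), the log of per-spawner adult production
    (the linearized-Ricker response).  Rows where S_t <= 0 or R_t <= 0 carry
    ``survival = NaN`` and are flagged, never silently dropped.
    """

    taxon: str
    rows: pd.DataFrame  # columns: brood_year, spawners, recruits, survival, flagged
    truncation_note: str = ""

    COLUMNS = ("brood_year", "spawners", "recruits", "survival", "flagged")

    def __post_init__(self) -> None:
        df = self.rows.copy()
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"stock-recruit table missing columns {missing}")
        df = df[list(self.COLUMNS)].sort_values("brood_year")
        df["brood_year"] = df["brood_year"].astype(int)
        object.__setattr__(self, "rows", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def brood_years(self) -> list[int]:
        return self.rows["brood_year"].tolist()

    def survival_series(self) -> AnnualSeries:
        """Usable survival values (finite, unflagged) as an AnnualSeries."""
        ok = self.rows[~self.rows["flagged"]
                       & np.isfinite(self.rows["survival"])]
        return AnnualSeries(
            name=f"{self.taxon}_survival", unit="index",
            values=dict(zip(ok["brood_year"], ok["survival"])))
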