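"""Readers, writers and analysis configuration.

All tabular inputs are plain comma-separated text with a one-line
header: annual series as ``year,value``, monthly series as
``year,month,value``, age compositions as ``year,age,proportion``.
Malformed rows fail loudly with their line number — silent coercion of
agency data is how reconstruction errors go unnoticed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .covariates import CovariateSpec
from .screening import ScreenConfig
from .series import AgeComposition, AnnualSeries, MonthlySeries, StockRecruitTable

__all__ = [
    "read_annual_csv", "read_monthly_csv", "read_age_csv",
    "write_stock_recruit_csv",
    "TaxonConfig", "CovariateFileSpec", "AnalysisConfig", "load_config",
]

log = logging.getLogger(__name__)


class CsvFormatError(ValueError):
    """A malformed input table, carrying the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = path, lineno


def _rows(path: str | Path, expected: tuple[str, ...]):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError(path, 1, "empty file") from None
        header = [h.strip().lower() for h in header]
        if header != list(expected):
            raise CsvFormatError(
                path, 1, f"expected header {','.join(expected)}, "
                         f"got {','.join(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(expected):
                raise CsvFormatError(
                    path, lineno, f"expected {len(expected)} fields, "
                                  f"got {len(row)}")
            yield lineno, row


def _parse(path, lineno, text: str, kind, what: str):
    try:
        return kind(text)
    except ValueError:
        raise CsvFormatError(
            path, lineno, f"non-numeric {what}: {text!r}") from None


def read_annual_csv(path: str | Path, name: str | None = None,
                    unit: str = "index") -> AnnualSeries:
    """Read a ``year,value`` table into an AnnualSeries."""
    path = Path(path)
    values: dict[int, float] = {}
    for lineno, row in _rows(path, ("year", "value")):
        year = _parse(path, lineno, row[0].strip(), int, "year")
        if year in values:
            raise CsvFormatError(path, lineno, f"duplicate year {year}")
        values[year] = _parse(path, lineno, row[1].strip(), float, "value")
    return AnnualSeries(name=name or path.stem, unit=unit, values=values)


def read_monthly_csv(path: str | Path, name: str | None = None,
                     unit: str = "index") -> MonthlySeries:
    """Read a ``year,month,value`` table into a MonthlySeries."""
    path = Path(path)
    values: dict[tuple[int, int], float] = {}
    for lineno, row in _rows(path, ("year", "month", "value")):
        year = _parse(path, lineno, row[0].strip(), int, "year")
        month = _parse(path, lineno, row[1].strip(), int, "month")
        if not 1 <= month <= 12:
            raise CsvFormatError(path, lineno, f"month {month} outside 1..12")
        if (year, month) in values:
            raise CsvFormatError(path, lineno,
                                 f"duplicate year/month {(year, month)}")
        values[(year, month)] = _parse(path, lineno, row[2].strip(),
                                       float, "value")
    return MonthlySeries(name=name or path.stem, unit=unit, values=values)


def read_age_csv(path: str | Path, taxon: str,
                 age_range: tuple[int, int]) -> AgeComposition:
    """Read a long-format ``year,age,proportion`` age-composition table."""
    path = Path(path)
    props: dict[int, dict[int, float]] = {}
    for lineno, row in _rows(path, ("year", "age", "proportion")):
        year = _parse(path, lineno, row[0].strip(), int, "year")
        age = _parse(path, lineno, row[1].strip(), int, "age")
        if not age_range[0] <= age <= age_range[1]:
            raise CsvFormatError(path, lineno,
                                 f"age {age} outside {age_range}")
        p = _parse(path, lineno, row[2].strip(), float, "proportion")
        if age in props.get(year, {}):
            raise CsvFormatError(path, lineno,
                                 f"duplicate year/age {(year, age)}")
        props.setdefault(year, {})[age] = p
    return AgeComposition(taxon=taxon, age_range=age_range, proportions=props)


def write_stock_recruit_csv(table: StockRecruitTable, path: str | Path) -> None:
    """Write ``brood_year,spawners,recruits,survival`` (flagged rows blank)."""
    lines = ["brood_year,spawners,recruits,survival"]
    for _, row in table.rows.iterrows():
        surv = "" if row["flagged"] else f"{row['survival']:.10g}"
        lines.append(f"{int(row['brood_year'])},{row['spawners']:.10g},"
                     f"{row['recruits']:.10g},{surv}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# analysis configuration


@dataclass(frozen=True)
class TaxonConfig:
    name: str
    age_range: tuple[int, int]
    spawner_file: Path
    age_file: Path | None = None       # None: borrow from another taxon
    borrow_ages_from: str | None = None
    unit: str = "fish"


@dataclass(frozen=True)
class CovariateFileSpec:
    spec: CovariateSpec
    file: Path


@dataclass(frozen=True)
class AnalysisConfig:
    taxa: list[TaxonConfig]
    covariates: list[CovariateFileSpec]
    screen: ScreenConfig
    likelihood: str = "REML"
    max_vars: int = 3
    interactions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("taxon names must be unique")


def load_config(path: str | Path, seed: int | None = None) -> AnalysisConfig:
    """Load a YAML analysis config; file paths resolve relative to it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    taxa = []
    for t in raw.get("taxa", []):
        taxa.append(TaxonConfig(
            name=t["name"],
            age_range=tuple(t["age_range"]),
            spawner_file=base / t["spawner_file"],
            age_file=(base / t["age_file"]) if t.get("age_file") else None,
            borrow_ages_from=t.get("borrow_ages_from"),
            unit=t.get("unit", "fish"),
        ))

    covs = []
    for c in raw.get("covariates", []):
        season = None
        if c.get("season"):
            season = (tuple(c["season"]["months"]),
                      c["season"].get("aggregator", "mean"))
        spec = CovariateSpec(
            name=c["name"],
            category=c.get("category", "population"),
            transform=c.get("transform", "identity"),
            season=season,
            lags=tuple(c.get("lags", [0])),
        )
        covs.append(CovariateFileSpec(spec=spec, file=base / c["file"]))

    s = raw.get("screen", {})
    screen = ScreenConfig(
        n_perm=int(s.get("n_perm", 99_999)),
        alpha=float(s.get("alpha", 0.05)),
        seed=int(seed if seed is not None else s.get("seed", 0)),
        top_k=int(s.get("top_k", 5)),
    )
    m = raw.get("model", {})
    return AnalysisConfig(
        taxa=taxa, covariates=covs, screen=screen,
        likelihood=m.get("likelihood", "REML"),
        max_vars=int(m.get("max_vars", 3)),
        interactions=[tuple(p) for p in m.get("interactions", [])],
    )
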