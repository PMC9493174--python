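"""Reading, validating and writing city-year panel tables.

The panel is a plain CSV (UTF-8, comma-delimited, decimal point) with one
row per city and year. Numeric cells may carry thousands separators, as
statistical-yearbook tables usually do ("327,846" parses to 327846).
Currency units are metadata only: subsidies are carried in millions and
medical revenue in billions, and no automatic conversion is ever applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
import yaml

__all__ = ["CityYearRecord", "Panel", "PanelError", "SchemaError",
           "ParseError", "IntegrityError", "DEFAULT_SCHEMA",
           "DEFAULT_REGION_PARTITION", "ENV_COLUMNS", "read_panel",
           "write_table", "load_config"]

ENV_COLUMNS = (
    "gdp_per_capita",
    "urbanization_rate",
    "population_density",
    "highschool_share",
    "insurance_share",
    "gov_health_share",
)

#: Environmental variables that are proportions and must lie in [0, 1].
_PROPORTION_ENV = {"urbanization_rate", "highschool_share",
                   "insurance_share", "gov_health_share"}

DEFAULT_SCHEMA = {
    "city_id": "city_id", "region": "region", "year": "year",
    "population": "population", "area": "area",
    "hospitals": "hospitals", "beds": "beds", "technicians": "technicians",
    "subsidies": "subsidies", "visits": "visits", "discharges": "discharges",
    "examinations": "examinations", "revenue": "revenue",
    **{c: c for c in ENV_COLUMNS},
}

#: Four-region grouping of Guangdong's 21 prefecture-level cities by
#: economic development and geography (fully configurable).
DEFAULT_REGION_PARTITION = {
    "pearl_river_delta": ("GZ", "SZ", "ZH", "FS", "HZ", "DG", "ZS", "JM", "ZQ"),
    "eastern": ("ST", "SW", "CZ", "JY"),
    "western": ("YJ", "ZJ", "MM"),
    "mountainous": ("SG", "HY", "MZ", "QY", "YF"),
}


class PanelError(ValueError):
    """Base class for panel validation failures."""


class SchemaError(PanelError):
    pass


class ParseError(PanelError):
    pass


class IntegrityError(PanelError):
    pass


@dataclass(frozen=True)
class CityYearRecord:
    """One city in one year: demography, DEA inputs/outputs, environment."""

    city_id: str
    region: str
    year: int
    population: float          # end-of-year residents, persons
    area: float                # km^2
    hospitals: float
    beds: float
    technicians: float
    subsidies: float           # currency, millions
    visits: float
    discharges: float
    examinations: float
    revenue: float             # currency, billions
    env: tuple = field(default=())

    def __post_init__(self):
        if self.population <= 0 or self.area <= 0:
            raise IntegrityError(
                f"{self.city_id}/{self.year}: population and area must be > 0")
        for name in ("hospitals", "beds", "technicians", "subsidies",
                     "visits", "discharges", "examinations", "revenue"):
            if getattr(self, name) < 0:
                raise IntegrityError(
                    f"{self.city_id}/{self.year}: {name} must be >= 0")
        if len(self.env) != len(ENV_COLUMNS):
            raise IntegrityError(
                f"{self.city_id}/{self.year}: expected {len(ENV_COLUMNS)} "
                f"environmental variables, got {len(self.env)}")
        for name, val in zip(ENV_COLUMNS, self.env):
            if name in _PROPORTION_ENV and not (0.0 <= val <= 1.0):
                raise IntegrityError(
                    f"{self.city_id}/{self.year}: {name} = {val} outside [0, 1]")


@dataclass(frozen=True)
class Panel:
    """A validated collection of city-year records."""

    records: tuple
    region_partition: dict

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.city_id, r.year)
            if key in seen:
                raise IntegrityError(f"duplicate (city, year) pair {key}")
            seen.add(key)
        # balanced-panel check: every city present in every year
        years = self.years
        cities = self.cities
        missing = [(c, y) for c in cities for y in years
                   if (c, y) not in seen]
        if missing:
            raise IntegrityError(f"unbalanced panel; missing {missing[:5]}"
                                 + ("..." if len(missing) > 5 else ""))

    @property
    def years(self) -> tuple:
        return tuple(sorted({r.year for r in self.records}))

    @property
    def cities(self) -> tuple:
        return tuple(dict.fromkeys(r.city_id for r in self.records))

    def year_slice(self, year: int) -> list:
        rows = [r for r in self.records if r.year == year]
        if not rows:
            raise KeyError(f"year {year} not in panel")
        return rows

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in dc_fields(CityYearRecord) if f.name != "env"]
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        for i, ec in enumerate(ENV_COLUMNS):
            data[ec] = [r.env[i] for r in self.records]
        return pd.DataFrame(data)

    def validate_dea_size(self, n_inputs: int = 3, n_outputs: int = 4) -> None:
        for y in self.years:
            n = len(self.year_slice(y))
            if n < 2 * (n_inputs + n_outputs):
                raise IntegrityError(
                    f"year {y}: {n} cities < 2(m+s) = {2 * (n_inputs + n_outputs)}; "
                    "DEA lacks discriminative power")


def _parse_numeric(series: pd.Series, column: str) -> pd.Series:
    """Parse a numeric column, stripping thousands separators."""
    cleaned = series.astype(str).str.replace(",", "", regex=False).str.strip()
    out = pd.to_numeric(cleaned, errors="coerce")
    bad = out.isna() & ~series.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in column "
            f"{column!r}, data row {row}")
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ParseError(f"missing value in column {column!r}, data row {row}")
    return out


def read_panel(path, schema: dict | None = None,
               region_partition: dict | None = None) -> Panel:
    """Read a city-year panel CSV into a validated :class:`Panel`.

    ``schema`` maps canonical field names to file column names; ``None``
    uses the canonical names directly. ``region_partition`` overrides the
    region column, mapping region name -> iterable of city ids.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, dtype=str)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    city = df[schema["city_id"]].astype(str)
    if region_partition is not None:
        city_to_region = {c: g for g, cities in region_partition.items()
                          for c in cities}
        unknown = sorted(set(city) - set(city_to_region))
        if unknown:
            raise SchemaError(f"cities missing from region partition: {unknown}")
        region = city.map(city_to_region)
    else:
        region = df[schema["region"]].astype(str)
        city_to_region = dict(zip(city, region))

    numeric_fields = ["year", "population", "area", "hospitals", "beds",
                      "technicians", "subsidies", "visits", "discharges",
                      "examinations", "revenue", *ENV_COLUMNS]
    parsed = {f: _parse_numeric(df[schema[f]], schema[f]) for f in numeric_fields}

    records = []
    for idx in range(len(df)):
        env = tuple(float(parsed[c].iloc[idx]) for c in ENV_COLUMNS)
        records.append(CityYearRecord(
            city_id=str(city.iloc[idx]), region=str(region.iloc[idx]),
            year=int(parsed["year"].iloc[idx]),
            population=float(parsed["population"].iloc[idx]),
            area=float(parsed["area"].iloc[idx]),
            hospitals=float(parsed["hospitals"].iloc[idx]),
            beds=float(parsed["beds"].iloc[idx]),
            technicians=float(parsed["technicians"].iloc[idx]),
            subsidies=float(parsed["subsidies"].iloc[idx]),
            visits=float(parsed["visits"].iloc[idx]),
            discharges=float(parsed["discharges"].iloc[idx]),
            examinations=float(parsed["examinations"].iloc[idx]),
            revenue=float(parsed["revenue"].iloc[idx]),
            env=env,
        ))
    return Panel(records=tuple(records), region_partition=city_to_region)


def write_table(rows, path) -> str:
    """Write homogeneous result records to CSV with full float precision.

    ``rows`` may be a DataFrame, a list of dicts, or a list of dataclass
    instances. Values survive a read-back round trip to 12 significant
    digits (floats are written with 17 significant digits).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("refusing to write an empty result table")
        if hasattr(rows[0], "__dataclass_fields__"):
            rows = [{f.name: getattr(r, f.name)
                     for f in dc_fields(r)} for r in rows]
        keys = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != keys:
                raise ValueError("result rows are not homogeneous")
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("refusing to write an empty result table")
    df.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def load_config(path) -> dict:
    """Load a YAML config (columns, region partition, years, options)."""
    if hasattr(path, "read"):
        return yaml.safe_load(path) or {}
    with io.open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
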