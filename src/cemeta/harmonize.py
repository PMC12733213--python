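"""Two-step monetary harmonization: CPI inflation, then PPP conversion.

Costs reported in different countries, currencies and price years are made
comparable by (1) inflating each amount to a common target price year with
the country's own consumer price index, preserving domestic price dynamics,
and (2) converting the inflated local-currency amount into international
dollars with a purchasing-power-parity conversion factor (LCU per
international dollar).  PPP conversion is preferred to market exchange
rates because it corrects for cross-country price-level differences rather
than importing nominal-exchange-rate noise.

CPI and PPP tables are plain local CSV files (``country,year,index`` and
``country,year,lcu_per_intl_dollar``); no network access is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .records import StudyRecord, canonical_country

__all__ = [
    "CpiSeries",
    "PppFactor",
    "CoverageError",
    "load_cpi",
    "load_ppp",
    "inflate",
    "ppp_convert",
    "harmonize_record",
    "harmonize_table",
]

HARMONIZED_CODE = "PPP-USD"


class CoverageError(KeyError):
    """A CPI year or PPP factor needed for harmonization is not available."""


@dataclass
class CpiSeries:
    """A country's consumer price index by year (arbitrary base)."""

    country: str
    index_by_year: dict[int, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.index_by_year.values()):
            raise ValueError(f"{self.country}: CPI index values must be > 0")

    def index(self, year: int, interpolate: bool = False) -> float:
        """The index value for ``year``.

        With ``interpolate=True``, a missing year strictly inside the
        covered range is filled log-linearly from its nearest covered
        neighbours (a constant-inflation-rate assumption).
        """
        if year in self.index_by_year:
            return self.index_by_year[year]
        years = sorted(self.index_by_year)
        if interpolate and years and years[0] < year < years[-1]:
            lo = max(y for y in years if y < year)
            hi = min(y for y in years if y > year)
            frac = (year - lo) / (hi - lo)
            return math.exp(
                (1 - frac) * math.log(self.index_by_year[lo])
                + frac * math.log(self.index_by_year[hi])
            )
        raise CoverageError(f"no CPI index for {self.country} in {year}")


@dataclass(frozen=True)
class PppFactor:
    """Local currency units per international dollar for (country, year)."""

    country: str
    year: int
    lcu_per_intl_dollar: float

    def __post_init__(self) -> None:
        if self.lcu_per_intl_dollar <= 0:
            raise ValueError("PPP factor must be > 0")


def load_cpi(path: str | Path) -> dict[str, CpiSeries]:
    """Read ``country,year,index`` CSV into per-country CPI series."""
    df = pd.read_csv(path)
    out: dict[str, CpiSeries] = {}
    for country, grp in df.groupby("country"):
        name = canonical_country(str(country))
        out[name] = CpiSeries(
            country=name,
            index_by_year={int(y): float(v) for y, v in zip(grp["year"], grp["index"])},
        )
    return out


def load_ppp(path: str | Path) -> dict[tuple[str, int], PppFactor]:
    """Read ``country,year,lcu_per_intl_dollar`` CSV into a factor table."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        name = canonical_country(str(row["country"]))
        f = PppFactor(name, int(row["year"]), float(row["lcu_per_intl_dollar"]))
        out[(f.country, f.year)] = f
    return out


def inflate(
    amount: float,
    country: str,
    from_year: int,
    to_year: int,
    cpi: dict[str, CpiSeries],
    interpolate: bool = False,
) -> float:
    """Inflate ``amount`` (LCU) from ``from_year`` to ``to_year`` prices.

    Returns ``amount × index(to_year) / index(from_year)``.
    """
    country = canonical_country(country)
    if country not in cpi:
        raise CoverageError(f"no CPI series for {country}")
    series = cpi[country]
    return amount * series.index(to_year, interpolate) / series.index(from_year, interpolate)


def ppp_convert(
    amount: float,
    country: str,
    year: int,
    ppp: dict[tuple[str, int], PppFactor],
) -> float:
    """Convert an LCU ``amount`` into international dollars at ``year``."""
    key = (canonical_country(country), year)
    if key not in ppp:
        raise CoverageError(f"no PPP factor for {key[0]} in {year}")
    return amount / ppp[key].lcu_per_intl_dollar


def harmonize_record(
    record: StudyRecord,
    cpi: dict[str, CpiSeries],
    ppp: dict[tuple[str, int], PppFactor],
    target_year: int = 2024,
    interpolate: bool = False,
) -> StudyRecord:
    """Inflate-then-convert all monetary fields of one record.

    The same composite factor multiplies ``total_cost``,
    ``incremental_cost`` and ``icer_per_qaly``, so internal consistency of
    the record is preserved; QALY fields are untouched.  Records already in
    PPP-USD pass through unchanged (idempotence).  Original monetary values
    are retained in ``record.provenance``.
    """
    if record.currency_code == HARMONIZED_CODE:
        return record
    inflation = inflate(1.0, record.country, record.price_year, target_year, cpi, interpolate)
    factor = ppp_convert(inflation, record.country, target_year, ppp)
    new = replace(
        record,
        total_cost=record.total_cost * factor,
        incremental_cost=record.incremental_cost * factor,
        icer_per_qaly=record.icer_per_qaly * factor,
        currency_code=HARMONIZED_CODE,
        price_year=target_year,
    )
    new.provenance = dict(record.provenance)
    new.provenance["pre_harmonization"] = {
        "currency_code": record.currency_code,
        "price_year": record.price_year,
        "total_cost": record.total_cost,
        "incremental_cost": record.incremental_cost,
        "icer_per_qaly": record.icer_per_qaly,
    }
    return new


def harmonize_table(table, cpi, ppp, target_year: int = 2024, interpolate: bool = False):
    """Harmonize every record of a :class:`~cemeta.records.StudyTable`."""
    from .records import StudyTable

    return StudyTable(
        records=[harmonize_record(r, cpi, ppp, target_year, interpolate) for r in table],
        provenance=table.provenance,
    )
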