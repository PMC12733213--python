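"""Study-level data model and tabular I/O for cost-effectiveness meta-analysis.

The unit of analysis is one modeled sub-scenario of a published economic
evaluation: its incremental health gain (``qaly_gain``, ΔE), incremental
lifetime cost (``incremental_cost``, ΔC), total lifetime cost under the
intervention arm, and reported incremental cost-effectiveness ratio
(``icer_per_qaly``), all expressed in purchasing-power-parity-adjusted US
dollars after harmonization.  Sub-scenarios of one publication are retained
as separate observations because they model analytically distinct
populations.

The packaged fixture ``mastaleru2025`` transcribes the 17-observation
dataset of a published Inclisiran cost-effectiveness meta-analysis, with
monetary values already harmonized to PPP-USD at 2024 prices.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "StudyRecord",
    "StudyTable",
    "ConsistencyFlag",
    "SchemaError",
    "ValidationError",
    "EmptyInputError",
    "CSV_COLUMNS",
    "INTERVENTIONS",
    "AGE_GROUPS",
    "canonical_country",
    "load_records",
    "write_records",
    "validate_table",
]


class SchemaError(ValueError):
    """The input table is missing required columns or has malformed cells."""


class ValidationError(ValueError):
    """The input table violates a dataset invariant (e.g. duplicate ids)."""


class EmptyInputError(ValueError):
    """The input table contains no records."""


#: Fixed interchange header, in order.
CSV_COLUMNS = [
    "study_id",
    "authors_label",
    "pub_year",
    "country",
    "intervention",
    "population_tag",
    "age_group",
    "model_type",
    "qaly_gain",
    "total_qaly",
    "total_cost",
    "incremental_cost",
    "icer_per_qaly",
    "currency_code",
    "price_year",
]

#: Optional within-study standard-error columns (empty in the fixture: the
#: source publications report point estimates only).
OPTIONAL_COLUMNS = ["se_qaly_gain", "se_incremental_cost"]

NUMERIC_COLUMNS = [
    "pub_year",
    "qaly_gain",
    "total_qaly",
    "total_cost",
    "incremental_cost",
    "icer_per_qaly",
    "price_year",
]

INTERVENTIONS = {"Inclisiran", "Inclisiran+statin", "Inclisiran+SoC", "Other"}
AGE_GROUPS = {"<45", "45-60", ">60", "unknown"}

_COUNTRY_ALIASES = {
    "united kingdom": "UK",
    "uk": "UK",
    "u.k.": "UK",
    "great britain": "UK",
    "usa": "USA",
    "united states": "USA",
    "united states of america": "USA",
    "us": "USA",
}

_DASHES = "‐‑‒–—−"  # hyphen/figure/en/em/minus


def canonical_country(name: str) -> str:
    """Map country-name variants to one canonical label (e.g. 'United
    Kingdom' and 'UK' both become 'UK')."""
    return _COUNTRY_ALIASES.get(name.strip().lower(), name.strip())


def _normalize_number(cell: object) -> float:
    """Parse a numeric cell tolerating thousands separators and typographic
    minus/dash characters."""
    if isinstance(cell, (int, float)):
        return float(cell)
    text = str(cell).strip().replace(",", "").replace("$", "")
    for d in _DASHES:
        text = text.replace(d, "-")
    return float(text)


@dataclass
class StudyRecord:
    """One modeled sub-scenario of an economic evaluation.

    Monetary fields are in the units given by ``currency_code`` at
    ``price_year`` prices; after harmonization the code is ``"PPP-USD"``.
    """

    study_id: str
    authors_label: str
    pub_year: int
    country: str
    intervention: str
    population_tag: str
    age_group: str
    model_type: str
    qaly_gain: float          # ΔE, incremental QALYs per patient
    total_qaly: float         # QALYs in the intervention arm
    total_cost: float         # per-patient lifetime cost, intervention arm
    incremental_cost: float   # ΔC, per-patient incremental lifetime cost
    icer_per_qaly: float      # reported ICER (may disagree with ΔC/ΔE)
    currency_code: str = "PPP-USD"
    price_year: int = 2024
    se_qaly_gain: Optional[float] = None
    se_incremental_cost: Optional[float] = None
    #: Free-form provenance (original country label, pre-harmonization
    #: monetary values); not part of the CSV interchange schema.
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.intervention not in INTERVENTIONS:
            raise ValidationError(
                f"{self.study_id}: unknown intervention {self.intervention!r}; "
                f"expected one of {sorted(INTERVENTIONS)}"
            )
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"{self.study_id}: unknown age_group {self.age_group!r}"
            )
        if self.total_qaly <= 0:
            raise ValidationError(f"{self.study_id}: total_qaly must be > 0")

    def implied_icer(self) -> float:
        """ΔC / ΔE from the record's own columns (undefined when ΔE = 0)."""
        if self.qaly_gain == 0:
            return math.nan
        return self.incremental_cost / self.qaly_gain


@dataclass
class StudyTable:
    """An ordered collection of :class:`StudyRecord` with distinct ids."""

    records: list[StudyRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("a StudyTable must contain at least one record")
        ids = [r.study_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate study_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for r in self.records:
            if r.study_id == study_id:
                return r
        raise KeyError(study_id)

    def column(self, name: str) -> list:
        return [getattr(r, name) for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        cols = CSV_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "StudyTable":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if len(df) == 0:
            raise EmptyInputError("input table has a header but no rows")
        records = []
        for idx, row in df.iterrows():
            kwargs = {}
            for c in CSV_COLUMNS + OPTIONAL_COLUMNS:
                if c not in df.columns:
                    kwargs[c] = None
                    continue
                cell = row[c]
                if c in NUMERIC_COLUMNS or c in OPTIONAL_COLUMNS:
                    if cell is None or (isinstance(cell, float) and math.isnan(cell)) \
                            or (isinstance(cell, str) and not cell.strip()):
                        if c in OPTIONAL_COLUMNS:
                            kwargs[c] = None
                            continue
                        raise SchemaError(f"row {idx}, column {c!r}: empty numeric cell")
                    try:
                        value = _normalize_number(cell)
                    except ValueError:
                        raise SchemaError(
                            f"row {idx}, column {c!r}: malformed numeric cell {cell!r}"
                        ) from None
                    if c in ("pub_year", "price_year"):
                        value = int(value)
                    kwargs[c] = value
                else:
                    kwargs[c] = str(cell).strip()
            raw_country = kwargs["country"]
            kwargs["country"] = canonical_country(raw_country)
            rec = StudyRecord(**kwargs)
            if rec.country != raw_country:
                rec.provenance["country_original"] = raw_country
            records.append(rec)
        return cls(records=records, provenance=provenance)


def load_records(path_or_fixture: str | Path) -> StudyTable:
    """Load a study table from a CSV path or a packaged fixture.

    ``"fixture:mastaleru2025"`` (or the bare fixture name) loads the
    packaged 17-observation dataset.
    """
    name = str(path_or_fixture)
    if name.startswith("fixture:"):
        name = name[len("fixture:"):]
    fixture = resources.files("cemeta").joinpath("data", f"{name}.csv")
    if not Path(name).suffix and fixture.is_file():
        with fixture.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, dtype=str)
        return StudyTable.from_frame(df, provenance=f"fixture:{name}")
    path = Path(path_or_fixture)
    if not path.exists():
        raise FileNotFoundError(f"no such file or fixture: {path_or_fixture}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    return StudyTable.from_frame(df, provenance=str(path))


def write_records(table: StudyTable, path: str | Path) -> None:
    """Write a study table as UTF-8 CSV with the fixed interchange header."""
    df = table.to_frame()
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class ConsistencyFlag:
    """A record whose reported ICER disagrees with ΔC/ΔE beyond tolerance.

    Flags report, they never reject: published ICERs can legitimately
    diverge from the ratio of extracted columns (different rounding,
    different cost aggregates), and the divergence itself is informative.
    """

    study_id: str
    reported_icer: float
    implied_icer: float
    relative_error: float


def validate_table(table: StudyTable, tol: float = 0.01) -> list[ConsistencyFlag]:
    """Return one flag per record where |ICER − ΔC/ΔE| / ICER exceeds ``tol``.

    Never mutates the table.  ``tol=math.inf`` disables flagging.
    """
    flags = []
    for r in table:
        if r.icer_per_qaly == 0 or r.qaly_gain == 0:
            continue
        implied = r.implied_icer()
        rel = abs(r.icer_per_qaly - implied) / abs(r.icer_per_qaly)
        if rel > tol:
            flags.append(
                ConsistencyFlag(
                    study_id=r.study_id,
                    reported_icer=r.icer_per_qaly,
                    implied_icer=implied,
                    relative_error=rel,
                )
            )
    return flags
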