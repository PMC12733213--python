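"""Per-study cost-effectiveness metrics: ICER, net monetary benefit,
classification at willingness-to-pay thresholds, and country affordability.

The net monetary benefit at willingness-to-pay λ monetizes the health gain:
``NMB = λ·ΔE − cost``.  A positive NMB means the intervention is
cost-effective at that threshold.  Two cost bases are supported because
published summaries use both: ``incremental`` (ΔC, the standard
health-economics definition and the default) and ``total`` (the
intervention arm's total lifetime cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd

from .records import StudyRecord, StudyTable, canonical_country

__all__ = [
    "CostBasis",
    "WtpThreshold",
    "NMBRecord",
    "AffordabilityRow",
    "UndefinedRatioError",
    "icer",
    "quadrant",
    "nmb",
    "nmb_linearity_shift",
    "classify",
    "affordability",
    "load_thresholds",
]

CostBasis = Literal["incremental", "total"]


class UndefinedRatioError(ZeroDivisionError):
    """ICER requested with ΔE = 0."""


def icer(delta_cost: float, delta_qaly: float) -> float:
    """Incremental cost-effectiveness ratio ΔC/ΔE (currency per QALY).

    Negative ΔE or ΔC place the comparison in a dominance quadrant (see
    :func:`quadrant`); the ratio is still returned but is not a valid
    decision statistic there.
    """
    if delta_qaly == 0:
        raise UndefinedRatioError("ICER undefined: ΔE = 0")
    if delta_qaly < 0:
        warnings.warn(
            f"negative QALY gain ({delta_qaly}): ICER lies in the "
            f"{quadrant(delta_cost, delta_qaly)} quadrant and should not be "
            "compared against a threshold",
            stacklevel=2,
        )
    return delta_cost / delta_qaly


def quadrant(delta_cost: float, delta_qaly: float) -> str:
    """Cost-effectiveness-plane quadrant: NE (more costly, more effective),
    SE (dominant), NW (dominated), SW (less costly, less effective)."""
    ns = "N" if delta_cost >= 0 else "S"
    ew = "E" if delta_qaly >= 0 else "W"
    return ns + ew


@dataclass(frozen=True)
class NMBRecord:
    """One study's monetized net benefit at one threshold and cost basis."""

    study_id: str
    lam: float          # willingness-to-pay, USD per QALY
    cost_basis: CostBasis
    nmb: float          # λ·ΔE − cost, USD


def _cost(record: StudyRecord, basis: CostBasis) -> float:
    if basis == "incremental":
        return record.incremental_cost
    if basis == "total":
        return record.total_cost
    raise ValueError(f"unknown cost basis {basis!r}")


def nmb(record: StudyRecord, lam: float, basis: CostBasis = "incremental") -> NMBRecord:
    """Net monetary benefit ``λ·ΔE − cost(basis)`` for one record."""
    return NMBRecord(
        study_id=record.study_id,
        lam=lam,
        cost_basis=basis,
        nmb=lam * record.qaly_gain - _cost(record, basis),
    )


def nmb_linearity_shift(rec: NMBRecord, lam2: float, delta_qaly: float) -> NMBRecord:
    """Re-threshold an NMB in closed form: NMB(λ₂) = NMB(λ₁) + (λ₂−λ₁)·ΔE.

    Exact because NMB is affine in λ with slope ΔE; agrees bit-for-bit with
    direct recomputation when ΔE matches the record's.
    """
    return NMBRecord(
        study_id=rec.study_id,
        lam=lam2,
        cost_basis=rec.cost_basis,
        nmb=rec.nmb + (lam2 - rec.lam) * delta_qaly,
    )


def classify(
    table: StudyTable,
    lam: float,
    criterion: Literal["icer_below_lambda", "nmb_positive"] = "nmb_positive",
    basis: CostBasis = "incremental",
) -> tuple[dict[str, bool], int]:
    """Flag each record as cost-effective at λ; return flags and the count.

    ``nmb_positive`` flags NMB > 0 on the chosen basis;
    ``icer_below_lambda`` flags reported ICER < λ.  Records in a dominance
    quadrant (negative ΔE or ΔC) are excluded from the ICER criterion with
    a warning, since their ICER is not threshold-comparable.
    """
    flags: dict[str, bool] = {}
    for r in table:
        if criterion == "nmb_positive":
            flags[r.study_id] = nmb(r, lam, basis).nmb > 0
        elif criterion == "icer_below_lambda":
            if r.qaly_gain < 0 or r.incremental_cost < 0:
                warnings.warn(
                    f"{r.study_id}: dominance quadrant "
                    f"{quadrant(r.incremental_cost, r.qaly_gain)}; excluded "
                    "from ICER-based classification",
                    stacklevel=2,
                )
                flags[r.study_id] = False
                continue
            flags[r.study_id] = r.icer_per_qaly < lam
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return flags, sum(flags.values())


@dataclass(frozen=True)
class WtpThreshold:
    """A willingness-to-pay threshold, explicit or a GDP-per-capita multiple."""

    lam: float
    scope: Literal["global", "country-specific"] = "global"
    source: Literal["explicit", "gdp_multiple"] = "explicit"
    gdp_multiple: Optional[float] = None
    country: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("threshold must be > 0")
        if (self.source == "gdp_multiple") != (self.gdp_multiple is not None):
            raise ValueError("gdp_multiple present iff source='gdp_multiple'")


def load_thresholds(path: str | Path | None = None) -> dict[str, WtpThreshold]:
    """Read a ``country,lambda,source,gdp_multiple`` CSV.

    With no path, loads the packaged default country thresholds.
    """
    if path is None:
        path = resources.files("cemeta").joinpath("data", "wtp_thresholds.csv")
    with (path.open("r", encoding="utf-8") if hasattr(path, "open") else open(path)) as fh:
        df = pd.read_csv(fh)
    out = {}
    for _, row in df.iterrows():
        country = canonical_country(str(row["country"]))
        source = str(row.get("source", "explicit"))
        gm = row.get("gdp_multiple")
        gm = None if pd.isna(gm) else float(gm)
        out[country] = WtpThreshold(
            lam=float(row["lambda"]),
            scope="country-specific",
            source="gdp_multiple" if source == "gdp_multiple" else "explicit",
            gdp_multiple=gm if source == "gdp_multiple" else None,
            country=country,
        )
    return out


@dataclass(frozen=True)
class AffordabilityRow:
    """Country-level affordability verdict at that country's threshold."""

    country: str
    mean_icer: float
    threshold: Optional[WtpThreshold]
    mean_nmb: Optional[float]
    n_studies: int
    n_cost_effective: int
    verdict: Literal["yes", "no", "unknown"]


def affordability(
    table: StudyTable,
    thresholds: dict[str, WtpThreshold],
    gdp_per_capita: Optional[dict[str, float]] = None,
    gdp_multiple: float = 1.0,
    basis: CostBasis = "incremental",
) -> list[AffordabilityRow]:
    """Per-country affordability at country-specific thresholds.

    The country threshold is the explicit entry in ``thresholds`` or, for
    countries absent there but present in ``gdp_per_capita``, the stated
    multiple (default 1×, convention range 1–3×) of per-capita GDP.  The
    verdict is ``yes`` iff the country's mean NMB at its threshold is
    strictly positive, ``unknown`` when no threshold can be resolved.
    ``n_cost_effective`` counts the country's records whose reported ICER
    falls below the threshold.
    """
    if not 1.0 <= gdp_multiple <= 3.0:
        raise ValueError("gdp_multiple must lie in [1, 3]")
    rows = []
    countries = sorted({r.country for r in table})
    for country in countries:
        recs = [r for r in table if r.country == country]
        mean_icer = sum(r.icer_per_qaly for r in recs) / len(recs)
        thr = thresholds.get(country)
        if thr is None and gdp_per_capita and country in gdp_per_capita:
            thr = WtpThreshold(
                lam=gdp_multiple * gdp_per_capita[country],
                scope="country-specific",
                source="gdp_multiple",
                gdp_multiple=gdp_multiple,
                country=country,
            )
        if thr is None:
            rows.append(
                AffordabilityRow(country, mean_icer, None, None, len(recs), 0, "unknown")
            )
            continue
        nmbs = [nmb(r, thr.lam, basis).nmb for r in recs]
        mean_nmb = sum(nmbs) / len(nmbs)
        n_ce = sum(r.icer_per_qaly < thr.lam for r in recs)
        verdict = "yes" if mean_nmb > 0 else "no"  # tie at exactly 0 -> no
        rows.append(
            AffordabilityRow(country, mean_icer, thr, mean_nmb, len(recs), n_ce, verdict)
        )
    return rows
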