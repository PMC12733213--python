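"""Descriptive synthesis of study-level quantities.

Conventions are fixed so that the summaries are reproducible to the digit:
sample SD with the n−1 denominator, SE = SD/√n, normal 95% CI
(mean ± 1.96·SE), and quantiles by linear interpolation at rank (n−1)·p —
the only quantile rule consistent with the reference dataset's published
quartiles.  Full precision is kept internally; rounding is a formatting
concern of the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .metrics import CostBasis, nmb
from .records import EmptyInputError, StudyTable

__all__ = ["SummaryStats", "summarize", "group_summary", "nmb_summary", "GroupRow"]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: Optional[float]       # None when n = 1
    se: Optional[float]
    ci95_low: Optional[float]
    ci95_high: Optional[float]
    min: float
    q25: float
    median: float
    q75: float
    max: float
    quantile_rule: str = "linear:(n-1)p"


def summarize(values: Sequence[float]) -> SummaryStats:
    """Full descriptive summary of a list of reals (n ≥ 1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise EmptyInputError("cannot summarize an empty list")
    mean = float(x.mean())
    if x.size == 1:
        sd = se = lo = hi = None
    else:
        sd = float(x.std(ddof=1))
        se = sd / float(np.sqrt(x.size))
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    q25, med, q75 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    return SummaryStats(
        n=int(x.size), mean=mean, sd=sd, se=se, ci95_low=lo, ci95_high=hi,
        min=float(x.min()), q25=q25, median=med, q75=q75, max=float(x.max()),
    )


@dataclass(frozen=True)
class GroupRow:
    """One group level's summaries of ΔE, ΔC and NMB at each threshold."""

    group: str
    n: int
    qaly_gain: SummaryStats
    incremental_cost: SummaryStats
    nmb: dict[float, SummaryStats]  # λ -> summary


def group_summary(
    table: StudyTable,
    group_key: Literal["intervention", "country", "age_group"],
    lambdas: Iterable[float] = (50_000, 100_000, 150_000),
    basis: CostBasis = "incremental",
    include_unknown_age: bool = False,
) -> list[GroupRow]:
    """Summaries of ΔE, ΔC and NMB per level of a stratifying covariate.

    Rows with unknown age are excluded from age-stratified summaries unless
    requested; groups of size 1 report the mean only (SD absent).
    """
    if group_key not in ("intervention", "country", "age_group"):
        raise ValueError(f"unknown group key {group_key!r}")
    recs = list(table)
    if group_key == "age_group" and not include_unknown_age:
        recs = [r for r in recs if r.age_group != "unknown"]
    levels = sorted({getattr(r, group_key) for r in recs})
    rows = []
    for level in levels:
        members = [r for r in recs if getattr(r, group_key) == level]
        rows.append(
            GroupRow(
                group=level,
                n=len(members),
                qaly_gain=summarize([r.qaly_gain for r in members]),
                incremental_cost=summarize([r.incremental_cost for r in members]),
                nmb={
                    lam: summarize([nmb(r, lam, basis).nmb for r in members])
                    for lam in lambdas
                },
            )
        )
    return rows


def nmb_summary(table: StudyTable, lam: float, basis: CostBasis = "incremental") -> SummaryStats:
    """Distribution of per-record NMB at threshold λ on the chosen basis."""
    return summarize([nmb(r, lam, basis).nmb for r in table])
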