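"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Egger's regression test fits the standardized effect yᵢ/SEᵢ on precision
1/SEᵢ; under a symmetric funnel the intercept is zero, and a nonzero
intercept signals small-study asymmetry.  Leave-one-out sensitivity
recomputes a summary k times, excluding one study each time; for the mean
the exact exclusion identity mean₋ᵢ = (k·mean − xᵢ)/(k−1) holds and is
used as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from .pooling import (
    EffectInput,
    InsufficientStudiesError,
    PooledEstimate,
    random_effects_dl,
)

__all__ = [
    "EggerResult",
    "LOOResult",
    "egger_test",
    "leave_one_out",
    "leave_one_out_pooled",
    "funnel_coordinates",
]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    t: float
    p: float          # two-sided, for H0: intercept = 0
    slope: float      # estimates the underlying pooled effect
    k: int


def egger_test(inputs: Sequence[EffectInput]) -> EggerResult:
    """Egger's regression asymmetry test (k ≥ 3, all SEs > 0)."""
    if len(inputs) < 3:
        raise InsufficientStudiesError("Egger's test requires at least 3 studies")
    y = np.array([i.estimate / i.se for i in inputs])
    x = np.array([1.0 / i.se for i in inputs])
    X = np.column_stack([np.ones_like(x), x])
    fit_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ fit_beta
    df = len(y) - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    se_b0 = float(np.sqrt(cov[0, 0]))
    t = float(fit_beta[0] / se_b0)
    p = float(2 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=float(fit_beta[0]), se_intercept=se_b0, t=t, p=p,
        slope=float(fit_beta[1]), k=len(inputs),
    )


@dataclass(frozen=True)
class LOOResult:
    rows: list[tuple[str, float]]   # (excluded study id, recomputed value)
    full_value: float
    min_loo: float
    max_loo: float


def leave_one_out(
    values: Sequence[float],
    statistic: Literal["mean", "median"] = "mean",
    ids: Sequence[str] | None = None,
) -> LOOResult:
    """Recompute a summary excluding each observation in turn (k ≥ 2)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise InsufficientStudiesError("leave-one-out requires at least 2 values")
    if ids is None:
        ids = [f"x{i}" for i in range(x.size)]
    stat: Callable[[np.ndarray], float] = {
        "mean": lambda a: float(np.mean(a)),
        "median": lambda a: float(np.median(a)),
    }[statistic]
    rows = [
        (str(ids[i]), stat(np.delete(x, i)))
        for i in range(x.size)
    ]
    loo = [v for _, v in rows]
    return LOOResult(rows=rows, full_value=stat(x), min_loo=min(loo), max_loo=max(loo))


def leave_one_out_pooled(
    inputs: Sequence[EffectInput],
    tau2_method: Literal["dl", "reml"] = "dl",
) -> list[tuple[str, PooledEstimate]]:
    """Leave-one-out for the random-effects pooled estimate.

    τ² is re-estimated inside every replicate (a full re-fit, not a
    plug-in of the all-studies τ²), so each row reflects what the
    meta-analysis would have concluded without that study.
    """
    if len(inputs) < 3:
        raise InsufficientStudiesError("pooled leave-one-out requires at least 3 studies")
    out = []
    for i, excl in enumerate(inputs):
        rest = [inp for j, inp in enumerate(inputs) if j != i]
        out.append((excl.study_id, random_effects_dl(rest, tau2_method)))
    return out


def funnel_coordinates(inputs: Sequence[EffectInput]) -> list[tuple[float, float]]:
    """(effect, SE) pairs ordered by descending precision, for funnel plots."""
    return [(i.estimate, i.se) for i in sorted(inputs, key=lambda i: i.se)]
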