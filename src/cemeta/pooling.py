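"""Inverse-variance meta-analytic pooling with heterogeneity statistics.

Fixed-effect pooling weights each study by its inverse squared standard
error.  The random-effects model adds a between-study variance τ²,
estimated by the DerSimonian–Laird moment estimator

    τ² = max(0, (Q − df) / (Σwᵢ − Σwᵢ²/Σwᵢ)),   wᵢ = 1/SEᵢ²,

where Q is Cochran's heterogeneity statistic and df = k − 1; studies are
then re-weighted by 1/(SEᵢ² + τ²).  I² = max(0, (Q − df)/Q)·100 expresses
the share of total variability attributable to heterogeneity.  A REML
estimate of τ² is available as a sensitivity option.

Ratio quantities (ICERs) are pooled on the log scale and back-transformed,
yielding a geometric-mean-type summary.  Because published study-level
economic evaluations rarely report within-study variances, explicit SE
imputation conventions are provided and every pooled output should be
labeled with the convention used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .metrics import CostBasis, nmb as _nmb
from .records import StudyTable

__all__ = [
    "EffectInput",
    "PooledEstimate",
    "InsufficientStudiesError",
    "fixed_effect",
    "random_effects_dl",
    "pool_log_icer",
    "impute_se",
]


class InsufficientStudiesError(ValueError):
    """Fewer studies than the operation requires."""


@dataclass(frozen=True)
class EffectInput:
    """One study's effect estimate and standard error on a stated scale."""

    study_id: str
    estimate: float
    se: float
    scale: Literal["identity", "log"] = "identity"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study_id}: se must be > 0")


@dataclass(frozen=True)
class PooledEstimate:
    method: Literal["FE", "RE_DL", "RE_REML"]
    k: int
    pooled: float
    se_pooled: float
    ci95_low: float
    ci95_high: float
    Q: float
    df: int
    i2: float                 # percent, in [0, 100)
    tau2: float
    scale: Literal["identity", "log"] = "identity"
    #: exp of (pooled, ci95_low, ci95_high) when scale='log'
    back_transformed: Optional[tuple[float, float, float]] = None
    se_convention: Optional[str] = None


def _check(inputs: Sequence[EffectInput]) -> tuple[np.ndarray, np.ndarray]:
    if len(inputs) < 2:
        raise InsufficientStudiesError("pooling requires at least 2 studies")
    scales = {i.scale for i in inputs}
    if len(scales) > 1:
        raise ValueError(f"mixed scales in pooling inputs: {scales}")
    y = np.array([i.estimate for i in inputs], dtype=float)
    se = np.array([i.se for i in inputs], dtype=float)
    return y, se


def _assemble(method, y, se, tau2, scale, convention) -> PooledEstimate:
    w = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = float(np.sqrt(1.0 / np.sum(w)))
    # Q and I2 are always computed from the fixed-effect weights
    wfe = 1.0 / se**2
    mu_fe = np.sum(wfe * y) / np.sum(wfe)
    Q = float(np.sum(wfe * (y - mu_fe) ** 2))
    df = len(y) - 1
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    lo, hi = pooled - 1.96 * se_pooled, pooled + 1.96 * se_pooled
    back = (math.exp(pooled), math.exp(lo), math.exp(hi)) if scale == "log" else None
    return PooledEstimate(
        method=method, k=len(y), pooled=pooled, se_pooled=se_pooled,
        ci95_low=lo, ci95_high=hi, Q=Q, df=df, i2=i2, tau2=tau2,
        scale=scale, back_transformed=back, se_convention=convention,
    )


def fixed_effect(inputs: Sequence[EffectInput], se_convention: str | None = None) -> PooledEstimate:
    """Inverse-variance fixed-effect pooled estimate with Cochran's Q."""
    y, se = _check(inputs)
    return _assemble("FE", y, se, 0.0, inputs[0].scale, se_convention)


def _tau2_dl(y: np.ndarray, se: np.ndarray) -> float:
    w = 1.0 / se**2
    mu = np.sum(w * y) / np.sum(w)
    Q = np.sum(w * (y - mu) ** 2)
    df = len(y) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (Q - df) / c))


def _tau2_reml(y: np.ndarray, se: np.ndarray) -> float:
    def neg_restricted_ll(log_tau2: float) -> float:
        tau2 = math.exp(log_tau2)
        v = se**2 + tau2
        w = 1.0 / v
        mu = np.sum(w * y) / np.sum(w)
        return float(
            0.5 * np.sum(np.log(v))
            + 0.5 * math.log(np.sum(w))
            + 0.5 * np.sum(w * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-30.0, 15.0), method="bounded"
    )
    tau2 = math.exp(res.x)
    return 0.0 if tau2 < 1e-12 else float(tau2)


def random_effects_dl(
    inputs: Sequence[EffectInput],
    tau2_method: Literal["dl", "reml"] = "dl",
    se_convention: str | None = None,
) -> PooledEstimate:
    """Random-effects pooled estimate (DerSimonian–Laird τ² by default)."""
    y, se = _check(inputs)
    tau2 = _tau2_dl(y, se) if tau2_method == "dl" else _tau2_reml(y, se)
    method = "RE_DL" if tau2_method == "dl" else "RE_REML"
    return _assemble(method, y, se, tau2, inputs[0].scale, se_convention)


def pool_log_icer(
    icers: Sequence[float],
    ses_log: Sequence[float],
    study_ids: Sequence[str] | None = None,
    tau2_method: Literal["dl", "reml"] = "dl",
    se_convention: str | None = None,
) -> PooledEstimate:
    """Random-effects pool of log(ICER), back-transformed to the dollar scale.

    Nonpositive ICERs cannot be log-pooled; they are excluded with a
    warning and k adjusted.
    """
    if study_ids is None:
        study_ids = [f"x{i}" for i in range(len(icers))]
    inputs = []
    for sid, v, s in zip(study_ids, icers, ses_log):
        if v <= 0:
            warnings.warn(f"{sid}: nonpositive ICER {v} excluded from log pooling",
                          stacklevel=2)
            continue
        inputs.append(EffectInput(sid, math.log(v), s, scale="log"))
    return random_effects_dl(inputs, tau2_method, se_convention)


def impute_se(
    table: StudyTable,
    quantity: Literal["qaly_gain", "incremental_cost", "nmb"],
    convention: Literal["constant_cv", "fixed_se", "user_column"] = "constant_cv",
    param: float = 0.2,
    lam: float = 50_000,
    basis: CostBasis = "incremental",
) -> list[EffectInput]:
    """Deterministic within-study SEs for tables that report none.

    ``constant_cv`` sets SEᵢ = param·|yᵢ| (a fixed coefficient of
    variation), floored at 1e−6 of the column's mean absolute value so
    near-zero estimates cannot receive infinite weight; ``fixed_se`` sets
    SEᵢ = param for all studies; ``user_column`` reads the record's own
    optional SE column.
    """
    if convention in ("constant_cv", "fixed_se") and param <= 0:
        raise ValueError("convention parameter must be > 0")
    if quantity == "nmb":
        y = [_nmb(r, lam, basis).nmb for r in table]
    else:
        y = [getattr(r, quantity) for r in table]
    out = []
    floor = 1e-6 * float(np.mean(np.abs(y))) if any(y) else 1e-6
    for r, yi in zip(table, y):
        if convention == "constant_cv":
            se = max(param * abs(yi), floor)
        elif convention == "fixed_se":
            se = param
        elif convention == "user_column":
            col = "se_qaly_gain" if quantity == "qaly_gain" else "se_incremental_cost"
            se = getattr(r, col, None)
            if se is None:
                raise ValueError(
                    f"{r.study_id}: user_column convention requires {col} to be present"
                )
        else:
            raise ValueError(f"unknown convention {convention!r}")
        out.append(EffectInput(r.study_id, yi, float(se)))
    return out
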