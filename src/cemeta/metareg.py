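"""OLS meta-regression of study-level outcomes on study covariates.

Responses are NMB at a stated threshold, the reported ICER, or the QALY
gain; covariates are publication year plus treatment-coded country and
intervention indicators (reference levels: Australia, Inclisiran), so each
dummy coefficient is a contrast against the reference.  Models are
unweighted OLS — study-level economic evaluations carry no usable
within-study variances — with plain t-based inference at n − rank degrees
of freedom.

Perfectly collinear columns are dropped deterministically (last-entered
first) before fitting and reported, so a redundant indicator shows up as a
named dropped term rather than a silent NaN.  Added-variable (partial
regression) data are exposed for every fitted covariate; by the
Frisch–Waugh–Lovell theorem the slope of each partial-regression cloud
equals the covariate's coefficient in the full model, which is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import CostBasis, nmb as _nmb
from .records import StudyTable

__all__ = [
    "DesignSpec",
    "RegressionResult",
    "CoefficientRow",
    "fit_ols",
    "trend_slope",
    "partial_regression",
    "DroppedTermError",
    "InsufficientDataError",
]

_RANK_TOL = 1e-10


class InsufficientDataError(ValueError):
    """More estimable terms than observations."""


class DroppedTermError(KeyError):
    """Partial-regression data requested for a collinearity-dropped term."""


@dataclass(frozen=True)
class DesignSpec:
    """What to regress on what, with explicit reference levels."""

    response: Literal["nmb", "icer_per_qaly", "qaly_gain"] = "nmb"
    lam: Optional[float] = None                # required when response='nmb'
    basis: CostBasis = "incremental"
    covariates: tuple[str, ...] = ("year", "country", "intervention")
    reference_levels: dict = field(
        default_factory=lambda: {"country": "Australia", "intervention": "Inclisiran"}
    )

    def __post_init__(self) -> None:
        if self.response == "nmb" and self.lam is None:
            raise ValueError("response='nmb' requires a willingness-to-pay lam")
        bad = set(self.covariates) - {"year", "country", "intervention"}
        if bad:
            raise ValueError(f"unknown covariates: {sorted(bad)}")


@dataclass(frozen=True)
class CoefficientRow:
    term: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class RegressionResult:
    coefficients: list[CoefficientRow]
    r2: float
    adj_r2: float
    n: int
    residuals: np.ndarray
    dropped_terms: list[str]
    #: fitted design matrix (with intercept) and response, for partial plots
    design: pd.DataFrame = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def coef(self, term: str) -> CoefficientRow:
        for c in self.coefficients:
            if c.term == term:
                return c
        raise KeyError(term)


def _response_vector(spec: DesignSpec, table: StudyTable) -> np.ndarray:
    if spec.response == "nmb":
        return np.array([_nmb(r, spec.lam, spec.basis).nmb for r in table])
    return np.array([getattr(r, spec.response) for r in table], dtype=float)


def _design_matrix(spec: DesignSpec, table: StudyTable) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(table))}
    for cov in spec.covariates:
        if cov == "year":
            cols["year"] = np.array([r.pub_year for r in table], dtype=float)
        else:
            ref = spec.reference_levels.get(cov)
            levels = sorted({getattr(r, cov) for r in table})
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov} data")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = np.array(
                    [1.0 if getattr(r, cov) == lev else 0.0 for r in table]
                )
    return pd.DataFrame(cols)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy in-order column selection: a column entering after the ones
    already kept is dropped iff it is numerically in their span (relative
    tolerance 1e-10), so redundant terms are removed last-entered first."""
    kept: list[str] = []
    dropped: list[str] = []
    for name in X.columns:
        cand = X[kept + [name]].to_numpy()
        s = np.linalg.svd(cand, compute_uv=False)
        if s[-1] <= _RANK_TOL * s[0]:
            dropped.append(name)
        else:
            kept.append(name)
    return X[kept], dropped


def fit_ols(spec: DesignSpec, table: StudyTable) -> RegressionResult:
    """Unweighted OLS fit of the specified model with rank-safe design."""
    y = _response_vector(spec, table)
    X_full = _design_matrix(spec, table)
    X, dropped = _drop_collinear(X_full)
    if len(table) <= X.shape[1]:
        raise InsufficientDataError(
            f"n={len(table)} observations cannot estimate {X.shape[1]} terms"
        )
    fit = sm.OLS(y, X).fit()
    coefs = [
        CoefficientRow(term, float(fit.params[term]), float(fit.bse[term]),
                       float(fit.tvalues[term]), float(fit.pvalues[term]))
        for term in X.columns
    ]
    return RegressionResult(
        coefficients=coefs,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=len(table),
        residuals=np.asarray(fit.resid),
        dropped_terms=dropped,
        design=X,
        y=y,
    )


def trend_slope(y: Sequence[float], years: Sequence[int]) -> tuple[float, float]:
    """Simple OLS slope of y on calendar year with its two-sided p-value."""
    y = np.asarray(y, dtype=float)
    years = np.asarray(years, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError("trend regression needs at least 3 points")
    if len(np.unique(years)) < 2:
        raise InsufficientDataError("all years identical: slope is not estimable")
    res = stats.linregress(years, y)
    return float(res.slope), float(res.pvalue)


def partial_regression(result: RegressionResult, covariate: str) -> tuple[np.ndarray, np.ndarray]:
    """Added-variable data for one fitted covariate.

    Returns ``(e_y, e_x)``: residuals of the response and of the covariate,
    each regressed on all *other* fitted terms.  The OLS slope of e_y on
    e_x equals the covariate's full-model coefficient.
    """
    if covariate in result.dropped_terms:
        raise DroppedTermError(
            f"{covariate!r} was dropped for perfect collinearity; no partial data"
        )
    if covariate not in result.design.columns:
        raise KeyError(covariate)
    others = result.design.drop(columns=[covariate])
    x = result.design[covariate].to_numpy()
    Z = others.to_numpy()
    beta_y, *_ = np.linalg.lstsq(Z, result.y, rcond=None)
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    return result.y - Z @ beta_y, x - Z @ beta_x
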