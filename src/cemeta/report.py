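"""Pipeline orchestration: load → harmonize → metrics → descriptives →
pooling → meta-regression → bias/sensitivity, with machine-readable output.

Every emitted number is produced by exactly one library operation; this
module only arranges results into CSV/JSON files.  A ``manifest.json``
records every convention in force (cost basis, SE imputation, quantile
rule, τ² estimator, thresholds source, target price year), which together
with the input fully determines the bundle: replaying a manifest
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import bias as _bias
from . import descriptives as _desc
from . import harmonize as _harm
from . import metareg as _mreg
from . import metrics as _metrics
from . import pooling as _pool
from .records import StudyTable, load_records, validate_table, write_records

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError"]

log = logging.getLogger("cemeta")


class ConfigError(ValueError):
    """Invalid pipeline configuration (caught before any computation)."""


@dataclass
class PipelineConfig:
    input: str = "fixture:mastaleru2025"
    out_dir: str | Path = "cemeta_report"
    wtp_list: tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0)
    basis: str = "incremental"
    se_convention: str = "constant_cv:0.2"
    price_year: int = 2024
    thresholds_path: Optional[str] = None      # None -> packaged defaults
    cpi_path: Optional[str] = None
    ppp_path: Optional[str] = None
    consistency_tol: float = 0.01
    tau2_method: str = "dl"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.wtp_list:
            raise ConfigError("wtp_list must be non-empty")
        if any(l <= 0 for l in self.wtp_list):
            raise ConfigError("all WTP thresholds must be positive")
        if self.basis not in ("incremental", "total"):
            raise ConfigError(f"unknown cost basis {self.basis!r}")
        if self.tau2_method not in ("dl", "reml"):
            raise ConfigError(f"unknown tau2 method {self.tau2_method!r}")
        conv, _, _ = self.se_convention.partition(":")
        if conv not in ("constant_cv", "fixed_se", "user_column"):
            raise ConfigError(f"unknown SE convention {self.se_convention!r}")


def _parse_convention(spec: str) -> tuple[str, float]:
    conv, _, param = spec.partition(":")
    return conv, float(param) if param else 0.2


def _stats_row(name: str, s: _desc.SummaryStats) -> dict:
    return {
        "quantity": name, "n": s.n, "mean": s.mean, "sd": s.sd, "se": s.se,
        "ci95_low": s.ci95_low, "ci95_high": s.ci95_high, "min": s.min,
        "q25": s.q25, "median": s.median, "q75": s.q75, "max": s.max,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle; returns the manifest."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        table = load_records(config.input)
        log.info("load: %d records from %s", len(table), config.input)

        stage = "harmonize"
        if config.cpi_path and config.ppp_path:
            cpi = _harm.load_cpi(config.cpi_path)
            ppp = _harm.load_ppp(config.ppp_path)
            table = _harm.harmonize_table(table, cpi, ppp, config.price_year)
            log.info("harmonize: converted to PPP-USD at %d prices", config.price_year)
        else:
            log.info("harmonize: no CPI/PPP tables supplied; records pass through "
                     "(already %s)", {r.currency_code for r in table})
        write_records(table, out / "harmonized_data.csv")

        stage = "validate"
        flags = validate_table(table, tol=config.consistency_tol)
        pd.DataFrame([vars(f) for f in flags]).to_csv(
            out / "consistency_flags.csv", index=False)
        log.info("validate: %d consistency flags at tol=%g", len(flags),
                 config.consistency_tol)

        stage = "descriptives"
        for key in ("intervention", "country", "age_group"):
            rows = []
            for g in _desc.group_summary(table, key, config.wtp_list, config.basis):
                row = {"group": g.group, "n": g.n,
                       "qaly_gain_mean": g.qaly_gain.mean, "qaly_gain_sd": g.qaly_gain.sd,
                       "incremental_cost_mean": g.incremental_cost.mean,
                       "incremental_cost_sd": g.incremental_cost.sd}
                for lam, s in g.nmb.items():
                    row[f"nmb_mean_{int(lam)}"] = s.mean
                rows.append(row)
            pd.DataFrame(rows).to_csv(out / f"subgroup_{key}.csv", index=False)

        summary_rows = [
            _stats_row("qaly_gain", _desc.summarize(table.column("qaly_gain"))),
            _stats_row("incremental_cost",
                       _desc.summarize(table.column("incremental_cost"))),
            _stats_row("icer_per_qaly", _desc.summarize(table.column("icer_per_qaly"))),
        ]
        pd.DataFrame(summary_rows).to_csv(out / "incremental_summary.csv", index=False)

        icer_stats = _desc.summarize(table.column("icer_per_qaly"))
        pd.DataFrame([
            {"statistic": "min", "value": icer_stats.min},
            {"statistic": "q25", "value": icer_stats.q25},
            {"statistic": "median", "value": icer_stats.median},
            {"statistic": "mean", "value": icer_stats.mean},
            {"statistic": "q75", "value": icer_stats.q75},
            {"statistic": "max", "value": icer_stats.max},
            {"statistic": "sd", "value": icer_stats.sd},
        ]).to_csv(out / "icer_distribution.csv", index=False)

        stage = "nmb"
        nmb_rows = []
        for basis in ("incremental", "total"):
            for lam in config.wtp_list:
                s = _desc.nmb_summary(table, lam, basis)
                nmb_rows.append({"basis": basis, "lambda": lam, **_stats_row("nmb", s)})
        pd.DataFrame(nmb_rows).to_csv(out / "nmb_summary.csv", index=False)

        cls_rows = []
        for lam in config.wtp_list:
            for criterion in ("nmb_positive", "icer_below_lambda"):
                _, count = _metrics.classify(table, lam, criterion, config.basis)
                cls_rows.append({"lambda": lam, "criterion": criterion,
                                 "basis": config.basis, "n_cost_effective": count,
                                 "n_total": len(table)})
        pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)

        stage = "affordability"
        thresholds = _metrics.load_thresholds(config.thresholds_path)
        aff = _metrics.affordability(table, thresholds, basis=config.basis)
        pd.DataFrame([
            {"country": a.country, "mean_icer": a.mean_icer,
             "threshold": a.threshold.lam if a.threshold else None,
             "mean_nmb": a.mean_nmb, "n_studies": a.n_studies,
             "n_cost_effective": a.n_cost_effective, "verdict": a.verdict}
            for a in aff
        ]).to_csv(out / "affordability.csv", index=False)

        stage = "pooling"
        conv, param = _parse_convention(config.se_convention)
        pooled_rows = []
        for quantity in ("qaly_gain", "incremental_cost"):
            inputs = _pool.impute_se(table, quantity, conv, param)
            est = _pool.random_effects_dl(inputs, config.tau2_method,
                                          se_convention=config.se_convention)
            pooled_rows.append({"quantity": quantity, **_pooled_row(est)})
        icers = table.column("icer_per_qaly")
        log_est = _pool.pool_log_icer(
            icers, [param] * len(icers), table.column("study_id"),
            config.tau2_method, se_convention=config.se_convention)
        pooled_rows.append({"quantity": "log_icer", **_pooled_row(log_est)})
        pd.DataFrame(pooled_rows).to_csv(out / "pooled_estimates.csv", index=False)

        stage = "metareg"
        trend_rows = []
        years = table.column("pub_year")
        for response in ("icer_per_qaly", "qaly_gain"):
            slope, p = _mreg.trend_slope(table.column(response), years)
            trend_rows.append({"response": response, "slope_per_year": slope, "p": p})
        pd.DataFrame(trend_rows).to_csv(out / "trend_regressions.csv", index=False)

        mreg_rows = []
        for lam in config.wtp_list:
            spec = _mreg.DesignSpec(response="nmb", lam=lam, basis=config.basis)
            res = _mreg.fit_ols(spec, table)
            for c in res.coefficients:
                mreg_rows.append({"lambda": lam, "term": c.term, "estimate": c.estimate,
                                  "se": c.se, "t": c.t, "p": c.p,
                                  "adj_r2": res.adj_r2, "dropped": ""})
            for term in res.dropped_terms:
                mreg_rows.append({"lambda": lam, "term": term, "estimate": None,
                                  "se": None, "t": None, "p": None,
                                  "adj_r2": res.adj_r2, "dropped": "collinear"})
        pd.DataFrame(mreg_rows).to_csv(out / "metareg_nmb.csv", index=False)

        stage = "bias_sensitivity"
        loo = _bias.leave_one_out(table.column("icer_per_qaly"), "mean",
                                  table.column("study_id"))
        pd.DataFrame(loo.rows, columns=["excluded_study_id", "loo_mean_icer"]).to_csv(
            out / "leave_one_out_icer.csv", index=False)

        egger_rows = []
        for quantity in ("icer_per_qaly", "qaly_gain"):
            inputs = _pool.impute_se(table, quantity, conv, param)
            e = _bias.egger_test(inputs)
            egger_rows.append({"quantity": quantity, "intercept": e.intercept,
                               "se_intercept": e.se_intercept, "t": e.t, "p": e.p,
                               "slope": e.slope, "k": e.k,
                               "se_convention": config.se_convention})
        pd.DataFrame(egger_rows).to_csv(out / "egger.csv", index=False)

    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "input": str(config.input),
        "n_records": len(table),
        "wtp_list": list(config.wtp_list),
        "cost_basis": config.basis,
        "se_convention": config.se_convention,
        "quantile_rule": "linear:(n-1)p",
        "sd_denominator": "n-1",
        "tau2_estimator": config.tau2_method,
        "price_year": config.price_year,
        "thresholds": config.thresholds_path or "packaged:wtp_thresholds.csv",
        "consistency_tol": config.consistency_tol,
        "n_consistency_flags": len(flags),
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("report bundle written to %s", out)
    return manifest


def _pooled_row(est: _pool.PooledEstimate) -> dict:
    row = {
        "method": est.method, "k": est.k, "pooled": est.pooled,
        "se_pooled": est.se_pooled, "ci95_low": est.ci95_low,
        "ci95_high": est.ci95_high, "Q": est.Q, "i2": est.i2, "tau2": est.tau2,
        "scale": est.scale, "se_convention": est.se_convention,
    }
    if est.back_transformed:
        row["back_pooled"], row["back_ci_low"], row["back_ci_high"] = est.back_transformed
    return row
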