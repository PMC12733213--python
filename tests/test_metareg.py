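import numpy as np
import pytest

from cemeta.metareg import (
    DesignSpec,
    DroppedTermError,
    InsufficientDataError,
    fit_ols,
    partial_regression,
    trend_slope,
)
from cemeta.records import StudyRecord, StudyTable
from cemeta.synth import SyntheticConfig, generate


def _table(rows):
    recs = []
    for i, row in enumerate(rows):
        base = dict(
            study_id=f"T{i:02d}", authors_label="x", pub_year=2024,
            country="Australia", intervention="Inclisiran", population_tag="x",
            age_group="unknown", model_type="markov", qaly_gain=0.5,
            total_qaly=10.0, total_cost=30_000.0, incremental_cost=10_000.0,
            icer_per_qaly=20_000.0)
        base.update(row)
        recs.append(StudyRecord(**base))
    return StudyTable(recs)


class TestFitOls:
    def test_exact_linear_data(self):
        # qaly_gain = 2·(year-2020) + 1 exactly -> perfect fit
        t = _table([{"pub_year": 2020 + i, "qaly_gain": 2.0 * i + 1.0}
                    for i in range(6)])
        res = fit_ols(DesignSpec(response="qaly_gain", covariates=("year",)), t)
        assert res.coef("year").estimate == pytest.approx(2.0)
        assert res.coef("const").estimate == pytest.approx(1.0 - 2.0 * 2020)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        t, _ = generate(SyntheticConfig(k_studies=25, seed=3))
        spec = DesignSpec(response="nmb", lam=50_000, basis="incremental",
                          reference_levels={"country": "Singapore",
                                            "intervention": "Inclisiran"})
        res = fit_ols(spec, t)
        X = res.design.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ res.y)
        for b, c in zip(beta, res.coefficients):
            assert c.estimate == pytest.approx(b, rel=1e-8, abs=1e-8)

    def test_fixture_sign_pattern_at_50k_total_basis(self, table):
        res = fit_ols(DesignSpec(response="nmb", lam=50_000, basis="total"), table)
        assert res.coef("country[China]").estimate > 0
        assert res.coef("country[Singapore]").estimate > 0
        assert res.coef("year").estimate < 0
        assert res.coef("country[UK]").estimate < 0
        assert res.adj_r2 <= res.r2

    def test_residuals_sum_to_zero_with_intercept(self, table):
        res = fit_ols(DesignSpec(response="nmb", lam=100_000, basis="total"), table)
        scale = float(np.max(np.abs(res.y)))
        assert float(np.sum(res.residuals)) / scale == pytest.approx(0.0, abs=1e-10)

    def test_collinear_term_dropped_last_entered_first(self):
        # every China row is Inclisiran+statin and vice versa, so the
        # intervention dummy duplicates the country dummy; intervention
        # enters after country and must be the one dropped
        rows = []
        for i in range(8):
            country = "China" if i % 2 else "Australia"
            interv = "Inclisiran+statin" if i % 2 else "Inclisiran"
            rows.append({"country": country, "intervention": interv,
                         "pub_year": 2020 + i % 3, "qaly_gain": 0.1 + 0.05 * i})
        res = fit_ols(DesignSpec(response="qaly_gain"), _table(rows))
        assert res.dropped_terms == ["intervention[Inclisiran+statin]"]
        assert all(c.term != "intervention[Inclisiran+statin]"
                   for c in res.coefficients)

    def test_insufficient_data(self):
        t = _table([{"country": c, "pub_year": 2020 + i}
                    for i, c in enumerate(["Australia", "China", "USA"])])
        with pytest.raises(InsufficientDataError):
            fit_ols(DesignSpec(response="qaly_gain"), t)

    def test_missing_reference_level_rejected(self):
        t = _table([{"country": "China", "pub_year": 2020 + i} for i in range(5)])
        with pytest.raises(ValueError, match="Australia"):
            fit_ols(DesignSpec(response="qaly_gain", covariates=("country",)), t)

    def test_nmb_response_requires_lambda(self):
        with pytest.raises(ValueError):
            DesignSpec(response="nmb", lam=None)


class TestTrendSlope:
    def test_fixture_icer_trend(self, table):
        slope, p = trend_slope(table.column("icer_per_qaly"), table.column("pub_year"))
        assert slope == pytest.approx(-170_748.43, abs=0.01)
        assert p == pytest.approx(0.56, abs=0.005)

    def test_fixture_qaly_trend(self, table):
        slope, p = trend_slope(table.column("qaly_gain"), table.column("pub_year"))
        assert slope == pytest.approx(0.035, abs=5e-4)
        assert p == pytest.approx(0.45, abs=0.005)

    def test_constant_response_has_zero_slope(self):
        slope, _ = trend_slope([3.0, 3.0, 3.0, 3.0], [2020, 2021, 2022, 2023])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(InsufficientDataError):
            trend_slope([1.0, 2.0], [2020, 2021])
        with pytest.raises(InsufficientDataError):
            trend_slope([1.0, 2.0, 3.0], [2020, 2020, 2020])


class TestPartialRegression:
    def test_frisch_waugh_identity_on_every_covariate(self, table):
        res = fit_ols(DesignSpec(response="nmb", lam=50_000, basis="total"), table)
        for c in res.coefficients:
            if c.term == "const":
                continue
            e_y, e_x = partial_regression(res, c.term)
            slope = float(e_x @ e_y / (e_x @ e_x))
            assert slope == pytest.approx(c.estimate, rel=1e-8, abs=1e-6)

    def test_single_covariate_model_gives_centered_data(self):
        t = _table([{"pub_year": 2020 + i, "qaly_gain": 0.1 * i + 0.2}
                    for i in range(5)])
        res = fit_ols(DesignSpec(response="qaly_gain", covariates=("year",)), t)
        e_y, e_x = partial_regression(res, "year")
        years = np.array([2020 + i for i in range(5)], dtype=float)
        assert e_x == pytest.approx(years - years.mean())

    def test_dropped_term_raises(self):
        rows = []
        for i in range(8):
            country = "China" if i % 2 else "Australia"
            interv = "Inclisiran+statin" if i % 2 else "Inclisiran"
            rows.append({"country": country, "intervention": interv,
                         "pub_year": 2020 + i % 3, "qaly_gain": 0.1 + 0.05 * i})
        res = fit_ols(DesignSpec(response="qaly_gain"), _table(rows))
        with pytest.raises(DroppedTermError):
            partial_regression(res, "intervention[Inclisiran+statin]")


def test_coefficient_recovery_with_known_year_effect():
    """Generating NMB with a known year effect, the fitted year coefficient
    is unbiased and its CI covers the truth at close to nominal rate."""
    from scipy.stats import linregress

    cover = 0
    n_rep = 100
    for rep in range(n_rep):
        cfg = SyntheticConfig(k_studies=60, seed=20_000 + rep,
                              year_effect_on_nmb=-2_000.0, cost_sigma_log=0.3)
        t, _ = generate(cfg)
        from cemeta.metrics import nmb

        y = [nmb(r, 50_000, "incremental").nmb for r in t]
        fit = linregress([r.pub_year for r in t], y)
        if fit.slope - 1.96 * fit.stderr <= -2_000.0 <= fit.slope + 1.96 * fit.stderr:
            cover += 1
    assert 0.88 <= cover / n_rep <= 1.0
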