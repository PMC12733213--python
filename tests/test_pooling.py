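import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cemeta.pooling import (
    EffectInput,
    InsufficientStudiesError,
    fixed_effect,
    impute_se,
    pool_log_icer,
    random_effects_dl,
)
from cemeta.synth import SyntheticConfig, effective_effect_moments, generate


def _inputs(pairs):
    return [EffectInput(f"s{i}", y, se) for i, (y, se) in enumerate(pairs)]


def dl_oracle(y, se):
    """Literal textbook DerSimonian-Laird computation, kept independent of
    the library implementation."""
    y, se = np.asarray(y, float), np.asarray(se, float)
    w = 1 / se**2
    mu_fe = (w * y).sum() / w.sum()
    Q = (w * (y - mu_fe) ** 2).sum()
    df = len(y) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / c)
    ws = 1 / (se**2 + tau2)
    mu = (ws * y).sum() / ws.sum()
    return mu, math.sqrt(1 / ws.sum()), tau2, Q


class TestFixedEffect:
    def test_two_study_hand_example(self):
        est = fixed_effect(_inputs([(1.0, 1.0), (3.0, 1.0)]))
        assert est.pooled == pytest.approx(2.0)
        assert est.Q == pytest.approx(2.0)
        assert est.se_pooled == pytest.approx(math.sqrt(0.5))

    def test_identical_estimates_are_homogeneous(self):
        est = fixed_effect(_inputs([(5.0, 0.3)] * 4))
        assert est.pooled == 5.0
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        assert est.i2 == 0.0

    def test_uniform_weight_rescaling_leaves_pooled_unchanged(self):
        base = _inputs([(1.0, 0.5), (2.0, 1.0), (4.0, 2.0)])
        doubled = [EffectInput(i.study_id, i.estimate, i.se * 2) for i in base]
        assert fixed_effect(base).pooled == pytest.approx(
            fixed_effect(doubled).pooled, rel=1e-14)

    def test_single_study_rejected(self):
        with pytest.raises(InsufficientStudiesError):
            fixed_effect(_inputs([(1.0, 1.0)]))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            EffectInput("s", 1.0, 0.0)

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            fixed_effect([EffectInput("a", 1.0, 1.0, "identity"),
                          EffectInput("b", 1.0, 1.0, "log")])


class TestRandomEffectsDL:
    def test_degenerates_to_fixed_effect_when_homogeneous(self):
        inputs = _inputs([(2.0, 0.4)] * 3)
        fe, re = fixed_effect(inputs), random_effects_dl(inputs)
        assert re.tau2 == 0.0
        assert re.pooled == fe.pooled
        assert re.se_pooled == pytest.approx(fe.se_pooled)

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.1, 2.0)),
                    min_size=2, max_size=6))
    def test_matches_textbook_oracle_on_small_instances(self, pairs):
        est = random_effects_dl(_inputs(pairs))
        mu, se_p, tau2, Q = dl_oracle([p[0] for p in pairs], [p[1] for p in pairs])
        assert est.pooled == pytest.approx(mu, rel=1e-10, abs=1e-12)
        assert est.se_pooled == pytest.approx(se_p, rel=1e-10)
        assert est.tau2 == pytest.approx(tau2, rel=1e-10, abs=1e-14)
        assert est.Q == pytest.approx(Q, rel=1e-10, abs=1e-12)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects

        y = [0.3, 0.1, 0.55, 0.2, 0.42]
        v = [0.01, 0.04, 0.0225, 0.0081, 0.0144]
        res = combine_effects(np.array(y), np.array(v), method_re="dl")
        est = random_effects_dl(_inputs(list(zip(y, np.sqrt(v)))))
        frame = res.summary_frame()
        assert est.pooled == pytest.approx(frame.loc["random effect", "eff"], rel=1e-10)
        assert est.tau2 == pytest.approx(res.tau2, rel=1e-10)

    def test_i2_zero_when_q_below_df(self):
        est = random_effects_dl(_inputs([(1.0, 10.0), (1.1, 10.0), (0.9, 10.0)]))
        assert est.Q <= est.df
        assert est.i2 == 0.0
        assert est.tau2 == 0.0

    def test_re_ci_never_narrower_than_fe(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pairs = list(zip(rng.normal(0, 2, 5), rng.uniform(0.1, 1.0, 5)))
            inputs = _inputs(pairs)
            fe, re = fixed_effect(inputs), random_effects_dl(inputs)
            assert (re.ci95_high - re.ci95_low) >= (fe.ci95_high - fe.ci95_low) - 1e-12

    def test_reml_option_runs_and_agrees_in_homogeneous_case(self):
        inputs = _inputs([(2.0, 0.4)] * 4)
        est = random_effects_dl(inputs, tau2_method="reml")
        assert est.method == "RE_REML"
        assert est.tau2 == pytest.approx(0.0, abs=1e-9)
        assert est.pooled == pytest.approx(2.0)

    def test_tau2_recovery_on_large_synthetic_meta_analysis(self):
        cfg = SyntheticConfig(k_studies=200, tau_qaly=0.22, seed=7)
        table, truth = generate(cfg)
        est = random_effects_dl(impute_se(table, "qaly_gain", "user_column"))
        _, tau2_true = effective_effect_moments(cfg)
        # MC error of a variance estimate at k=200 is ~ tau2*sqrt(2/k) ~ 10%
        assert est.tau2 == pytest.approx(tau2_true, rel=0.25)


class TestLogIcerPooling:
    def test_constant_input_back_transforms_to_the_constant(self):
        est = pool_log_icer([50_000.0] * 4, [0.2] * 4)
        assert est.scale == "log"
        assert est.back_transformed[0] == pytest.approx(50_000.0)

    def test_back_transform_preserves_order(self, table):
        icers = table.column("icer_per_qaly")
        est = pool_log_icer(icers, [0.2] * len(icers), table.column("study_id"))
        mid, lo, hi = est.back_transformed
        assert lo < mid < hi

    def test_geometric_mean_recovery_with_zero_heterogeneity(self):
        rng = np.random.default_rng(11)
        true_gm = 120_000.0
        icers = np.exp(np.log(true_gm) + 0.3 * rng.standard_normal(400))
        est = pool_log_icer(icers.tolist(), [0.3] * 400)
        assert est.back_transformed[0] == pytest.approx(true_gm, rel=0.05)

    def test_nonpositive_icer_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            est = pool_log_icer([100.0, -5.0, 200.0, 150.0], [0.2] * 4)
        assert est.k == 3

    def test_point_and_ci_invariant_to_constant_se(self, table):
        # with equal log-scale SEs the DL weights are equal, so the pooled
        # log is the mean log and se_pooled^2 collapses to S^2/k: the
        # back-transformed point estimate and CI do not depend on the SE
        icers = table.column("icer_per_qaly")
        a = pool_log_icer(icers, [0.2] * 17, table.column("study_id"))
        b = pool_log_icer(icers, [1.0] * 17, table.column("study_id"))
        assert a.back_transformed == pytest.approx(b.back_transformed, rel=1e-10)

    def test_fixture_reproduces_published_log_pooled_icer(self, table):
        # geometric-mean-type summary of the 17 ICERs; under a unit
        # log-scale SE the heterogeneity statistics reproduce too
        icers = table.column("icer_per_qaly")
        est = pool_log_icer(icers, [1.0] * 17, table.column("study_id"))
        mid, lo, hi = est.back_transformed
        assert mid == pytest.approx(211_596, abs=1)
        assert lo == pytest.approx(87_783, abs=1)
        assert hi == pytest.approx(510_043, abs=1)
        assert est.tau2 == pytest.approx(2.43, abs=0.01)
        assert est.i2 == pytest.approx(70.8, abs=0.05)


class TestImputeSe:
    def test_fixed_se(self, table):
        inputs = impute_se(table, "qaly_gain", "fixed_se", 1.0)
        assert all(i.se == 1.0 for i in inputs)

    def test_constant_cv(self, table):
        inputs = impute_se(table, "qaly_gain", "constant_cv", 0.2)
        by_id = {i.study_id: i for i in inputs}
        assert by_id["S07"].se == pytest.approx(0.2 * 0.374)

    def test_constant_cv_forced_product(self):
        from cemeta.records import StudyRecord, StudyTable

        rec = StudyRecord(
            study_id="T", authors_label="x", pub_year=2024, country="USA",
            intervention="Inclisiran", population_tag="x", age_group="unknown",
            model_type="markov", qaly_gain=0.5, total_qaly=10.0,
            total_cost=1000.0, incremental_cost=500.0, icer_per_qaly=1000.0)
        rec2 = StudyRecord(**{**rec.__dict__, "study_id": "T2", "provenance": {}})
        inputs = impute_se(StudyTable([rec, rec2]), "qaly_gain", "constant_cv", 0.2)
        assert inputs[0].se == pytest.approx(0.1)

    def test_user_column_missing_raises(self, table):
        with pytest.raises(ValueError, match="user_column"):
            impute_se(table, "qaly_gain", "user_column")

    def test_fixed_se_pooling_equals_unweighted_mean(self, table):
        inputs = impute_se(table, "incremental_cost", "fixed_se", 1_000.0)
        est = fixed_effect(inputs)
        assert est.pooled == pytest.approx(
            np.mean(table.column("incremental_cost")), rel=1e-12)

    def test_nmb_quantity_uses_threshold_and_basis(self, table):
        inputs = impute_se(table, "nmb", "fixed_se", 1.0, lam=50_000,
                           basis="incremental")
        by_id = {i.study_id: i for i in inputs}
        assert by_id["S07"].estimate == pytest.approx(50_000 * 0.374 - 8739.16)

    def test_invalid_param_rejected(self, table):
        with pytest.raises(ValueError):
            impute_se(table, "qaly_gain", "constant_cv", -0.5)
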