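import math

import numpy as np
import pandas as pd
import pytest

from lipidsphere import (
    GeneratorConfig,
    LipidPanel,
    LogisticModel,
    Sex,
    attach_standardization,
    compose_indices,
    default_models,
    fit_logistic,
    fit_standardization,
    generate_cohort,
    logit_shift,
    models_from_file,
    models_to_file,
    risk_enhancer_flags,
    score_cohort,
    score_l1,
    score_logistic,
    simulate_outcomes,
)
from lipidsphere.spherical import StandardizationParams
from lipidsphere.errors import (
    ConvergenceError,
    DomainError,
    FitError,
    SchemaError,
    UnitError,
)


def sigma(eta):
    return 1.0 / (1.0 + math.exp(-eta))


# Hand-evaluated linear predictors for the published coefficient sets at
# the octant centre (subject at the feature means): independent oracle.
R_MEAN = math.sqrt(75.0)
THETA_MEAN = math.degrees(math.acos(1.0 / math.sqrt(3.0)))
PHI_MEAN = 45.0
L1_MEAN = sigma(-2.371 + 0.3550 * R_MEAN - 0.0107 * THETA_MEAN - 0.0268 * PHI_MEAN)
L2_MALE = sigma(-1.383 + 3.783 * L1_MEAN - 0.3693)
L2_FEMALE = sigma(-1.383 + 3.783 * L1_MEAN - 0.9089)
L3_MALE_55 = sigma(-4.756 + 3.718 * L1_MEAN + 0.0504 * 55 + 0.2615)


class TestScoreLogistic:
    def test_all_zero_coefficients_give_half(self):
        m = LogisticModel("z", 0.0, (("a", 0.0), ("b", 0.0)))
        assert score_logistic(m, {"a": 123.0, "b": -9.0}) == 0.5

    def test_published_l1_at_octant_centre(self):
        m = default_models()["L1"]
        p = score_logistic(m, {"r": R_MEAN, "theta": THETA_MEAN, "phi": PHI_MEAN})
        assert p == pytest.approx(L1_MEAN, rel=1e-12)
        assert p == pytest.approx(0.2519, abs=1e-4)

    def test_published_l3_chained(self):
        m = default_models()["L3"]
        p = score_logistic(m, {"L1": L1_MEAN, "age": 55, "female": 0, "male": 1})
        assert p == pytest.approx(L3_MALE_55, rel=1e-12)
        assert p == pytest.approx(0.3131, abs=1e-4)

    def test_missing_feature_is_schema_error(self):
        m = default_models()["L1"]
        with pytest.raises(SchemaError, match="phi"):
            score_logistic(m, {"r": 8.0, "theta": 50.0})

    def test_angle_unit_mismatch(self):
        m = default_models()["L1"]
        with pytest.raises(UnitError):
            score_logistic(
                m, {"r": 8.0, "theta": 0.95, "phi": 0.78}, angle_unit="radians"
            )

    def test_monotone_in_positive_coefficient(self):
        m = default_models()["L1"]
        lo = score_logistic(m, {"r": 7.0, "theta": 55.0, "phi": 45.0})
        hi = score_logistic(m, {"r": 9.0, "theta": 55.0, "phi": 45.0})
        assert hi > lo  # B_r = 0.3550 > 0


class TestComposeIndices:
    def test_mean_subject_male(self, bundled_models, mean_subject):
        res = compose_indices(mean_subject, bundled_models)
        assert res.l1 == pytest.approx(L1_MEAN, abs=1e-6)
        assert res.l2 == pytest.approx(L2_MALE, abs=1e-6)
        assert res.l3 == pytest.approx(L3_MALE_55, abs=1e-6)
        assert res.li3 == pytest.approx(100 * res.l3)

    def test_mean_subject_female(self, bundled_models, mean_subject):
        panel = LipidPanel(
            "f", tc=mean_subject.tc, hdlc=mean_subject.hdlc, tg=mean_subject.tg,
            age=55.0, sex=Sex.FEMALE,
        )
        res = compose_indices(panel, bundled_models)
        assert res.l2 == pytest.approx(L2_FEMALE, abs=1e-6)

    def test_degenerate_all_minimum_subject(self):
        # standardization placed so z = (-5,-5,-5) is a physiological panel:
        # shifted point is the origin, angles are undefined, L1 = sigma(B0)
        params = StandardizationParams(
            mean_inv_h=0.02, sd_inv_h=0.002,
            mean_ln_tg=4.7, sd_ln_tg=0.5,
            mean_nhdlc=150.0, sd_nhdlc=20.0,
        )
        models = attach_standardization(default_models(), params)
        panel = LipidPanel(
            "min", tc=150.0, hdlc=100.0, tg=float(math.exp(2.2)),
            age=55.0, sex=Sex.MALE,
        )
        res = compose_indices(panel, models)
        assert res.degenerate
        assert res.l1 == pytest.approx(sigma(-2.371), abs=1e-9)
        assert res.l1 == pytest.approx(0.0854, abs=1e-4)

    def test_missing_sex_is_schema_error_but_l1_scores(self, bundled_models):
        panel = LipidPanel("ns", tc=197.0, hdlc=51.0, tg=107.0, age=55.0)
        with pytest.raises(SchemaError):
            compose_indices(panel, bundled_models)
        assert 0 < score_l1(panel, bundled_models["L1"]) < 1

    def test_missing_standardization_refused(self, mean_subject):
        with pytest.raises(SchemaError, match="standardization"):
            compose_indices(mean_subject, default_models())

    def test_probabilities_in_open_unit_interval(self, synthetic_cohort):
        cohort, models = synthetic_cohort
        scored = score_cohort(cohort, models)
        for col in ("L1", "L2", "L3"):
            assert ((scored[col] > 0) & (scored[col] < 1)).all()
            assert ((scored["LI" + col[1]] > 0) & (scored["LI" + col[1]] < 100)).all()

    def test_score_cohort_matches_compose_indices(self, synthetic_cohort):
        cohort, models = synthetic_cohort
        scored = score_cohort(cohort, models)
        for i in [0, 17, 123]:
            res = compose_indices(cohort.records[i], models)
            row = scored.iloc[i]
            assert row["L1"] == pytest.approx(res.l1, rel=1e-12)
            assert row["L3"] == pytest.approx(res.l3, rel=1e-12)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        m = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert m.intercept == pytest.approx(math.log(0.3 / 0.7), abs=1e-9)
        assert m.training_prevalence == pytest.approx(0.3)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        with pytest.raises(FitError):
            fit_logistic(X, np.ones(20))

    def test_separated_data_without_ridge_raises_convergence_error(self):
        X = pd.DataFrame({"x": np.concatenate([np.arange(10.0), 10 + np.arange(10.0)])})
        y = np.array([0] * 10 + [1] * 10)
        with pytest.raises(ConvergenceError):
            fit_logistic(X, y, ridge=0.0)
        # a small ridge resolves it
        m = fit_logistic(X, y, ridge=1e-2)
        assert dict(m.coefficients)["x"] > 0

    def test_parameter_recovery_moderate_scale(self):
        rng = np.random.default_rng(21)
        n = 20000
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        truth = {"a": 0.8, "b": -0.5}
        eta = -1.0 + X["a"] * truth["a"] + X["b"] * truth["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(X, y)
        assert m.intercept == pytest.approx(-1.0, abs=0.08)
        for k, v in truth.items():
            assert dict(m.coefficients)[k] == pytest.approx(v, abs=0.08)

    def test_collinear_sex_indicators_fit_with_default_ridge(self):
        rng = np.random.default_rng(4)
        n = 2000
        female = (rng.random(n) < 0.5).astype(float)
        X = pd.DataFrame({"female": female, "male": 1 - female})
        eta = -1.0 - 0.5 * female
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(X, y)  # would be singular without regularisation
        coefs = dict(m.coefficients)
        # the identified contrast female-male is recovered
        assert coefs["female"] - coefs["male"] == pytest.approx(-0.5, abs=0.15)

    def test_wald_coverage_three_se(self):
        # ~99.7% of estimates should fall within 3 SE of truth; demand >= 95%
        rng = np.random.default_rng(8)
        truth = np.array([-1.0, 0.8, -0.5])
        hits = np.zeros(3)
        reps = 200
        for _ in range(reps):
            n = 2000
            X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
            eta = truth[0] + truth[1] * X["a"] + truth[2] * X["b"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            m = fit_logistic(X, y)
            est = np.array([m.intercept, *[b for _, b in m.coefficients]])
            ses = np.array([s for _, s in m.standard_errors])
            hits += (np.abs(est - truth) <= 3 * ses).astype(int)
        assert np.all(hits / reps >= 0.95)


class TestLogitShift:
    def test_identity_shift(self):
        m = default_models()["L1"]
        assert logit_shift(m, 0.3, 0.3).intercept == m.intercept

    def test_closed_form_delta(self):
        m = default_models()["L1"]
        shifted = logit_shift(m, 0.30, 0.10)
        delta = math.log(1 / 9) - math.log(3 / 7)
        assert shifted.intercept - m.intercept == pytest.approx(delta, abs=1e-12)
        assert shifted.intercept - m.intercept == pytest.approx(-1.3499, abs=1e-4)
        assert shifted.coefficients == m.coefficients

    def test_round_trip_restores_intercept_bitwise(self):
        m = default_models()["L3"]
        back = logit_shift(logit_shift(m, 0.30, 0.10), 0.10, 0.30)
        assert back.intercept == m.intercept

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_proportions_outside_unit_interval_rejected(self, bad):
        m = default_models()["L1"]
        with pytest.raises(DomainError):
            logit_shift(m, bad, 0.5)
        with pytest.raises(DomainError):
            logit_shift(m, 0.5, bad)


class TestRiskEnhancers:
    # tc=245/hdlc=50/tg=100 gives a Sampson LDL of ~177 (high);
    # tc=180/hdlc=50/tg=100 gives ~112 (unremarkable)
    HIGH_LDL = dict(tc=245.0, hdlc=50.0, tg=100.0)
    NORMAL_LDL = dict(tc=180.0, hdlc=50.0, tg=100.0)

    def test_high_ldl_only(self):
        panel = LipidPanel("e", apob=120.0, **self.HIGH_LDL)
        assert panel.ldlc >= 160  # sanity of the construction
        res = risk_enhancer_flags(panel, l3=0.2)
        assert res.flags == {"ldlc_high"}

    def test_l3_threshold_default(self):
        panel = LipidPanel("e", apob=100.0, **self.NORMAL_LDL)
        res = risk_enhancer_flags(panel, l3=0.40)
        assert res.flags == {"l3_high"}

    def test_all_below_thresholds_empty(self):
        panel = LipidPanel("e", apob=100.0, **self.NORMAL_LDL)
        res = risk_enhancer_flags(panel, l3=0.2)
        assert res.flags == frozenset()

    def test_missing_apob_noted_not_flagged(self):
        panel = LipidPanel("na", tc=220.0, hdlc=50.0, tg=200.0)
        res = risk_enhancer_flags(panel, l3=0.1)
        assert "apob" in res.missing and "apob_high" not in res.flags
        assert "tg_high" in res.flags  # 200 >= 175

    def test_inequalities_are_greater_equal(self):
        panel = LipidPanel("eq", tc=225.0, hdlc=50.0, tg=175.0, apob=130.0)
        res = risk_enhancer_flags(panel, l3=0.37)
        assert {"tg_high", "apob_high", "l3_high"} <= res.flags


class TestModelFileIO:
    def test_roundtrip_preserves_scoring(self, bundled_models, mean_subject, tmp_path):
        path = tmp_path / "models.txt"
        models_to_file(bundled_models, str(path))
        loaded = models_from_file(str(path))
        before = compose_indices(mean_subject, bundled_models)
        after = compose_indices(mean_subject, loaded)
        assert after.l3 == pytest.approx(before.l3, rel=1e-12)
        assert loaded["L1"].standardization == bundled_models["L1"].standardization

    def test_shift_survives_roundtrip(self, bundled_models, tmp_path):
        shifted = {k: logit_shift(m, 0.3, 0.1) for k, m in bundled_models.items()}
        path = tmp_path / "shifted.txt"
        models_to_file(shifted, str(path))
        loaded = models_from_file(str(path))
        back = logit_shift(loaded["L1"], 0.1, 0.3)
        assert back.intercept == pytest.approx(
            bundled_models["L1"].intercept, abs=1e-15
        )
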