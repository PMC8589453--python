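"""KDM1 and MLR: calibration recovery, the weighted-inversion estimator and
its oracle equivalences, and the regression-to-the-mean contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

import bioage as ba
from bioage.errors import FitError, PredictionError
from bioage.models import KDMModel, MLRModel
from conftest import make_cohort


def _model(panel, triples, gender="female"):
    return KDMModel(panel=tuple(panel),
                    params={gender: dict(zip(panel, triples))})


def _subjects(panel, values, ca=50.0, gender="female"):
    df = pd.DataFrame({name: [v] for name, v in zip(panel, values)})
    df.insert(0, "subject_id", ["s0"])
    df.insert(1, "ca", [ca])
    df.insert(2, "gender", [gender])
    return df


class TestFitKDM:
    def test_noise_free_training_recovers_generative_parameters(self):
        specs = tuple(ba.BiomarkerSpec(s.name, s.intercept, s.slope, 0.0)
                      for s in ba.kdm8_specs())
        cfg = ba.GenerativeConfig(n_subjects=60, biomarker_specs=specs,
                                  s_ba=0.0, seed=1)
        train = ba.generate_controls(cfg)
        model = ba.fit_kdm(train, [s.name for s in specs])
        for gender in model.params:
            for spec in specs:
                q, k, s = model.params[gender][spec.name]
                assert q == pytest.approx(spec.intercept, abs=1e-8)
                assert k == pytest.approx(spec.slope, abs=1e-10)
                assert s < 1e-10

    def test_noisy_training_within_three_standard_errors(self):
        train = ba.generate_controls(ba.GenerativeConfig(n_subjects=5000, seed=2))
        model = ba.fit_kdm(train, [s.name for s in ba.kdm8_specs()])
        for gender, stratum in train.groupby("gender"):
            n = len(stratum)
            var_ca = stratum["ca"].var(ddof=1)
            for spec in ba.kdm8_specs():
                q, k, s = model.params[str(gender)][spec.name]
                # sd of the biomarker around the CA regression line includes
                # the BA-noise leakage: s^2 ~ spec.s^2 + (k * s_ba)^2
                s_true = np.hypot(spec.noise_sd, spec.slope * 5.0)
                se_k = s_true / np.sqrt(var_ca * (n - 1))
                # 32 slope checks (8 markers x 2 genders x 2 seeds-worth):
                # a 4-SE band keeps the joint false-alarm rate negligible
                assert abs(k - spec.slope) < 4 * se_k
                assert abs(s - s_true) / s_true < 0.1

    def test_three_point_fixture_matches_normal_equations(self):
        ca = np.array([30.0, 50.0, 70.0])
        x = np.array([1.0, 2.2, 2.8])
        table = make_cohort({"m": x}, ca=ca)
        model = ba.fit_kdm(table, ["m"])
        q, k, s = model.params["female"]["m"]
        X = np.column_stack([np.ones(3), ca])
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        resid = x - X @ beta
        assert q == pytest.approx(beta[0], abs=1e-10)
        assert k == pytest.approx(beta[1], abs=1e-12)
        assert s == pytest.approx(np.sqrt(resid @ resid / 1), abs=1e-10)

    def test_constant_biomarker_named_in_error(self):
        table = make_cohort({"flat": np.ones(10)}, ca=np.linspace(20, 80, 10))
        with pytest.raises(FitError) as err:
            ba.fit_kdm(table, ["flat"])
        assert "flat" in str(err.value)


class TestPredictKDM:
    def test_single_biomarker_inverts_the_linear_law(self):
        model = _model(["m"], [(10.0, 0.5, 1.0)])
        subj = _subjects(["m"], [10.0 + 0.5 * 42.0], ca=42.0)
        ba_hat = ba.predict_kdm(model, subj)["ba"].iloc[0]
        assert ba_hat == pytest.approx(42.0, abs=1e-12)

    def test_equal_weights_average_standalone_ages(self):
        # two markers implying stand-alone ages 40 and 60, equal k/s
        model = _model(["a", "b"], [(0.0, 1.0, 2.0), (0.0, 1.0, 2.0)])
        subj = _subjects(["a", "b"], [40.0, 60.0])
        assert ba.predict_kdm(model, subj)["ba"].iloc[0] == pytest.approx(50.0)

    def test_hand_evaluated_weighted_sum(self):
        # q=(10,5), k=(0.5,-0.2), s=(1,2), x=(35,-6) -> 13.05/0.26
        model = _model(["a", "b"], [(10.0, 0.5, 1.0), (5.0, -0.2, 2.0)])
        subj = _subjects(["a", "b"], [35.0, -6.0])
        assert ba.predict_kdm(model, subj)["ba"].iloc[0] == pytest.approx(
            13.05 / 0.26, abs=1e-12
        )

    def test_matches_weighted_least_squares_minimiser(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = rng.integers(2, 9)
            q = rng.normal(0, 10, m)
            k = rng.normal(0, 1, m)
            k[np.abs(k) < 0.05] = 0.3
            s = rng.uniform(0.2, 3.0, m)
            x = rng.normal(0, 20, m)
            names = [f"m{j}" for j in range(m)]
            model = _model(names, list(zip(q, k, s)))
            est = ba.predict_kdm(model, _subjects(names, x))["ba"].iloc[0]

            # independent WLS minimiser: root of the objective's gradient,
            # evaluated term by term (exact for a quadratic objective)
            def gradient(b):
                return -2.0 * np.sum(k * (x - q - k * b) / s**2)

            oracle = optimize.brentq(gradient, -5000, 5000, xtol=1e-12)
            assert abs(est - oracle) < 1e-8

    def test_invariant_to_rescaling_a_biomarker_with_its_triple(self):
        names = ["a", "b"]
        model = _model(names, [(10.0, 0.5, 1.0), (5.0, -0.2, 2.0)])
        scaled = _model(names, [(10.0 * 7, 0.5 * 7, 1.0 * 7), (5.0, -0.2, 2.0)])
        subj = _subjects(names, [35.0, -6.0])
        subj_scaled = _subjects(names, [35.0 * 7, -6.0])
        a = ba.predict_kdm(model, subj)["ba"].iloc[0]
        b = ba.predict_kdm(scaled, subj_scaled)["ba"].iloc[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_missing_biomarker_and_unknown_gender_rejected(self):
        model = _model(["a"], [(0.0, 1.0, 1.0)])
        with pytest.raises(PredictionError):
            ba.predict_kdm(model, _subjects(["z"], [1.0]))
        with pytest.raises(PredictionError):
            ba.predict_kdm(model, _subjects(["a"], [1.0], gender="male"))


class TestMLR:
    def test_single_perfect_biomarker_gives_identity(self):
        ca = np.linspace(20, 80, 40)
        table = make_cohort({"m": ca.copy()}, ca=ca)
        model = ba.fit_mlr(table, ["m"])
        b0, b = model.coef["female"]
        assert b0 == pytest.approx(0.0, abs=1e-9)
        assert b[0] == pytest.approx(1.0, abs=1e-10)
        pred = ba.predict_mlr(model, table)
        np.testing.assert_allclose(pred["ba"], ca, atol=1e-9)

    def test_four_row_fixture_matches_normal_equations(self):
        ca = np.array([30.0, 40.0, 55.0, 70.0])
        table = make_cohort(
            {"a": [1.0, 2.0, 2.5, 4.0], "b": [10.0, 8.0, 9.0, 5.0]}, ca=ca
        )
        model = ba.fit_mlr(table, ["a", "b"])
        b0, b = model.coef["female"]
        X = np.column_stack([np.ones(4), table["a"], table["b"]])
        beta = np.linalg.solve(X.T @ X, X.T @ ca)
        assert b0 == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(b, beta[1:], atol=1e-8)

    def test_intercept_only_prediction(self):
        model = MLRModel(panel=("a",), coef={"female": (20.0, np.array([0.0]))})
        pred = ba.predict_mlr(model, _subjects(["a"], [123.0]))
        assert pred["ba"].iloc[0] == 20.0

    def test_fixture_arithmetic(self):
        model = MLRModel(
            panel=("a", "b"), coef={"female": (20.0, np.array([2.0, -1.0]))}
        )
        pred = ba.predict_mlr(model, _subjects(["a", "b"], [15.0, 5.0]))
        assert pred["ba"].iloc[0] == pytest.approx(45.0)

    def test_uninformative_markers_collapse_to_mean_age(self):
        rng = np.random.default_rng(3)
        ca = rng.uniform(20, 80, 800)
        table = make_cohort(
            {"a": rng.normal(size=800), "b": rng.normal(size=800)}, ca=ca
        )
        model = ba.fit_mlr(table, ["a", "b"])
        test = make_cohort(
            {"a": rng.normal(size=400), "b": rng.normal(size=400)},
            ca=rng.uniform(20, 80, 400),
        )
        pred = ba.predict_mlr(model, test)
        slope = stats.linregress(test["ca"], pred["ba"]).slope
        assert abs(slope) < 0.1
        assert abs(pred["ba"].mean() - ca.mean()) < 3.0

    def test_collinear_design_rejected_with_names(self):
        ca = np.linspace(20, 80, 30)
        x = np.sin(ca)
        table = make_cohort({"a": x, "b": 2 * x}, ca=ca)
        with pytest.raises(FitError) as err:
            ba.fit_mlr(table, ["a", "b"])
        assert "a" in str(err.value) and "b" in str(err.value)


class TestEstimatorContrast:
    def test_kdm_slope_near_one_mlr_strictly_flatter(self, trained_models):
        train, test, kdm, mlr = trained_models
        kdm_ba = ba.predict_kdm(kdm, test)["ba"]
        mlr_ba = ba.predict_mlr(mlr, test)["ba"]
        s_kdm = stats.linregress(test["ca"], kdm_ba).slope
        s_mlr = stats.linregress(test["ca"], mlr_ba).slope
        assert s_kdm == pytest.approx(1.0, abs=0.06)
        assert s_mlr < s_kdm

    def test_noise_free_loop_returns_ca_exactly(self, kdm_panel):
        specs = tuple(ba.BiomarkerSpec(s.name, s.intercept, s.slope, 0.0)
                      for s in ba.kdm8_specs())
        cfg = ba.GenerativeConfig(n_subjects=80, biomarker_specs=specs,
                                  s_ba=0.0, seed=5)
        cohort = ba.generate_controls(cfg)
        model = ba.fit_kdm(cohort, kdm_panel)
        pred = ba.predict_kdm(model, cohort)
        np.testing.assert_allclose(pred["ba"], cohort["ca"], atol=1e-7)


class TestSerialization:
    @given(st.integers(0, 2**31 - 1))
    def test_kdm_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        model = _model(["a", "b"], [tuple(rng.normal(size=3) + [0, 1, 2]) for _ in range(2)])
        back = KDMModel.from_json(model.to_json())
        assert back.panel == model.panel
        for g in model.params:
            for m in model.params[g]:
                np.testing.assert_allclose(back.params[g][m], model.params[g][m])
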