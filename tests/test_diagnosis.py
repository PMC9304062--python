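"""Diagnosis models: logistic fits, stepwise selection, ROC/Youden, DeLong."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from datspect import diagnosis, phantom
from datspect.diagnosis import (compare_auc, fit_logistic, forward_stepwise,
                                predict_probability, roc_with_youden)
from datspect.feature_ml import auc_mann_whitney


def brute_force_youden(scores, labels):
    """Exhaustive scan over every real-valued cut (oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cand = np.concatenate([[scores.min() - 1],
                           (np.sort(np.unique(scores))[:-1] + np.sort(np.unique(scores))[1:]) / 2,
                           [scores.max() + 1]])
    best = None
    for c in cand:
        sens = np.mean(scores[labels == 1] >= c)
        spec = np.mean(scores[labels == 0] < c)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and spec > best[1]):
            best = (j, spec, c)
    return best[2], best[0]


class TestPredictProbability:
    def test_zero_coefficients_give_half(self):
        m = diagnosis.DiagnosisModel("null", ["a", "b"], 0.0, [0.0, 0.0])
        assert predict_probability(m, {"a": 12.0, "b": -3.0}) == 0.5

    def test_closed_form_value(self):
        m = diagnosis.DiagnosisModel("one", ["x"], 0.0, [1.0])
        assert predict_probability(m, {"x": np.log(3)}) == pytest.approx(0.75)

    def test_matches_direct_formula_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(1, 5))
            b0 = rng.normal()
            b = rng.normal(size=k)
            x = rng.normal(size=k)
            m = diagnosis.DiagnosisModel("r", [f"v{i}" for i in range(k)], b0, b)
            expected = 1 / (1 + np.exp(-(b0 + b @ x)))
            assert predict_probability(m, dict(zip(m.variables, x))) == pytest.approx(
                expected, rel=1e-12)

    def test_monotone_in_positive_coefficient(self):
        m = diagnosis.DiagnosisModel("m", ["x"], -1.0, [2.0])
        ps = [predict_probability(m, {"x": v}) for v in np.linspace(-3, 3, 20)]
        assert all(b > a for a, b in zip(ps, ps[1:]))

    def test_missing_predictor_rejected(self):
        m = diagnosis.DiagnosisModel("m", ["x", "y"], 0.0, [1.0, 1.0])
        with pytest.raises(ValueError, match="missing"):
            predict_probability(m, {"x": 1.0})


class TestFitLogistic:
    def test_recovers_known_coefficients(self):
        """Default label generator with known logistic rule: every fitted
        coefficient lies within 3 standard errors of truth at n = 2000."""
        table = phantom.generate_label_table(2000, seed=17)
        X = table[["age", "low", "asymmetric", "dot"]].astype(float)
        m = fit_logistic(X, table["diagnosis"].astype(int), name="recovery")
        rule = phantom.DEFAULT_RULE
        truth = {"age": rule.b_age, "low": rule.b_low,
                 "asymmetric": rule.b_asym, "dot": rule.b_dot}
        assert m.converged and not m.separation
        for var, b, se in zip(m.variables, m.coefficients, m.standard_errors):
            assert abs(b - truth[var]) < 3 * se, f"{var}: {b} vs {truth[var]} (se {se})"

    def test_null_model_predicts_prevalence(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=400)})
        y = (rng.random(400) < 0.3).astype(int)
        m = fit_logistic(X, y)
        p = predict_probability(m, X)
        assert p.mean() == pytest.approx(y.mean(), abs=0.02)

    def test_duplicate_predictor_rank_error(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": x})
        y = (x + rng.normal(size=100) > 0).astype(int)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(X, y)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(X, np.zeros(20, dtype=int))

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.separation
        assert predict_probability(m, {"x": 2.0}) > 0.9

    def test_consistency_with_n(self):
        """Coefficient error shrinks as the sample grows."""
        errs = []
        for n in (500, 4000):
            table = phantom.generate_label_table(n, seed=23)
            m = fit_logistic(table[["age", "low", "asymmetric", "dot"]].astype(float),
                             table["diagnosis"].astype(int))
            rule = phantom.DEFAULT_RULE
            truth = np.array([rule.b_age, rule.b_low, rule.b_asym, rule.b_dot])
            errs.append(np.linalg.norm(m.coefficients - truth))
        assert errs[1] < errs[0]


class TestRocYouden:
    def test_perfectly_separated_midpoint(self):
        r = roc_with_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.sens_at_youden == 1.0 and r.spec_at_youden == 1.0
        assert r.youden_threshold == pytest.approx(0.5)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(8, 30))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            r = roc_with_youden(scores, labels)
            thr, j = brute_force_youden(scores, labels)
            assert r.youden_threshold == pytest.approx(thr)
            assert r.sens_at_youden + r.spec_at_youden - 1 == pytest.approx(j)
            assert r.auc == pytest.approx(auc_mann_whitney(scores, labels))

    def test_negated_scores_flipped_labels_same_auc(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7])
        labels = np.array([0, 0, 1, 1, 1])
        a = roc_with_youden(scores, labels)
        b = roc_with_youden(-scores, 1 - labels)
        assert a.auc == pytest.approx(b.auc)

    def test_constant_scores_flagged(self):
        r = roc_with_youden([0.5] * 8, [0, 1] * 4)
        assert r.auc == 0.5 and not r.youden_defined

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        r = roc_with_youden(scores, labels)
        assert (np.diff(r.sensitivities) <= 1e-12).all()


class TestModels:
    def _cohort_frame(self, n, seed, b_sbr=-2.0, b_ai=0.0):
        rng = np.random.default_rng(seed)
        sbr = rng.uniform(1, 7, size=n)
        ai = rng.uniform(0, 50, size=n)
        lin = 3.0 + b_sbr * sbr + b_ai * ai / 10
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        return pd.DataFrame({"sbr_mean": sbr, "asymmetry_index": ai}), y

    def test_model1_null_asymmetry_coefficient(self):
        X, y = self._cohort_frame(2000, 4)
        m = diagnosis.build_model1(X, y)
        i = m.variables.index("asymmetry_index")
        assert abs(m.coefficients[i]) < 3 * m.standard_errors[i]

    def test_model1_independent_outcome_chance_auc(self):
        rng = np.random.default_rng(8)
        X, _ = self._cohort_frame(400, 8)
        y = rng.integers(0, 2, size=400)
        m = diagnosis.build_model1(X, y)
        p = predict_probability(m, X)
        assert abs(auc_mann_whitney(p, y) - 0.5) < 0.08

    def test_model2_extremes(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        r = diagnosis.build_model2(y.astype(float), y)
        assert r.auc == 1.0
        rng = np.random.default_rng(1)
        r2 = diagnosis.build_model2(rng.random(200), rng.integers(0, 2, 200))
        assert abs(r2.auc - 0.5) < 0.1

    def test_model2_rank_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        y = (rng.random(100) < p).astype(int)
        a = diagnosis.build_model2(p, y)
        b = diagnosis.build_model2(p ** 3, y)  # strictly monotone transform
        assert a.auc == pytest.approx(b.auc)


class TestForwardStepwise:
    def test_picks_informative_over_noise(self):
        rng = np.random.default_rng(6)
        n = 300
        signal = rng.normal(size=n)
        y = (signal + 0.5 * rng.normal(size=n) > 0).astype(int)
        cols = {"signal": signal}
        cols.update({f"noise{i}": rng.normal(size=n) for i in range(9)})
        model, trace = forward_stepwise(pd.DataFrame(cols), y, seed=0)
        assert trace[0]["added"] == "signal"
        assert len(model.variables) <= 2

    def test_identical_candidates_select_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = (x > 0).astype(int)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        model, _ = forward_stepwise(X, y, seed=0)
        assert len(model.variables) == 1

    def test_four_independent_effects_all_selected(self):
        """Age plus one probability per feature family, all independently
        informative: stepwise selects all four and respects the one-method-
        per-family constraint."""
        rng = np.random.default_rng(11)
        n = 600
        low = rng.integers(0, 2, n)
        asym = rng.integers(0, 2, n)
        dot = rng.integers(0, 2, n)
        age = rng.normal(70, 10, n)
        lin = -7 + 0.1 * age + 1.5 * low + 1.5 * asym + 1.5 * dot
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        cols = {"age": age}
        for fam, lab in (("low", low), ("asym", asym), ("dot", dot)):
            for meth in ("lr", "knn", "gbt"):
                cols[f"p_{fam}_{meth}"] = np.clip(
                    lab + 0.15 * rng.normal(size=n), 0, 1)
        model, _ = forward_stepwise(pd.DataFrame(cols), y, seed=1)
        fams = {diagnosis._feature_family(v) for v in model.variables}
        assert fams == {"age", "low", "asym", "dot"}
        assert len(model.variables) == 4


class TestCompareAuc:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        out = compare_auc(s, s, y)
        assert out["difference"] == 0.0 and out["p_value"] == 1.0

    def test_monotone_transform_zero_difference(self):
        rng = np.random.default_rng(1)
        s = rng.random(80)
        y = rng.integers(0, 2, 80)
        out = compare_auc(s, np.exp(2 * s), y)
        assert out["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([0.1, 0.2], [0.1], [0, 1])

    def test_type_one_error_calibrated(self):
        """Under the null (two independent uninformative scores), the paired
        test rejects at ~5%."""
        rng = np.random.default_rng(123)
        n, reps = 200, 800
        rejections = 0
        y = np.array([0, 1] * (n // 2))
        for _ in range(reps):
            a = rng.random(n)
            b = rng.random(n)
            rejections += compare_auc(a, b, y)["p_value"] < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.02

    def test_detects_real_difference(self):
        rng = np.random.default_rng(3)
        n = 300
        y = rng.integers(0, 2, n)
        good = y + 0.5 * rng.normal(size=n)
        bad = rng.random(n)
        out = compare_auc(good, bad, y)
        assert out["auc_a"] > 0.8 and out["p_value"] < 1e-6
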