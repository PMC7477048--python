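"""Survival models, screening and validation statistics."""

import numpy as np
import pandas as pd
import pytest

from petfactor.prognostics import (
    backward_select,
    compare_models,
    concordance,
    cox_fit,
    cross_validate,
    harrell_c,
    incident_auc,
    logrank,
    null_loglik,
    spearman_screen,
)
from petfactor.simulate import SurvivalGroundTruth, generate_survival


def _cohort(beta, n=500, seed=0, censoring=0.3, horizon=1e9, h0=0.02,
            binary_first=True):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.standard_normal((n, p))
    if binary_first:
        X[:, 0] = rng.binomial(1, 0.5, n)
    gt = SurvivalGroundTruth(true_beta=beta, baseline_hazard_rate=h0,
                             censoring_rate=censoring, horizon_months=horizon,
                             seed=seed)
    ev = generate_survival(X, gt)
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["time_months"] = ev["time_months"]
    df["event"] = ev["event"]
    return df


class TestSpearman:
    def test_monotone_pair_is_one(self):
        a = pd.DataFrame({"u": np.arange(10.0)})
        b = pd.DataFrame({"v": np.exp(np.arange(10.0))})
        r, p, sig = spearman_screen(a, b)
        assert r.loc["u", "v"] == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # rank differences d = (-1, 1, -1, 1, 0), sum d^2 = 4:
        # rho = 1 - 6*4/(5*(25-1)) = 0.8
        a = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
        b = pd.DataFrame({"y": [2, 1, 4, 3, 5]})
        r, _, _ = spearman_screen(a, b)
        assert r.loc["x", "y"] == pytest.approx(0.8)

    def test_bonferroni_family_threshold(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"a{i}" for i in range(8)])
        b = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"b{i}" for i in range(8)])
        b["b0"] = a["a0"] + 0.01 * rng.standard_normal(60)
        r, p, sig = spearman_screen(a, b, alpha=0.05)
        # 64 tests: per-test threshold 0.05/64 = 0.00078125
        assert sig.equals(p < 0.05 / 64)
        assert sig.loc["a0", "b0"]

    def test_constant_column_flagged(self):
        a = pd.DataFrame({"x": np.ones(10)})
        b = pd.DataFrame({"y": np.arange(10.0)})
        r, _, _ = spearman_screen(a, b)
        assert np.isnan(r.loc["x", "y"])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], float)
        e = np.ones(10, int)
        g = np.repeat([0, 1], 5)
        stat, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])

    def test_strong_effect_detected(self):
        df = _cohort([1.2], n=300, seed=2, censoring=0.0)
        stat, p = logrank(df["time_months"], df["event"], df["x0"])
        assert p < 1e-4


class TestCoxFit:
    def test_null_covariate_near_zero(self):
        df = _cohort([0.0], n=1000, seed=3)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        assert abs(fit.beta["x0"]) < 0.15
        ci, _ = concordance(fit, df)
        assert abs(ci - 0.5) < 0.03

    def test_effect_recovery(self):
        df = _cohort([0.7], n=800, seed=4, censoring=0.2)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        assert fit.beta["x0"] == pytest.approx(0.7, abs=0.2)

    def test_loglik_beats_null(self):
        df = _cohort([0.5, -0.3], n=300, seed=5)
        fit = cox_fit(df, "time_months", "event", ["x0", "x1"])
        assert fit.loglik >= null_loglik(df, "time_months", "event")

    def test_constant_predictor_rejected(self):
        df = _cohort([0.5], n=50, seed=6)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "time_months", "event", ["c"])


class TestBackwardSelection:
    def test_strong_predictors_all_kept(self):
        df = _cohort([0.9, -0.8], n=600, seed=7)
        fit = backward_select(df, "time_months", "event", ["x0", "x1"])
        assert set(fit.predictors) == {"x0", "x1"}
        assert fit.elimination_path == []

    def test_noise_dropped_signal_kept(self):
        df = _cohort([0.9, 0.0, 0.0], n=600, seed=8)
        fit = backward_select(df, "time_months", "event", ["x0", "x1", "x2"])
        assert "x0" in fit.predictors
        assert all(fit.p[c] <= 0.157 for c in fit.predictors)

    def test_pure_noise_returns_null_model(self):
        rng = np.random.default_rng(9)
        df = _cohort([0.0], n=80, seed=9)
        fit = backward_select(df, "time_months", "event", ["x0"])
        # either x0 survived by chance (p <= 0.157) or the model is null
        if fit.predictors:
            assert fit.p["x0"] <= 0.157
        else:
            assert fit.elimination_path


class TestConcordance:
    def test_four_subject_enumeration(self):
        # 6 pairs, risk ordering wrong only for subjects 3 vs 4 -> 5/6
        c, se = harrell_c([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 1, 2])
        assert c == pytest.approx(5.0 / 6.0)

    def test_perfect_ordering(self):
        t = np.arange(1.0, 21.0)
        c, _ = harrell_c(t, np.ones(20), -t)
        assert c == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 1000)
        c, _ = harrell_c(t, np.ones(1000), rng.standard_normal(1000))
        assert abs(c - 0.5) < 0.03

    def test_agrees_with_lifelines(self):
        from lifelines.utils import concordance_index

        df = _cohort([0.6], n=300, seed=11, censoring=0.3)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        c, _ = concordance(fit, df)
        want = concordance_index(df["time_months"], -fit.linear_predictor(df),
                                 df["event"])
        assert c == pytest.approx(want, abs=1e-12)


class TestIncidentAUC:
    def test_perfect_ordering_gives_one(self):
        df = pd.DataFrame({
            "x0": [4.0, 3.0, 2.0, 1.0, 0.5, 0.2],
            "time_months": [1, 2, 3, 4, 5, 6],
            "event": [1, 1, 1, 1, 1, 1],
        })
        fit = cox_fit(df, "time_months", "event", ["x0"])
        curve, summary = incident_auc(fit, df, horizon=10)
        assert np.allclose(curve["auc"], 1.0)
        assert summary == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        df = _cohort([0.0], n=800, seed=12, censoring=0.0, horizon=60, h0=0.05)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        _, summary = incident_auc(fit, df, horizon=60)
        assert abs(summary - 0.5) < 0.05

    def test_two_group_closed_form(self):
        # binary marker, exponential arms: at time t cases are events, so
        # AUC(t) = P(case in group 1)*P(control in group 0) + 0.5*(ties)
        hr = 3.0
        df = _cohort([np.log(hr)], n=6000, seed=13, censoring=0.0,
                     horizon=1e9, h0=0.02)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        curve, _ = incident_auc(fit, df, horizon=40.0)
        h0, h1 = 0.02, 0.02 * hr
        for t in (10.0, 25.0):
            s0, s1 = np.exp(-h0 * t), np.exp(-h1 * t)
            p_case1 = h1 * s1 / (h1 * s1 + h0 * s0)
            p_ctrl1 = s1 / (s1 + s0)
            want = p_case1 * (1 - p_ctrl1) + 0.5 * (
                p_case1 * p_ctrl1 + (1 - p_case1) * (1 - p_ctrl1)
            )
            near = curve[(curve["time"] > t - 4) & (curve["time"] < t + 4)]
            got = np.average(near["auc"], weights=near["weight"])
            assert got == pytest.approx(want, abs=0.03)

    def test_no_pre_horizon_events_rejected(self):
        df = pd.DataFrame({"x0": [1.0, 2.0, 1.5], "time_months": [30, 40, 50],
                           "event": [1, 1, 0]})
        fit = cox_fit(df, "time_months", "event", ["x0"])
        with pytest.raises(ValueError, match="horizon"):
            incident_auc(fit, df, horizon=10)


class TestCrossValidation:
    def test_same_seed_same_result(self):
        df = _cohort([0.8], n=200, seed=14)
        a = cross_validate(df, "time_months", "event", ["x0"], seed=3)
        b = cross_validate(df, "time_months", "event", ["x0"], seed=3)
        assert a == b

    def test_null_predictors_near_half(self):
        df = _cohort([0.0, 0.0], n=400, seed=15)
        ci, _ = cross_validate(df, "time_months", "event", ["x0", "x1"],
                               seed=0, select=False)
        assert abs(ci - 0.5) < 0.07

    def test_low_overfit_regime_tracks_apparent_ci(self):
        df = _cohort([1.0], n=500, seed=16)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        apparent, _ = concordance(fit, df)
        cv, _ = cross_validate(df, "time_months", "event", ["x0"], seed=0)
        assert abs(cv - apparent) < 0.03


class TestModelComparison:
    def test_same_model_gives_unit_p(self):
        df = _cohort([0.7], n=200, seed=17)
        fit = cox_fit(df, "time_months", "event", ["x0"])
        stat, p = compare_models(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_added_signal_detected(self):
        df = _cohort([0.3, 1.0], n=500, seed=18)
        small = cox_fit(df, "time_months", "event", ["x0"])
        big = cox_fit(df, "time_months", "event", ["x0", "x1"])
        stat, p = compare_models(small, big)
        assert p < 1e-4

    def test_non_nested_rejected(self):
        df = _cohort([0.3, 0.4], n=200, seed=19)
        a = cox_fit(df, "time_months", "event", ["x0"])
        b = cox_fit(df, "time_months", "event", ["x1"])
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)
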