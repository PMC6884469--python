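"""Regression-ladder tests: oracle agreement for SSEs and F-test p-values,
label thresholds, the rapid-adaptation prefix, and the calibration
properties (type-I control on constant trains, power under true adaptation).
"""

import numpy as np
import pytest
from scipy import stats

from fireclass import (CriteriaConfig, RegressionFit, fit_ladder,
                       label_from_fit, detect_rasp_prefix)
from fireclass.adaptation_regression import InsufficientDataError


# --- independent least-squares / F-test oracle -----------------------------

def oracle_sse(x, y, model, xstar=None):
    x, y = np.asarray(x, float), np.asarray(y, float)
    if model == "M1":
        return float(((y - y.mean()) ** 2).sum())
    if model == "M2":
        A = np.column_stack([x, np.ones_like(x)])
    elif model == "M3":
        A = np.column_stack([np.minimum(x, xstar), np.ones_like(x)])
    elif model == "M4":
        A = np.column_stack([np.minimum(x, xstar),
                             np.maximum(x - xstar, 0.0), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def oracle_best_piecewise(x, y, model):
    return min(oracle_sse(x, y, model, xs) for xs in np.unique(x[1:-1]))


def oracle_f_p(sse_small, sse_large, df_extra, df_resid):
    if sse_large <= 0 or sse_small <= sse_large:
        return 1.0
    f = ((sse_small - sse_large) / df_extra) / (sse_large / df_resid)
    return float(stats.f.sf(f, df_extra, df_resid))


def fixture_sets():
    rng = np.random.default_rng(1234)
    out = []
    for n in (6, 8, 12, 20):
        x = np.sort(rng.uniform(0.02, 1.0, n))
        x[-1] = 1.0
        out.append((x, 1 + 0.8 * x + 0.05 * rng.standard_normal(n)))
        out.append((x, np.where(x < 0.5, 1 + 2 * x, 2.0)
                    + 0.05 * rng.standard_normal(n)))
        out.append((x, np.full(n, 1.5) + 0.1 * rng.standard_normal(n)))
    return out


class TestFitLadderAgainstOracle:
    @pytest.mark.parametrize("i,xy", list(enumerate(fixture_sets())))
    def test_sse_and_pvalues_match_bruteforce(self, i, xy):
        x, y = xy
        n = len(y)
        fit = fit_ladder(y, x)
        s1 = oracle_sse(x, y, "M1")
        s2 = min(oracle_sse(x, y, "M2"), s1)
        s3 = min(oracle_best_piecewise(x, y, "M3"), s2)
        s4 = min(oracle_best_piecewise(x, y, "M4"), s3)
        assert fit.sse["M1"] == pytest.approx(s1, abs=1e-8)
        assert fit.sse["M2"] == pytest.approx(s2, abs=1e-8)
        assert fit.sse["M3"] == pytest.approx(s3, abs=1e-8)
        assert fit.sse["M4"] == pytest.approx(s4, abs=1e-8)
        assert fit.p_21 == pytest.approx(oracle_f_p(s1, s2, 1, n - 2),
                                         abs=1e-10)
        assert fit.p_32 == pytest.approx(oracle_f_p(s2, s3, 1, n - 3),
                                         abs=1e-10)
        assert fit.p_43 == pytest.approx(oracle_f_p(s3, s4, 1, n - 4),
                                         abs=1e-10)
        # ladder invariant: SSE monotone non-increasing
        assert fit.sse["M1"] >= fit.sse["M2"] >= fit.sse["M3"] >= fit.sse["M4"]


class TestFitLadderExamples:
    def test_zero_variance_constant(self):
        fit = fit_ladder([1, 1, 1, 1, 1], [0.2, 0.4, 0.6, 0.8, 1.0])
        assert fit.model == "M1" and fit.p_21 == 1.0 and fit.a1 == 0.0

    def test_perfect_line_recovers_slope(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        fit = fit_ladder(1 + 0.5 * x, x)
        assert fit.model == "M2"
        assert fit.a1 == pytest.approx(0.5, abs=1e-9)
        assert fit.p_21 < 1e-10

    def test_noisy_plateau_selects_m3_near_true_breakpoint(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.08, 1.0, 12)
        y = np.where(x < 0.5, 1 + 2 * x, 2.0) + 0.05 * rng.standard_normal(12)
        fit = fit_ladder(y, x)
        assert fit.model == "M3"
        assert abs(fit.breakpoint - 0.5) < 0.15
        assert fit.a2 == 0.0
        assert fit.b2 == pytest.approx(fit.a1 * fit.breakpoint + fit.b1)

    def test_appending_exact_point_never_increases_selected_sse(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0.1, 1.0, 10)
        y = 1 + 0.7 * x + 0.05 * rng.standard_normal(10)
        fit = fit_ladder(y, x)
        # a new point lying exactly on the fitted line at x=1.05 (rescaled)
        x2 = np.append(x, 1.05) / 1.05
        y2 = np.append(y, fit.a1 * 1.05 + fit.b1)
        fit2 = fit_ladder(y2, x2)
        assert fit2.sse[fit2.model] <= fit.sse[fit.model] + 1e-9

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_ladder([1, 2], [0.5, 1.0])


class TestLabelThresholds:
    def mk(self, **kw):
        base = dict(n=12, model="M2", a1=0.5, b1=1.0, a2=0.0, b2=1.0,
                    breakpoint=None, sse={}, p_21=0.001, p_32=1.0, p_43=1.0)
        base.update(kw)
        return RegressionFit(**base)

    @pytest.mark.parametrize("kw,want", [
        (dict(p_21=0.2), "NASP"),                      # line not significant
        (dict(p_21=0.01, a1=0.002), "NASP"),           # slope below guard
        (dict(a1=-0.4), "ACSP."),
        (dict(p_32=0.01, p_43=0.4, model="M3"), "ASP.NASP"),
        (dict(p_32=0.01, p_43=0.001, a2=0.4, model="M4"), "ASP.ASP."),
        (dict(p_32=0.01, p_43=0.001, a2=0.001, model="M4"), "ASP.NASP"),
        (dict(), "ASP."),
    ])
    def test_threshold_ladder(self, cfg, kw, want):
        assert label_from_fit(self.mk(**kw), cfg) == want

    def test_bonferroni_defaults(self, cfg):
        assert cfg.alpha == 0.05
        assert cfg.p32_threshold == 0.025
        assert cfg.p43_threshold == pytest.approx(0.05 / 3)


class TestRASPPrefix:
    def test_rapid_then_constant(self, cfg):
        fires, k = detect_rasp_prefix([5, 15, 30, 31, 30, 32, 31], cfg)
        assert fires and k == 2

    def test_gentle_uniform_adaptation_rejected(self, cfg):
        assert detect_rasp_prefix([20, 21, 22, 23, 24, 25], cfg) == (False, 0)

    def test_default_rasp_slope(self, cfg):
        assert cfg.S_RASP == 0.2

    def test_too_short_train(self, cfg):
        assert detect_rasp_prefix([5, 15, 30, 30], cfg) == (False, 0)


def _label_of_train(isis, cfg):
    isis = np.asarray(isis, float)
    y = isis / isis.min()
    x = np.cumsum(isis) / isis.sum()
    return label_from_fit(fit_ladder(y, x, cfg), cfg)


class TestCalibration:
    def test_type_one_error_on_constant_trains(self, cfg):
        rng = np.random.default_rng(0)
        bad = 0
        for _ in range(400):
            isis = np.maximum(20 * (1 + 0.1 * rng.standard_normal(20)), 1.0)
            if _label_of_train(isis, cfg) != "NASP":
                bad += 1
        assert bad / 400 <= 0.06 + 0.02  # small-sample slack; full run in acceptance

    def test_power_at_moderate_slope(self, cfg):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(400):
            x = np.linspace(0.05, 1.0, 20)
            y = (1 + 0.5 * x) * (1 + 0.1 * rng.standard_normal(20))
            lab = label_from_fit(fit_ladder(y, x, cfg), cfg)
            if lab.startswith("ASP"):
                hits += 1
        assert hits / 400 >= 0.95
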