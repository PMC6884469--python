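"""Detector tests, including brute-force-oracle equivalence and the
strictness / scale-covariance properties of the threshold criteria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fireclass import (CriteriaConfig, detect_delay, detect_sln,
                       detect_transient_break, classify_break,
                       detect_persistent_interrupted, measure_swa,
                       TraceValidationError)
from conftest import make_series


# --- independent brute-force evaluators of the published inequalities ------

def oracle_delay(delay, isis, DF=2.0):
    return delay > DF * (isis[0] + isis[1]) / 2.0


def oracle_sln(pfs, isis, SF=2.0):
    return (pfs > SF * (isis[-1] + isis[-2]) / 2.0
            and pfs > SF * max(isis))


def oracle_break(isis, F_pre=2.5, F_post=1.5, f_min=25.0, idx=(2, 3, 4)):
    n = len(isis)
    for i in idx:                      # 1-based index of the long ISI
        if i < 2 or i + 1 > n:
            continue
        isi_i = isis[i - 1]
        pre = isis[: i - 1]
        post = isis[i - 1:]
        if (isi_i > F_pre * isis[i - 2]
                and isi_i > F_post * isis[i]
                and sum(post) / len(post) > F_pre * sum(pre) / len(pre)
                and all(1000.0 / x > f_min for x in pre)):
            return i
    return None


def oracle_persistent(isis, F=5.0):
    i = int(np.argmax(isis))
    if i == 0 or i == len(isis) - 1:
        return False
    return isis[i] / isis[i - 1] + isis[i] / isis[i + 1] > F


class TestDelay:
    def test_fires_when_latency_dominates(self, cfg, series):
        assert detect_delay(series([20, 20, 20], delay=50), cfg) is True

    def test_boundary_equality_rejected(self, cfg, series):
        assert detect_delay(series([20, 20, 20], delay=40), cfg) is False

    def test_single_isi_not_evaluable(self, cfg, series):
        assert detect_delay(series([20], delay=100), cfg) is None

    def test_default_delay_factor_is_two(self, cfg):
        assert cfg.DF == 2.0


class TestSLN:
    def test_both_clauses_required(self, cfg, series):
        assert detect_sln(series([20, 30], pfs=100), cfg) is True
        assert detect_sln(series([20, 30], pfs=55), cfg) is False

    def test_truncated_not_evaluable(self, cfg, series):
        assert detect_sln(series([20, 30], pfs=100, truncated=True),
                          cfg) is None

    def test_default_silence_factor_is_two(self, cfg):
        assert cfg.SF == 2.0


class TestTransientBreak:
    def test_qualifying_cluster(self, cfg, series):
        b = detect_transient_break(series([10, 10, 60, 35, 34, 36]), cfg)
        assert b is not None and b.index == 3
        assert b.post_mean == pytest.approx(41.25)
        assert b.pre_mean == pytest.approx(10.0)

    def test_post_mean_clause_fails(self, cfg, series):
        assert detect_transient_break(
            series([12, 12, 45, 14, 13, 12]), cfg) is None

    def test_fmin_clause_fails_on_slow_cluster(self, cfg, series):
        assert detect_transient_break(
            series([50, 50, 200, 60, 60, 60]), cfg) is None

    def test_agrees_with_bruteforce_on_random_vectors(self, cfg):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            n = int(rng.integers(4, 31))
            isis = np.exp(rng.normal(3.0, 0.9, n))
            got = detect_transient_break(make_series(isis), cfg)
            want = oracle_break(list(isis))
            assert (got.index if got else None) == want


class TestClassifyBreak:
    def test_swa_resolves_burst_vs_stutter(self, cfg, series):
        b = detect_transient_break(series([10, 10, 60, 35, 34, 36]), cfg)
        assert classify_break(b, 8.0, cfg) == "TSWB."
        assert classify_break(b, 3.0, cfg) == "TSTUT."
        assert classify_break(b, None, cfg) == "TSTUT."
        assert cfg.SWA_min == 5.0


class TestPersistentInterrupted:
    def test_stutter_then_burst_with_swa(self, cfg, series):
        s = series([8, 9, 100, 8, 9, 110, 9, 8])
        assert detect_persistent_interrupted(s, None, cfg).value == "PSTUT"
        assert detect_persistent_interrupted(s, 7.0, cfg).value == "PSWB"

    def test_weak_ratio_rejected(self, cfg, series):
        s = series([20, 22, 30, 21, 20])
        assert detect_persistent_interrupted(s, None, cfg) is None

    def test_terminal_max_isi_disqualifies(self, cfg, series):
        assert detect_persistent_interrupted(
            series([10, 10, 100]), None, cfg) is None

    def test_agrees_with_bruteforce(self, cfg):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            n = int(rng.integers(3, 31))
            isis = np.exp(rng.normal(3.0, 1.2, n))
            got = detect_persistent_interrupted(make_series(isis), None, cfg)
            assert (got is not None) == oracle_persistent(list(isis))


class TestScaleCovariance:
    @given(st.floats(0.1, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_ratio_detectors_invariant_under_scaling(self, c):
        cfg = CriteriaConfig()
        delay, pfs = 55.0, 90.0
        isis = np.array([10.0, 12.0, 60.0, 30.0, 34.0, 30.0])
        s1 = make_series(isis, delay=delay, pfs=pfs)
        s2 = make_series(c * isis, delay=c * delay, pfs=c * pfs)
        assert detect_delay(s1, cfg) == detect_delay(s2, cfg)
        assert detect_sln(s1, cfg) == detect_sln(s2, cfg)
        p1 = detect_persistent_interrupted(s1, None, cfg)
        p2 = detect_persistent_interrupted(s2, None, cfg)
        assert (p1 is None) == (p2 is None)

    def test_fmin_clause_flips_at_rate_threshold(self, cfg):
        # 1/ISI must exceed 25 Hz: ISIs under 40 ms pass, over 40 ms fail
        fast = make_series([39.0, 39.0, 300.0, 150.0, 150.0, 150.0])
        slow = make_series([41.0, 41.0, 300.0, 150.0, 150.0, 150.0])
        assert detect_transient_break(fast, cfg) is not None
        assert detect_transient_break(slow, cfg) is None


class TestSlowWaveAmplitude:
    @staticmethod
    def ramp_trace(v0=-60.0, v1=-50.0, slow=0.5, fast=50.0, dt=0.2):
        t_ramp = (v1 - v0) / slow
        t = np.arange(0.0, t_ramp + 5.0, dt)
        v = np.where(t <= t_ramp, v0 + slow * t, v1 + fast * (t - t_ramp))
        return np.column_stack([t, v])

    def test_two_threshold_definition(self, cfg):
        assert measure_swa(self.ramp_trace(), cfg) == pytest.approx(10.0, abs=0.2)

    def test_flat_trace_unknown(self, cfg):
        t = np.arange(0, 50, 0.5)
        v = np.full_like(t, -65.0)
        assert measure_swa(np.column_stack([t, v]), cfg) is None

    def test_instant_upstroke_degenerate_zero(self, cfg):
        t = np.arange(0, 20, 0.5)
        v = np.where(t < 10, -65.0, -65.0 + 50.0 * (t - 10))
        with pytest.warns(UserWarning, match="degenerate"):
            assert measure_swa(np.column_stack([t, v]), cfg) == 0.0

    def test_unsorted_samples_rejected(self, cfg):
        bad = np.array([[0.0, -60.0], [1.0, -59.0], [0.5, -58.0]])
        with pytest.raises(TraceValidationError):
            measure_swa(bad, cfg)
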