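"""Pointwise t statistics, the consecutive-significance runs criterion
and the model/results interface."""

import math

import numpy as np
import pandas as pd
import pytest

from vmmn import (ConfigurationError, DetectionCriterion, VmmnTest, detect,
                  find_runs, pointwise_t)
from vmmn.detection import TSeries

TIMES = np.arange(-100.0, 601.0)


def _tseries_from_p(p, times=TIMES, t=None):
    t = t if t is not None else np.where(np.asarray(p) < 1.0, -3.0, 0.0)
    return TSeries(np.asarray(t, dtype=float), np.asarray(p, dtype=float), 14,
                   times, np.zeros(len(p), dtype=bool))


def brute_force_runs(p, times, alpha, min_run_ms, window):
    """Independent oracle: enumerate every maximal all-significant
    interval inside the window by exhaustive scanning."""
    inside = (times >= window[0]) & (times <= window[1])
    sig = (np.asarray(p) < alpha) & inside
    dt = times[1] - times[0]
    min_n = math.ceil(min_run_ms / dt)
    found = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            if j - i + 1 >= min_n:
                found.append((times[i], times[j], j - i + 1))
            i = j + 1
        else:
            i += 1
    return found


class TestPointwiseT:
    def test_matches_textbook_formula(self):
        """t = mean / (sd / √n) on a five-subject sample."""
        values = np.array([-2.5, -1.0, -1.5, -2.0, -3.0])
        series = np.tile(values[:, None], (1, 3))
        ts = pointwise_t(series, np.array([0.0, 1.0, 2.0]))
        mean = values.mean()
        sd = math.sqrt(((values - mean) ** 2).sum() / 4)
        expected_t = mean / (sd / math.sqrt(5))
        assert ts.t[0] == pytest.approx(expected_t)
        assert ts.df == 4
        from scipy.stats import t as tdist
        assert ts.p[0] == pytest.approx(2 * tdist.sf(abs(expected_t), 4))

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        ts = pointwise_t(rng.normal(size=(15, 10)), np.arange(10.0))
        assert ts.df == 14

    def test_all_zero_series_degenerate(self):
        ts = pointwise_t(np.zeros((15, 701)), TIMES)
        assert np.all(ts.p == 1.0)
        assert np.all(ts.degenerate)
        assert find_runs(ts) == []

    def test_degenerate_nonzero_mean_is_certain(self):
        series = np.full((5, 701), -1.0)
        ts = pointwise_t(series, TIMES)
        assert np.all(ts.p == 0.0)
        assert np.all(np.isinf(ts.t)) and np.all(ts.t < 0)

    def test_one_tailed_negative(self):
        rng = np.random.default_rng(1)
        x = rng.normal(loc=-1.0, size=(10, 5))
        two = pointwise_t(x, np.arange(5.0), tails="two")
        one = pointwise_t(x, np.arange(5.0), tails="one")
        np.testing.assert_allclose(one.p, two.p / 2.0)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ConfigurationError):
            pointwise_t(np.zeros((2, 10)), np.arange(10.0))


class TestFindRuns:
    @pytest.mark.parametrize("run_len,expected_windows", [(19, 0), (20, 1), (25, 1)])
    def test_minimum_run_boundary(self, run_len, expected_windows):
        """At 1 kHz, 19 consecutive significant samples are not enough;
        20 are."""
        p = np.ones_like(TIMES)
        start = np.searchsorted(TIMES, 200.0)
        p[start:start + run_len] = 0.01
        windows = find_runs(_tseries_from_p(p))
        assert len(windows) == expected_windows
        if windows:
            assert windows[0].duration == run_len
            assert windows[0].start == 200.0

    def test_saturated_window(self):
        p = np.ones_like(TIMES)
        inside = (TIMES >= 150.0) & (TIMES <= 300.0)
        p[inside] = 0.001
        (w,) = find_runs(_tseries_from_p(p))
        assert (w.start, w.end) == (150.0, 300.0)
        assert w.n_samples == 151

    def test_run_straddling_edge_keeps_inside_portion(self):
        p = np.ones_like(TIMES)
        sig = (TIMES >= 120.0) & (TIMES <= 180.0)
        p[sig] = 0.01
        (w,) = find_runs(_tseries_from_p(p))
        assert (w.start, w.end) == (150.0, 180.0)

    def test_oracle_equivalence_on_random_series(self):
        """find_runs must agree with the brute-force scanner on 1,000
        random p-series."""
        rng = np.random.default_rng(2)
        criterion = DetectionCriterion()
        for _ in range(1000):
            p = rng.uniform(size=TIMES.size) ** 2  # denser sub-alpha stretches
            ts = _tseries_from_p(p)
            ours = [(w.start, w.end, w.n_samples) for w in find_runs(ts, criterion)]
            brute = brute_force_runs(p, TIMES, criterion.alpha, criterion.min_run,
                                     criterion.search_window)
            assert ours == brute

    def test_monotone_in_alpha_and_min_run(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=TIMES.size) ** 3
            ts = _tseries_from_p(p)
            loose = find_runs(ts, DetectionCriterion(alpha=0.05, min_run=20.0))
            strict_alpha = find_runs(ts, DetectionCriterion(alpha=0.01, min_run=20.0))
            longer_run = find_runs(ts, DetectionCriterion(alpha=0.05, min_run=40.0))
            for strict in (strict_alpha, longer_run):
                for w in strict:
                    assert any(o.start <= w.start and w.end <= o.end for o in loose), \
                        "tightening the criterion created a new window"


class TestDetect:
    def _series_with_effect(self, rng, effect=0.0, n=15):
        base = rng.normal(scale=0.3, size=(n, TIMES.size))
        bump = effect * np.exp(-((TIMES - 240.0) ** 2) / (2 * 30.0 ** 2))
        return base + bump

    def test_any_roi_rule(self):
        rng = np.random.default_rng(4)
        present = self._series_with_effect(rng, effect=-1.0)
        absent = self._series_with_effect(rng, effect=0.0)
        res = detect({"left": present, "right": absent}, TIMES)
        assert res.vmmn_present
        assert {w.roi for w in res.windows} == {"left"}

    def test_all_roi_rule(self):
        rng = np.random.default_rng(5)
        present = self._series_with_effect(rng, effect=-1.0)
        absent = self._series_with_effect(rng, effect=0.0)
        criterion = DetectionCriterion(require="all-roi")
        assert not detect({"left": present, "right": absent}, TIMES, criterion).vmmn_present
        present2 = self._series_with_effect(np.random.default_rng(6), effect=-1.0)
        assert detect({"left": present, "right": present2}, TIMES, criterion).vmmn_present

    def test_nothing_significant_is_absent(self):
        rng = np.random.default_rng(7)
        absent = self._series_with_effect(rng, effect=0.0)
        res = detect({"left": absent, "right": absent.copy()}, TIMES)
        assert not res.vmmn_present and res.windows == []

    def test_positive_runs_do_not_count_as_mismatch(self):
        """A significant *positivity* is reported as a window but does
        not flag vMMN presence under the default polarity rule."""
        rng = np.random.default_rng(8)
        positive = self._series_with_effect(rng, effect=+1.0)
        res = detect({"left": positive, "right": positive.copy()}, TIMES)
        assert res.windows and not res.vmmn_present
        res_any = detect({"left": positive, "right": positive.copy()}, TIMES,
                         DetectionCriterion(polarity="any"))
        assert res_any.vmmn_present


class TestVmmnTestModel:
    def test_fit_matches_functional_path(self):
        rng = np.random.default_rng(9)
        series = {"left": rng.normal(size=(15, TIMES.size)) - 0.8,
                  "right": rng.normal(size=(15, TIMES.size))}
        res = VmmnTest(series, TIMES, condition={"group": "older"}).fit()
        func = detect(series, TIMES, condition={"group": "older"})
        assert res.vmmn_present == func.vmmn_present
        assert [(w.start, w.end) for w in res.windows] == \
            [(w.start, w.end) for w in func.windows]
        assert "vMMN present" in res.summary()
        assert set(res.peaks) == {"left", "right"}

    def test_from_dataframe(self):
        rng = np.random.default_rng(10)
        times = np.arange(100.0, 400.0)
        rows = []
        for s in range(5):
            for roi in ("left", "right"):
                vals = rng.normal(size=times.size)
                for t, v in zip(times, vals):
                    rows.append({"subject": s, "roi": roi, "time_ms": t, "value": v})
        frame = pd.DataFrame(rows)
        model = VmmnTest.from_dataframe(frame)
        assert model.n_subjects == 5
        res = model.fit()
        assert set(res.tseries) == {"left", "right"}

    def test_peak_frame_schema(self):
        rng = np.random.default_rng(11)
        series = {"right": rng.normal(size=(6, TIMES.size))}
        res = VmmnTest(series, TIMES, condition={"group": "young",
                                                 "category": "letter",
                                                 "soa": 0.0}).fit()
        frame = res.peak_frame()
        assert {"roi", "latency_ms", "amplitude_uv"}.issubset(frame.columns)
        assert len(frame) == 1


class TestPermutationOption:
    def test_strong_effect_gets_small_familywise_p(self):
        from vmmn import permutation_max_run_test

        rng = np.random.default_rng(12)
        bump = -1.2 * np.exp(-((TIMES - 240.0) ** 2) / (2 * 30.0 ** 2))
        series = {"right": rng.normal(scale=0.4, size=(15, TIMES.size)) + bump}
        out = permutation_max_run_test(series, TIMES, n_permutations=200, seed=0)
        assert out["observed_run_samples"] >= 20
        assert out["p_familywise"] < 0.05

    def test_null_data_keeps_large_p(self):
        from vmmn import permutation_max_run_test

        rng = np.random.default_rng(13)
        series = {"right": rng.normal(size=(15, TIMES.size)),
                  "left": rng.normal(size=(15, TIMES.size))}
        out = permutation_max_run_test(series, TIMES, n_permutations=100, seed=1)
        assert out["p_familywise"] > 0.05
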