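"""Runs-based vMMN detection on subject-level difference waves.

The detector computes a one-sample t statistic against zero at every
sample of the ROI-pooled difference wave across subjects, then declares
a mismatch response present when at least ``min_run`` ms of
*consecutive* significant samples (p < alpha) fall inside the a-priori
search window (150–300 ms after change onset), in at least one ROI.
Requiring a run rather than any single significant sample is the
standard guard against false positives from temporally autocorrelated
ERP noise.

The model/results split follows the usual statsmodels idiom:
``VmmnTest(data, times).fit()`` returns :class:`VmmnTestResults` with
the t series, significant windows, peak measures and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import DetectionCriterion
from .erp import PeakMeasure, measure_peak
from .exceptions import ConfigurationError, VmmnError


@dataclass
class TSeries:
    """Per-sample one-sample t test of subject values against zero."""

    t: np.ndarray
    p: np.ndarray
    df: int
    times: np.ndarray
    degenerate: np.ndarray  # samples with zero across-subject variance

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class SignificantWindow:
    """A maximal run of consecutive significant samples inside the
    search window.

    ``start``/``end`` are the times of the first and last significant
    sample; the run's duration counts samples (``n_samples * dt``), so
    20 consecutive samples at 1 kHz constitute a 20 ms run.
    ``negative`` records whether the mean difference over the run is
    negative-going — only such runs can support a mismatch response.
    """

    roi: str
    start: float
    end: float
    n_samples: int
    duration: float
    negative: bool = True


def pointwise_t(subject_series: np.ndarray, times: np.ndarray,
                tails: str = "two") -> TSeries:
    """One-sample t against zero at every time point.

    Parameters
    ----------
    subject_series
        Array (n_subjects, n_samples) of ROI-pooled difference waves.
    times
        Analysis time axis in ms.
    tails
        ``"two"`` (default) or ``"one"``; the one-tailed test is in the
        negative direction, the predicted polarity of a mismatch
        response.

    Zero across-subject variance makes t undefined; such samples are
    flagged and given p = 0 when the mean is nonzero (the data are then
    exactly reproducible across subjects) and p = 1 when it is zero.
    """
    x = np.asarray(subject_series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ConfigurationError("need >= 3 subjects as a 2-D (subjects x samples) array")
    if x.shape[1] != len(times):
        raise ConfigurationError("time axis length does not match series")
    n = x.shape[0]
    df = n - 1
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    if tails == "two":
        p = 2.0 * sstats.t.sf(np.abs(t), df)
    elif tails == "one":
        p = sstats.t.cdf(t, df)  # H1: mean < 0
    else:
        raise ConfigurationError("tails must be 'two' or 'one'")
    deg_sign = np.sign(mean[degenerate])
    deg_t = np.zeros(deg_sign.shape)
    deg_t[deg_sign > 0] = np.inf
    deg_t[deg_sign < 0] = -np.inf
    t[degenerate] = deg_t
    p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
    return TSeries(t, p, df, np.asarray(times, dtype=float), degenerate)


def find_runs(ts: TSeries, criterion: DetectionCriterion | None = None,
              roi: str = "") -> list[SignificantWindow]:
    """Maximal consecutive-significance runs meeting the criterion.

    Runs of p < alpha are found on the full series, intersected with
    the search window (a run straddling the edge keeps only its inside
    portion), and retained when they still span at least
    ``ceil(min_run · rate / 1000)`` samples.
    """
    criterion = criterion or DetectionCriterion()
    w0, w1 = criterion.search_window
    if w0 < ts.times[0] or w1 > ts.times[-1]:
        raise VmmnError(f"search window {criterion.search_window} outside series span")
    dt = 1000.0 / ts.sampling_rate
    min_samples = math.ceil(criterion.min_run * ts.sampling_rate / 1000.0)

    significant = ts.p < criterion.alpha
    inside = (ts.times >= w0) & (ts.times <= w1)
    keep = significant & inside

    windows: list[SignificantWindow] = []
    run_start = None
    for i, flag in enumerate(np.append(keep, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            n = i - run_start
            if n >= min_samples:
                mean_t = float(np.mean(np.sign(ts.t[run_start:i])))
                windows.append(SignificantWindow(
                    roi=roi,
                    start=float(ts.times[run_start]),
                    end=float(ts.times[i - 1]),
                    n_samples=n,
                    duration=n * dt,
                    negative=mean_t < 0,
                ))
            run_start = None
    return windows


@dataclass
class DetectionResult:
    """Presence/absence of the mismatch response for one condition."""

    condition: dict
    windows: list[SignificantWindow]
    vmmn_present: bool
    tseries: dict[str, TSeries]
    peaks: dict[str, PeakMeasure] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        """Rows of the detection table (the machine twin of the
        published significant-window table)."""
        rows = []
        for w in self.windows:
            rows.append({**{k: self.condition[k] for k in ("group", "category", "soa")
                            if k in self.condition},
                         "roi": w.roi,
                         "window_start_ms": w.start,
                         "window_end_ms": w.end,
                         "duration_ms": w.duration,
                         "polarity": "negative" if w.negative else "positive"})
        return rows


def detect(roi_series: dict[str, np.ndarray], times: np.ndarray,
           criterion: DetectionCriterion | None = None,
           condition: dict | None = None) -> DetectionResult:
    """Apply the runs criterion to every ROI and combine.

    ``roi_series`` maps ROI name → (n_subjects, n_samples) array of
    difference waves.  With ``require='any-roi'`` (default) the
    response counts as present when any ROI shows a qualifying run.
    """
    criterion = criterion or DetectionCriterion()
    if not roi_series:
        raise ConfigurationError("no ROI series supplied")
    tseries: dict[str, TSeries] = {}
    windows: list[SignificantWindow] = []
    per_roi_present = []
    for roi, series in roi_series.items():
        ts = pointwise_t(series, times, tails=criterion.tails)
        found = find_runs(ts, criterion, roi=roi)
        tseries[roi] = ts
        windows.extend(found)
        qualifying = found if criterion.polarity == "any" else [w for w in found if w.negative]
        per_roi_present.append(bool(qualifying))
    present = any(per_roi_present) if criterion.require == "any-roi" else all(per_roi_present)
    return DetectionResult(condition or {}, windows, present, tseries)


def _max_run_samples(p: np.ndarray, inside: np.ndarray, alpha: float) -> int:
    keep = (p < alpha) & inside
    best = cur = 0
    for flag in keep:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best


def permutation_max_run_test(roi_series: dict[str, np.ndarray], times: np.ndarray,
                             criterion: DetectionCriterion | None = None,
                             n_permutations: int = 500,
                             seed: int | np.random.SeedSequence = 0) -> dict:
    """Family-wise sign-flip permutation test on the longest run.

    Optional stricter alternative to the plain runs criterion: under
    the null the subject difference waves are sign-symmetric, so random
    sign flips generate the null distribution of the *longest*
    consecutive-significance run across all ROIs inside the search
    window.  Returns the observed longest run (samples) and its
    family-wise p value ``(1 + #{perm >= obs}) / (1 + n)``.

    Off by default throughout the pipeline: the published criterion
    applies no correction beyond the run length itself.
    """
    criterion = criterion or DetectionCriterion()
    times = np.asarray(times, dtype=float)
    inside = (times >= criterion.search_window[0]) & (times <= criterion.search_window[1])
    rng = np.random.default_rng(seed)

    def longest(series_by_roi) -> int:
        return max(_max_run_samples(
            pointwise_t(series, times, criterion.tails).p, inside, criterion.alpha)
            for series in series_by_roi.values())

    observed = longest(roi_series)
    n_subjects = next(iter(roi_series.values())).shape[0]
    exceed = 0
    for _ in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_subjects)[:, None]
        flipped = {roi: flips * series for roi, series in roi_series.items()}
        if longest(flipped) >= observed:
            exceed += 1
    return {"observed_run_samples": observed,
            "p_familywise": (1 + exceed) / (1 + n_permutations),
            "n_permutations": n_permutations}


class VmmnTest:
    """Model object for the runs-based mismatch test.

    Parameters
    ----------
    roi_series
        Mapping ROI name → (n_subjects, n_samples) subject-level
        difference waves (μV), on a common analysis time axis.
    times
        Analysis time axis in ms (0 = change onset).
    criterion
        Detection criterion; defaults to ≥20 ms of consecutive
        p < 0.05 inside 150–300 ms, two-tailed, any ROI.

    Examples
    --------
    >>> res = VmmnTest({"right": waves}, times).fit()
    >>> res.vmmn_present, res.windows_frame()
    """

    def __init__(self, roi_series: dict[str, np.ndarray], times: np.ndarray,
                 criterion: DetectionCriterion | None = None,
                 condition: dict | None = None):
        self.roi_series = {k: np.asarray(v, dtype=float) for k, v in roi_series.items()}
        self.times = np.asarray(times, dtype=float)
        self.criterion = criterion or DetectionCriterion()
        self.condition = condition or {}
        n_subj = {v.shape[0] for v in self.roi_series.values()}
        if len(n_subj) != 1:
            raise ConfigurationError("all ROIs must have the same number of subjects")
        self.n_subjects = n_subj.pop()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, value: str = "value",
                       criterion: DetectionCriterion | None = None,
                       condition: dict | None = None) -> "VmmnTest":
        """Build from a long table with columns subject, roi, time_ms
        and a value column."""
        needed = {"subject", "roi", "time_ms", value}
        if not needed.issubset(frame.columns):
            raise ConfigurationError(f"frame must have columns {sorted(needed)}")
        times = np.sort(frame["time_ms"].unique())
        roi_series = {}
        for roi, sub in frame.groupby("roi"):
            pivot = sub.pivot(index="subject", columns="time_ms", values=value)
            pivot = pivot.reindex(columns=times)
            if pivot.isna().any().any():
                raise ConfigurationError("unbalanced subject x time grid")
            roi_series[str(roi)] = pivot.to_numpy()
        return cls(roi_series, times, criterion, condition)

    def fit(self) -> "VmmnTestResults":
        """Run the pointwise t tests, the runs criterion and the peak
        measurement; returns a results object."""
        result = detect(self.roi_series, self.times, self.criterion, self.condition)
        peaks: dict[str, dict] = {}
        w0, w1 = self.criterion.search_window
        for roi, series in self.roi_series.items():
            grand = series.mean(axis=0)
            group_peak = measure_peak(grand, self.times, (w0, w1), "negative",
                                      "subject-peak")
            subject_amps = np.array([
                measure_peak(s, self.times, (w0, w1), "negative",
                             "group-peak-centered-mean",
                             group_peak_latency=group_peak.latency).amplitude
                for s in series
            ])
            subject_lats = np.array([
                measure_peak(s, self.times, (w0, w1), "negative",
                             "subject-peak").latency
                for s in series
            ])
            peaks[roi] = {
                "group_peak": group_peak,
                "subject_amplitudes": subject_amps,
                "subject_latencies": subject_lats,
            }
        return VmmnTestResults(self, result, peaks)


class VmmnTestResults:
    """Fitted results of :class:`VmmnTest`.

    Attributes
    ----------
    vmmn_present : bool
        Verdict under the criterion's ROI-combination rule.
    windows : list of SignificantWindow
    tseries : dict roi -> TSeries
    peaks : dict roi -> {'group_peak', 'subject_amplitudes', 'subject_latencies'}
    """

    def __init__(self, model: VmmnTest, result: DetectionResult, peaks: dict):
        self.model = model
        self.detection = result
        self.vmmn_present = result.vmmn_present
        self.windows = result.windows
        self.tseries = result.tseries
        self.peaks = peaks

    def windows_frame(self) -> pd.DataFrame:
        cols = ["group", "category", "soa", "roi", "window_start_ms",
                "window_end_ms", "duration_ms", "polarity"]
        rows = self.detection.to_rows()
        return pd.DataFrame(rows, columns=[c for c in cols
                                           if rows == [] or c in rows[0]])

    def peak_frame(self) -> pd.DataFrame:
        rows = []
        for roi, p in self.peaks.items():
            rows.append({
                **self.model.condition,
                "roi": roi,
                "latency_ms": p["group_peak"].latency,
                "amplitude_uv": float(np.mean(p["subject_amplitudes"])),
                "amplitude_sd": float(np.std(p["subject_amplitudes"], ddof=1)),
                "latency_mean_ms": float(np.mean(p["subject_latencies"])),
                "latency_sd_ms": float(np.std(p["subject_latencies"], ddof=1)),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable account of the test."""
        c = self.model.criterion
        lines = [
            "Runs-based mismatch-negativity test",
            "===================================",
            f"condition: {self.model.condition or 'n/a'}",
            f"subjects:  {self.model.n_subjects} (df = {self.model.n_subjects - 1})",
            f"criterion: >= {c.min_run:g} ms consecutive p < {c.alpha:g} "
            f"({c.tails}-tailed) in {c.search_window[0]:g}-{c.search_window[1]:g} ms, "
            f"{c.require}",
            f"vMMN present: {self.vmmn_present}",
        ]
        if self.windows:
            lines.append("significant windows:")
            for w in self.windows:
                lines.append(f"  {w.roi:>6s}: {w.start:6.1f}-{w.end:6.1f} ms "
                             f"({w.duration:.0f} ms)")
        else:
            lines.append("significant windows: none")
        for roi, p in self.peaks.items():
            gp = p["group_peak"]
            lines.append(
                f"{roi:>6s} peak: {gp.latency:.1f} ms, "
                f"group-centered mean amplitude "
                f"{np.mean(p['subject_amplitudes']):.2f} μV"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<VmmnTestResults present={self.vmmn_present} "
                f"windows={len(self.windows)}>")
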