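"""ERP-level operations: condition averages, opposite-condition
difference waves, ROI pooling and peak measurement.

The opposite-condition subtraction contrasts the ERP to stimulus
category X presented as deviant with the ERP to the *physically
identical* X presented as standard in the sequence where the roles are
swapped; stimulus-specific exogenous activity therefore cancels and
what remains indexes the sequential role of the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyConditionError, LabelError, PairingError, VmmnError
from .preprocessing import EpochSet


@dataclass(frozen=True)
class ROIDef:
    """A named set of electrodes averaged into one virtual channel."""

    name: str
    channels: tuple[str, ...]


#: The analysis ROIs: parieto-occipital pairs on each hemisphere.
DEFAULT_ROIS: dict[str, ROIDef] = {
    "left": ROIDef("left", ("PO7", "PO9")),
    "right": ROIDef("right", ("PO8", "PO10")),
}


@dataclass
class ERPWaveform:
    """Average of retained epochs for one condition."""

    data: np.ndarray  # channels x samples, μV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    time_axis_acquisition: np.ndarray
    time_axis_analysis: np.ndarray
    condition: dict
    n_epochs: int

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV-friendly table: analysis time (ms) × channels."""
        frame = pd.DataFrame(self.data.T, columns=list(self.channel_labels))
        frame.insert(0, "time_ms", self.time_axis_analysis)
        return frame


@dataclass
class DifferenceWave:
    """Deviant-minus-(opposite-condition standard) waveform."""

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float
    time_axis_analysis: np.ndarray
    minuend: dict
    subtrahend: dict
    subject: str | None = None

    @property
    def category(self) -> str:
        return self.minuend["category"]

    @property
    def soa(self) -> float:
        return self.minuend["soa"]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data.T, columns=list(self.channel_labels))
        frame.insert(0, "time_ms", self.time_axis_analysis)
        return frame


@dataclass(frozen=True)
class PeakMeasure:
    """Latency/amplitude of an extremum inside an a-priori window.

    ``method='subject-peak'`` reports the amplitude at the series' own
    extremum; ``'group-peak-centered-mean'`` reports the series mean
    over a 20 ms span centred on a supplied group-average peak latency
    (clipped at the window edges, with the clipping recorded).
    """

    latency: float
    amplitude: float
    window: tuple[float, float]
    polarity: str
    method: str
    span: tuple[float, float] | None = None
    clipped: bool = False


def average(epochs: EpochSet, condition: dict) -> ERPWaveform:
    """Pointwise mean over retained epochs matching ``condition``.

    ``condition`` is a mapping over epoch-info columns, e.g.
    ``{"role": "deviant"}``; variants are pooled unless ``variant`` is
    given explicitly.  All matched epochs must share one SOA so the
    analysis axis is well defined.
    """
    mask = epochs.retained.copy()
    for key, value in condition.items():
        mask &= (epochs.info[key] == value).to_numpy()
    if not mask.any():
        raise EmptyConditionError(f"no retained epochs match condition {condition!r}")
    soas = epochs.info.loc[mask, "soa"].unique()
    if len(soas) > 1:
        raise VmmnError(f"condition {condition!r} mixes SOAs {sorted(soas)}")
    soa = float(soas[0])
    data = epochs.data[mask].mean(axis=0)
    cond = dict(condition)
    cond.setdefault("soa", soa)
    return ERPWaveform(
        data, epochs.channel_labels, epochs.sampling_rate,
        epochs.time_axis_acquisition, epochs.time_axis_acquisition - soa,
        cond, int(mask.sum()),
    )


def difference_wave(deviant_erp: ERPWaveform, opposite_standard_erp: ERPWaveform,
                    subject: str | None = None) -> DifferenceWave:
    """Opposite-condition subtraction for one category and SOA.

    Both operands must describe the same stimulus category and SOA but
    opposite sequential roles; they come from the two sequences in
    which the category's role is swapped.
    """
    a, b = deviant_erp.condition, opposite_standard_erp.condition
    if a.get("role") == b.get("role"):
        raise PairingError("operands must have opposite roles (deviant vs standard)")
    if a.get("category") != b.get("category") or a.get("soa") != b.get("soa"):
        raise PairingError(
            "minuend and subtrahend must share category and SOA; got "
            f"{a!r} vs {b!r}"
        )
    if deviant_erp.channel_labels != opposite_standard_erp.channel_labels:
        raise PairingError("operands recorded on different montages")
    if not np.array_equal(deviant_erp.time_axis_analysis,
                          opposite_standard_erp.time_axis_analysis):
        raise PairingError("operands have different time axes")
    return DifferenceWave(
        deviant_erp.data - opposite_standard_erp.data,
        deviant_erp.channel_labels,
        deviant_erp.sampling_rate,
        deviant_erp.time_axis_analysis,
        minuend=dict(a), subtrahend=dict(b), subject=subject,
    )


def roi_pool(wave, roi: ROIDef) -> np.ndarray:
    """Unweighted per-sample mean over the ROI's channels.

    ``wave`` is any object with ``data`` (channels × samples) and
    ``channel_labels``.
    """
    labels = list(wave.channel_labels)
    try:
        rows = [labels.index(c) for c in roi.channels]
    except ValueError as err:
        raise LabelError(f"ROI {roi.name!r} channel missing from montage: {err}") from None
    return wave.data[rows].mean(axis=0)


def measure_peak(series: np.ndarray, times: np.ndarray,
                 window: tuple[float, float] = (150.0, 300.0),
                 polarity: str = "negative",
                 method: str = "subject-peak",
                 group_peak_latency: float | None = None,
                 span_ms: float = 20.0) -> PeakMeasure:
    """Locate and quantify an extremum inside ``window``.

    Latency is the time of the largest polarity-oriented value within
    the window (ties resolved to the earliest sample).  With
    ``method='group-peak-centered-mean'`` the amplitude is the mean
    over ``[group_peak − span/2, group_peak + span/2]``, clipped to the
    window.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if polarity not in ("positive", "negative"):
        raise VmmnError("polarity must be 'positive' or 'negative'")
    w0, w1 = window
    if w0 < times[0] or w1 > times[-1]:
        raise VmmnError(f"window {window} outside series span "
                        f"[{times[0]:g}, {times[-1]:g}]")
    mask = (times >= w0) & (times <= w1)
    oriented = series[mask] if polarity == "positive" else -series[mask]
    peak_pos = int(np.argmax(oriented))  # argmax takes the earliest tie
    latency = float(times[mask][peak_pos])

    if method == "subject-peak":
        return PeakMeasure(latency, float(series[mask][peak_pos]), window,
                           polarity, method)
    if method != "group-peak-centered-mean":
        raise VmmnError(f"unknown method {method!r}")
    if group_peak_latency is None:
        raise VmmnError("group_peak_latency required for group-peak-centered-mean")
    half = span_ms / 2.0
    s0, s1 = group_peak_latency - half, group_peak_latency + half
    clipped = s0 < w0 or s1 > w1
    s0, s1 = max(s0, w0), min(s1, w1)
    span_mask = (times >= s0) & (times <= s1)
    return PeakMeasure(latency, float(series[span_mask].mean()), window,
                       polarity, method, span=(s0, s1), clipped=clipped)


def peak_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble a report table with the published schema: condition,
    ROI, amplitude (μV), latency (ms)."""
    return pd.DataFrame(rows, columns=["group", "category", "soa", "roi",
                                       "amplitude_uv", "latency_ms"])
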