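"""ERP preprocessing: band-pass filtering, epoching, baseline
correction and amplitude-based artifact rejection.

Conventions
-----------
* Epochs are cut from −100 to +600 ms around fragment-1 onset,
  inclusive of both endpoints (701 samples at 1 kHz).
* Baseline is the pre-stimulus interval [−100, 0] ms relative to
  fragment-1 onset; its per-channel mean is subtracted.
* The *analysis* time axis places 0 ms at fragment-2 onset (the onset
  of deviance), i.e. it is the acquisition axis shifted by the SOA.
* The ±100 μV screen is applied on every channel, EOG included.  The
  phrase "amplitude change exceeding ±100 μV" admits two readings, so
  an epoch is rejected when **either** any absolute sample value
  exceeds the threshold **or** its peak-to-peak range exceeds twice the
  threshold; each sub-criterion can also be selected alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import EpochWindow, FilterSpec
from .exceptions import ConfigurationError
from .recording import RawRecording
from .schedule import TrialSchedule

REJECT_MODES = ("absolute", "peak-to-peak", "both")


def _design_sos(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    spec.validate(sampling_rate)
    return signal.butter(spec.order, [spec.low_cutoff, spec.high_cutoff],
                         btype="bandpass", fs=sampling_rate, output="sos")


def bandpass_filter_array(data: np.ndarray, sampling_rate: float,
                          spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter order is ``rolloff / 6`` (a 24 dB/octave slope → 4th
    order); applying it forward and backward doubles the effective
    attenuation and cancels the phase response.
    """
    sos = _design_sos(spec or FilterSpec(), sampling_rate)
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_filter(recording: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Filter a recording, returning a new :class:`RawRecording`."""
    filtered = bandpass_filter_array(recording.data, recording.sampling_rate, spec)
    return RawRecording(recording.channel_labels, recording.sampling_rate,
                        filtered, recording.schedule, dict(recording.meta))


@dataclass
class Epoch:
    """One baseline-corrected trial with both time conventions."""

    data: np.ndarray  # channels x samples, μV
    time_axis_acquisition: np.ndarray  # ms relative to fragment-1 onset
    time_axis_analysis: np.ndarray  # ms relative to fragment-2 onset
    condition: dict
    rejected: bool = False
    rejection_reason: str | None = None


@dataclass
class EpochSet:
    """Stack of epochs from one (or several pooled) sequences.

    ``data`` is (n_epochs, n_channels, n_samples); ``info`` carries one
    row per epoch (role, category, variant, soa, rejected, reason).
    All epochs share the acquisition axis; the analysis axis is the
    acquisition axis shifted by each epoch's SOA.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float
    time_axis_acquisition: np.ndarray
    info: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> Epoch:
        row = self.info.iloc[i]
        return Epoch(
            data=self.data[i],
            time_axis_acquisition=self.time_axis_acquisition,
            time_axis_analysis=self.time_axis_acquisition - row["soa"],
            condition={k: row[k] for k in ("role", "category", "variant", "soa")},
            rejected=bool(row["rejected"]),
            rejection_reason=row["reason"] if row["reason"] else None,
        )

    @property
    def retained(self) -> np.ndarray:
        return ~self.info["rejected"].to_numpy()

    def counts(self) -> pd.DataFrame:
        """Epoch counts per (role, category, soa) before/after rejection."""
        g = self.info.groupby(["role", "category", "soa"], observed=True)
        out = g.agg(n_total=("rejected", "size"),
                    n_retained=("rejected", lambda r: int((~r).sum())))
        return out.reset_index()

    def concat(self, other: "EpochSet") -> "EpochSet":
        if self.channel_labels != other.channel_labels:
            raise ConfigurationError("cannot pool epochs over different montages")
        if not np.array_equal(self.time_axis_acquisition, other.time_axis_acquisition):
            raise ConfigurationError("cannot pool epochs over different windows")
        return EpochSet(
            np.concatenate([self.data, other.data], axis=0),
            self.channel_labels,
            self.sampling_rate,
            self.time_axis_acquisition,
            pd.concat([self.info, other.info], ignore_index=True),
            {"pooled_from": [self.provenance, other.provenance]},
        )

    # -- persistence (HDF5 container + CSV rejection log) -----------------
    def to_hdf5(self, path: str | Path) -> Path:
        import h5py

        path = Path(path)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data, compression="gzip")
            fh.create_dataset("time_axis_acquisition", data=self.time_axis_acquisition)
            fh.attrs["sampling_rate"] = self.sampling_rate
            fh.attrs["channel_labels"] = list(self.channel_labels)
            fh.attrs["info_csv"] = self.info.to_csv(index=False)
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochSet":
        import io

        import h5py

        with h5py.File(path, "r") as fh:
            info = pd.read_csv(io.StringIO(fh.attrs["info_csv"]))
            info["reason"] = info["reason"].fillna("") if "reason" in info else ""
            return cls(
                fh["data"][()],
                tuple(str(c) for c in fh.attrs["channel_labels"]),
                float(fh.attrs["sampling_rate"]),
                fh["time_axis_acquisition"][()],
                info,
            )

    def rejection_log(self, path: str | Path | None = None) -> pd.DataFrame:
        log = self.info[self.info["rejected"]][["index", "role", "category", "soa", "reason"]]
        if path is not None:
            log.to_csv(path, index=False)
        return log


def segment(recording: RawRecording, schedule: TrialSchedule | None = None,
            window: EpochWindow | None = None) -> EpochSet:
    """Cut one epoch per stimulus event and baseline-correct it.

    Epochs are inclusive of both window endpoints; at 1 kHz the default
    −100..+600 ms window yields 701 samples.  Events whose window falls
    outside the recording are kept (as zeros) but flagged rejected with
    reason ``"out-of-bounds"``.
    """
    schedule = schedule or recording.schedule
    if schedule is None:
        raise ConfigurationError("no schedule attached to the recording or given")
    window = window or EpochWindow()
    fs = recording.sampling_rate
    dt = 1000.0 / fs
    n_epoch = round((window.end - window.start) / dt) + 1
    time_axis = window.start + dt * np.arange(n_epoch)

    baseline_mask = (time_axis >= window.baseline[0]) & (time_axis <= window.baseline[1])
    if not baseline_mask.any():
        raise ConfigurationError("baseline interval contains no samples")

    n_ch = len(recording.channel_labels)
    data = np.zeros((len(schedule.events), n_ch, n_epoch))
    starts = np.array([round(ev.onset_fragment1 * fs / 1000.0) for ev in schedule.events],
                      dtype=np.int64) + round(window.start / dt)
    in_bounds = (starts >= 0) & (starts + n_epoch <= recording.n_samples)
    if in_bounds.any():
        gather = starts[in_bounds][:, None] + np.arange(n_epoch)
        cut = recording.data[:, gather]  # (ch, n_valid, n_epoch)
        cut = np.moveaxis(cut, 0, 1)
        data[in_bounds] = cut - cut[:, :, baseline_mask].mean(axis=2, keepdims=True)
    rows = [{"index": ev.index, "role": ev.role, "category": ev.category,
             "variant": ev.variant, "soa": ev.soa,
             "rejected": not ok, "reason": "" if ok else "out-of-bounds"}
            for ev, ok in zip(schedule.events, in_bounds)]

    return EpochSet(
        data, recording.channel_labels, fs, time_axis,
        pd.DataFrame(rows),
        provenance={
            "sequence_id": schedule.sequence_id,
            "window": (window.start, window.end),
            "baseline": window.baseline,
        },
    )


def reject_artifacts(epochs: EpochSet, threshold: float = 100.0,
                     mode: str = "both") -> EpochSet:
    """Flag epochs whose amplitude exceeds the screen on any channel.

    ``mode='absolute'`` rejects when any \\|sample\\| > threshold;
    ``mode='peak-to-peak'`` when (max − min) > 2·threshold on a
    channel; ``mode='both'`` (default) when either holds.  Previously
    flagged epochs (e.g. out-of-bounds) stay flagged.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if mode not in REJECT_MODES:
        raise ConfigurationError(f"mode must be one of {REJECT_MODES}")

    abs_exceeds = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    ptp_exceeds = ptp.max(axis=1) > 2.0 * threshold
    if mode == "absolute":
        hit = abs_exceeds
    elif mode == "peak-to-peak":
        hit = ptp_exceeds
    else:
        hit = abs_exceeds | ptp_exceeds

    info = epochs.info.copy()
    newly = hit & ~info["rejected"].to_numpy()
    info.loc[newly, "rejected"] = True
    reasons = np.where(abs_exceeds, "amplitude>threshold", "peak-to-peak>2*threshold")
    info.loc[newly, "reason"] = reasons[newly]

    provenance = dict(epochs.provenance)
    provenance.update({"rejection_threshold": threshold, "rejection_mode": mode})
    return EpochSet(epochs.data, epochs.channel_labels, epochs.sampling_rate,
                    epochs.time_axis_acquisition, info, provenance)


def preprocess(recording: RawRecording, schedule: TrialSchedule | None = None,
               filter_spec: FilterSpec | None = None,
               window: EpochWindow | None = None,
               reject_threshold: float = 100.0) -> EpochSet:
    """Filter → segment → reject, the standard chain."""
    filtered = bandpass_filter(recording, filter_spec)
    return reject_artifacts(segment(filtered, schedule, window), reject_threshold)
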