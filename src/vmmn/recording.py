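"""Synthetic multichannel EEG: forward model and raw-recording I/O.

The forward model is deliberately simple and fully linear: the
recording is the sum of per-event component waveforms (Gaussian pulses
scaled by a per-channel topography) over 1/f background noise.  The
mismatch component is injected for a deviant event only when the
condition's SOA does not exceed the group's persistence limit for the
deviant's category — this is the generative twin of the
temporal-integration hypothesis the analysis is meant to recover.

Recordings are written as plain EDF (16-bit, one-second records; the
writer lives here because no EDF-export library ships with the stack)
and read back through :func:`mne.io.read_raw_edf`.  An ``.npz`` array
form is provided for fast intermediate storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import channels as chan
from .config import ComponentSpec, FilterSpec, GroupProfile
from .exceptions import ConfigurationError
from .schedule import TrialSchedule


@dataclass
class RawRecording:
    """A multichannel time series in μV with its stimulus schedule."""

    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray  # channels x samples, μV
    schedule: TrialSchedule | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ConfigurationError("data must be (n_channels, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise chan.LabelError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


def pink_noise(n_channels: int, n_samples: int, sampling_rate: float,
               exponent: float, rng: np.random.Generator,
               f_floor: float = 0.1) -> np.ndarray:
    """Unit-RMS noise with power spectral density ∝ f^-exponent.

    Synthesised in the frequency domain with independent complex
    Gaussian coefficients shaped by f^(-exponent/2); the spectrum is
    flattened below ``f_floor`` so total power stays finite, and DC is
    zero.  Each channel is independent and normalised to RMS 1.
    """
    from scipy.fft import irfft, next_fast_len

    n_fft = next_fast_len(n_samples)  # pad awkward lengths, then slice
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    coeff = rng.normal(size=(n_channels, freqs.size)) + 1j * rng.normal(size=(n_channels, freqs.size))
    series = irfft(coeff * shape, n=n_fft, axis=1)[:, :n_samples]
    rms = np.sqrt(np.mean(series ** 2, axis=1, keepdims=True))
    return series / rms


def _component_kernel(spec: ComponentSpec, sampling_rate: float,
                      n_sd: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample offsets (relative to the locked onset) and waveform values
    of one Gaussian component, truncated at ±n_sd standard deviations."""
    dt = 1000.0 / sampling_rate
    k0 = round((spec.peak_latency - n_sd * spec.width) / dt)
    k1 = round((spec.peak_latency + n_sd * spec.width) / dt)
    offsets = np.arange(k0, k1 + 1)
    t = offsets * dt
    kernel = spec.amplitude * np.exp(-((t - spec.peak_latency) ** 2) / (2.0 * spec.width ** 2))
    return offsets, kernel


def _component_applies(spec: ComponentSpec, profile: GroupProfile,
                       role: str, category: str, soa: float) -> bool:
    if spec.conditions is not None:
        return bool(spec.conditions(role, category, soa, profile.group))
    if spec.mismatch:
        limit = profile.persistence_limit(category)
        return role == "deviant" and limit >= 0 and soa <= limit
    return True


def generate_recording(schedule: TrialSchedule, profile: GroupProfile,
                       seed: int | np.random.SeedSequence,
                       channel_labels: tuple[str, ...] | None = None,
                       pad_ms: float = 800.0) -> RawRecording:
    """Simulate one raw oddball recording from a schedule and a group
    profile.

    The output is ``noise + Σ_events Σ_components topography ⊗ kernel``:
    per-channel independent 1/f noise of RMS ``profile.noise_amplitude``
    plus, for every stimulus event, each component whose conditions
    predicate holds.  Exogenous components are locked to fragment-1
    onset, the mismatch component to fragment-2 onset.  Deterministic
    for a fixed seed.

    ``channel_labels`` defaults to the full 39-channel montage; passing
    a subset (e.g. only the ROI electrodes) simulates a cheaper
    recording with identical statistics on the retained channels.
    """
    labels = tuple(channel_labels) if channel_labels is not None else chan.ALL_CHANNELS
    chan.validate_channels(labels)
    fs = schedule.sampling_rate
    last = schedule.events[-1]
    n_samples = round((last.onset_fragment2 + schedule.fragment_duration + pad_ms) * fs / 1000.0)

    rng = np.random.default_rng(seed)
    data = np.zeros((len(labels), n_samples))
    if profile.noise_amplitude > 0:
        noise = pink_noise(len(labels), n_samples, fs, profile.noise_exponent, rng)
        if profile.spatial_mixing is not None:
            mix = np.asarray(profile.spatial_mixing, dtype=float)
            if mix.shape != (len(labels), len(labels)):
                raise ConfigurationError("spatial_mixing must be (n_channels, n_channels)")
            noise = mix @ noise
        data += profile.noise_amplitude * noise

    label_index = {c: i for i, c in enumerate(labels)}
    for spec in profile.component_specs:
        gains = np.zeros(len(labels))
        touched = False
        for ch_label, g in spec.topography.items():
            if ch_label in label_index:
                gains[label_index[ch_label]] = g
                touched = True
        if not touched:
            continue
        offsets, kernel = _component_kernel(spec, fs)
        for ev in schedule.events:
            if not _component_applies(spec, profile, ev.role, ev.category, ev.soa):
                continue
            onset = ev.onset_fragment1 if spec.lock == "fragment1" else ev.onset_fragment2
            scale = profile.mismatch_amplitude_scale(ev.soa) if spec.mismatch else 1.0
            s0 = round(onset * fs / 1000.0)
            idx = s0 + offsets
            valid = (idx >= 0) & (idx < n_samples)
            data[:, idx[valid]] += scale * np.outer(gains, kernel[valid])

    if profile.blink_rate_hz > 0:
        _inject_blinks(data, labels, fs, profile.blink_rate_hz, rng)

    return RawRecording(labels, fs, data, schedule,
                        meta={"group": profile.group})


def _inject_blinks(data: np.ndarray, labels: tuple[str, ...], fs: float,
                   rate_hz: float, rng: np.random.Generator,
                   amplitude: float = 200.0, width_ms: float = 60.0) -> None:
    """Optional ocular artifacts: large frontal Gaussian transients, for
    exercising the rejection stage."""
    n_samples = data.shape[1]
    n_blinks = rng.poisson(rate_hz * n_samples / fs)
    gains = np.array([chan.BLINK_TOPOGRAPHY.get(c, 0.0) for c in labels])
    half = round(4 * width_ms * fs / 1000.0)
    offsets = np.arange(-half, half + 1)
    t = offsets * 1000.0 / fs
    kernel = amplitude * np.exp(-(t ** 2) / (2.0 * width_ms ** 2))
    for center in rng.integers(0, n_samples, size=n_blinks):
        idx = center + offsets
        valid = (idx >= 0) & (idx < n_samples)
        data[:, idx[valid]] += np.outer(gains, kernel[valid])


def simulate_null_difference_waves(
    n_subjects: int,
    n_channels: int,
    epoch_samples: int,
    profile: GroupProfile,
    seed: int | np.random.SeedSequence,
    n_deviant_epochs: int = 100,
    n_standard_epochs: int = 400,
    filter_spec: FilterSpec | None = None,
    sampling_rate: float = 1000.0,
    baseline_samples: int = 101,
) -> np.ndarray:
    """Subject-level difference waves under the null (no mismatch).

    The average of ``m`` independent noise epochs is noise with the same
    spectrum scaled by 1/√m, so a subject's deviant-minus-standard
    residual is simulated directly as 1/f noise with RMS
    ``noise_amplitude · sqrt(1/m_dev + 1/m_std)``, band-pass filtered
    with the default analysis filter and baseline-corrected — the
    spectral shape and scale a noise-only pipeline run would deliver,
    at a fraction of the cost.

    Returns an array (n_subjects, n_channels, epoch_samples) in μV.
    """
    from .preprocessing import bandpass_filter_array

    spec = filter_spec or FilterSpec()
    rng = np.random.default_rng(seed)
    sigma = profile.noise_amplitude * np.sqrt(1.0 / n_deviant_epochs + 1.0 / n_standard_epochs)
    # Simulate a longer stretch and cut the centre so filter edge
    # effects do not concentrate inside the epoch.
    pad = epoch_samples
    total = epoch_samples + 2 * pad
    out = np.empty((n_subjects, n_channels, epoch_samples))
    for s in range(n_subjects):
        trace = sigma * pink_noise(n_channels, total, sampling_rate,
                                   profile.noise_exponent, rng)
        trace = bandpass_filter_array(trace, sampling_rate, spec)
        segment = trace[:, pad:pad + epoch_samples]
        segment = segment - segment[:, :baseline_samples].mean(axis=1, keepdims=True)
        out[s] = segment
    return out


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: RawRecording, path: str | Path,
              startdate: str = "01.01.00", starttime: str = "00.00.00") -> Path:
    """Write a recording as a plain EDF file (16-bit, 1 s data records).

    Physical units are μV; the final record is zero-padded to a whole
    second, so readers may return up to one second of trailing zeros
    beyond ``recording.n_samples``.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_records = int(np.ceil(recording.n_samples / spr))
    n_sig = len(recording.channel_labels)

    padded = np.zeros((n_sig, n_records * spr))
    padded[:, :recording.n_samples] = recording.data
    phys_max = float(np.max(np.abs(padded)))
    phys_max = max(np.ceil(phys_max), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.clip(np.round((padded + phys_max) * scale) + dig_min,
                      dig_min, dig_max).astype("<i2")

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_pad(startdate, 8))
        fh.write(_pad(starttime, 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_sig), 4))
        for label in recording.channel_labels:
            prefix = "EEG" if label not in chan.EOG_CHANNELS else "EOG"
            fh.write(_pad(f"{prefix} {label}", 16))
        for _ in range(n_sig):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_sig):
            fh.write(_pad("uV", 8))
        for _ in range(n_sig):
            fh.write(_pad(f"{-phys_max:g}", 8))
        for _ in range(n_sig):
            fh.write(_pad(f"{phys_max:g}", 8))
        for _ in range(n_sig):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(n_sig):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(n_sig):
            fh.write(_pad("", 80))
        for _ in range(n_sig):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_sig):
            fh.write(_pad("", 32))
        # Data records: record-major, signal-major within a record.
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, schedule: TrialSchedule | None = None) -> RawRecording:
    """Read an EDF recording via :mod:`mne` and return it in μV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(name.split()[-1] for name in raw.ch_names)
    data = raw.get_data() * 1e6  # volts -> μV
    return RawRecording(labels, float(raw.info["sfreq"]), data, schedule)


def save_npz(recording: RawRecording, path: str | Path) -> Path:
    """Internal array format for fast intermediate storage."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=recording.data,
        channel_labels=np.array(recording.channel_labels),
        sampling_rate=recording.sampling_rate,
    )
    return path


def load_npz(path: str | Path, schedule: TrialSchedule | None = None) -> RawRecording:
    with np.load(path, allow_pickle=False) as payload:
        return RawRecording(
            tuple(str(c) for c in payload["channel_labels"]),
            float(payload["sampling_rate"]),
            payload["data"],
            schedule,
        )
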