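"""Configuration dataclasses for the oddball session, the synthetic
forward model, preprocessing and detection.

Defaults reproduce the study design: 250-trial oddball sequences with
deviant probability 0.2 split evenly over two stimulus variants, 30 ms
character fragments at SOAs of 0/30/50/70 ms, 600 ± 50 ms inter-trial
intervals, a frame-thickening task whose 300 ms events occur every
5–15 s, and 1000 Hz acquisition over the extended 10-20 montage.

Group profiles encode the temporal-integration behaviour observed per
age group as a *persistence limit*: the largest SOA (ms) at which a
deviant of a given category still elicits a mismatch response.  ``-1``
means the category never does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from . import channels
from .exceptions import ConfigurationError

Predicate = Callable[[str, str, float, str], bool]  # (role, category, soa, group)


@dataclass(frozen=True)
class SessionConfig:
    """Design parameters of one recording session.

    All times are milliseconds; ``sampling_rate`` is Hz.
    """

    n_trials_per_sequence: int = 250
    deviant_prob: float = 0.2
    n_variants_per_role: int = 2
    soa_levels: tuple[float, ...] = (0.0, 30.0, 50.0, 70.0)
    fragment_duration: float = 30.0
    iti_mean: float = 600.0
    iti_jitter: float = 50.0
    n_sequences: int = 16
    task_event_mean_interval: float = 10_000.0
    task_event_interval_range: tuple[float, float] = (5_000.0, 15_000.0)
    task_event_duration: float = 300.0
    sampling_rate: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.deviant_prob < 0.5:
            raise ConfigurationError("deviant_prob must lie in (0, 0.5)")
        n_dev = self.n_trials_per_sequence * self.deviant_prob
        if abs(n_dev - round(n_dev)) > 1e-9:
            raise ConfigurationError(
                "exact-count design: n_trials_per_sequence * deviant_prob "
                f"must be an integer, got {n_dev!r}"
            )
        if self.iti_jitter >= self.iti_mean:
            raise ConfigurationError("iti_jitter must be smaller than iti_mean")
        if list(self.soa_levels) != sorted(self.soa_levels):
            raise ConfigurationError("soa_levels must be sorted ascending")
        lo, hi = self.task_event_interval_range
        if not lo <= self.task_event_mean_interval <= hi:
            raise ConfigurationError("task_event_mean_interval outside its range")

    @property
    def n_deviants(self) -> int:
        return round(self.n_trials_per_sequence * self.deviant_prob)

    @property
    def n_standards(self) -> int:
        return self.n_trials_per_sequence - self.n_deviants


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component of the forward model.

    ``peak_latency`` is relative to the onset the component is locked
    to: fragment 1 for exogenous components (``lock='fragment1'``),
    fragment 2 — the change onset — for the mismatch response
    (``lock='fragment2'``).  ``width`` is the Gaussian SD in ms and
    ``topography`` maps channel labels to gains in [0, 1].

    ``mismatch=True`` marks the component as deviance-related: it is
    injected only for deviant events whose SOA does not exceed the
    group's persistence limit for the deviant's category.  A custom
    ``conditions`` predicate over ``(role, category, soa, group)`` may
    replace that rule entirely.
    """

    name: str
    peak_latency: float
    amplitude: float
    width: float
    topography: Mapping[str, float]
    lock: str = "fragment1"
    mismatch: bool = False
    conditions: Predicate | None = None

    def __post_init__(self) -> None:
        channels.validate_channels(self.topography)
        if self.lock not in ("fragment1", "fragment2"):
            raise ConfigurationError("lock must be 'fragment1' or 'fragment2'")
        if self.name == "vMMN":
            if self.amplitude >= 0:
                raise ConfigurationError("vMMN amplitude must be negative")
            if not 150.0 <= self.peak_latency <= 300.0:
                raise ConfigurationError("vMMN peak latency must lie in 150-300 ms")


@dataclass(frozen=True)
class GroupProfile:
    """Generative profile of one age group.

    ``persistence_limit_*`` give the largest SOA (ms, a member of the
    session's SOA levels) at which a deviant of that category still
    produces the mismatch component; ``-1`` disables it.  Noise is
    per-channel 1/f background with RMS ``noise_amplitude`` (μV) and
    log-log spectral slope ``-noise_exponent``.

    ``soa_decay_constant``, when set, scales the mismatch amplitude by
    ``exp(-soa / soa_decay_constant)`` instead of the all-or-none rule
    being the only SOA dependence (the gate still applies).
    """

    group: str
    persistence_limit_letter: float
    persistence_limit_pseudo: float
    component_specs: tuple[ComponentSpec, ...]
    noise_amplitude: float = 10.0
    noise_exponent: float = 1.0
    soa_decay_constant: float | None = None
    blink_rate_hz: float = 0.0
    spatial_mixing: object | None = None  # optional channels x channels matrix

    def persistence_limit(self, category: str) -> float:
        if category == "letter":
            return self.persistence_limit_letter
        if category == "pseudo-letter":
            return self.persistence_limit_pseudo
        raise ConfigurationError(f"unknown category {category!r}")

    def mismatch_amplitude_scale(self, soa: float) -> float:
        import math

        if self.soa_decay_constant is None:
            return 1.0
        return math.exp(-soa / self.soa_decay_constant)


def _exogenous_specs(p1_amp: float, p1_lat: float, n1_amp: float, n1_lat: float,
                     n1_width: float) -> tuple[ComponentSpec, ...]:
    return (
        ComponentSpec("P1", p1_lat, p1_amp, 12.0, channels.P1_TOPOGRAPHY),
        ComponentSpec("N1", n1_lat, n1_amp, n1_width, channels.N1_TOPOGRAPHY),
    )


def young_profile(**overrides) -> GroupProfile:
    """Default young-adult profile.

    Mismatch response only for pseudo-letter deviants in the
    whole-character (SOA 0) condition; exogenous P1/N1 around 106 and
    185 ms.
    """
    specs = _exogenous_specs(2.3, 106.0, -4.0, 185.0, 18.0) + (
        ComponentSpec("vMMN", 235.0, -1.0, 30.0, channels.VMMN_TOPOGRAPHY,
                      lock="fragment2", mismatch=True),
    )
    profile = GroupProfile(
        group="young",
        persistence_limit_letter=-1.0,
        persistence_limit_pseudo=0.0,
        component_specs=specs,
    )
    return replace(profile, **overrides) if overrides else profile


def older_profile(**overrides) -> GroupProfile:
    """Default older-adult profile.

    Longer stimulus persistence: letter deviants integrate only at
    SOA 0, pseudo-letter deviants up to SOA 50 ms.  The N1 is broader
    and earlier than in the young profile.
    """
    specs = _exogenous_specs(3.0, 110.0, -3.7, 177.0, 25.0) + (
        ComponentSpec("vMMN", 245.0, -1.0, 30.0, channels.VMMN_TOPOGRAPHY,
                      lock="fragment2", mismatch=True),
    )
    profile = GroupProfile(
        group="older",
        persistence_limit_letter=0.0,
        persistence_limit_pseudo=50.0,
        component_specs=specs,
    )
    return replace(profile, **overrides) if overrides else profile


DEFAULT_PROFILES = {"young": young_profile, "older": older_profile}


@dataclass(frozen=True)
class FilterSpec:
    """Offline band-pass: 0.1–30 Hz with a 24 dB/octave roll-off."""

    low_cutoff: float = 0.1
    high_cutoff: float = 30.0
    rolloff: float = 24.0  # dB per octave; order = rolloff / 6

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not 0.0 < self.low_cutoff < self.high_cutoff < nyquist:
            raise ConfigurationError(
                f"cutoffs ({self.low_cutoff}, {self.high_cutoff}) invalid for "
                f"sampling rate {sampling_rate} Hz"
            )

    @property
    def order(self) -> int:
        order = self.rolloff / 6.0
        if abs(order - round(order)) > 1e-9 or order < 1:
            raise ConfigurationError("rolloff must be a positive multiple of 6 dB/octave")
        return round(order)


@dataclass(frozen=True)
class EpochWindow:
    """Epoch limits in ms relative to fragment-1 onset.

    ``analysis_zero='fragment2'`` re-expresses the time axis relative to
    the second fragment (the change onset) for statistics, so an epoch
    cut at acquisition times [-100, 600] around an SOA-50 event spans
    analysis times [-150, 550].
    """

    start: float = -100.0
    end: float = 600.0
    baseline: tuple[float, float] = (-100.0, 0.0)
    analysis_zero: str = "fragment2"

    def __post_init__(self) -> None:
        if self.end <= 0:
            raise ConfigurationError("window end must be positive")
        b0, b1 = self.baseline
        if not (self.start <= b0 < b1 <= 0.0):
            raise ConfigurationError("baseline must lie within [start, 0]")
        if self.analysis_zero not in ("fragment1", "fragment2"):
            raise ConfigurationError("analysis_zero must be 'fragment1' or 'fragment2'")


@dataclass(frozen=True)
class DetectionCriterion:
    """Runs criterion: ≥ ``min_run`` ms of consecutive pointwise
    significance (p < ``alpha``) inside ``search_window``, in at least
    one ROI (``require='any-roi'``) or in all of them."""

    alpha: float = 0.05
    min_run: float = 20.0
    search_window: tuple[float, float] = (150.0, 300.0)
    tails: str = "two"
    require: str = "any-roi"
    #: 'negative' counts only negative-going runs toward presence (a
    #: mismatch response is a negativity by definition); 'any' counts
    #: every significant run.
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.min_run <= 0:
            raise ConfigurationError("min_run must be positive")
        if self.tails not in ("two", "one"):
            raise ConfigurationError("tails must be 'two' or 'one'")
        if self.require not in ("any-roi", "all-roi"):
            raise ConfigurationError("require must be 'any-roi' or 'all-roi'")
        if self.polarity not in ("negative", "any"):
            raise ConfigurationError("polarity must be 'negative' or 'any'")


@dataclass(frozen=True)
class Psychometric2AFC:
    """Two-alternative forced-choice performance model.

    Accuracy decays exponentially from ``p_correct_at_min_soa`` at the
    shortest SOA toward chance (0.5) with time constant
    ``decay_constant`` (ms); ``lapse_rate`` mixes in stimulus-independent
    guessing.  The defaults emulate near-ceiling integration at 30 ms
    falling to chance by 50 ms.
    """

    n_trials: int = 164
    soa_levels: tuple[float, ...] = (30.0, 50.0, 70.0)
    p_correct_at_min_soa: float = 0.9
    decay_constant: float = 10.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_correct_at_min_soa <= 1.0:
            raise ConfigurationError("p_correct_at_min_soa must lie in [0.5, 1]")
        if self.decay_constant <= 0:
            raise ConfigurationError("decay_constant must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ConfigurationError("lapse_rate must lie in [0, 1]")

    def p_correct(self, soa: float) -> float:
        """Modelled probability correct at ``soa`` ms; in [0.5, 1] and
        non-increasing in SOA."""
        import math

        base = 0.5 + (self.p_correct_at_min_soa - 0.5) * math.exp(
            -(soa - min(self.soa_levels)) / self.decay_constant
        )
        return (1.0 - self.lapse_rate) * base + self.lapse_rate * 0.5
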