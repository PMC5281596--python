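"""Constrained oddball stimulus scheduling.

A sequence is a stream of character *pairs* (two 30 ms fragments,
separated by the condition's SOA; at SOA 0 the whole character is shown
at once).  Deviants occur with an exact count (probability × length),
are separated by at least two standards, and the two variants of each
role appear equally often.  Task events (frame thickenings) are placed
every 5–15 s, balanced over the four frame sides, and never overlap a
deviant pair nor the standard pair immediately preceding it.

All times are milliseconds from sequence start.  Schedules serialize to
JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .config import SessionConfig
from .exceptions import ConfigurationError, ConstraintError

ROLES = ("standard", "deviant")
CATEGORIES = ("letter", "pseudo-letter")
TASK_SIDES = ("top", "bottom", "left", "right")

#: Leading trials that are forced to be standards so the "last standard
#: before the deviant" is always defined and regularity can build up.
MIN_LEADING_STANDARDS = 2
#: Minimum number of standards between consecutive deviants.
MIN_STANDARD_GAP = 2


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus pair: role/category/variant plus fragment timing."""

    index: int
    onset_fragment1: float
    onset_fragment2: float
    role: str
    category: str
    variant: int
    fragmentation: int
    soa: float


@dataclass(frozen=True)
class TaskEvent:
    """One frame-thickening event the participant responds to."""

    onset: float
    side: str
    duration: float


@dataclass
class TrialSchedule:
    """Complete stimulus and task timeline of one oddball sequence."""

    sequence_id: str
    soa: float
    deviant_category: str
    fragment_duration: float
    sampling_rate: float
    events: list[StimulusEvent]
    task_events: list[TaskEvent]

    @property
    def n_deviants(self) -> int:
        return sum(e.role == "deviant" for e in self.events)

    @property
    def duration_ms(self) -> float:
        """Span from sequence start to the end of the last presentation,
        plus one mean ITI of tail."""
        last = self.events[-1]
        return last.onset_fragment2 + self.fragment_duration + 600.0

    def stimulus_interval(self, event: StimulusEvent) -> tuple[float, float]:
        """Half-open presentation interval [fragment-1 onset, fragment-2
        offset) of one stimulus pair."""
        return event.onset_fragment1, event.onset_fragment2 + self.fragment_duration

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sequence_id": self.sequence_id,
            "soa": self.soa,
            "deviant_category": self.deviant_category,
            "fragment_duration": self.fragment_duration,
            "sampling_rate": self.sampling_rate,
            "events": [asdict(e) for e in self.events],
            "task_events": [asdict(t) for t in self.task_events],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrialSchedule":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            sequence_id=payload["sequence_id"],
            soa=payload["soa"],
            deviant_category=payload["deviant_category"],
            fragment_duration=payload["fragment_duration"],
            sampling_rate=payload["sampling_rate"],
            events=[StimulusEvent(**e) for e in payload["events"]],
            task_events=[TaskEvent(**t) for t in payload["task_events"]],
        )


def _deviant_positions(n_trials: int, n_deviants: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample deviant trial indices with the gap constraints.

    Valid configurations are strictly increasing indices ``x`` with
    ``x[0] >= MIN_LEADING_STANDARDS`` and ``x[i+1] - x[i] >= MIN_STANDARD_GAP+1``.
    Subtracting ``(MIN_STANDARD_GAP+1)*i`` from ``x[i]`` maps them
    bijectively onto plain increasing sequences, which are sampled by a
    uniform choice without replacement.
    """
    step = MIN_STANDARD_GAP + 1
    lo = MIN_LEADING_STANDARDS
    hi = n_trials - 1 - step * (n_deviants - 1)
    n_free = hi - lo + 1
    if n_free < n_deviants:
        raise ConstraintError(
            f"cannot place {n_deviants} deviants with >= {MIN_STANDARD_GAP} "
            f"standards between them in {n_trials} trials"
        )
    compressed = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_deviants, replace=False))
    return compressed + step * np.arange(n_deviants)


def _balanced_variants(n: int, n_variants: int, rng: np.random.Generator) -> np.ndarray:
    """Variant labels 1..n_variants, each appearing n//n_variants (+1 for
    the first n % n_variants variants) times, in random order."""
    base, extra = divmod(n, n_variants)
    labels = np.concatenate(
        [np.full(base + (1 if v <= extra else 0), v) for v in range(1, n_variants + 1)]
    )
    rng.shuffle(labels)
    return labels


def _exclusion_zones(events: list[StimulusEvent], fragment_duration: float) -> list[tuple[float, float]]:
    """Intervals a task event may not overlap: each deviant pair's
    presentation together with the presentation of the preceding
    standard (merged into one zone per deviant)."""
    zones = []
    for i, ev in enumerate(events):
        if ev.role != "deviant":
            continue
        prev = events[i - 1]
        zones.append((prev.onset_fragment1, ev.onset_fragment2 + fragment_duration))
    return zones


def _place_task_events(config: SessionConfig, events: list[StimulusEvent],
                       seq_end: float, rng: np.random.Generator) -> list[TaskEvent]:
    zones = _exclusion_zones(events, config.fragment_duration)
    lo, hi = config.task_event_interval_range
    dur = config.task_event_duration
    sides: list[str] = []
    placed: list[TaskEvent] = []
    t = float(rng.uniform(lo, hi))
    while t + dur <= seq_end:
        shifted = True
        while shifted:
            shifted = False
            for z0, z1 in zones:
                if t < z1 and t + dur > z0:  # overlap
                    t = z1
                    shifted = True
        if t + dur > seq_end:
            break
        if not sides:
            block = list(TASK_SIDES)
            rng.shuffle(block)
            sides = block
        placed.append(TaskEvent(onset=t, side=sides.pop(), duration=dur))
        t += float(rng.uniform(lo, hi))
    if not placed:
        raise ConstraintError(
            "task-event placement infeasible: exclusion zones cover the sequence"
        )
    return placed


def generate_schedule(config: SessionConfig, soa: float, deviant_category: str,
                      seed: int | np.random.SeedSequence,
                      sequence_id: str | None = None) -> TrialSchedule:
    """Generate one constrained oddball sequence.

    Parameters
    ----------
    config
        Session design; ``n_trials_per_sequence * deviant_prob`` must be
        an integer (validated at construction).
    soa
        Fragment onset asynchrony in ms; must be one of
        ``config.soa_levels``.  At 0 the character appears whole.
    deviant_category
        ``'letter'`` or ``'pseudo-letter'``; standards take the other
        category.
    seed
        Any ``numpy`` seed; a fixed seed reproduces the schedule exactly.

    Returns
    -------
    TrialSchedule
        Satisfies the exact deviant count, balanced variants (±1),
        the ≥2-standard gap between deviants, and the task-event
        placement rules.
    """
    if soa not in config.soa_levels:
        raise ConfigurationError(f"soa {soa} not in configured levels {config.soa_levels}")
    if deviant_category not in CATEGORIES:
        raise ConfigurationError(f"unknown deviant_category {deviant_category!r}")
    standard_category = CATEGORIES[1 - CATEGORIES.index(deviant_category)]

    rng = np.random.default_rng(seed)
    n = config.n_trials_per_sequence
    n_dev = config.n_deviants

    dev_idx = set(_deviant_positions(n, n_dev, rng).tolist())
    dev_variants = iter(_balanced_variants(n_dev, config.n_variants_per_role, rng))
    std_variants = iter(_balanced_variants(n - n_dev, config.n_variants_per_role, rng))
    fragmentations = rng.integers(1, 6, size=n)

    # Inter-onset intervals, the first measured from sequence start.
    itis = rng.uniform(config.iti_mean - config.iti_jitter,
                       config.iti_mean + config.iti_jitter, size=n)
    onsets = np.cumsum(itis)

    events = []
    for i in range(n):
        deviant = i in dev_idx
        events.append(StimulusEvent(
            index=i,
            onset_fragment1=float(onsets[i]),
            onset_fragment2=float(onsets[i] + soa),
            role="deviant" if deviant else "standard",
            category=deviant_category if deviant else standard_category,
            variant=int(next(dev_variants if deviant else std_variants)),
            fragmentation=int(fragmentations[i]),
            soa=float(soa),
        ))

    seq_end = events[-1].onset_fragment2 + config.fragment_duration + config.iti_mean
    task_events = _place_task_events(config, events, seq_end, rng)

    return TrialSchedule(
        sequence_id=sequence_id or f"{deviant_category}-dev_soa{soa:g}",
        soa=float(soa),
        deviant_category=deviant_category,
        fragment_duration=config.fragment_duration,
        sampling_rate=config.sampling_rate,
        events=events,
        task_events=task_events,
    )


def session_sequence_plan(config: SessionConfig) -> list[tuple[float, str, int]]:
    """The (soa, deviant_category, repetition) grid of a full session:
    every SOA level × both deviant categories × 2 repetitions (16
    sequences at the defaults)."""
    reps = config.n_sequences // (len(config.soa_levels) * 2)
    if reps * len(config.soa_levels) * 2 != config.n_sequences:
        raise ConfigurationError(
            "n_sequences must be a multiple of len(soa_levels) * 2"
        )
    return [(soa, cat, rep)
            for soa in config.soa_levels
            for cat in CATEGORIES
            for rep in range(reps)]
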