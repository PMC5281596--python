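"""Synthetic behavioural data: the 2AFC integration session and the
frame-thickening task responder.

In the forced-choice session a letter/pseudo-letter pair is shown as
fragments at SOA 30/50/70 ms and the observer reports which member was
the legal letter; performance is Bernoulli with the psychometric
model's p(correct | SOA).  The default 164-trial session is split as
evenly as possible over the SOA × letter-position grid (164 is not a
multiple of six, so two cells carry one extra trial).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import Psychometric2AFC
from .exceptions import ConfigurationError
from .schedule import TrialSchedule

LETTER_POSITIONS = ("first", "second")

RESPONSE_COLUMNS = ["trial", "soa_ms", "letter_position", "response", "correct"]


def _cell_counts(n_trials: int, soa_levels, strict: bool) -> dict[tuple[float, str], int]:
    n_cells = len(soa_levels) * len(LETTER_POSITIONS)
    if strict and n_trials % n_cells:
        raise ConfigurationError(
            f"{n_trials} trials cannot be balanced exactly over {n_cells} "
            "SOA x order cells"
        )
    # Distribute the remainder over SOAs first, so SOA counts differ by
    # at most one even when order cells cannot all be equal.
    per_soa = {s: n_trials // len(soa_levels) + (1 if i < n_trials % len(soa_levels) else 0)
               for i, s in enumerate(soa_levels)}
    counts = {}
    for s in soa_levels:
        first = per_soa[s] // 2 + per_soa[s] % 2
        counts[(s, "first")] = first
        counts[(s, "second")] = per_soa[s] - first
    return counts


def generate_2afc_responses(model: Psychometric2AFC | None = None,
                            seed: int | np.random.SeedSequence = 0,
                            subject: str | None = None,
                            strict_balance: bool = False) -> pd.DataFrame:
    """Simulate one forced-choice session.

    Returns a frame with columns ``trial, soa_ms, letter_position,
    response, correct``; trial order is shuffled, responses are
    Bernoulli draws with p = model.p_correct(soa).  Deterministic per
    seed.
    """
    model = model or Psychometric2AFC()
    rng = np.random.default_rng(seed)
    counts = _cell_counts(model.n_trials, model.soa_levels, strict_balance)

    cells = []
    for (soa, pos), n in counts.items():
        cells.extend([(soa, pos)] * n)
    order = rng.permutation(len(cells))
    rows = []
    for trial, k in enumerate(order):
        soa, pos = cells[k]
        correct = bool(rng.random() < model.p_correct(soa))
        response = pos if correct else LETTER_POSITIONS[1 - LETTER_POSITIONS.index(pos)]
        rows.append({"trial": trial, "soa_ms": soa, "letter_position": pos,
                     "response": response, "correct": correct})
    frame = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    if subject is not None:
        frame.insert(0, "subject", subject)
    return frame


def simulate_task_responses(schedule: TrialSchedule,
                            hit_prob: float = 0.8,
                            rt_mean: float = 450.0,
                            rt_sd: float = 120.0,
                            rt_bounds: tuple[float, float] = (200.0, 1000.0),
                            seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Button-press times (ms) to the frame-thickening events.

    Each task event is answered with probability ``hit_prob`` after a
    truncated-Gaussian reaction time; misses produce no response.
    """
    if not 0.0 <= hit_prob <= 1.0:
        raise ConfigurationError("hit_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times = []
    lo, hi = rt_bounds
    for ev in schedule.task_events:
        if rng.random() >= hit_prob:
            continue
        rt = float(np.clip(rng.normal(rt_mean, rt_sd), lo, hi))
        times.append(ev.onset + rt)
    return np.asarray(times)
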