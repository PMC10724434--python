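"""Session scoring, chance-level Monte-Carlo and day-trend regressions.

Online accuracy is the percentage of registered real-time classifications
matching the transcription when a command was indeed issued; false
detections are registered decodes with no attempted word, missed detections
are attempted words with no registered decode.  Latency is the interval
between speech offset and the moment a decode was registered.

Chance level follows the original Monte-Carlo recipe: a uniform six-way
random classification per truth event, optionally passed through the same
enter->back correction the live system applied, averaged over many
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .application import apply_enter_back_rule
from .decoder import DecodeResult
from .recordings import COMMANDS, TranscriptEvent

#: Default slack (s) added around a truth event when pairing decodes to it.
DEFAULT_MATCH_WINDOW_S = 0.75


@dataclass
class Alignment:
    """Pairing of registered decodes with ground-truth events."""

    matched: list[tuple[DecodeResult, TranscriptEvent]]
    false_detections: list[DecodeResult]
    missed: list[TranscriptEvent]


@dataclass
class SessionMetrics:
    """Per-session performance numbers (accuracy in %, rates per minute)."""

    accuracy_pct: float | None
    correct_per_min: float
    commands_per_min: float
    false_per_min: float
    missed_per_min: float
    latency_median_s: float | None
    session_duration_min: float
    day_id: str = ""

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "correct_per_min": self.correct_per_min,
            "commands_per_min": self.commands_per_min,
            "false_per_min": self.false_per_min,
            "missed_per_min": self.missed_per_min,
            "latency_median_s": self.latency_median_s,
            "session_duration_min": self.session_duration_min,
            "day_id": self.day_id,
        }


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares fit of a metric against days after implant."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided Wald test on the slope, t(n-2)
    n_points: int


def _check_sorted(times: Sequence[float], what: str) -> None:
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError(f"{what} must be sorted by time")


def align(
    decodes: Sequence[DecodeResult],
    truth: Sequence[TranscriptEvent],
    match_window_s: float = DEFAULT_MATCH_WINDOW_S,
) -> Alignment:
    """Pair registered decodes with truth events.

    A decode can match a truth event when its peak time lies inside
    [onset - tol, offset + tol].  Candidate pairs are committed greedily in
    order of increasing |peak - onset|, each decode and each truth event
    matching at most once.  Unmatched registered decodes are false
    detections; truth events without a registered decode (including those
    whose decode fell below the registration threshold) are missed.
    """
    _check_sorted([d.peak_time_s for d in decodes], "decodes")
    _check_sorted([t.onset_s for t in truth], "truth events")
    registered = [d for d in decodes if d.registered]
    pairs: list[tuple[float, int, int]] = []
    for i, d in enumerate(registered):
        for j, ev in enumerate(truth):
            if ev.onset_s - match_window_s <= d.peak_time_s <= ev.offset_s + match_window_s:
                pairs.append((abs(d.peak_time_s - ev.onset_s), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[DecodeResult, TranscriptEvent]] = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched.append((registered[i], truth[j]))
    matched.sort(key=lambda p: p[1].onset_s)
    false_detections = [d for i, d in enumerate(registered) if i not in used_d]
    missed = [ev for j, ev in enumerate(truth) if j not in used_t]
    return Alignment(matched, false_detections, missed)


def session_metrics(
    alignment: Alignment,
    truth: Sequence[TranscriptEvent],
    duration_min: float,
    day_id: str = "",
) -> SessionMetrics:
    """Compute the per-session metrics from an alignment.

    Accuracy is over matched decodes only ("when a command was indeed
    issued"); with zero matches it is reported as missing (None), not 0.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    n_matched = len(alignment.matched)
    n_correct = sum(1 for d, ev in alignment.matched if d.label == ev.label)
    accuracy = 100.0 * n_correct / n_matched if n_matched else None
    latencies = [
        d.registered_time_s - ev.offset_s for d, ev in alignment.matched
    ]
    return SessionMetrics(
        accuracy_pct=accuracy,
        correct_per_min=n_correct / duration_min,
        commands_per_min=len(truth) / duration_min,
        false_per_min=len(alignment.false_detections) / duration_min,
        missed_per_min=len(alignment.missed) / duration_min,
        latency_median_s=float(np.median(latencies)) if latencies else None,
        session_duration_min=duration_min,
        day_id=day_id,
    )


def chance_simulation(
    truth_labels: Sequence[str],
    n_sims: int = 10000,
    enter_back: bool = True,
    seed: int = 0,
) -> float:
    """Mean accuracy (%) of a uniform six-way random classifier.

    Per simulation, one uniform label is drawn per truth event; with
    ``enter_back`` the simulated sequence is passed through the enter->back
    correction (a simulated result following an effective enter becomes
    back) before scoring against the truth sequence, position by position.
    """
    labels = list(truth_labels)
    if not labels:
        raise ValueError("truth sequence must not be empty")
    idx = {c: i for i, c in enumerate(COMMANDS)}
    try:
        y = np.array([idx[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"unknown command {e.args[0]!r}") from None
    rng = np.random.default_rng(seed)
    sims = rng.integers(0, len(COMMANDS), size=(n_sims, y.size))
    if enter_back:
        enter, back = idx["enter"], idx["back"]
        for j in range(1, y.size):
            mask = sims[:, j - 1] == enter
            sims[mask, j] = back
    acc = (sims == y[None, :]).mean(axis=1)
    return float(acc.mean() * 100.0)


def trend_fit(days: Sequence[float], metric: Sequence[float]) -> TrendFit:
    """OLS regression of a metric on days, with a Wald t-test on the slope."""
    x = np.asarray(days, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("days and metric must be matching 1-D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("days must not all be equal")
    res = sstats.linregress(x, y)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        p_value=float(res.pvalue),
        n_points=int(x.size),
    )


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation via the covariance formula; NaN if degenerate."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be matching 1-D sequences")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return float("nan")
    return float((xc * yc).sum() / den)
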