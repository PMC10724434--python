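"""Signal-stability analytics across days of use.

Covers the long-term stability battery of the study: per-channel Pearson
correlation of each usage trial's raw (unnormalized) high-gamma time course
against the command's training-phase template, per-channel day trends with
Wald-t significance, per-command daily channel-average log HGE, per-period
electrode-contribution maps from gradient saliency, their cross-period
correlation, and the motor-only / sensory-only ablation harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import decoder as dec
from .evaluation import TrendFit, align, pearson_r, trend_fit

@dataclass
class ClassTemplate:
    """Per-command, per-channel average unnormalized HGE over (-1.0, 1.5] s."""

    series: dict[str, np.ndarray]  # command -> (n_channels, 250)

    def __post_init__(self) -> None:
        for cmd, arr in self.series.items():
            if arr.ndim != 2:
                raise ValueError(f"template for {cmd!r} must be 2-D")

    @property
    def commands(self) -> tuple[str, ...]:
        return tuple(self.series)


@dataclass
class ContributionMap:
    """Relative per-channel contribution within one usage period (sums to 1)."""

    scores: np.ndarray  # (n_channels,), non-negative, sum 1
    period_id: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("contribution scores must be non-negative")


def build_class_template(
    trials: Sequence[tuple[np.ndarray, str, str]],
) -> ClassTemplate:
    """Average onset-aligned unnormalized HGE per command over training trials."""
    by_cmd: dict[str, list[np.ndarray]] = {}
    for values, label, _ in trials:
        by_cmd.setdefault(label, []).append(values)
    return ClassTemplate(
        {cmd: np.mean(arrs, axis=0) for cmd, arrs in by_cmd.items()}
    )


def trial_correlations(
    usage_trials: Sequence[tuple[np.ndarray, str, str]],
    template: ClassTemplate,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-day per-channel mean correlation of usage trials to their templates.

    Each trial contributes, per channel, the Pearson r between its raw HGE
    time course and the matching command's template series.  Per day and
    channel the plain mean over that day's trials is taken, which weights
    each command by its frequency of use that day.  Zero-variance series
    give an undefined r; those are excluded and counted (second return
    value).
    """
    by_day: dict[str, list[np.ndarray]] = {}
    n_excluded = 0
    for values, label, day in usage_trials:
        if label not in template.series:
            raise ValueError(f"template missing command {label!r}")
        tmpl = template.series[label]
        if values.shape != tmpl.shape:
            raise ValueError("trial/template shape mismatch")
        rs = _rowwise_pearson(values, tmpl)
        n_excluded += int(np.isnan(rs).sum())
        by_day.setdefault(day, []).append(rs)
    daily = {}
    for day, rs_list in sorted(by_day.items()):
        stacked = np.stack(rs_list)
        counts = (~np.isnan(stacked)).sum(axis=0)
        sums = np.nansum(stacked, axis=0)
        with np.errstate(invalid="ignore"):
            daily[day] = np.where(counts > 0, sums / counts, np.nan)
    return daily, n_excluded


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row (channel) via the covariance formula; NaN rows
    flag zero variance."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


@dataclass
class ChannelTrendSummary:
    """Per-channel correlation-vs-day regressions and significance counts."""

    fits: list[TrendFit]
    n_significant_positive: int
    n_significant_negative: int
    alpha: float = 0.05


def channel_trends(
    daily_correlations: Mapping[str, np.ndarray],
    days: Mapping[str, float],
    alpha: float = 0.05,
) -> ChannelTrendSummary:
    """OLS + Wald-t trend of each channel's daily correlation against day number."""
    day_ids = sorted(daily_correlations)
    if len(day_ids) < 3:
        raise ValueError("need at least 3 days for channel trends")
    x = np.array([days[d] for d in day_ids], dtype=float)
    mat = np.stack([daily_correlations[d] for d in day_ids])  # (days, channels)
    fits = [trend_fit(x, mat[:, ch]) for ch in range(mat.shape[1])]
    pos = sum(1 for f in fits if f.p_value < alpha and f.slope > 0)
    neg = sum(1 for f in fits if f.p_value < alpha and f.slope < 0)
    return ChannelTrendSummary(fits, pos, neg, alpha)


def hge_per_command_daily(
    usage_trials: Sequence[tuple[np.ndarray, str, str]],
    days: Mapping[str, float],
) -> tuple[dict[str, dict[str, float]], dict[str, TrendFit | None]]:
    """Per-day per-command channel-and-time average of unnormalized log HGE.

    Returns (daily values keyed day -> command, per-command TrendFit or None
    when a command appears on fewer than 3 days).
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for values, label, day in usage_trials:
        acc.setdefault((day, label), []).append(float(values.mean()))
    daily: dict[str, dict[str, float]] = {}
    for (day, label), vals in sorted(acc.items()):
        daily.setdefault(day, {})[label] = float(np.mean(vals))
    trends: dict[str, TrendFit | None] = {}
    commands = sorted({label for _, label in acc})
    for cmd in commands:
        pts = [(days[d], daily[d][cmd]) for d in daily if cmd in daily[d]]
        if len(pts) >= 3 and np.ptp([p[0] for p in pts]) > 0:
            xs, ys = zip(*pts)
            trends[cmd] = trend_fit(xs, ys)
        else:
            trends[cmd] = None
    return daily, trends


def contribution_map(
    saliency_vectors: Sequence[np.ndarray], period_id: str,
) -> ContributionMap:
    """Channel-wise mean of trial saliencies, normalized to sum to 1."""
    if len(saliency_vectors) == 0:
        raise ValueError(f"period {period_id!r} has no trials")
    mean = np.mean(np.stack(saliency_vectors), axis=0)
    total = mean.sum()
    if total <= 0:
        raise ValueError("saliencies sum to zero; cannot normalize")
    return ContributionMap(mean / total, period_id)


def period_correlation(map_a: ContributionMap, map_b: ContributionMap) -> float:
    """Pearson r across channels between two contribution maps."""
    if map_a.scores.shape != map_b.scores.shape:
        raise ValueError("maps must cover the same channel set")
    return pearson_r(map_a.scores, map_b.scores)


def ablation_eval(
    training_trials,
    sessions,
    channel_subsets: Mapping[str, Sequence[int]],
    stats,
    model_spec: dec.ModelSpec | None = None,
    train_config: dec.TrainConfig | None = None,
    det_config=None,
    match_window_s: float = 0.75,
) -> dict[str, list[float]]:
    """Retrain and score the decoder on channel subsets.

    ``sessions`` is a sequence of (recording, transcript) pairs.  For each
    named subset a decoder is retrained on the training corpus restricted to
    those channels and applied to decode windows produced by full-channel
    detection, restricted the same way; per-session accuracies (%) are
    returned (None-valued sessions, with no matched decodes, are skipped).
    """
    from . import pipeline
    from .evaluation import session_metrics

    results: dict[str, list[float]] = {}
    base_spec = model_spec or dec.ModelSpec()
    cfg = train_config or dec.TrainConfig(holdout_day="day00")
    for name, subset in channel_subsets.items():
        subset = list(subset)
        if not subset:
            raise ValueError(f"channel subset {name!r} is empty")
        spec = dec.ModelSpec(**{**_spec_dict(base_spec),
                                "n_channels": len(subset)})
        model = dec.build_model(spec, seed=cfg.seed)
        triples = pipeline.training_windows(
            training_trials, stats, channel_subset=subset)
        dec.train(model, triples, cfg)
        accs: list[float] = []
        for recording, truth in sessions:
            out = pipeline.process_session(
                recording, stats, model, det_config=det_config,
                channel_subset=subset,
            )
            al = align(out.decodes, truth, match_window_s)
            m = session_metrics(al, truth, recording.duration_s / 60.0)
            if m.accuracy_pct is not None:
                accs.append(m.accuracy_pct)
        results[name] = accs
    return results


def _spec_dict(spec: dec.ModelSpec) -> dict:
    from dataclasses import asdict

    return asdict(spec)
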