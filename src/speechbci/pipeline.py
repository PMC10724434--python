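"""End-to-end plumbing: raw recording -> features -> detection -> decodes.

Glues the stages together the way the live system ran them: causal HGE
extraction, one-off silence z-normalization, streaming peak detection on the
full channel set, decode-window assembly and classification.  Channel-subset
classification (for the motor-only / sensory-only ablation) restricts only
the decoder input; detection always uses every channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import decoder as dec
from .detection import (DecodeWindow, DetectionEvent, DetectorConfig,
                        assemble_window, stream_detect)
from .hge import FilterSpec, HgeFrames, SilenceStats, extract_hge, zscore
from .recordings import RawRecording
from .synthetic import GeneratorConfig, TrainingTrial, generate_calibration_recording


def compute_session_frames(
    recording: RawRecording, stats: SilenceStats,
    spec: FilterSpec | None = None,
) -> HgeFrames:
    """Extract and z-normalize HGE frames for one recording."""
    return zscore(extract_hge(recording, spec), stats)


def calibration_stats(
    config: GeneratorConfig, n_cues: int = 30, source_id: str = "calibration",
) -> SilenceStats:
    """Silence statistics from a generated calibration recording."""
    from .hge import compute_silence_stats

    rec, cues = generate_calibration_recording(config, n_cues)
    frames = extract_hge(rec)
    # skip cues whose silence window would overlap the filter warm-up
    cues = cues[cues - 0.8 >= 0.55]
    return compute_silence_stats(frames, cues, source_id=source_id)


@dataclass
class SessionDecodes:
    """Output of a processed session."""

    events: list[DetectionEvent]
    decodes: list[dec.DecodeResult]
    windows: list[DecodeWindow]


def process_session(
    recording: RawRecording,
    stats: SilenceStats,
    model: dec.InceptionTimeNet,
    det_config: DetectorConfig | None = None,
    threshold: float = dec.REGISTRATION_THRESHOLD,
    channel_subset: Sequence[int] | None = None,
    inference_delay_s: float = 0.0,
) -> SessionDecodes:
    """Run the full real-time pipeline over one recording.

    Detection uses all channels; classification optionally restricts the
    decode window to ``channel_subset``.  ``inference_delay_s`` is added to
    the confirm time to form the registered time.
    """
    det_config = det_config or DetectorConfig()
    frames = compute_session_frames(recording, stats)
    events = stream_detect(frames, det_config)
    decodes: list[dec.DecodeResult] = []
    windows: list[DecodeWindow] = []
    for ev in events:
        if not ev.accepted:
            continue
        try:
            window = assemble_window(frames, ev.peak_time_s, "detected")
        except ValueError:
            continue  # peak too close to the recording edge
        cls_window = window
        if channel_subset is not None:
            cls_window = DecodeWindow(
                window.values[np.asarray(channel_subset)],
                window.peak_time_s, window.mode,
            )
        result = dec.classify(
            model, cls_window, threshold=threshold,
            registered_time_s=ev.confirm_time_s + inference_delay_s,
        )
        decodes.append(result)
        windows.append(window)
    return SessionDecodes(events=events, decodes=decodes, windows=windows)


def training_windows(
    trials: Sequence[TrainingTrial],
    stats: SilenceStats,
    burst_duration_s: float | None = None,
    channel_subset: Sequence[int] | None = None,
    normalized: bool = True,
) -> list[tuple[DecodeWindow, str, str]]:
    """Assemble (window, label, day_id) triples from cue-locked trials.

    Trials are too short for the 10-s streaming baseline to fill, so the
    decode window is anchored at the known burst centre
    (speech onset + burst_duration/2), matching where the live detector
    reports peaks.  With ``normalized=False`` the raw log-power frames are
    used (the convention of the signal-stability analyses).
    """
    out: list[tuple[DecodeWindow, str, str]] = []
    for tr in trials:
        frames = extract_hge(tr.recording)
        if normalized:
            frames = zscore(frames, stats)
        else:
            frames = HgeFrames(
                values=frames.values, frame_times_s=frames.frame_times_s,
                normalized=True,  # marker only, to satisfy window assembly
            )
        dur = burst_duration_s if burst_duration_s is not None else 0.8
        anchor = tr.speech_onset_s + dur / 2.0
        window = assemble_window(frames, anchor, "detected")
        if channel_subset is not None:
            window = DecodeWindow(
                window.values[np.asarray(channel_subset)],
                window.peak_time_s, window.mode,
            )
        out.append((window, tr.label, tr.day_id))
    return out


def onset_aligned_windows(
    trials: Sequence[TrainingTrial],
    pre_s: float = 1.0,
    post_s: float = 1.5,
) -> list[tuple[np.ndarray, str, str]]:
    """Unnormalized HGE windows over (onset - 1.0, onset + 1.5] per trial.

    Returns (values, label, day_id) with values (n_channels, 250); used by
    the signal-stability analyses, which work on raw log HGE.
    """
    out: list[tuple[np.ndarray, str, str]] = []
    for tr in trials:
        frames = extract_hge(tr.recording)
        t = frames.frame_times_s
        lo, hi = tr.speech_onset_s - pre_s, tr.speech_onset_s + post_s
        mask = (t > lo + 1e-9) & (t <= hi + 0.005)
        idx = np.flatnonzero(mask)[:int(round((pre_s + post_s) * 100))]
        if idx.size != int(round((pre_s + post_s) * 100)):
            raise ValueError("trial too short for onset-aligned window")
        out.append((frames.values[:, idx], tr.label, tr.day_id))
    return out
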