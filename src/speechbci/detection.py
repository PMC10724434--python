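"""Streaming speech-intent detection from normalized high-gamma frames.

The detection signal is the channel average of normalized HGE integrated
over a trailing 1-s window, updated every 10 ms.  Detection runs against two
rolling buffers of this signal: a 3-s detection buffer and a 10-s baseline
buffer.  At every 10-ms update, each local maximum inside the detection
buffer is (re-)evaluated: it fires as a detection the first time its
topographic prominence within the buffer exceeds ``prominence_factor``
times the baseline-buffer standard deviation, unless the peak minus the
baseline-buffer minimum falls below ``rejection_factor`` times that
standard deviation.  Because a peak's right flank keeps descending as the
buffer slides, its prominence grows over successive updates: a peak is
typically confirmed a few hundred milliseconds to ~1 s after it occurs,
which sets the system's response latency.  An accepted peak anchors a 2.5-s
decode window of normalized HGE covering 2 s before and 0.5 s after the
peak.

Timestamp convention: each detection-signal value is stamped at the centre
of its 1-s integration window, so a reported peak time coincides with the
centre of the underlying burst of high-gamma power, and the 0.5 s of data
after the peak required by the decode window is already available when the
peak's value is computed.  A candidate is first evaluated once 0.5 s of
updates have accumulated after it (the latency floor), and keeps being
re-evaluated until it is accepted or slides out of the detection buffer.

Two implementations produce identical event lists: :func:`stream_detect`,
a vectorized offline sweep, and :class:`StreamingDetector`, a true
incremental detector that accepts frame chunks of any size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hge import FRAME_HOP_S, WARMUP_S, HgeFrames


@dataclass(frozen=True)
class DetectorConfig:
    """Buffer lengths and thresholds of the streaming detector."""

    integral_window_s: float = 1.0
    detection_buffer_s: float = 3.0
    baseline_buffer_s: float = 10.0
    prominence_factor: float = 2.0  # x baseline sd
    rejection_factor: float = 1.0  # x baseline sd
    pre_peak_s: float = 2.0
    post_peak_s: float = 0.5
    refractory_s: float = 2.5
    update_period_s: float = FRAME_HOP_S
    prominence_sd_source: str = "baseline"  # or "detection"

    def __post_init__(self) -> None:
        vals = (
            self.integral_window_s, self.detection_buffer_s,
            self.baseline_buffer_s, self.prominence_factor,
            self.rejection_factor, self.pre_peak_s, self.post_peak_s,
            self.refractory_s, self.update_period_s,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all detector parameters must be positive")
        if abs(self.pre_peak_s + self.post_peak_s - 2.5) > 1e-9:
            raise ValueError("pre_peak_s + post_peak_s must equal 2.5 s")
        if self.detection_buffer_s > self.baseline_buffer_s:
            raise ValueError("detection buffer must not exceed baseline buffer")
        if self.prominence_sd_source not in ("baseline", "detection"):
            raise ValueError("prominence_sd_source must be baseline|detection")

    @property
    def integral_steps(self) -> int:
        return int(round(self.integral_window_s / self.update_period_s))

    @property
    def detection_steps(self) -> int:
        return int(round(self.detection_buffer_s / self.update_period_s))

    @property
    def baseline_steps(self) -> int:
        return int(round(self.baseline_buffer_s / self.update_period_s))

    @property
    def confirm_steps(self) -> int:
        """Updates accumulated after a candidate before its first evaluation."""
        return int(round(self.post_peak_s / self.update_period_s))


@dataclass(frozen=True)
class DetectionEvent:
    """One candidate peak of the detection signal and its final verdict."""

    peak_time_s: float
    prominence: float  # at confirm time (accepted) or last evaluation
    baseline_sd: float
    accepted: bool
    rejection_reason: str  # none|low_prominence|below_baseline_floor|refractory|warmup
    confirm_time_s: float

    def __post_init__(self) -> None:
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted events carry rejection_reason 'none'")


@dataclass
class DecodeWindow:
    """Exactly 250 frames (2.5 s) of normalized HGE around an anchor."""

    values: np.ndarray  # (n_channels, 250)
    peak_time_s: float
    mode: str  # detected|cued

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 250:
            raise ValueError("decode window must be channels x 250 frames")
        if self.mode not in ("detected", "cued"):
            raise ValueError("mode must be 'detected' or 'cued'")


def detection_signal(
    frames: HgeFrames, config: DetectorConfig | None = None,
    drop_warmup: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel-mean HGE averaged over a trailing 1-s integral window.

    Returns ``(times, values)``.  Value j averages the ``integral_steps``
    most recent channel-mean frames and is stamped at the centre of that
    window (frame right-edge time minus half the integral window).  Frames
    inside the filter warm-up period are excluded before integration.
    """
    config = config or DetectorConfig()
    if not frames.normalized:
        raise ValueError("detection requires normalized frames")
    keep = frames.warmup_mask() if drop_warmup else np.ones(frames.n_frames, bool)
    ch_mean = frames.values[:, keep].mean(axis=0)
    t = frames.frame_times_s[keep]
    w = config.integral_steps
    if ch_mean.size < w:
        raise ValueError(f"need at least {w} frames for the integral window")
    kernel = np.full(w, 1.0 / w)
    values = np.convolve(ch_mean, kernel, mode="valid")
    times = t[w - 1:] - config.integral_window_s / 2.0
    return times, values


def peak_prominence(series: np.ndarray, peak_index: int) -> float:
    """Topographic prominence of a strict local maximum within a segment.

    Walk left (right) from the peak to the nearest strictly-higher sample or
    the segment edge; the key saddle on that side is the minimum over the
    walk.  Prominence is peak height minus the higher of the two saddles.
    """
    s = np.asarray(series, dtype=float)
    n = s.size
    i = peak_index
    if not _is_local_max(s, i, horizon=n):
        raise ValueError(f"index {i} is not a strict local maximum")
    h = s[i]
    left_min = h
    j = i - 1
    while j >= 0 and s[j] <= h:
        left_min = min(left_min, s[j])
        j -= 1
    right_min = h
    j = i + 1
    while j < n and s[j] <= h:
        right_min = min(right_min, s[j])
        j += 1
    return h - max(left_min, right_min)


def _is_local_max(s: np.ndarray, i: int, horizon: int = 50) -> bool:
    """Strict local maximum; plateaus take the first index.

    s[i] must strictly exceed the previous sample and the next *differing*
    sample within ``horizon`` steps (ties extend the plateau rightward).
    """
    n = s.size
    if i <= 0 or i >= n - 1:
        return False
    if not s[i] > s[i - 1]:
        return False
    j = i + 1
    while j < n and j <= i + horizon and s[j] == s[i]:
        j += 1
    if j >= n or j > i + horizon:
        return False
    return s[j] < s[i]


def _rolling_trailing(values: np.ndarray, window: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window (population) sd and min at every index.

    Entry c summarizes values[c - window + 1 .. c]; entries with an
    incomplete window are NaN.
    """
    s = pd.Series(values)
    sd = s.rolling(window).std(ddof=0).to_numpy()
    mn = s.rolling(window).min().to_numpy()
    return sd, mn


def _candidate_indices(values: np.ndarray, horizon: int) -> list[int]:
    """Strict local maxima (plateaus take the first index)."""
    strict = np.flatnonzero(
        (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    ) + 1
    ties = np.flatnonzero(
        (values[1:-1] > values[:-2]) & (values[1:-1] == values[2:])
    ) + 1
    out = set(strict.tolist())
    out.update(i for i in ties.tolist() if _is_local_max(values, i, horizon))
    return sorted(out)


def _prominence_series(values: np.ndarray, i: int, c_lo: int, c_hi: int,
                       det_steps: int) -> np.ndarray:
    """Prominence of peak i within the sliding detection buffer, for every
    confirm index c in [c_lo, c_hi].

    The right saddle is a running minimum that freezes at the nearest
    strictly-higher sample; the left saddle is the minimum between the peak
    and either the nearest strictly-higher sample or the (moving) left
    buffer edge.
    """
    h = values[i]
    n = values.size
    cs = np.arange(c_lo, c_hi + 1)
    # right side: running min of values[i+1..c], frozen once a higher sample enters
    right = np.minimum.accumulate(values[i + 1:c_hi + 1])
    higher = np.flatnonzero(values[i + 1:c_hi + 1] > h)
    if higher.size:
        jstar = higher[0]  # offset of first strictly-higher sample
        frozen = values[i + 1:i + 1 + jstar].min() if jstar > 0 else h
        right[jstar:] = frozen
    right_min = right[cs - (i + 1)]
    # left side: suffix minima of values[.. i-1], window edge a = c - det + 1
    a = np.maximum(cs - det_steps + 1, 0)
    lo_needed = int(a.min())
    suffix = np.minimum.accumulate(values[lo_needed:i][::-1])[::-1]
    jl = None
    seg = values[lo_needed:i]
    higher_left = np.flatnonzero(seg > h)
    if higher_left.size:
        jl = lo_needed + higher_left[-1]  # nearest strictly-higher on the left
    start = a.copy()
    if jl is not None:
        start = np.maximum(start, jl + 1)
    left_min = suffix[start - lo_needed]
    return h - np.maximum(left_min, right_min)


def _final_reason(prom: float, sd: float, peak_val: float, base_min: float,
                  config: DetectorConfig, saw_refractory_block: bool) -> str:
    if saw_refractory_block:
        return "refractory"
    if not prom > config.prominence_factor * sd:
        return "low_prominence"
    if peak_val - base_min < config.rejection_factor * sd:
        return "below_baseline_floor"
    return "refractory"  # passed statically at the end but stayed blocked


def _detect_from_signal(
    times: np.ndarray, values: np.ndarray, config: DetectorConfig,
) -> list[DetectionEvent]:
    """Offline sweep replicating the per-update evaluation exactly."""
    n = values.size
    det = config.detection_steps
    base = config.baseline_steps
    base_sd, base_min = _rolling_trailing(values, base)
    if config.prominence_sd_source == "detection":
        det_sd, _ = _rolling_trailing(values, det)
    cands = _candidate_indices(values, config.confirm_steps)
    # static pass masks per candidate
    entries = []  # (c, cand_order) pairs where static rules pass
    info = {}
    for order, i in enumerate(cands):
        c_lo = i + config.confirm_steps
        c_hi = min(i + det - 2, n - 1)  # peak must stay interior to the buffer
        if c_lo > c_hi:
            continue
        cs = np.arange(c_lo, c_hi + 1)
        prom = _prominence_series(values, i, c_lo, c_hi, det)
        with np.errstate(invalid="ignore"):
            sd = det_sd[cs] if config.prominence_sd_source == "detection" \
                else base_sd[cs]
            ok = (
                ~np.isnan(base_sd[cs])
                & (prom > config.prominence_factor * sd)
                & (values[i] - base_min[cs] >= config.rejection_factor * base_sd[cs])
            )
        info[i] = (cs, prom, ok)
        for c in cs[ok]:
            entries.append((int(c), order, i))
    entries.sort()
    accepted_at: dict[int, int] = {}  # cand index -> confirm c
    blocked: set[int] = set()
    last_peak = -np.inf
    for c, _, i in entries:
        if i in accepted_at:
            continue
        if times[i] - last_peak < config.refractory_s:
            blocked.add(i)
            continue
        accepted_at[i] = c
        last_peak = times[i]
    events: list[DetectionEvent] = []
    for i in cands:
        if i not in info:
            continue
        cs, prom, ok = info[i]
        if i in accepted_at:
            c = accepted_at[i]
            k = int(c - cs[0])
            events.append(DetectionEvent(
                times[i], float(prom[k]), float(base_sd[c]), True, "none",
                times[c]))
            continue
        c_end = int(cs[-1])
        if np.isnan(base_sd[c_end]):
            events.append(DetectionEvent(
                times[i], np.nan, np.nan, False, "warmup", times[c_end]))
            continue
        sd_end = base_sd[c_end] if config.prominence_sd_source == "baseline" \
            else det_sd[c_end]
        reason = _final_reason(
            float(prom[-1]), float(sd_end), float(values[i]),
            float(base_min[c_end]), config, i in blocked)
        events.append(DetectionEvent(
            times[i], float(prom[-1]), float(base_sd[c_end]), False, reason,
            times[c_end]))
    events.sort(key=lambda e: e.confirm_time_s)
    return events


def stream_detect(
    frames: HgeFrames, config: DetectorConfig | None = None,
) -> list[DetectionEvent]:
    """Detect speech events over a full recording.

    Replicates the per-update streaming evaluation: every strict local
    maximum of the detection signal is evaluated at each 10-ms update from
    0.5 s after its occurrence until it leaves the 3-s detection buffer, and
    fires at the first update where the prominence and baseline-floor rules
    pass and no refractory block applies.  Events are reported in
    confirm-time order.
    """
    config = config or DetectorConfig()
    times, values = detection_signal(frames, config)
    if values.size <= config.baseline_steps:
        raise ValueError("stream shorter than the baseline buffer warm-up")
    return _detect_from_signal(times, values, config)


class StreamingDetector:
    """Incremental detector fed with frame chunks of any size.

    Maintains the integral window and the detection/baseline buffers
    explicitly and re-evaluates the live candidates at every update; yields
    the same accepted events and rejection reasons as :func:`stream_detect`
    for any chunking of the input.  Rejected candidates are reported when
    they slide out of the detection buffer.
    """

    def __init__(self, config: DetectorConfig | None = None) -> None:
        self.config = config or DetectorConfig()
        self._ch_mean: list[float] = []
        self._signal: list[float] = []
        self._times: list[float] = []
        self._running_sum = 0.0
        self._last_peak = -np.inf
        self._live: dict[int, dict] = {}  # cand index -> state
        self.events: list[DetectionEvent] = []

    def push(self, frames: HgeFrames) -> list[DetectionEvent]:
        """Feed a chunk of normalized frames; return newly finalized events."""
        cfg = self.config
        if not frames.normalized:
            raise ValueError("detection requires normalized frames")
        w = cfg.integral_steps
        out: list[DetectionEvent] = []
        for j in range(frames.n_frames):
            t = float(frames.frame_times_s[j])
            if t < WARMUP_S:
                continue
            self._ch_mean.append(float(frames.values[:, j].mean()))
            self._running_sum += self._ch_mean[-1]
            if len(self._ch_mean) < w:
                continue
            if len(self._ch_mean) > w:
                self._running_sum -= self._ch_mean[len(self._ch_mean) - w - 1]
            self._signal.append(self._running_sum / w)
            self._times.append(t - cfg.integral_window_s / 2.0)
            out.extend(self._update())
        self.events.extend(out)
        return out

    def _update(self) -> list[DetectionEvent]:
        cfg = self.config
        s = self._signal
        c = len(s) - 1
        det = cfg.detection_steps
        base = cfg.baseline_steps
        finalized: list[DetectionEvent] = []
        # a new candidate becomes eligible once confirm_steps updates old
        i_new = c - cfg.confirm_steps
        if i_new >= 1:
            seg = np.asarray(s[i_new - 1:c + 1])
            if _is_local_max(seg, 1, horizon=cfg.confirm_steps):
                self._live[i_new] = {"blocked": False}
        arr = np.asarray(s[max(0, c - base + 1):c + 1])
        base_full = c >= base - 1
        base_sd = float(arr.std()) if base_full else np.nan
        base_min = float(arr.min()) if base_full else np.nan
        det_lo = max(0, c - det + 1)
        det_buf = np.asarray(s[det_lo:c + 1])
        sd = base_sd if cfg.prominence_sd_source == "baseline" \
            else float(det_buf.std())
        for i in sorted(self._live):
            st = self._live[i]
            pos = i - det_lo
            if pos < 1:  # slid out of the buffer: finalize as rejected
                finalized.append(self._finalize(i, st))
                del self._live[i]
                continue
            prom = peak_prominence(det_buf, pos)
            st["last"] = (prom, base_sd, base_min, s[i], self._times[c])
            if not base_full:
                continue
            ok = (
                prom > cfg.prominence_factor * sd
                and s[i] - base_min >= cfg.rejection_factor * base_sd
            )
            if not ok:
                continue
            if self._times[i] - self._last_peak < cfg.refractory_s:
                st["blocked"] = True
                continue
            self._last_peak = self._times[i]
            finalized.append(DetectionEvent(
                self._times[i], float(prom), base_sd, True, "none",
                self._times[c]))
            del self._live[i]
        return finalized

    def _finalize(self, i: int, st: dict) -> DetectionEvent:
        cfg = self.config
        prom, base_sd, base_min, peak_val, t_last = st["last"]
        if np.isnan(base_sd):
            return DetectionEvent(self._times[i], np.nan, np.nan, False,
                                  "warmup", t_last)
        reason = _final_reason(prom, base_sd, peak_val, base_min, cfg,
                               st["blocked"])
        return DetectionEvent(self._times[i], float(prom), float(base_sd),
                              False, reason, t_last)

    def finalize(self) -> list[DetectionEvent]:
        """Flush still-live candidates at end of stream (as rejections)."""
        out = [self._finalize(i, st) for i, st in sorted(self._live.items())
               if "last" in st]
        self._live.clear()
        self.events.extend(out)
        return out


def assemble_window(
    frames: HgeFrames, anchor_time_s: float, mode: str = "detected",
) -> DecodeWindow:
    """Cut the 250-frame decode window around an anchor.

    detected: frames with times in (anchor - 2.0, anchor + 0.5];
    cued: frames with times in (anchor, anchor + 2.5].
    """
    if not frames.normalized:
        raise ValueError("decode windows require normalized frames")
    if mode == "detected":
        lo, hi = anchor_time_s - 2.0, anchor_time_s + 0.5
    elif mode == "cued":
        lo, hi = anchor_time_s, anchor_time_s + 2.5
    else:
        raise ValueError("mode must be 'detected' or 'cued'")
    t = frames.frame_times_s
    # half-open selection (lo, hi] with a half-hop guard on the 10-ms grid
    mask = (t > lo + 1e-9) & (t <= hi + FRAME_HOP_S / 2.0)
    idx = np.flatnonzero(mask)[:250]
    if idx.size != 250:
        raise ValueError(
            f"insufficient frames for decode window around {anchor_time_s}s "
            f"({idx.size} available)"
        )
    return DecodeWindow(frames.values[:, idx], anchor_time_s, mode)


def save_detection_log(events: Sequence[DetectionEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peak_time_s": [e.peak_time_s for e in events],
            "confirm_time_s": [e.confirm_time_s for e in events],
            "prominence": [e.prominence for e in events],
            "baseline_sd": [e.baseline_sd for e in events],
            "accepted": [e.accepted for e in events],
            "rejection_reason": [e.rejection_reason for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)
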