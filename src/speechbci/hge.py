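"""High-gamma energy (HGE) feature extraction.

Raw multichannel signal is causally band-pass filtered to the 70-170 Hz high
gamma band (8th-order Butterworth), line noise is removed with a 118-122 Hz
band-stop notch, and the log power of each 50-ms window is emitted every
10 ms ("once 10-ms data was received").  Streaming and batch execution give
bit-identical results: the filters are plain one-pass IIR recursions with
persistent state, and each frame is a pure function of its 50 samples.

Normalization uses per-channel silence statistics: the mean and standard
deviation of HGE frames falling in the 0.8-s pre-stimulus quiet periods of a
calibration task.  Frames are z-scored once against those statistics and
never recalibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .recordings import RawRecording

#: Frame hop in seconds (one frame "once 10-ms data was received").
FRAME_HOP_S = 0.01
#: Analysis window length in seconds.
FRAME_WINDOW_S = 0.05
#: Frame rate in Hz implied by the hop.
FRAME_RATE = 100.0
#: Power floor added before taking the log, so silence maps to log(EPS).
LOG_POWER_FLOOR = 1e-12
#: Frames within this time of stream start are filter warm-up and are
#: excluded from detection.
WARMUP_S = 0.5


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + notch design for high-gamma extraction.

    ``bandpass_order`` and ``notch_order`` are the overall filter orders
    (a Butterworth band filter of order 2N comes from an order-N prototype).
    """

    band_hz: tuple[float, float] = (70.0, 170.0)
    bandpass_order: int = 8
    notch_hz: tuple[float, float] = (118.0, 122.0)
    notch_order: int = 4

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        for lo, hi in (self.band_hz, self.notch_hz):
            if not (0 < lo < hi < nyq):
                raise ValueError(
                    f"band edges ({lo}, {hi}) must lie inside (0, {nyq}) Hz"
                )
        if self.bandpass_order % 2 or self.notch_order % 2:
            raise ValueError("band filter orders must be even")

    def sos(self, sample_rate: float) -> np.ndarray:
        """Cascaded second-order sections: band-pass followed by band-stop."""
        self.validate(sample_rate)
        sos_bp = sps.butter(
            self.bandpass_order // 2, self.band_hz, btype="bandpass",
            fs=sample_rate, output="sos",
        )
        sos_notch = sps.butter(
            self.notch_order // 2, self.notch_hz, btype="bandstop",
            fs=sample_rate, output="sos",
        )
        return np.vstack([sos_bp, sos_notch])


@dataclass
class HgeFrames:
    """Per-channel log-power frames at a 10-ms hop.

    ``frame_times_s`` is the time of each frame's *right* edge: frame k covers
    the half-open sample interval (t_k - 0.05, t_k] with t_k = 0.05 + 0.01 k
    relative to recording start.
    """

    values: np.ndarray  # (n_channels, n_frames)
    frame_times_s: np.ndarray  # (n_frames,)
    frame_rate: float = FRAME_RATE
    window_s: float = FRAME_WINDOW_S
    normalized: bool = False
    stats_source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be channels x frames")
        if self.values.shape[1] != self.frame_times_s.shape[0]:
            raise ValueError("frame_times_s length must match frame count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame values must be finite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def warmup_mask(self, warmup_s: float = WARMUP_S) -> np.ndarray:
        """Boolean mask of frames past the filter warm-up period."""
        return self.frame_times_s >= warmup_s

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("frame_times_s", data=self.frame_times_s)
            f.attrs["frame_rate"] = self.frame_rate
            f.attrs["window_s"] = self.window_s
            f.attrs["normalized"] = self.normalized
            f.attrs["stats_source"] = self.stats_source

    @classmethod
    def load(cls, path: str | Path) -> "HgeFrames":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["values"][...],
                frame_times_s=f["frame_times_s"][...],
                frame_rate=float(f.attrs["frame_rate"]),
                window_s=float(f.attrs["window_s"]),
                normalized=bool(f.attrs["normalized"]),
                stats_source=str(f.attrs.get("stats_source", "")),
            )


@dataclass
class SilenceStats:
    """Per-channel mean/sd of HGE during pre-stimulus silence."""

    mean: np.ndarray  # (n_channels,)
    sd: np.ndarray  # (n_channels,)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be matching 1-D arrays")
        if np.any(self.sd <= 0):
            bad = int(np.flatnonzero(self.sd <= 0)[0])
            raise ValueError(f"silence sd must be positive (channel {bad})")

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]

    def save(self, path: str | Path) -> None:
        doc = {
            "source_id": self.source_id,
            "channels": {
                str(i): {"mean": float(m), "sd": float(s)}
                for i, (m, s) in enumerate(zip(self.mean, self.sd))
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SilenceStats":
        doc = json.loads(Path(path).read_text())
        n = len(doc["channels"])
        mean = np.array([doc["channels"][str(i)]["mean"] for i in range(n)])
        sd = np.array([doc["channels"][str(i)]["sd"] for i in range(n)])
        return cls(mean=mean, sd=sd, source_id=doc.get("source_id", ""))


def _frame_log_power(filtered: np.ndarray, sample_rate: float) -> np.ndarray:
    """Log mean-square power of 50-ms windows at a 10-ms hop.

    ``filtered`` is (n_channels, n_samples); returns (n_channels, n_frames).
    """
    win = int(round(FRAME_WINDOW_S * sample_rate))
    hop = int(round(FRAME_HOP_S * sample_rate))
    n = filtered.shape[1]
    if n < win:
        raise ValueError("recording shorter than one analysis window")
    windows = np.lib.stride_tricks.sliding_window_view(filtered, win, axis=1)
    windows = windows[:, ::hop, :]
    power = np.mean(windows * windows, axis=2)
    return np.log(power + LOG_POWER_FLOOR)


def extract_hge(recording: RawRecording, spec: FilterSpec | None = None) -> HgeFrames:
    """Batch high-gamma feature extraction (causal filtering, no zero-phase)."""
    spec = spec or FilterSpec()
    x = recording.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("raw samples must be finite")
    sr = recording.sample_rate
    win = int(round(FRAME_WINDOW_S * sr))
    if x.shape[1] < win:
        raise ValueError("recording shorter than one analysis window")
    sos = spec.sos(sr)
    filtered = sps.sosfilt(sos, x, axis=1)
    values = _frame_log_power(filtered, sr)
    n_frames = values.shape[1]
    times = recording.start_time + FRAME_WINDOW_S + FRAME_HOP_S * np.arange(n_frames)
    return HgeFrames(values=values, frame_times_s=times)


class StreamingHgeExtractor:
    """Incremental HGE extraction with persistent filter state.

    Feed raw sample chunks of any size (down to single samples) with
    :meth:`push`; frames come out exactly as the batch :func:`extract_hge`
    would produce them, because the IIR recursion state and the partial
    window buffer are carried across chunks.
    """

    def __init__(
        self,
        n_channels: int,
        sample_rate: float,
        spec: FilterSpec | None = None,
        start_time: float = 0.0,
    ) -> None:
        self.spec = spec or FilterSpec()
        self.sample_rate = sample_rate
        self.n_channels = n_channels
        self.start_time = start_time
        sos = self.spec.sos(sample_rate)
        self._sos = sos
        self._zi = np.zeros((sos.shape[0], n_channels, 2))
        self._win = int(round(FRAME_WINDOW_S * sample_rate))
        self._hop = int(round(FRAME_HOP_S * sample_rate))
        self._buffer = np.empty((n_channels, 0))
        self._frame_index = 0

    def push(self, chunk: np.ndarray) -> HgeFrames | None:
        """Process a (n_channels, n_new) chunk; return newly completed frames."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=np.float64))
        if chunk.shape[0] != self.n_channels:
            raise ValueError("chunk channel count mismatch")
        if not np.all(np.isfinite(chunk)):
            raise ValueError("raw samples must be finite")
        filtered, self._zi = sps.sosfilt(self._sos, chunk, axis=1, zi=self._zi)
        self._buffer = np.concatenate([self._buffer, filtered], axis=1)
        n_avail = self._buffer.shape[1]
        if n_avail < self._win:
            return None
        n_new = (n_avail - self._win) // self._hop + 1
        values = _frame_log_power(self._buffer, self.sample_rate)[:, :n_new]
        self._buffer = self._buffer[:, n_new * self._hop:]
        k = self._frame_index + np.arange(n_new)
        times = self.start_time + FRAME_WINDOW_S + FRAME_HOP_S * k
        self._frame_index += n_new
        return HgeFrames(values=values, frame_times_s=times)


def compute_silence_stats(
    frames: HgeFrames,
    cue_onsets_s: Sequence[float],
    silence_s: float = 0.8,
    source_id: str = "",
) -> SilenceStats:
    """Pool per-channel mean/sd over all pre-cue silence frames.

    Silence frames are those whose (right-edge) times fall in any
    [cue - silence_s, cue) interval.  The sd is the population estimator
    (divide by n).  A zero-variance channel raises, naming the channel.
    """
    cues = np.asarray(list(cue_onsets_s), dtype=float)
    if cues.size == 0:
        raise ValueError("at least one cue onset required")
    t = frames.frame_times_s
    mask = np.zeros(t.shape, dtype=bool)
    for cue in cues:
        if cue - silence_s < t[0] - FRAME_HOP_S / 2:
            raise ValueError(
                f"cue at {cue:.3f}s lacks {silence_s}s of preceding frames"
            )
        mask |= (t >= cue - silence_s) & (t < cue)
    if mask.sum() < 2:
        raise ValueError("need at least 2 silence frames")
    sel = frames.values[:, mask]
    mean = sel.mean(axis=1)
    sd = sel.std(axis=1)  # population (ddof=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance silence on channel {bad}")
    return SilenceStats(mean=mean, sd=sd, source_id=source_id)


def zscore(frames: HgeFrames, stats: SilenceStats) -> HgeFrames:
    """Z-score frames against silence statistics; marks them normalized."""
    if stats.n_channels != frames.n_channels:
        raise ValueError(
            f"stats cover {stats.n_channels} channels, frames have "
            f"{frames.n_channels}"
        )
    values = (frames.values - stats.mean[:, None]) / stats.sd[:, None]
    return HgeFrames(
        values=values,
        frame_times_s=frames.frame_times_s.copy(),
        frame_rate=frames.frame_rate,
        window_s=frames.window_s,
        normalized=True,
        stats_source=stats.source_id,
    )
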