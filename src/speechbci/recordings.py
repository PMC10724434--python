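"""Core data containers for raw multichannel recordings and ground-truth transcripts.

A :class:`RawRecording` holds a channels x time matrix of surface field
potentials in arbitrary amplitude units together with its sample rate and
per-channel metadata (label and cortical region, motor or sensory).  A
:class:`TranscriptEvent` is one ground-truth spoken command with its speech
onset and offset in seconds.

Recordings round-trip through a small HDF5 container; transcripts and cue
tables round-trip through tab-separated files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: The six speech commands used as discrete control signals.
COMMANDS: tuple[str, ...] = ("up", "down", "left", "right", "enter", "back")

#: Valid cortical region labels for channels.
REGIONS: tuple[str, str] = ("motor", "sensory")


@dataclass
class RawRecording:
    """Multichannel raw signal with sample rate and channel metadata."""

    samples: np.ndarray  # (n_channels, n_samples), float
    sample_rate: float  # Hz
    channel_labels: tuple[str, ...] = ()
    channel_regions: tuple[str, ...] = ()
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        n_ch = self.samples.shape[0]
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i:02d}" for i in range(n_ch))
        if not self.channel_regions:
            # default split: first half motor, second half sensory
            half = n_ch // 2
            self.channel_regions = ("motor",) * half + ("sensory",) * (n_ch - half)
        if len(self.channel_labels) != n_ch or len(self.channel_regions) != n_ch:
            raise ValueError("channel metadata length must match channel count")
        bad = set(self.channel_regions) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown channel regions: {sorted(bad)}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def region_indices(self, region: str) -> np.ndarray:
        """Indices of channels in *region* ('motor' or 'sensory')."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.array([i for i, r in enumerate(self.channel_regions) if r == region])

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["start_time"] = self.start_time
            f.create_dataset(
                "channel_labels", data=np.array(self.channel_labels, dtype="S32")
            )
            f.create_dataset(
                "channel_regions", data=np.array(self.channel_regions, dtype="S16")
            )

    @classmethod
    def load(cls, path: str | Path) -> "RawRecording":
        with h5py.File(path, "r") as f:
            return cls(
                samples=f["samples"][...],
                sample_rate=float(f.attrs["sample_rate"]),
                channel_labels=tuple(
                    s.decode() for s in f["channel_labels"][...]
                ),
                channel_regions=tuple(
                    s.decode() for s in f["channel_regions"][...]
                ),
                start_time=float(f.attrs.get("start_time", 0.0)),
            )


@dataclass(frozen=True)
class TranscriptEvent:
    """One ground-truth spoken command with speech onset/offset times."""

    label: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.label not in COMMANDS:
            raise ValueError(f"unknown command {self.label!r}")
        if not self.onset_s < self.offset_s:
            raise ValueError("onset_s must precede offset_s")


def validate_transcript(events: Sequence[TranscriptEvent]) -> None:
    """Check that events are sorted by onset and non-overlapping."""
    for prev, cur in zip(events, events[1:]):
        if cur.onset_s < prev.onset_s:
            raise ValueError("transcript events must be sorted by onset")
        if cur.onset_s < prev.offset_s:
            raise ValueError("transcript events must not overlap")


def save_transcript(events: Sequence[TranscriptEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": [e.label for e in events],
            "onset_s": [e.onset_s for e in events],
            "offset_s": [e.offset_s for e in events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_transcript(path: str | Path) -> list[TranscriptEvent]:
    df = pd.read_csv(path, sep="\t")
    events = [
        TranscriptEvent(str(r.label), float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
    ]
    validate_transcript(events)
    return events


def save_cue_table(
    cue_onsets: Sequence[float], path: str | Path, labels: Sequence[str] | None = None
) -> None:
    df = pd.DataFrame({"cue_onset_s": list(cue_onsets)})
    df["label"] = list(labels) if labels is not None else ""
    df.to_csv(path, sep="\t", index=False)


def load_cue_table(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["cue_onset_s"].to_numpy(dtype=float)
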