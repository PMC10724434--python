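"""Synthetic multichannel ECoG-like signal generator.

Real chronic ECoG recordings from the speech BCI study are not public, so
every downstream stage is exercised on surrogate signals that reproduce the
statistical structure the pipeline assumes:

* per-channel 1/f background noise (unit variance, arbitrary amplitude units),
* a 120-Hz line-noise component (removed downstream by the notch filter),
* command-specific, event-related band-limited (70-170 Hz) power increases
  with channel-specific spatial weighting: each command has a distinct
  non-negative gain vector over channels, giving the classifier a learnable
  spatial code analogous to somatotopy over the sensorimotor cortex.

Bursts are Hann-windowed band-pass-filtered Gaussian noise carriers.  Their
amplitude is calibrated against the generator's own band-noise statistics so
that ``event_snr`` is the time-mean channel-mean z of the normalized
high-gamma feature over the burst (the instantaneous profile is Hann-shaped,
peaking at twice that value).  The first half of the channels is labelled
"motor", the second half "sensory"; the share of class-discriminative gain
carried by the motor half is configurable, which enables the motor-only /
sensory-only ablation contrast.

Everything is deterministic given (config, seed): the same configuration and
inputs reproduce outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from . import hge as hge_mod
from .hge import FilterSpec
from .recordings import COMMANDS, RawRecording, TranscriptEvent, validate_transcript

# Seed salts: distinct RNG streams per generator function, all derived from
# the single config seed.
_SALT_GAINS = 0
_SALT_SESSION = 1
_SALT_TRAINING = 2
_SALT_CALIBRATION = 3
_SALT_PROBE = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic signal generator.

    ``event_snr`` is the target time-mean channel-mean z (in
    silence-normalized HGE units) of a burst; the per-channel profile is
    ``event_snr * gain_matrix`` scaled by a Hann envelope of mean 1.
    """

    n_channels: int = 60
    sample_rate: float = 1000.0
    noise_exponent: float = 1.0  # 1/f slope of the background
    line_noise_hz: float = 120.0
    line_noise_amp: float = 1.0  # sinusoid amplitude, units of noise sd
    command_set: tuple[str, ...] = COMMANDS
    burst_gain_matrix: np.ndarray | None = None  # (n_channels, 6), mean 1/command
    burst_duration_s: float = 0.8
    event_snr: float = 3.5
    inter_command_interval_s: float = 7.0  # mean onset-to-onset interval
    motor_info_share: float = 0.75  # share of discriminative gain on motor half
    disc_share: float = 0.7  # discriminative vs shared burst gain
    drift_sd: float = 0.25  # sd of slow shared log-power modulation (ln units)
    drift_timescale_s: float = 8.0  # correlation time of the slow drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sample_rate <= 2 * 170.0:
            raise ValueError("sample_rate must exceed twice the 170-Hz band edge")
        if len(set(self.command_set)) != 6:
            raise ValueError("command_set must hold exactly 6 distinct labels")
        if self.burst_gain_matrix is not None:
            g = np.asarray(self.burst_gain_matrix)
            if g.shape != (self.n_channels, 6):
                raise ValueError("burst_gain_matrix must be n_channels x 6")
            if np.any(g < 0):
                raise ValueError("burst_gain_matrix must be non-negative")
        if not 0.0 <= self.motor_info_share <= 1.0:
            raise ValueError("motor_info_share must be in [0, 1]")

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))

    def variant(self, seed: int) -> "GeneratorConfig":
        """Same simulated participant, new noise realization.

        Freezes the burst gain matrix (the participant's spatial code) so
        that recordings generated on different "days" remain decodable by a
        model trained on this configuration, then swaps the seed.
        """
        return replace(self, seed=seed, burst_gain_matrix=gain_matrix(self))


@dataclass(frozen=True)
class TrainingTrial:
    """One cue-locked word-production trial."""

    recording: RawRecording
    cue_onset_s: float
    label: str
    speech_onset_s: float
    day_id: str


def gain_matrix(config: GeneratorConfig) -> np.ndarray:
    """Per-channel x per-command burst gain, channel-mean 1 for each command.

    The matrix mixes a shared (command-independent) component with a
    command-specific discriminative component; the discriminative mass on
    the motor half of the channels is ``motor_info_share``.
    """
    if config.burst_gain_matrix is not None:
        return np.asarray(config.burst_gain_matrix, dtype=float)
    rng = config.rng(_SALT_GAINS)
    n_ch, n_cmd = config.n_channels, len(config.command_set)
    common = rng.gamma(2.0, 1.0, n_ch)
    common /= common.mean()
    disc = rng.gamma(2.0, 1.0, (n_ch, n_cmd))
    half = n_ch // 2
    if 0 < half < n_ch:
        disc[:half] /= max(disc[:half].mean(), 1e-12)
        disc[half:] /= max(disc[half:].mean(), 1e-12)
        disc[:half] *= 2.0 * config.motor_info_share
        disc[half:] *= 2.0 * (1.0 - config.motor_info_share)
    g = (1.0 - config.disc_share) * common[:, None] + config.disc_share * disc
    g /= g.mean(axis=0, keepdims=True)
    return g


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    sample_rate: float, exponent: float,
) -> np.ndarray:
    """Unit-variance 1/f^exponent Gaussian noise per channel (FFT shaping)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _noise_field(config: GeneratorConfig, rng: np.random.Generator,
                 n_samples: int) -> np.ndarray:
    """Background = drift-modulated 1/f noise + per-channel-phase line noise.

    The slow modulation is a channel-shared multiplicative gain
    exp(drift_sd/2 * u(t)) with u a unit-sd process of correlation time
    ``drift_timescale_s``; it shifts the log band power by drift_sd * u(t),
    emulating the slow excitability drifts that dominate the 10-s baseline
    variance of real recordings.
    """
    x = _pink_noise(rng, config.n_channels, n_samples,
                    config.sample_rate, config.noise_exponent)
    if config.drift_sd > 0:
        white = rng.standard_normal(n_samples)
        fc = 1.0 / config.drift_timescale_s
        sos = sps.butter(2, fc, btype="lowpass", fs=config.sample_rate,
                         output="sos")
        u = sps.sosfiltfilt(sos, white)
        sd = u.std()
        if sd > 0:
            u /= sd
        x *= np.exp((config.drift_sd / 2.0) * u)[None, :]
    t = np.arange(n_samples) / config.sample_rate
    phases = rng.uniform(0, 2 * np.pi, config.n_channels)
    x += config.line_noise_amp * np.sin(
        2 * np.pi * config.line_noise_hz * t[None, :] + phases[:, None]
    )
    return x


def _band_noise_stats(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (sigma, s_log) of the background in the analysis band.

    sigma: per-channel sd of the band-passed+notched background;
    s_log: per-channel sd of silence log-power frames.  Estimated once on a
    20-s probe realization with its own seed stream, so the calibration is a
    pure function of the configuration.
    """
    rng = config.rng(_SALT_PROBE)
    n = int(20.0 * config.sample_rate)
    x = _noise_field(config, rng, n)
    rec = RawRecording(samples=x, sample_rate=config.sample_rate)
    frames = hge_mod.extract_hge(rec, FilterSpec())
    keep = frames.warmup_mask()
    s_log = frames.values[:, keep].std(axis=1)
    sos = FilterSpec().sos(config.sample_rate)
    filt = sps.sosfilt(sos, x, axis=1)
    sigma = filt[:, int(config.sample_rate):].std(axis=1)
    return sigma, s_log


def _burst_envelopes(config: GeneratorConfig) -> np.ndarray:
    """Per-command amplitude envelopes hitting the event_snr calibration.

    ``event_snr`` is the time-mean channel-mean z of a burst: the target
    instantaneous z profile on channel ch for command c is

        z(ch, c, t) = event_snr * gain[ch, c] * 2 * hann(t)

    whose time average over the burst is event_snr * gain (the Hann window
    has mean 1/2).  Adding band noise of sd a on top of background band
    noise of sd sigma lifts the log-power frame by log(1 + a^2/sigma^2);
    dividing by the silence log-power sd s_log gives z, so the required
    carrier amplitude is a(t) = sigma * sqrt(exp(z(t) * s_log) - 1).

    Returns (n_commands, n_channels, n_burst_samples).
    """
    n_burst = int(round(config.burst_duration_s * config.sample_rate))
    n_cmd = len(config.command_set)
    if config.event_snr <= 0:
        return np.zeros((n_cmd, config.n_channels, n_burst))
    sigma, s_log = _band_noise_stats(config)
    z_peak = 2.0 * config.event_snr * gain_matrix(config)  # (n_ch, n_cmd)
    hann = np.hanning(n_burst)
    zprof = z_peak.T[:, :, None] * hann[None, None, :]  # (cmd, ch, t)
    return sigma[None, :, None] * np.sqrt(
        np.expm1(zprof * s_log[None, :, None])
    )


def _make_burst(config: GeneratorConfig, rng: np.random.Generator,
                envelope: np.ndarray) -> np.ndarray:
    """One band-limited burst, (n_channels, n_burst) samples.

    Carriers are independent per channel, band-passed to 70-170 Hz and
    normalized to unit sd, then shaped by the per-channel amplitude
    envelope.
    """
    sr = config.sample_rate
    n_burst = envelope.shape[1]
    pre = int(round(0.5 * sr))  # pre-roll swallows the filter transient
    carrier = rng.standard_normal((config.n_channels, n_burst + pre))
    sos = sps.butter(4, (70.0, 170.0), btype="bandpass", fs=sr, output="sos")
    carrier = sps.sosfilt(sos, carrier, axis=1)[:, pre:]
    sd = carrier.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    carrier /= sd
    return envelope * carrier


def _plan_events(
    config: GeneratorConfig,
    rng: np.random.Generator,
    duration_s: float,
    command_sequence: Sequence[str] | None,
) -> list[TranscriptEvent]:
    """Lay out non-overlapping events with jittered inter-onset intervals."""
    dur = config.burst_duration_s
    t_first = 12.0  # past the 10-s baseline buffer warm-up
    t_last = duration_s - dur - 1.0
    min_gap = max(dur + 1.0, 2.7)  # floor: no overlap, clears the refractory
    events: list[TranscriptEvent] = []
    t = t_first
    if command_sequence is not None:
        for label in command_sequence:
            if label not in config.command_set:
                raise ValueError(f"unknown command {label!r}")
            if t > t_last:
                raise ValueError(
                    f"duration {duration_s}s too short for "
                    f"{len(command_sequence)} events"
                )
            events.append(TranscriptEvent(label, round(t, 3), round(t + dur, 3)))
            gap = max(min_gap, config.inter_command_interval_s * rng.uniform(0.7, 1.3))
            t += gap
    else:
        while t <= t_last:
            label = config.command_set[rng.integers(len(config.command_set))]
            events.append(TranscriptEvent(label, round(t, 3), round(t + dur, 3)))
            gap = max(min_gap, config.inter_command_interval_s * rng.uniform(0.7, 1.3))
            t += gap
    validate_transcript(events)
    return events


def _inject_events(
    config: GeneratorConfig,
    rng: np.random.Generator,
    samples: np.ndarray,
    events: Sequence[TranscriptEvent],
    envelopes: np.ndarray,
) -> None:
    cmd_index = {c: i for i, c in enumerate(config.command_set)}
    sr = config.sample_rate
    for ev in events:
        i0 = int(round(ev.onset_s * sr))
        burst = _make_burst(config, rng, envelopes[cmd_index[ev.label]])
        samples[:, i0:i0 + burst.shape[1]] += burst


def generate_session(
    config: GeneratorConfig,
    duration_s: float,
    command_sequence: Sequence[str] | None = None,
) -> tuple[RawRecording, list[TranscriptEvent]]:
    """Free-paced usage session: background noise plus self-paced commands.

    Returns the raw recording and the ground-truth transcript of every
    embedded command event (onset = burst onset, offset = burst end).
    """
    if duration_s <= 12.0:
        raise ValueError("duration_s must exceed 12 s (baseline warm-up)")
    rng = config.rng(_SALT_SESSION)
    n = int(round(duration_s * config.sample_rate))
    samples = _noise_field(config, rng, n)
    events = _plan_events(config, rng, duration_s, command_sequence)
    if events and config.event_snr > 0:
        envelopes = _burst_envelopes(config)
        _inject_events(config, rng, samples, events, envelopes)
    rec = RawRecording(samples=samples, sample_rate=config.sample_rate)
    return rec, events


def generate_training_corpus(
    config: GeneratorConfig,
    n_trials_per_class: int,
    n_days: int = 3,
    trial_duration_s: float = 6.0,
    cue_onset_s: float = 2.5,
) -> list[TrainingTrial]:
    """Cue-locked word-production trials, exactly balanced across classes.

    Each trial holds >= 0.8 s of burst-free pre-cue signal (the whole
    pre-cue span is silence), a cue time, and a single command burst whose
    speech onset follows the cue by a 0.3-0.7 s reaction delay.  Trials are
    assigned round-robin to ``n_days`` pseudo-days for holdout validation.
    """
    if n_trials_per_class < 1:
        raise ValueError("n_trials_per_class must be >= 1")
    rng = config.rng(_SALT_TRAINING)
    envelopes = _burst_envelopes(config)
    n_samp = int(round(trial_duration_s * config.sample_rate))
    trials: list[TrainingTrial] = []
    for rep in range(n_trials_per_class):
        day = f"day{rep % n_days:02d}"
        for label in config.command_set:
            samples = _noise_field(config, rng, n_samp)
            onset = cue_onset_s + rng.uniform(0.3, 0.7)
            if config.event_snr > 0:
                ev = TranscriptEvent(label, onset, onset + config.burst_duration_s)
                _inject_events(config, rng, samples, [ev], envelopes)
            rec = RawRecording(samples=samples, sample_rate=config.sample_rate)
            trials.append(TrainingTrial(rec, cue_onset_s, label, onset, day))
    return trials


def generate_calibration_recording(
    config: GeneratorConfig,
    n_cues: int,
    cue_interval_s: float = 2.0,
    first_cue_s: float = 1.0,
) -> tuple[RawRecording, np.ndarray]:
    """Noise-only recording with marked cue onsets for silence statistics.

    Every 0.8-s pre-cue window is silence by construction (the whole
    recording is), mirroring the pre-stimulus quiet period of a syllable
    repetition task used for one-off normalization.
    """
    if n_cues < 1:
        raise ValueError("n_cues must be >= 1")
    rng = config.rng(_SALT_CALIBRATION)
    duration = first_cue_s + cue_interval_s * n_cues
    n = int(round(duration * config.sample_rate))
    samples = _noise_field(config, rng, n)
    rec = RawRecording(samples=samples, sample_rate=config.sample_rate)
    cues = first_cue_s + cue_interval_s * np.arange(n_cues)
    return rec, cues
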