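"""Detection: integral signal, prominence, streaming/offline equivalence
against an independently coded per-update reference, and window assembly."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

import speechbci as sb
from speechbci.detection import (DetectorConfig, StreamingDetector,
                                 _is_local_max, detection_signal,
                                 peak_prominence, stream_detect)
from speechbci.hge import HgeFrames


def make_frames(values: np.ndarray, normalized: bool = True) -> HgeFrames:
    times = 0.05 + 0.01 * np.arange(values.shape[1])
    return HgeFrames(values=values, frame_times_s=times, normalized=normalized)


def reference_detect(times, values, config: DetectorConfig):
    """Independent per-update scan: at every update, re-evaluate every strict
    local maximum inside the detection buffer using brute-force prominence
    (scipy cross-check) and plain numpy buffer statistics."""
    det, base = config.detection_steps, config.baseline_steps
    confirm = config.confirm_steps
    n = values.size
    live: dict[int, dict] = {}
    last_peak = -np.inf
    accepted, rejected = [], []
    for c in range(n):
        i_new = c - confirm
        if i_new >= 1 and _is_local_max(values, i_new, horizon=confirm):
            live[i_new] = {"blocked": False, "last": None}
        lo = max(0, c - det + 1)
        buf = values[lo:c + 1]
        bb = values[max(0, c - base + 1):c + 1]
        full = c >= base - 1
        bsd = bb.std() if full else np.nan
        bmin = bb.min() if full else np.nan
        for i in sorted(live):
            st = live[i]
            pos = i - lo
            if pos < 1:
                rejected.append((i, st))
                del live[i]
                continue
            prom = peak_prominence(buf, pos)
            st["last"] = (prom, bsd, bmin, values[i], times[c])
            if not full:
                continue
            if not (prom > config.prominence_factor * bsd
                    and values[i] - bmin >= config.rejection_factor * bsd):
                continue
            if times[i] - last_peak < config.refractory_s:
                st["blocked"] = True
                continue
            last_peak = times[i]
            accepted.append((times[i], prom, bsd, times[c]))
            del live[i]
    for i, st in sorted(live.items()):
        if st["last"] is not None:
            rejected.append((i, st))
    reasons = {}
    for i, st in rejected:
        prom, bsd, bmin, pv, _ = st["last"]
        if np.isnan(bsd):
            reasons[times[i]] = "warmup"
        elif st["blocked"]:
            reasons[times[i]] = "refractory"
        elif not prom > config.prominence_factor * bsd:
            reasons[times[i]] = "low_prominence"
        elif pv - bmin < config.rejection_factor * bsd:
            reasons[times[i]] = "below_baseline_floor"
        else:
            reasons[times[i]] = "refractory"
    return accepted, reasons


def noisy_signal_frames(seed: int, n_frames: int, n_channels: int = 4,
                        bursts=()):
    """Frames whose channel mean is fast noise over a slow (~0.2 Hz) drift,
    plus optional Hann bumps (t0, amplitude, width) — the background regime
    the detector's baseline-sd thresholds assume."""
    rng = np.random.default_rng(seed)
    sos = sps.butter(2, 0.004, output="sos")
    slow = sps.sosfiltfilt(sos, rng.standard_normal(n_frames + 2000))
    slow = slow / slow.std() * 0.8
    ch_mean = (0.1 * rng.standard_normal(n_frames + 2000) + slow)[2000:]
    for t0, amp, width in bursts:
        k0 = int(t0 * 100)
        prof = amp * np.hanning(int(width * 100))
        ch_mean[k0:k0 + prof.size] += prof
    values = np.tile(ch_mean, (n_channels, 1))
    return make_frames(values)


class TestDetectionSignal:
    def test_constant_input_passes_through(self):
        frames = make_frames(np.full((5, 300), 2.5))
        _, s = detection_signal(frames)
        assert np.allclose(s, 2.5)

    def test_single_channel_step_ramps_to_channel_fraction(self):
        values = np.zeros((4, 400))
        values[0, 200:] = 1.0
        frames = make_frames(values)
        t, s = detection_signal(frames)
        assert s[-1] == pytest.approx(0.25)
        ramp = s[(s > 1e-12) & (s < 0.25 - 1e-12)]
        assert 95 <= ramp.size <= 100  # linear rise across the 1-s window
        assert np.all(np.diff(ramp) > 0)

    def test_matches_independent_convolution(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal((6, 700))
        frames = make_frames(values)
        t, s = detection_signal(frames, drop_warmup=False)
        ch = values.mean(axis=0)
        expected = np.convolve(ch, np.ones(100) / 100, mode="valid")
        np.testing.assert_allclose(s, expected, atol=1e-12)

    def test_requires_normalized(self):
        frames = make_frames(np.zeros((2, 300)), normalized=False)
        with pytest.raises(ValueError):
            detection_signal(frames)


class TestPeakProminence:
    def test_isolated_peak(self):
        assert peak_prominence(np.array([0.0, 5.0, 0.0]), 1) == 5.0

    def test_saddle_bounded_by_higher_peak(self):
        s = np.array([0.0, 3.0, 1.0, 5.0, 0.0])
        assert peak_prominence(s, 1) == pytest.approx(2.0)
        assert peak_prominence(s, 3) == pytest.approx(5.0)

    def test_monotone_series_has_no_local_maxima(self):
        s = np.arange(5.0)
        assert not any(_is_local_max(s, i, horizon=5) for i in range(5))
        with pytest.raises(ValueError):
            peak_prominence(s, 2)

    def test_matches_scipy_on_random_series(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s = rng.standard_normal(200)
            peaks, _ = sps.find_peaks(s)
            expected = sps.peak_prominences(s, peaks)[0]
            got = [peak_prominence(s, int(p)) for p in peaks]
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestStreamDetect:
    def test_single_burst_detected_once_near_center(self):
        frames = noisy_signal_frames(1, 4000, bursts=[(25.0, 8.0, 0.8)])
        events = stream_detect(frames)
        acc = [e for e in events if e.accepted]
        assert len(acc) == 1
        assert abs(acc[0].peak_time_s - 25.4) <= 0.5
        assert acc[0].confirm_time_s >= acc[0].peak_time_s + 0.5

    def test_second_burst_in_refractory_rejected(self):
        frames = noisy_signal_frames(
            1, 4000, bursts=[(25.0, 8.0, 0.8), (27.0, 8.0, 0.8)])
        events = stream_detect(frames)
        acc = [e for e in events if e.accepted]
        assert len(acc) == 1
        assert abs(acc[0].peak_time_s - 25.4) <= 0.5
        assert any(e.rejection_reason == "refractory" for e in events
                   if not e.accepted and 26.5 < e.peak_time_s < 28.5)

    def test_threshold_monotonicity(self):
        frames = noisy_signal_frames(3, 6000,
                                     bursts=[(20.0, 8.0, 0.8),
                                             (30.0, 5.0, 0.8),
                                             (45.0, 2.5, 0.8)])
        counts = []
        for factor in (0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = DetectorConfig(prominence_factor=factor)
            counts.append(sum(e.accepted for e in stream_detect(frames, cfg)))
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_offline_matches_independent_reference(self, seed):
        frames = noisy_signal_frames(
            seed, 4500, bursts=[(18.0, 8.0, 0.8), (31.0, 5.0, 0.8)])
        cfg = DetectorConfig()
        times, values = detection_signal(frames, cfg)
        ref_acc, ref_reasons = reference_detect(times, values, cfg)
        events = stream_detect(frames, cfg)
        acc = [e for e in events if e.accepted]
        assert [(e.peak_time_s, e.confirm_time_s) for e in acc] == \
            [(t, c) for t, _, _, c in ref_acc]
        np.testing.assert_allclose([e.prominence for e in acc],
                                   [p for _, p, _, _ in ref_acc], atol=1e-9)
        got_reasons = {e.peak_time_s: e.rejection_reason for e in events
                       if not e.accepted}
        assert got_reasons == ref_reasons

    @pytest.mark.parametrize("chunk", [1, 7, 100, 1000])
    def test_streaming_detector_matches_offline(self, chunk):
        frames = noisy_signal_frames(
            5, 3000, bursts=[(16.0, 8.0, 0.8), (23.0, 6.0, 0.8)])
        offline = stream_detect(frames)
        det = StreamingDetector()
        for k in range(0, frames.n_frames, chunk):
            sub = HgeFrames(values=frames.values[:, k:k + chunk],
                            frame_times_s=frames.frame_times_s[k:k + chunk],
                            normalized=True)
            det.push(sub)
        det.finalize()
        key = lambda e: (round(e.peak_time_s, 6), e.rejection_reason,
                         e.accepted)
        assert sorted(map(key, det.events)) == sorted(map(key, offline))
        acc_s = [e for e in det.events if e.accepted]
        acc_o = [e for e in offline if e.accepted]
        np.testing.assert_allclose([e.prominence for e in acc_s],
                                   [e.prominence for e in acc_o], rtol=1e-9)

    def test_short_stream_raises(self):
        frames = make_frames(np.zeros((2, 500)))
        with pytest.raises(ValueError):
            stream_detect(frames)


class TestAssembleWindow:
    def test_detected_window_slice(self):
        frames = make_frames(np.arange(2 * 3500, dtype=float).reshape(2, 3500))
        w = sb.assemble_window(frames, 30.0, "detected")
        assert w.values.shape == (2, 250)
        t = frames.frame_times_s
        sel = np.flatnonzero((t > 28.0) & (t <= 30.5 + 1e-9))
        np.testing.assert_array_equal(w.values, frames.values[:, sel])

    def test_cued_equals_detected_on_same_interval(self):
        frames = make_frames(
            np.random.default_rng(0).normal(size=(3, 2000)))
        d = sb.assemble_window(frames, 12.0, "detected")
        c = sb.assemble_window(frames, 10.0, "cued")
        np.testing.assert_array_equal(d.values, c.values)

    def test_insufficient_frames_raises(self):
        frames = make_frames(np.zeros((2, 100)))
        with pytest.raises(ValueError):
            sb.assemble_window(frames, 2.0, "detected")

    def test_requires_normalized(self):
        frames = make_frames(np.zeros((2, 1000)), normalized=False)
        with pytest.raises(ValueError):
            sb.assemble_window(frames, 5.0, "detected")
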