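"""Decoder: architecture audit, scoring/registration semantics, training on
a small separable problem, saliency against a finite-difference oracle."""

from __future__ import annotations

import numpy as np
import pytest

import speechbci as sb
from speechbci import nn
from speechbci.decoder import (InceptionTimeNet, ModelSpec, TrainConfig,
                               build_model, classify, saliency, train)
from speechbci.detection import DecodeWindow
from speechbci.recordings import COMMANDS

TINY = ModelSpec(n_channels=3, n_blocks=1, modules_per_block=1, n_filters=4,
                 bottleneck_filters=4, n_frames=250)


def make_window(values: np.ndarray) -> DecodeWindow:
    return DecodeWindow(values=values, peak_time_s=10.0, mode="detected")


def single_channel_corpus(info: int, n_per_class: int, seed: int,
                          n_channels: int = 5):
    """Corpus where only channel `info` carries class information: each
    class is a distinct oscillation frequency, all channels unit variance."""
    rng = np.random.default_rng(seed)
    t = np.arange(250) / 100
    freqs = [2, 4, 7, 11, 16, 22]
    trials = []
    for rep in range(n_per_class):
        day = f"day{rep % 2:02d}"
        for k, label in enumerate(COMMANDS):
            x = rng.standard_normal((n_channels, 250))
            sig = 0.3 * rng.standard_normal(250) + 4.0 * np.sin(
                2 * np.pi * freqs[k] * t + rng.uniform(0, 2 * np.pi))
            x[info] = sig / sig.std()
            trials.append((make_window(x), label, day))
    return trials


def blob_windows(rng, n_per_class, n_channels=6, scale=1.0):
    """Separable toy corpus: each class lifts one channel pair by `scale`."""
    out = []
    for rep in range(n_per_class):
        day = f"day{rep % 2:02d}"
        for k, label in enumerate(COMMANDS):
            x = rng.standard_normal((n_channels, 250))
            x[k % n_channels, 100:180] += scale
            x[(k + 1) % n_channels, 100:180] += scale / 2
            out.append((make_window(x), label, day))
    return out


class TestArchitecture:
    def test_default_spec_matches_reference_inventory(self):
        model = build_model(ModelSpec(), seed=0)
        assert len(model.blocks) == 6
        for block in model.blocks:
            assert len(block.modules) == 3
            for mod in block.modules:
                assert tuple(c.kernel for c in mod.branch_convs) == (5, 11, 23)
                assert all(c.c_out == 32 for c in mod.branch_convs)
                assert mod.bottleneck.kernel == 1
                assert mod.bottleneck.c_out == 32
                assert mod.pool.kernel == 3
                assert mod.pool_conv.kernel == 1
                assert mod.c_out == 4 * 32 == 128

    def test_output_is_probability_simplex(self):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 3, 250))
        p = model.predict_proba(x)
        assert p.shape == (2, 6)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_builds_are_identical(self):
        x = np.random.default_rng(1).standard_normal((1, 3, 250))
        a = build_model(TINY, seed=5).predict_proba(x)
        b = build_model(TINY, seed=5).predict_proba(x)
        np.testing.assert_array_equal(a, b)
        c = build_model(TINY, seed=6).predict_proba(x)
        assert not np.array_equal(a, c)

    def test_input_shape_checked(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 4, 250)))

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_model(TINY, seed=3)
        x = np.random.default_rng(2).standard_normal((2, 3, 250))
        p = tmp_path / "model.npz"
        model.save(p)
        back = InceptionTimeNet.load(p)
        np.testing.assert_array_equal(back.predict_proba(x),
                                      model.predict_proba(x))


class _StubModel:
    """Duck-typed stand-in returning a fixed score vector."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)
        self.spec = ModelSpec(n_channels=2)

    def predict_proba(self, x):
        return self.scores[None, :]


class TestClassify:
    def test_registration_threshold_is_inclusive(self):
        window = make_window(np.zeros((2, 250)))
        scores = [0.55, 0.09, 0.09, 0.09, 0.09, 0.09]
        res = classify(_StubModel(scores), window)
        assert res.label == "up" and res.registered
        res2 = classify(_StubModel([0.54, 0.2, 0.1, 0.06, 0.05, 0.05]), window)
        assert not res2.registered

    def test_uniform_scores_not_registered(self):
        res = classify(_StubModel([1 / 6] * 6), make_window(np.zeros((2, 250))))
        assert not res.registered
        assert res.score == pytest.approx(1 / 6)

    def test_zero_threshold_registers_everything(self):
        res = classify(_StubModel([0.3, 0.2, 0.2, 0.1, 0.1, 0.1]),
                       make_window(np.zeros((2, 250))), threshold=0.0)
        assert res.registered

    def test_argmax_tie_breaks_to_lowest_index(self):
        res = classify(_StubModel([0.3, 0.3, 0.1, 0.1, 0.1, 0.1]),
                       make_window(np.zeros((2, 250))), threshold=0.0)
        assert res.label == "up"


class TestTraining:
    def test_learns_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        trials = blob_windows(rng, n_per_class=8, scale=2.0)
        spec = ModelSpec(n_channels=6, n_blocks=1, modules_per_block=2,
                         n_filters=8, bottleneck_filters=8)
        model = build_model(spec, seed=0)
        cfg = TrainConfig(holdout_day="day01", max_epochs=20, patience=20,
                          seed=0, batch_size=16, learning_rate=1e-2)
        report = train(model, trials, cfg)
        assert report.holdout_accuracy >= 0.9
        assert report.confusion.sum() == 24
        assert set(report.per_class_accuracy) == set(COMMANDS)

    def test_missing_class_raises(self):
        rng = np.random.default_rng(0)
        trials = [t for t in blob_windows(rng, 2)
                  if not (t[1] == "up" and t[2] == "day00")]
        model = build_model(ModelSpec(n_channels=6, n_blocks=1,
                                      modules_per_block=1, n_filters=4,
                                      bottleneck_filters=4), seed=0)
        with pytest.raises(ValueError, match="up"):
            train(model, trials, TrainConfig(holdout_day="day01",
                                             max_epochs=1))

    def test_single_day_raises(self):
        rng = np.random.default_rng(0)
        trials = [(w, l, "day00") for w, l, _ in blob_windows(rng, 1)]
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, trials, TrainConfig(holdout_day="day00",
                                             max_epochs=1))


class TestSaliency:
    def test_matches_finite_difference_oracle(self):
        """Per-channel saliency equals the brute-force L1 norm of central
        finite-difference loss gradients on a tiny model."""
        spec = ModelSpec(n_channels=2, n_blocks=1, modules_per_block=1,
                         n_filters=2, bottleneck_filters=2)
        model = build_model(spec, seed=1)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 250))
        window = make_window(x)
        got = saliency(model, window, "left")
        y = np.array([COMMANDS.index("left")])
        eps = 1e-5
        grad = np.zeros_like(x)
        for c in range(2):
            for t in range(250):
                old = x[c, t]
                x[c, t] = old + eps
                hi = nn.cross_entropy(model.forward(x[None]), y)[0]
                x[c, t] = old - eps
                lo = nn.cross_entropy(model.forward(x[None]), y)[0]
                x[c, t] = old
                grad[c, t] = (hi - lo) / (2 * eps)
        expected = np.abs(grad).sum(axis=1)
        np.testing.assert_allclose(got, expected, rtol=1e-3)

    def test_informative_channel_dominates(self):
        """With class information confined to one channel (a class-specific
        oscillation frequency; all channels unit variance so batch-norm does
        not rescale the comparison), that channel has the largest mean
        saliency once the decoder has actually learned the task."""
        trials = single_channel_corpus(info=2, n_per_class=16, seed=7)
        spec = ModelSpec(n_channels=5, n_blocks=1, modules_per_block=2,
                         n_filters=8, bottleneck_filters=8)
        model = build_model(spec, seed=1)
        report = train(model, trials,
                       TrainConfig(holdout_day="day01", max_epochs=60,
                                   patience=30, seed=0, learning_rate=3e-3,
                                   batch_size=16))
        assert report.holdout_accuracy >= 0.9  # localization presumes skill
        sal = np.mean([saliency(model, w, lab) for w, lab, d in trials
                       if d == "day01"], axis=0)
        assert sal.shape == (5,)
        assert int(np.argmax(sal)) == 2

    def test_unknown_label_raises(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            saliency(model, make_window(np.zeros((3, 250))), "jump")
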