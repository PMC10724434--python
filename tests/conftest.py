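"""Shared fixtures: small generator configurations and cached silence stats.

Session-scoped fixtures cache the expensive artifacts (calibration
statistics, generated sessions) so independent tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import speechbci as sb


@pytest.fixture(scope="session")
def default_config() -> sb.GeneratorConfig:
    return sb.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def small_config() -> sb.GeneratorConfig:
    """A 12-channel configuration for cheap unit tests."""
    return sb.GeneratorConfig(n_channels=12, seed=7)


@pytest.fixture(scope="session")
def default_stats(default_config) -> sb.SilenceStats:
    return sb.pipeline.calibration_stats(default_config)


@pytest.fixture(scope="session")
def small_stats(small_config) -> sb.SilenceStats:
    return sb.pipeline.calibration_stats(small_config)


@pytest.fixture(scope="session")
def short_session(default_config):
    """A 90-s default-SNR session with its transcript."""
    rec, events = sb.generate_session(default_config, 90.0)
    return rec, events


@pytest.fixture(scope="session")
def short_session_frames(short_session, default_stats) -> sb.HgeFrames:
    rec, _ = short_session
    return sb.pipeline.compute_session_frames(rec, default_stats)
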