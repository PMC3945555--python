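"""Shared fixtures.

The heavyweight fixtures (a full synthetic dataset with pipeline features)
are session-scoped so the end-to-end classification, recovery, and tendency
tests reuse one computation.
"""

import numpy as np
import pytest

import wheezescan as ws
from wheezescan.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def sine_frame():
    """Unit-amplitude sinusoid exactly on bin 25 (430.66 Hz)."""
    t = np.arange(ws.FRAME_LEN) / ws.NOMINAL_RATE
    f = 25 * ws.BIN_HZ
    return ws.AudioFrame(samples=np.sin(2 * np.pi * f * t))


@pytest.fixture(scope="session")
def synth_study():
    """200-frame synthetic dataset with features extracted once.

    Returns (frames, labels, truths, features, config, pipeline_config).
    """
    cfg = SynthConfig(n_frames=200, wheeze_fraction=0.5, snr_db=15.0, seed=11)
    frames, labels, truths, _ = generate_dataset(cfg)
    pcfg = ws.PipelineConfig()
    feats = ws.extract_frame_features(frames, pcfg)
    return frames, labels, truths, feats, cfg, pcfg
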