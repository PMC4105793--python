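"""Shared fixtures: canonical beats, trains and conversion models."""

import numpy as np
import pytest

import pulsedecomp.signal as psig
from pulsedecomp import (
    BeatTrainSpec,
    ComponentSpec,
    ConversionModel,
    synthesize_central_pulse,
)
from pulsedecomp.signal import BeatSegment

FS = 500.0

# study-scale conversion models: population gains with the reference
# patient's fitted offsets
PATIENT38_SYSTOLE = ConversionModel(gain=100.0, offset=0.945, parameter="p2p1")
PATIENT38_PP = ConversionModel(gain=0.2, offset=0.0025, parameter="t13")


def beat_from_central(spec: ComponentSpec, fs: float = FS, extended: bool = False):
    """Build a BeatSegment from a synthesized central pulse.

    Mirrors the device chain: the envelope is emitted as a first-difference
    sensor stream, then the envelope and second derivative are
    reconstructed exactly as :func:`pulsedecomp.signal.detect_beats` does.
    """
    stream, truth = synthesize_central_pulse(spec, fs)
    env = stream.samples
    d1 = np.diff(env, prepend=0.0) * fs
    d1s = psig.WaveformStream(d1, fs, "d1")
    env_r = psig.integrate(d1s, detrend=False).samples
    d2 = psig.differentiate(d1s).samples
    beat = BeatSegment(0, env.size, fs, env_r, d1, d2)
    return beat, truth, stream


@pytest.fixture
def typical_spec():
    """Typical adult beat: normal ejection time, mid-range delays."""
    return ComponentSpec(lvet_ms=300.0, t12_ms=100.0, t13_ms=280.0)


@pytest.fixture
def short_lvet_spec():
    """Shortened ejection time resolving all five component pulses."""
    return ComponentSpec(lvet_ms=140.0, t12_ms=100.0, t13_ms=280.0, n_harmonics=2)


@pytest.fixture
def coupling():
    return (PATIENT38_SYSTOLE, PATIENT38_PP)


def drifting_train(
    n_beats: int = 60,
    noise_sd: float = 0.0,
    seed: int = 7,
    mean_ibi_ms: float = 900.0,
    ibi_sd_ms: float = 50.0,
) -> BeatTrainSpec:
    """Beat train with sinusoidally drifting systole (110-140 mmHg) and
    pulse pressure (40-60 mmHg), the package's reference test condition."""
    t = np.arange(n_beats) * mean_ibi_ms / 1000.0
    systole = 125.0 + 15.0 * np.sin(2 * np.pi * t / 120.0)
    pp = 50.0 + 10.0 * np.sin(2 * np.pi * t / 80.0 + 1.0)
    return BeatTrainSpec(
        n_beats=n_beats,
        mean_ibi_ms=mean_ibi_ms,
        ibi_sd_ms=ibi_sd_ms,
        systole_series=systole,
        diastole_series=systole - pp,
        coupling=(PATIENT38_SYSTOLE, PATIENT38_PP),
        noise_sd=noise_sd,
        seed=seed,
    )
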