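"""Shared fixtures: canonical synthetic cases used across the suite."""

import numpy as np
import pytest

from mrlap.synth import NoiseConfig, PatientTruth, render_spectrogram, simulate_envelope


def make_truth(lap=10.0, tau=0.05, p_systolic=None, v_peak=None, c=1.0, **kw):
    """A physiologically consistent PatientTruth with Bernoulli-matched peak."""
    if p_systolic is None:
        p_systolic = lap + 95.0
    if v_peak is None:
        v_peak = float(np.sqrt(p_systolic - lap) / 2.0)
    return PatientTruth(
        lap_true=lap,
        tau=tau,
        p_systolic=p_systolic,
        v_peak=v_peak,
        eccentricity_factor=c,
        **kw,
    )


@pytest.fixture
def reference_truth():
    """LAP 10 mmHg, tau 50 ms — the canonical worked case."""
    return make_truth(lap=10.0, tau=0.05)


@pytest.fixture
def noiseless_spectrogram(reference_truth):
    env = simulate_envelope(reference_truth, dt=0.001)
    return render_spectrogram(env, dv=0.02, noise=NoiseConfig.none())


@pytest.fixture
def noisy_spectrogram(reference_truth):
    env = simulate_envelope(reference_truth, dt=0.001)
    return render_spectrogram(env, dv=0.02, noise=NoiseConfig(), rng=42)
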