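import numpy as np
import pytest

from bcinet import CouplingSpec, EEGRecording, make_var_model, simulate_eeg
from bcinet.connectivity import VARFit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_varfit(rng, n=4, p=2, radius=0.9, noise_cov=None):
    """Random stable VAR coefficients rescaled to a given companion radius."""
    coeffs = rng.normal(scale=0.3, size=(p, n, n))
    comp = np.zeros((n * p, n * p))
    comp[:n] = np.concatenate(coeffs, axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    rho = np.max(np.abs(np.linalg.eigvals(comp)))
    if rho > 0:
        s = radius / rho
        coeffs = np.stack([coeffs[k] * s ** (k + 1) for k in range(p)])
    if noise_cov is None:
        M = rng.normal(size=(n, n))
        noise_cov = M @ M.T / n + np.eye(n)
    return VARFit(coeffs=coeffs, noise_cov=noise_cov, nobs=10_000)


@pytest.fixture
def chain3_spec():
    """Three-channel causal chain x1 -> x2 -> x3 with alpha resonators."""
    return CouplingSpec(
        n_channels=3,
        edges=(("x1", "x2", 0.5), ("x2", "x3", 0.5)),
        oscillator_freq=10.0,
        oscillator_damping=0.95,
    )


@pytest.fixture
def chain3_model(chain3_spec):
    return make_var_model(chain3_spec, fs=512.0)


@pytest.fixture
def montage22_recording(rng):
    """Short synthetic recording on the full 22-channel montage."""
    from bcinet import DEFAULT_COUPLING

    model = make_var_model(DEFAULT_COUPLING, fs=128.0)
    return simulate_eeg(
        model, 128 * 30, seed=7, lesion_side="L", subject_id="S1", session="pre"
    )


def sine_recording(freq, fs=512.0, duration=30.0, n_channels=2, labels=None):
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n_channels))
    return EEGRecording(data=data, labels=labels, fs=fs, lesion_side="L")
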