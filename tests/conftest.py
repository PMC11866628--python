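"""Shared fixtures: small fast synthetic recordings and graphs."""

import numpy as np
import pytest

from eegtopo.recording import Recording
from eegtopo.synth import CouplingSpec, Oscillator, generate_recording


@pytest.fixture(scope="session")
def small_labels() -> tuple[str, ...]:
    return tuple(f"ch{i:02d}" for i in range(6))


@pytest.fixture(scope="session")
def coupled_spec(small_labels) -> CouplingSpec:
    """6 channels, one 10-Hz quadrature-lagged pair, modest noise."""
    return CouplingSpec(
        n_channels=6,
        fs=250.0,
        duration=60.0,
        oscillators=(
            Oscillator(10.0, 2.0, small_labels[:2], phase_lag=np.pi / 2, strength=0.9),
        ),
        noise_level=0.5,
        labels=small_labels,
    )


@pytest.fixture(scope="session")
def coupled_recording(coupled_spec) -> Recording:
    return generate_recording(coupled_spec, seed=1234)


@pytest.fixture(scope="session")
def noise_spec(small_labels) -> CouplingSpec:
    """6 channels of independent 1/f noise only."""
    return CouplingSpec(
        n_channels=6, fs=250.0, duration=60.0, oscillators=(),
        noise_level=1.0, labels=small_labels,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_weight_matrix(n: int, seed: int) -> np.ndarray:
    """Symmetric positive weights with zero diagonal, entries in (0, 1)."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(0.01, 0.99, size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return w
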