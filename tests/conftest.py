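import numpy as np
import pytest

from aposignal import (
    CANONICAL_GRID,
    Spectrum,
    default_visual_system,
    flat_irradiance,
)


@pytest.fixture(scope="session")
def vs():
    return default_visual_system()


@pytest.fixture(scope="session")
def illum():
    return flat_irradiance()


@pytest.fixture
def flat_reflectance():
    def make(level, label="flat"):
        return Spectrum(
            CANONICAL_GRID,
            np.full(CANONICAL_GRID.size, float(level)),
            kind="reflectance",
            label=label,
        )

    return make


@pytest.fixture
def smooth_reflectance():
    """Random smooth (Gaussian-mixture) reflectance generator."""

    def make(rng, label="smooth"):
        w = CANONICAL_GRID
        v = np.full(w.size, rng.uniform(0.02, 0.1))
        for _ in range(rng.integers(1, 4)):
            v = v + rng.uniform(0.05, 0.5) * np.exp(
                -0.5 * ((w - rng.uniform(350, 650)) / rng.uniform(20, 80)) ** 2
            )
        return Spectrum(w, np.clip(v, 1e-4, 1.0), kind="reflectance", label=label)

    return make


def rnl_distance_oracle(delta_f, omega):
    """Generic receptor-noise-limited chromatic distance for n receptors.

    Mahalanobis distance of delta_f projected onto the hyperplane
    orthogonal to uniform (brightness) shifts, with independent receptor
    noise sd omega_i -- an independent route to the pairwise expansion.
    """
    df = np.asarray(delta_f, dtype=float)
    a = 1.0 / np.asarray(omega, dtype=float) ** 2
    return float(np.sqrt(np.dot(a, df**2) - np.dot(a, df) ** 2 / a.sum()))
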